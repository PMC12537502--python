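"""Per-cell-type pseudobulk ACR calling with empirical permutation FDR.

The pipeline mirrors bulk ATAC peak calling adapted to Tn5 insertion sites:
each insertion is extended to a 150 bp interval centred on the site
(shift −75, extsize 150), candidate peaks are maximal runs above a Poisson
background quantile, and the decisive filter is an empirical FDR computed
against permuted intervals placed in mappable, non-exonic space — candidates
are retained above the minimum Tn5 density at which the permutation FDR
stays below 0.05.  Surviving peaks are filtered on nucleosome overlap and
mean fragment size, resized to 500 bp summit windows, and merged across cell
types into an atlas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from . import intervals as iv
from .core import GenomeRef


@dataclass
class AcrCallParams:
    extsize: int = 150
    shift: int = -75
    fdr: float = 0.05
    n_perm_sets: int = 1
    window: int = 500
    nuc_overlap_max: float = 0.5
    frag_size_max: float = 150.0
    candidate_p: float = 1e-5
    merge_gap: int = 150


# ---------------------------------------------------------------- pileup

def pseudobulk_pileup(positions: np.ndarray, chrom_len: int, params: AcrCallParams = AcrCallParams()) -> np.ndarray:
    """Per-base coverage from insertion sites, each extended to 150 bp.

    An insertion at p contributes the interval [p+shift, p+shift+extsize),
    clipped to the chromosome; coverage is the count of overlapping
    intervals at each base.
    """
    cov = np.zeros(chrom_len + 1, dtype=np.int64)
    if positions is None or len(positions) == 0:
        return cov[:-1]
    pos = np.asarray(positions, dtype=np.int64)
    s = np.clip(pos + params.shift, 0, chrom_len)
    e = np.clip(pos + params.shift + params.extsize, 0, chrom_len)
    np.add.at(cov, s, 1)
    np.add.at(cov, e, -1)
    return np.cumsum(cov)[:-1]


# ---------------------------------------------------------------- candidates

def call_candidate_peaks(
    coverage: dict[str, np.ndarray],
    n_insertions: int,
    genome_len: int,
    params: AcrCallParams = AcrCallParams(),
) -> pd.DataFrame:
    """Maximal runs where coverage exceeds the Poisson background quantile.

    The null per-base coverage is Poisson with mean ``rate × extsize`` where
    rate is the global per-bp insertion rate; runs closer than 150 bp are
    merged; summit = leftmost coverage argmax within the run.
    """
    rows = []
    if n_insertions == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "summit"])
    mu = n_insertions / genome_len * params.extsize
    thresh = stats.poisson.isf(params.candidate_p, mu)
    for chrom, cov in coverage.items():
        above = cov > thresh
        if not above.any():
            continue
        d = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if above[0]:
            starts = np.concatenate([[0], starts])
        if above[-1]:
            ends = np.concatenate([ends, [cov.size]])
        ms, me, _ = iv.merge(starts, ends, gap=params.merge_gap)
        for s, e in zip(ms, me):
            summit = s + int(np.argmax(cov[s:e]))
            rows.append((chrom, int(s), int(e), summit))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "summit"])


# ---------------------------------------------------------------- densities

def _count_in_intervals(sorted_pos: np.ndarray, starts, ends) -> np.ndarray:
    lo = np.searchsorted(sorted_pos, starts, side="left")
    hi = np.searchsorted(sorted_pos, ends, side="left")
    return hi - lo


def tn5_density(candidates: pd.DataFrame, insertions: pd.DataFrame) -> np.ndarray:
    """Insertions per bp of span, per candidate."""
    dens = np.zeros(len(candidates))
    for chrom, sub in candidates.groupby("chrom"):
        pos = np.sort(insertions.loc[insertions["chrom"] == chrom, "pos"].to_numpy())
        n = _count_in_intervals(pos, sub["start"].to_numpy(), sub["end"].to_numpy())
        dens[candidates.index.get_indexer(sub.index)] = n / (sub["end"] - sub["start"]).to_numpy()
    return dens


def fdr_threshold(real: np.ndarray, perm: np.ndarray, fdr: float = 0.05):
    """Minimum density t* with FDR(t) = #{perm ≥ t} / #{real ≥ t} < fdr.

    Scans candidate thresholds (the real densities) from high to low and
    returns the smallest passing one, or None if no threshold passes.
    """
    if np.asarray(real).size == 0:
        return None
    return _fdr_threshold_multi(real, perm, 1, fdr)


def sample_permuted_intervals(widths: np.ndarray, genome: GenomeRef, rng) -> pd.DataFrame:
    """Uniformly place one interval per requested width in mappable∖exonic space."""
    spaces = []
    for chrom in genome.chrom_sizes:
        ss, se = genome.sampling_space(chrom)
        for s, e in zip(ss, se):
            spaces.append((chrom, int(s), int(e)))
    rows = []
    for w in np.asarray(widths, dtype=np.int64):
        fit = [(c, s, e) for c, s, e in spaces if e - s >= w]
        if not fit:
            raise ValueError("insufficient mappable non-exonic space for permutation")
        caps = np.array([e - s - w + 1 for _, s, e in fit], dtype=float)
        j = rng.choice(len(fit), p=caps / caps.sum())
        c, s, e = fit[j]
        off = int(rng.integers(0, e - s - w + 1))
        rows.append((c, s + off, s + off + w))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def permutation_fdr_filter(
    candidates: pd.DataFrame,
    insertions: pd.DataFrame,
    genome: GenomeRef,
    params: AcrCallParams = AcrCallParams(),
    seed: int = 0,
):
    """Retain candidates by the empirical permutation FDR rule.

    For each candidate an equal number of random same-width intervals is
    placed in mappable non-exonic space; real and permuted Tn5 densities
    define the FDR curve and candidates with density ≥ t* are kept.

    Returns (retained DataFrame with ``density``, threshold or None).
    """
    rng = np.random.default_rng(seed)
    cand = candidates.reset_index(drop=True)
    real = tn5_density(cand, insertions)
    perm_dens = []
    widths = (cand["end"] - cand["start"]).to_numpy()
    for _ in range(params.n_perm_sets):
        perm = sample_permuted_intervals(widths, genome, rng)
        perm_dens.append(tn5_density(perm, insertions))
    perm_all = np.concatenate(perm_dens) if perm_dens else np.array([])
    # compare each permutation set at its own scale: densities pooled, FDR
    # computed with per-set normalization
    n_sets = max(params.n_perm_sets, 1)
    t_star = _fdr_threshold_multi(real, perm_all, n_sets, params.fdr)
    out = cand.copy()
    out["density"] = real
    if t_star is None:
        return out.iloc[0:0], None
    return out[out["density"] >= t_star].reset_index(drop=True), t_star


def _fdr_threshold_multi(real, perm, n_sets, fdr):
    real = np.asarray(real, dtype=float)
    perm_sorted = np.sort(np.asarray(perm, dtype=float))
    best = None
    for t in np.unique(real)[::-1]:
        n_real = int((real >= t).sum())
        n_perm = (perm_sorted.size - np.searchsorted(perm_sorted, t, "left")) / n_sets
        if n_real > 0 and n_perm / n_real < fdr:
            best = float(t)
    return best


# ---------------------------------------------------------------- refinement

def refine_and_filter(
    peaks: pd.DataFrame,
    nucleosomes: pd.DataFrame,
    insertions: pd.DataFrame,
    genome: GenomeRef,
    params: AcrCallParams = AcrCallParams(),
) -> pd.DataFrame:
    """Nucleosome / fragment-size filters and 500 bp summit windows.

    Drops peaks with >50% of their span under nucleosome calls or with mean
    overlapping fragment size >150 bp; survivors become
    ``[summit−250, summit+250)`` windows (clipped at chromosome ends with a
    flag).
    """
    half = params.window // 2
    keep_rows = []
    for chrom, sub in peaks.groupby("chrom"):
        nuc = nucleosomes[nucleosomes["chrom"] == chrom]
        frac = iv.coverage_fraction(
            sub["start"].to_numpy(), sub["end"].to_numpy(),
            nuc["start"].to_numpy(), nuc["end"].to_numpy(),
        )
        ins = insertions[insertions["chrom"] == chrom].sort_values("pos")
        pos = ins["pos"].to_numpy()
        fs = ins["frag_size"].to_numpy()
        cum = np.concatenate([[0], np.cumsum(fs)])
        lo = np.searchsorted(pos, sub["start"].to_numpy(), "left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), "left")
        n = hi - lo
        mean_fs = np.where(n > 0, (cum[hi] - cum[lo]) / np.maximum(n, 1), 0.0)
        ok = (frac <= params.nuc_overlap_max) & (mean_fs <= params.frag_size_max)
        clen = genome.chrom_sizes[chrom]
        for row, good in zip(sub.itertuples(), ok):
            if not good:
                continue
            s = row.summit - half
            e = row.summit + half
            clipped = s < 0 or e > clen
            keep_rows.append((chrom, max(0, s), min(e, clen), row.summit, clipped))
    return pd.DataFrame(keep_rows, columns=["chrom", "start", "end", "summit", "clipped"])


def merge_atlas(
    per_celltype: dict[str, pd.DataFrame],
    pooled_coverage: dict[str, np.ndarray],
    genome: GenomeRef,
    params: AcrCallParams = AcrCallParams(),
) -> pd.DataFrame:
    """Amalgamate per-cell-type 500 bp windows into one atlas.

    Overlapping windows are unified and re-centred on the pooled-coverage
    summit of the union span, yielding non-overlapping 500 bp ACRs.  The
    ``accessible_in`` column lists contributing cell types per merged ACR.
    """
    half = params.window // 2
    frames = []
    for ct, df in per_celltype.items():
        d = df.copy()
        d["cell_type"] = ct
        frames.append(d)
    allw = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "cell_type"]
    )
    rows = []
    for chrom, sub in allw.groupby("chrom"):
        ms, me, cid = iv.merge(sub["start"].to_numpy(), sub["end"].to_numpy())
        cov = pooled_coverage.get(chrom)
        clen = genome.chrom_sizes[chrom]
        cts = sub["cell_type"].to_numpy()
        for k in range(len(ms)):
            s, e = int(ms[k]), int(me[k])
            summit = s + int(np.argmax(cov[s:e])) if cov is not None else (s + e) // 2
            ws = summit - half
            we = summit + half
            if ws < 0:
                ws, we = 0, params.window
            if we > clen:
                ws, we = clen - params.window, clen
            members = sorted(set(cts[cid == k]))
            rows.append((chrom, ws, we, summit, ",".join(members)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "accessible_in"])
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    # enforce non-overlap after re-centring: shift any window that now
    # overlaps its predecessor
    for chrom, sub in out.groupby("chrom"):
        idx = sub.index.to_numpy()
        for a, b in zip(idx[:-1], idx[1:]):
            if out.at[b, "start"] < out.at[a, "end"] and out.at[b, "chrom"] == out.at[a, "chrom"]:
                shiftv = out.at[a, "end"] - out.at[b, "start"]
                out.at[b, "start"] += shiftv
                out.at[b, "end"] += shiftv
    out["id"] = [f"acr_{i}" for i in range(len(out))]
    return out


# ---------------------------------------------------------------- matrix

def build_peak_matrix(acrs: pd.DataFrame, insertions: pd.DataFrame, cells: pd.DataFrame):
    """Sparse (ACR × barcode) Tn5 insertion counts over QC-passing cells.

    Half-open intervals: an insertion on ``start`` counts, on ``end`` does
    not.  Barcodes absent from ``cells`` are skipped (count returned).
    """
    barcodes = cells["barcode"].tolist()
    col = {b: j for j, b in enumerate(barcodes)}
    n_skip = 0
    ii, jj, vv = [], [], []
    acrs_r = acrs.reset_index(drop=True)
    for chrom, sub in acrs_r.groupby("chrom"):
        ins = insertions[insertions["chrom"] == chrom]
        if len(ins) == 0:
            continue
        pos = ins["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        bcs = ins["barcode"].to_numpy()[order]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = np.searchsorted(pos, starts, "left")
        hi = np.searchsorted(pos, ends, "left")
        for ridx, l, h in zip(sub.index, lo, hi):
            for b in bcs[l:h]:
                j = col.get(b)
                if j is None:
                    n_skip += 1
                    continue
                ii.append(ridx)
                jj.append(j)
                vv.append(1)
    mat = sparse.coo_matrix(
        (vv, (ii, jj)), shape=(len(acrs_r), len(barcodes)), dtype=np.int64
    ).tocsr()
    mat.sum_duplicates()
    return mat, n_skip


def per_celltype_acr_stats(
    acrs: pd.DataFrame,
    insertions: pd.DataFrame,
    genome: GenomeRef,
    params: AcrCallParams = AcrCallParams(),
):
    """Per-cell-type Tn5 counts and maximum pileup coverage within each ACR.

    Returns (counts, max_cov, totals): ACR × cell-type DataFrames plus the
    per-cell-type total insertion counts used for per-million scaling.
    """
    cts = sorted(insertions["cell_type"].unique())
    n = len(acrs)
    counts = pd.DataFrame(0, index=range(n), columns=cts, dtype=np.int64)
    max_cov = pd.DataFrame(0.0, index=range(n), columns=cts)
    totals = pd.Series(0, index=cts, dtype=np.int64)
    acrs_r = acrs.reset_index(drop=True)
    for ct in cts:
        sub = insertions[insertions["cell_type"] == ct]
        totals[ct] = len(sub)
        for chrom, g in acrs_r.groupby("chrom"):
            pos = np.sort(sub.loc[sub["chrom"] == chrom, "pos"].to_numpy())
            cov = pseudobulk_pileup(pos, genome.chrom_sizes[chrom], params)
            lo = np.searchsorted(pos, g["start"].to_numpy(), "left")
            hi = np.searchsorted(pos, g["end"].to_numpy(), "left")
            counts.loc[g.index, ct] = hi - lo
            max_cov.loc[g.index, ct] = [
                float(cov[s:e].max()) if e > s else 0.0
                for s, e in zip(g["start"], g["end"])
            ]
    return counts, max_cov, totals


# ---------------------------------------------------------------- pipeline

def call_acrs(
    insertions: pd.DataFrame,
    cells: pd.DataFrame,
    genome: GenomeRef,
    nucleosomes: pd.DataFrame | None = None,
    params: AcrCallParams = AcrCallParams(),
    seed: int = 0,
):
    """Full per-cell-type calling → atlas merge → peak×cell matrix."""
    if nucleosomes is None:
        nucleosomes = pd.DataFrame(columns=["chrom", "start", "end"])
    genome_len = sum(genome.chrom_sizes.values())
    ct_of = dict(zip(cells["barcode"], cells["cell_type"]))
    ins = insertions[insertions["barcode"].map(ct_of).notna()].copy()
    if "cell_type" not in ins.columns:
        ins["cell_type"] = ins["barcode"].map(ct_of)
    per_ct = {}
    pooled_cov = {
        c: pseudobulk_pileup(
            ins.loc[ins["chrom"] == c, "pos"].to_numpy(), genome.chrom_sizes[c], params
        )
        for c in genome.chrom_sizes
    }
    for k, (ct, sub) in enumerate(ins.groupby("cell_type")):
        cov = {
            c: pseudobulk_pileup(
                sub.loc[sub["chrom"] == c, "pos"].to_numpy(), genome.chrom_sizes[c], params
            )
            for c in genome.chrom_sizes
        }
        cand = call_candidate_peaks(cov, len(sub), genome_len, params)
        if len(cand) == 0:
            continue
        kept, _t = permutation_fdr_filter(cand, sub, genome, params, seed=seed + 7919 * k)
        if len(kept) == 0:
            continue
        refined = refine_and_filter(kept, nucleosomes, sub, genome, params)
        if len(refined):
            per_ct[ct] = refined
    atlas = merge_atlas(per_ct, pooled_cov, genome, params)
    mat, _ = build_peak_matrix(atlas, ins, cells)
    return atlas, mat, per_ct
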