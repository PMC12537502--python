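"""Motif scanning and the three enrichment procedures.

PWM scanning uses an exact log-likelihood-ratio score threshold: the score
distribution under the background model is computed by dynamic programming
over the discretized per-position scores, and the threshold is the smallest
score whose background tail probability is ≤ the requested p (default 1e−5).
Pattern motifs (the six PRE classes) are matched literally / by IUPAC
expansion.  Enrichment: negative-binomial regression per (motif, cell type),
an exact binomial test against length-matched simulated control regions, and
a one-tailed hypergeometric test per motif family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import intervals as iv
from .core import GenomeRef

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MotifModel:
    id: str
    kind: str  # "pwm" | "pattern"
    pwm: np.ndarray | None = None  # 4×L probabilities (A,C,G,T)
    pattern: str = ""
    family: str = ""

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray, pseudocount: float = 0.5, family: str = ""):
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(motif_id, "pwm", pwm=counts / counts.sum(axis=0, keepdims=True), family=family)

    @classmethod
    def from_pattern(cls, motif_id: str, pattern: str, family: str = ""):
        return cls(motif_id, "pattern", pattern=pattern.upper(), family=family)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def pwm_scores(pwm: np.ndarray, background=None) -> np.ndarray:
    """Per-position log2 likelihood-ratio scores (4×L)."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return np.log2(np.asarray(pwm) / bg[:, None])


def pwm_threshold(pwm: np.ndarray, p_thresh: float = 1e-5, background=None, precision: float | None = None):
    """Exact score threshold: smallest s with P(score ≥ s | background) ≤ p.

    The background score distribution is built by dynamic programming over
    per-position scores discretized to ``precision``; the DP support is
    bounded by 4^L, so short motifs (≤10 bp) default to an effectively
    exact 1e−9 grid and longer ones to 1e−4.  Returns +inf when no score
    attains the tail probability (short motifs at stringent p).
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    sc = pwm_scores(pwm, bg)
    if precision is None:
        precision = 1e-9 if sc.shape[1] <= 10 else 1e-4
    units = np.round(sc / precision).astype(np.int64)
    dist: dict[int, float] = {0: 1.0}
    for j in range(sc.shape[1]):
        new: dict[int, float] = {}
        for s0, pr in dist.items():
            for b in range(4):
                key = s0 + units[b, j]
                new[key] = new.get(key, 0.0) + pr * bg[b]
        dist = new
    keys = np.array(sorted(dist, reverse=True))
    probs = np.array([dist[k] for k in keys])
    tail = np.cumsum(probs)
    ok = tail <= p_thresh + 1e-15
    if not ok.any():
        return np.inf
    return float(keys[ok][-1] * precision)


def _seq_to_int(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int64)
    for b, i in _BASE_IDX.items():
        out[arr == ord(b)] = i
    return out


def _scan_pwm_one(seq_int: np.ndarray, sc: np.ndarray, thresh: float) -> np.ndarray:
    L = sc.shape[1]
    n = seq_int.size - L + 1
    if n <= 0 or not np.isfinite(thresh):
        return np.empty(0, dtype=np.int64)
    total = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        col = seq_int[j : j + n]
        bad = col < 0
        valid &= ~bad
        total += np.where(bad, 0.0, sc[np.clip(col, 0, 3), j])
    return np.flatnonzero(valid & (total >= thresh - 1e-9))


def _pattern_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in pattern))


def scan_motifs(
    sequences: dict[str, str],
    motifs: list[MotifModel],
    p_thresh: float = 1e-5,
    background=None,
):
    """Scan sequences on both strands.

    Returns (hits DataFrame [seq_id, motif, pos, strand, score], binary
    sequence × motif DataFrame).
    """
    hit_rows = []
    seq_ids = list(sequences)
    binmat = pd.DataFrame(False, index=seq_ids, columns=[m.id for m in motifs])
    prepped = []
    for m in motifs:
        if m.kind == "pwm":
            sc = pwm_scores(m.pwm, background)
            thr = pwm_threshold(m.pwm, p_thresh, background)
            sc_rc = sc[::-1, ::-1]  # reverse complement strand scores
            prepped.append((m, sc, sc_rc, thr, None, None))
        else:
            fwd = _pattern_regex(m.pattern)
            rev = _pattern_regex(_revcomp_iupac(m.pattern))
            prepped.append((m, None, None, None, fwd, rev))
    for sid, seq in sequences.items():
        seq_int = None
        for m, sc, sc_rc, thr, fwd, rev in prepped:
            if m.kind == "pwm":
                if len(seq) < sc.shape[1]:
                    continue
                if seq_int is None:
                    seq_int = _seq_to_int(seq)
                for strand, mat in (("+", sc), ("-", sc_rc)):
                    for pos in _scan_pwm_one(seq_int, mat, thr):
                        hit_rows.append((sid, m.id, int(pos), strand, 0.0))
                        binmat.at[sid, m.id] = True
            else:
                for strand, rx in (("+", fwd), ("-", rev)):
                    for match in rx.finditer(seq.upper()):
                        hit_rows.append((sid, m.id, match.start(), strand, 0.0))
                        binmat.at[sid, m.id] = True
    hits = pd.DataFrame(hit_rows, columns=["seq_id", "motif", "pos", "strand", "score"])
    return hits, binmat


def _revcomp_iupac(pattern: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
            "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}
    return "".join(comp[c] for c in reversed(pattern))


# ---------------------------------------------------------------- controls

def simulate_control_regions(
    targets: pd.DataFrame,
    genome: GenomeRef,
    n_sets: int = 100,
    exclusions: pd.DataFrame | None = None,
    seed: int = 0,
    max_tries: int = 50,
) -> list[pd.DataFrame]:
    """``n_sets`` length-matched control placements avoiding the targets.

    Each control set reproduces the target width multiset, placed uniformly
    in mappable space minus exclusions, rejecting draws that overlap any
    target interval.
    """
    rng = np.random.default_rng(seed)
    spaces = []
    for chrom in genome.chrom_sizes:
        if chrom in genome.mappable:
            ms, me = genome.mappable[chrom]
        else:
            ms, me = np.array([0]), np.array([genome.chrom_sizes[chrom]])
        ms, me = np.asarray(ms, np.int64), np.asarray(me, np.int64)
        if exclusions is not None:
            ex = exclusions[exclusions["chrom"] == chrom]
            ms, me = iv.subtract(ms, me, ex["start"].to_numpy(), ex["end"].to_numpy())
        for s, e in zip(ms, me):
            spaces.append((chrom, int(s), int(e)))
    tgt_by_chrom = {c: g for c, g in targets.groupby("chrom")}
    widths = (targets["end"] - targets["start"]).to_numpy()
    if sum(e - s for _, s, e in spaces) < widths.sum():
        raise ValueError("sampling space smaller than total target length")
    sets = []
    for _ in range(n_sets):
        rows = []
        for w in widths:
            fit = [(c, s, e) for c, s, e in spaces if e - s >= w]
            caps = np.array([e - s - w + 1 for _, s, e in fit], dtype=float)
            for _try in range(max_tries):
                j = rng.choice(len(fit), p=caps / caps.sum())
                c, s, e = fit[j]
                off = int(rng.integers(0, e - s - w + 1))
                tgt = tgt_by_chrom.get(c)
                if tgt is not None and iv.overlaps_any(
                    [s + off], [s + off + w], tgt["start"].to_numpy(), tgt["end"].to_numpy()
                )[0]:
                    continue
                rows.append((c, s + off, s + off + w))
                break
            else:
                raise ValueError("control placement space exhausted")
        sets.append(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    return sets


def capture_ratio(regions: pd.DataFrame, features: pd.DataFrame) -> float:
    """Fraction of regions overlapping ≥1 feature interval."""
    if len(regions) == 0:
        return 0.0
    hit = np.zeros(len(regions), dtype=bool)
    regions = regions.reset_index(drop=True)
    for chrom, sub in regions.groupby("chrom"):
        f = features[features["chrom"] == chrom]
        hit[sub.index.to_numpy()] = iv.overlaps_any(
            sub["start"].to_numpy(), sub["end"].to_numpy(),
            f["start"].to_numpy(), f["end"].to_numpy(),
        )
    return float(hit.mean())


def binomial_enrichment(k: int, n: int, null_ratios) -> tuple[float, float]:
    """Exact one-tailed (greater) binomial test against the null mean ratio.

    Returns (p0, p).  A degenerate p0 = 0 is clamped up to the resolution of
    the null draws (p0 = 1 is left alone: the upper tail is then exactly 1
    unless k > n, which cannot happen).
    """
    null_ratios = np.asarray(null_ratios, dtype=float)
    p0 = float(null_ratios.mean())
    eps = 1.0 / max(null_ratios.size * n, 1)
    p0 = max(p0, eps)
    p = stats.binomtest(k, n, p0, alternative="greater").pvalue
    return p0, float(p)


# ---------------------------------------------------------------- NB model

def nb_enrichment(
    motif_counts: pd.DataFrame,
    cells: pd.DataFrame,
    nonzero_per_cell: np.ndarray,
    downsample: int = 412,
    q_cut: float = 0.01,
    beta_cut: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial regression motif enrichment per (motif, cell type).

    For each cell type the model ``log μ = β0 + β1·1[type] + β2·log nonzero``
    is fitted on cells downsampled to 412 per type (with replacement,
    flagged, when a type is smaller).  Dispersion is method-of-moments from
    a Poisson fit, refitted once.  BH correction across motifs within each
    cell type; enriched = q < 0.01 and β1 > 0.05.
    """
    rng = np.random.default_rng(seed)
    cell_types = sorted(cells["cell_type"].unique())
    pick = []
    flags = {}
    for ct in cell_types:
        idx = np.flatnonzero((cells["cell_type"] == ct).to_numpy())
        replace = idx.size < downsample
        flags[ct] = replace
        pick.append(rng.choice(idx, size=downsample, replace=replace))
    pick = np.concatenate(pick)
    sub_cells = cells.iloc[pick].reset_index(drop=True)
    Y = motif_counts.iloc[:, pick].to_numpy()
    log_nz = np.log(np.maximum(np.asarray(nonzero_per_cell)[pick], 1))
    rows = []
    for ct in cell_types:
        ind = (sub_cells["cell_type"] == ct).to_numpy().astype(float)
        X = np.column_stack([np.ones_like(ind), ind, log_nz])
        for mi, motif in enumerate(motif_counts.index):
            y = Y[mi]
            beta, p, fallback = _fit_nb(y, X)
            rows.append((motif, ct, beta, np.exp(beta), p, fallback))
    out = pd.DataFrame(rows, columns=["motif", "cell_type", "beta", "fold_change", "p", "poisson_fallback"])
    out["q"] = np.nan
    for ct in cell_types:
        m = out["cell_type"] == ct
        out.loc[m, "q"] = multipletests(out.loc[m, "p"].fillna(1.0), method="fdr_bh")[1]
    out["enriched"] = (out["q"] < q_cut) & (out["beta"] > beta_cut)
    out.attrs["downsample_with_replacement"] = flags
    return out


def _fit_nb(y, X):
    try:
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        mu = pois.fittedvalues
        df = max(y.size - X.shape[1], 1)
        alpha = float(np.sum((y - mu) ** 2 - mu) / np.sum(mu**2))
        if alpha > 0:
            try:
                nb = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha)).fit()
                return float(nb.params[1]), float(nb.pvalues[1]), False
            except Exception:
                pass
        return float(pois.params[1]), float(pois.pvalues[1]), alpha <= 0
    except Exception:
        return 0.0, 1.0, True


# ---------------------------------------------------------------- families

def family_hypergeom(
    target_ids: list, universe_ids: list, families: dict[str, list], hits: pd.DataFrame
) -> pd.DataFrame:
    """One-tailed hypergeometric family enrichment.

    ``families`` maps family → motif ids; ``hits`` is the binary ACR×motif
    matrix (DataFrame).  Per family: N universe ACRs, K with ≥1 family
    motif, n targets, k targets with ≥1 family motif; p = P(X ≥ k).
    """
    target = [t for t in target_ids if t in hits.index]
    universe = [u for u in universe_ids if u in hits.index]
    N, n = len(universe), len(target)
    rows = []
    for fam, motif_ids in families.items():
        cols = [m for m in motif_ids if m in hits.columns]
        if not cols:
            rows.append((fam, 0, 0, 1.0))
            continue
        has = hits[cols].any(axis=1)
        K = int(has.loc[universe].sum())
        k = int(has.loc[target].sum())
        p = 1.0 if K == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((fam, K, k, p))
    return pd.DataFrame(rows, columns=["family", "K_universe", "k_target", "p"])
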