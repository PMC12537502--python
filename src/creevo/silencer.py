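"""H3K27me3-associated ACR classification and candidate-silencer analysis.

Broadly accessible ACRs lying within (or next to) H3K27me3 domains are
candidate Polycomb silencer elements: their constitutive accessibility can
provide a landing platform for PRC2 while the surrounding chromatin carries
the repressive mark.  This module makes the per-cell-type accessibility
calls (coverage, raw count and quantile-normalized CPM thresholds), splits
H3K27me3-associated ACRs into broad vs cell-type-specific, links candidate
silencers to nearby repressed genes for a paired expression contrast, and
calls broad methylation regions (BMRs) from windowed methylation tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as iv


@dataclass
class AccessCallParams:
    cov_thresh: float = 2.0
    min_tn5: int = 20
    cpm_thresh: float = 2.0
    assoc_flank: int = 500


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Column quantile normalization (rank-average on ties)."""
    ranks = df.rank(method="average")
    sorted_cols = np.sort(df.to_numpy(), axis=0)
    mean_sorted = sorted_cols.mean(axis=1)
    # map average ranks onto the mean sorted distribution
    n = len(df)
    grid = np.arange(1, n + 1)
    out = {}
    for c in df.columns:
        out[c] = np.interp(ranks[c].to_numpy(), grid, mean_sorted)
    return pd.DataFrame(out, index=df.index)


def accessible_call_matrix(
    max_cov: pd.DataFrame,
    counts: pd.DataFrame,
    total_insertions: pd.Series,
    params: AccessCallParams = AccessCallParams(),
) -> pd.DataFrame:
    """Binary ACR × cell-type accessibility calls.

    All three criteria must hold: per-million-scaled max coverage within the
    ACR > 2, raw Tn5 count ≥ 20, and quantile-normalized CPM > 2.
    """
    tot = total_insertions.reindex(counts.columns)
    cov_norm = max_cov / tot * 1e6
    cpm = counts / tot * 1e6
    cpm_qn = quantile_normalize(cpm)
    acc = (cov_norm > params.cov_thresh) & (counts >= params.min_tn5) & (
        cpm_qn > params.cpm_thresh
    )
    zero = tot[tot == 0].index
    for c in zero:
        acc[c] = False
    return acc


def breadth_rules(n_cell_types: int) -> tuple[int, int]:
    """(min accessible for broad, strict upper count for specific)."""
    if n_cell_types < 10:
        return n_cell_types - 1, 3
    return n_cell_types - 2, 4


def classify_h3k27me3_acrs(
    acrs: pd.DataFrame,
    accessible: pd.DataFrame,
    domains: pd.DataFrame,
    params: AccessCallParams = AccessCallParams(),
) -> pd.DataFrame:
    """Associate ACRs with H3K27me3 and classify accessibility breadth.

    Associated = overlapping a domain or within the association flank
    (default 500 bp).  Breadth from the accessible-call matrix with the
    n−1 / n−2 broad and <3 / <4 specific rules.
    """
    n = accessible.shape[1]
    broad_min, spec_below = breadth_rules(n)
    out = acrs.copy().reset_index(drop=True)
    assoc = np.zeros(len(out), dtype=bool)
    for chrom, sub in out.groupby("chrom"):
        dom = domains[domains["chrom"] == chrom]
        assoc[sub.index.to_numpy()] = iv.overlaps_any(
            sub["start"].to_numpy() - params.assoc_flank,
            sub["end"].to_numpy() + params.assoc_flank,
            dom["start"].to_numpy(),
            dom["end"].to_numpy(),
        )
    n_acc = accessible.to_numpy().sum(axis=1)
    breadth = np.where(
        n_acc >= broad_min, "broad", np.where(n_acc < spec_below, "cell-type-specific", "intermediate")
    )
    out["h3k27me3_status"] = np.where(assoc, "associated", "absent")
    out["n_accessible"] = n_acc
    out["breadth"] = breadth
    return out


# ---------------------------------------------------------------- gene link

def link_silencer_genes(
    acrs: pd.DataFrame,
    genes: pd.DataFrame,
    domains: pd.DataFrame,
    min_up: int = 500,
    max_up: int = 5000,
    min_body_cover: float = 0.5,
) -> pd.DataFrame:
    """Link ACRs to genes they may silence.

    A gene links to an ACR positioned 500–5,000 bp upstream of its TSS
    (strand-aware, ACR edge nearest the TSS) whose gene body is covered >50%
    by H3K27me3.
    """
    rows = []
    for chrom, gsub in genes.groupby("chrom"):
        dom = domains[domains["chrom"] == chrom]
        cover = iv.coverage_fraction(
            gsub["start"].to_numpy(), gsub["end"].to_numpy(),
            dom["start"].to_numpy(), dom["end"].to_numpy(),
        )
        asub = acrs[acrs["chrom"] == chrom]
        for (gi, g), cov in zip(gsub.iterrows(), cover):
            if cov <= min_body_cover:
                continue
            if g["strand"] == "+":
                tss = g["start"]
                dist = tss - asub["end"].to_numpy()  # ACR fully upstream
            else:
                tss = g["end"]
                dist = asub["start"].to_numpy() - tss
            hit = (dist >= min_up) & (dist <= max_up)
            for ai in asub.index[hit]:
                rows.append(
                    (asub.at[ai, "id"] if "id" in asub.columns else ai,
                     g["gene_id"], int(dist[asub.index.get_loc(ai)]), float(cov))
                )
    return pd.DataFrame(rows, columns=["acr_id", "gene_id", "upstream_bp", "body_cover"])


def compare_expression(
    silencer_genes: list[str],
    control_genes: list[str],
    expression: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """One-sided paired Wilcoxon: control (H3K27me3-absent) > silencer-linked.

    ``expression`` is gene × cell-type.  Per cell type, silencer-linked genes
    are paired with an equal-size control sample (nearest-rank matching on
    overall expression) and tested with the one-tailed signed-rank test.
    Skipped (p = NaN) when fewer than 6 pairs are available.
    """
    rng = np.random.default_rng(seed)
    sil = [g for g in silencer_genes if g in expression.index]
    ctl_pool = [g for g in control_genes if g in expression.index and g not in set(sil)]
    rows = []
    n = min(len(sil), len(ctl_pool))
    for ct in expression.columns:
        if n < 6:
            rows.append((ct, n, np.nan, np.nan))
            continue
        sil_v = expression.loc[sil, ct].to_numpy()
        # match controls on overall expression rank
        ctl_overall = expression.loc[ctl_pool].mean(axis=1)
        sil_overall = expression.loc[sil].mean(axis=1)
        order_c = np.argsort(ctl_overall.to_numpy())
        order_s = np.argsort(sil_overall.to_numpy())
        take = np.linspace(0, len(ctl_pool) - 1, n).astype(int)
        ctl = [ctl_pool[j] for j in order_c[take]]
        sil_matched = [sil[j] for j in order_s[np.linspace(0, len(sil) - 1, n).astype(int)]]
        ctl_v = expression.loc[ctl, ct].to_numpy()
        sil_v = expression.loc[sil_matched, ct].to_numpy()
        diff = ctl_v - sil_v
        if np.all(diff == 0):
            rows.append((ct, n, 0.0, 1.0))
            continue
        stat, p = stats.wilcoxon(ctl_v, sil_v, alternative="greater")
        rows.append((ct, n, float(stat), float(p)))
    return pd.DataFrame(rows, columns=["cell_type", "n_pairs", "stat", "p"])


# ---------------------------------------------------------------- BMRs

def call_bmrs(windows: pd.DataFrame, min_run: int = 3) -> pd.DataFrame:
    """Broad methylation regions: ≥3 consecutive windows above the mean.

    The genome-wide mean is computed over all windows (per context when a
    ``context`` column is present); maximal qualifying runs are emitted as
    merged intervals.
    """
    out = []
    groups = windows.groupby("context") if "context" in windows.columns else [("", windows)]
    for ctx, sub in groups:
        mean = sub["level"].mean()
        for chrom, csub in sub.groupby("chrom", sort=False):
            csub = csub.sort_values("start")
            # strict >, with a float guard so an all-equal track yields none
            above = (csub["level"].to_numpy() - mean) > 1e-12
            starts = csub["start"].to_numpy()
            ends = csub["end"].to_numpy()
            i = 0
            while i < len(above):
                if above[i]:
                    j = i
                    while j + 1 < len(above) and above[j + 1] and ends[j] == starts[j + 1]:
                        j += 1
                    if j - i + 1 >= min_run:
                        out.append((chrom, int(starts[i]), int(ends[j]), ctx))
                    i = j + 1
                else:
                    i += 1
    return pd.DataFrame(out, columns=["chrom", "start", "end", "context"])
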