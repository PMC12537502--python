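"""Gene accessibility scores, marker genes and cell-cycle assignment."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests


def gene_windows(genes: pd.DataFrame, upstream: int = 500) -> pd.DataFrame:
    """Gene body plus a strand-aware upstream extension, clipped at 0."""
    plus = (genes["strand"] == "+").to_numpy()
    start = np.where(plus, genes["start"] - upstream, genes["start"])
    end = np.where(plus, genes["end"], genes["end"] + upstream)
    out = genes.copy()
    out["start"] = np.maximum(start, 0)
    out["end"] = end
    return out


def gene_count_matrix(insertions: pd.DataFrame, genes: pd.DataFrame, cells: pd.DataFrame, upstream: int = 500):
    """Raw (gene × cell) insertion counts over gene body + upstream window."""
    win = gene_windows(genes, upstream).reset_index(drop=True)
    col = {b: j for j, b in enumerate(cells["barcode"])}
    ii, jj = [], []
    for chrom, sub in win.groupby("chrom"):
        ins = insertions[insertions["chrom"] == chrom]
        pos = ins["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, bcs = pos[order], ins["barcode"].to_numpy()[order]
        lo = np.searchsorted(pos, sub["start"].to_numpy(), "left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), "left")
        for gi, l, h in zip(sub.index, lo, hi):
            for b in bcs[l:h]:
                j = col.get(b)
                if j is not None:
                    ii.append(gi)
                    jj.append(j)
    mat = sparse.coo_matrix(
        (np.ones(len(ii), dtype=np.int64), (ii, jj)), shape=(len(win), len(col))
    ).tocsr()
    mat.sum_duplicates()
    return mat, win["gene_id"].tolist()


def gene_score_matrix(insertions, genes, cells, upstream: int = 500):
    """Binary gene accessibility scores.

    Counts are normalized (log counts-per-ten-thousand + 1) and every
    positive value is then scaled to 1, zeros stay 0 — the normalization is
    monotone on positives, so the binarized matrix is normalization-
    independent.
    """
    raw, gene_ids = gene_count_matrix(insertions, genes, cells, upstream)
    scores = raw.copy().astype(np.int8)
    scores.data = np.ones_like(scores.data, dtype=np.int8)
    return scores, gene_ids, raw


# ---------------------------------------------------------------- markers

def marker_genes(
    counts: pd.DataFrame, fdr: float = 0.05, min_log2fc: float = 0.0
) -> pd.DataFrame:
    """One-vs-rest differential accessibility on pseudobulk counts.

    ``counts`` is gene × cell-type.  For each cell type the focal count is
    tested against the library-size expectation under the pooled rest via an
    exact negative-binomial tail (method-of-moments dispersion shared across
    genes; mid-p upper tail, doubled for two-sidedness).  Markers require
    BH FDR < 0.05 and log2 fold-change > 0.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two cell types")
    lib = counts.sum(axis=0)
    zero = lib[lib == 0].index.tolist()
    counts = counts.drop(columns=zero)
    lib = counts.sum(axis=0)
    rows = []
    # common dispersion by count-scale method of moments with library-size
    # offsets: Var = μ + α μ² per (gene, cell type)
    rate = counts.sum(axis=1) / lib.sum()
    mu_gc = np.outer(rate.to_numpy(), lib.to_numpy())
    y = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = ((y - mu_gc) ** 2 - mu_gc).sum(axis=1)
        den = (mu_gc**2).sum(axis=1)
        alpha_g = np.where(den > 0, num / den, 0.0)
    alpha = float(max(np.nanmedian(alpha_g), 0.0)) if len(counts) else 0.0
    K = counts.shape[1]
    for ct in counts.columns:
        rest = counts.drop(columns=ct)
        rest_lib = lib.drop(ct).sum()
        rate = rest.sum(axis=1) / rest_lib  # per-gene rate per unit library
        k = counts[ct].to_numpy()
        n = counts.sum(axis=1).to_numpy()
        p0 = lib[ct] / lib.sum()
        # exact conditional test given the gene total: binomial under the
        # Poisson model, beta-binomial (Pólya) under shared NB dispersion
        p_hi, p_lo = _conditional_tails(k, n, p0, alpha, K)
        p = np.minimum(2 * np.minimum(p_hi, p_lo), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            focal_rate = (counts[ct] / lib[ct]).to_numpy()
            rate_a = rate.to_numpy()
            l2fc = np.where(
                rate_a > 0,
                np.log2(np.where(rate_a > 0, focal_rate / np.where(rate_a > 0, rate_a, 1), 1)),
                np.where(focal_rate > 0, np.inf, 0.0),  # exclusive to focal type
            )
        q = multipletests(p, method="fdr_bh")[1]
        for g, pv, qv, fc in zip(counts.index, p, q, l2fc):
            rows.append((g, ct, fc, pv, qv))
    out = pd.DataFrame(rows, columns=["gene", "cell_type", "log2FC", "p", "FDR"])
    out["marker"] = (out["FDR"] < fdr) & (out["log2FC"] > min_log2fc)
    return out


def _conditional_tails(k, n, p0, alpha, n_types):
    """Mid-p upper/lower tails of k | n under binomial or beta-binomial.

    With shared NB dispersion α, the gamma-Poisson representation (per-type
    gamma shape 1/α) makes the conditional Pólya; a = K·p0/α, b = K·(1−p0)/α
    recovers the exact Dirichlet-multinomial marginal at equal library sizes
    and the binomial as α → 0.
    """
    if alpha <= 1e-8:
        pmf = stats.binom.pmf(k, n, p0)
        hi = stats.binom.sf(k, n, p0) + 0.5 * pmf
        lo = stats.binom.cdf(k, n, p0) - 0.5 * pmf
    else:
        a = n_types * p0 / alpha
        b = n_types * (1 - p0) / alpha
        pmf = stats.betabinom.pmf(k, n, a, b)
        hi = stats.betabinom.sf(k, n, a, b) + 0.5 * pmf
        lo = stats.betabinom.cdf(k, n, a, b) - 0.5 * pmf
    return hi, lo


# ---------------------------------------------------------------- cell cycle

def cell_cycle_assign(
    scores, gene_ids: list[str], stage_markers: pd.DataFrame, n_perm: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Assign each cell a cell-cycle stage from marker accessibility.

    Per stage, the cell's score is the sum of that stage's marker gene
    scores; the null mean/sd come from ``n_perm`` equally sized random draws
    from the full marker panel excluding the focal stage's genes.  z-scores
    become probabilities through the normal CDF; the argmax stage is
    assigned, flagged low-confidence when all stage scores are zero.
    """
    rng = np.random.default_rng(seed)
    gi = {g: i for i, g in enumerate(gene_ids)}
    stage_markers = stage_markers[stage_markers["gene"].isin(gi)]
    stages = sorted(stage_markers["stage"].unique())
    dense = np.asarray(scores.todense()) if sparse.issparse(scores) else np.asarray(scores)
    n_cells = dense.shape[1]
    res = {}
    for st in stages:
        genes_st = [gi[g] for g in stage_markers.loc[stage_markers["stage"] == st, "gene"]]
        pool = [gi[g] for g in stage_markers.loc[stage_markers["stage"] != st, "gene"]]
        obs = dense[genes_st].sum(axis=0)
        perm_scores = np.empty((n_perm, n_cells))
        for b in range(n_perm):
            pick = rng.choice(pool, size=len(genes_st), replace=len(pool) < len(genes_st))
            perm_scores[b] = dense[pick].sum(axis=0)
        mu = perm_scores.mean(axis=0)
        sd = perm_scores.std(axis=0, ddof=0)
        z = np.where(sd > 0, (obs - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        res[st] = (obs, z, stats.norm.cdf(z), mu, sd)
    out = pd.DataFrame({"barcode_idx": np.arange(n_cells)})
    prob_mat = np.column_stack([res[st][2] for st in stages])
    score_mat = np.column_stack([res[st][0] for st in stages])
    for j, st in enumerate(stages):
        out[f"z_{st}"] = np.column_stack([res[s][1] for s in stages])[:, j]
        out[f"p_{st}"] = prob_mat[:, j]
        out[f"null_mean_{st}"] = res[st][3]
        out[f"null_sd_{st}"] = res[st][4]
    out["stage"] = [stages[j] for j in prob_mat.argmax(axis=1)]
    out["low_confidence"] = score_mat.sum(axis=1) == 0
    return out
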