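"""Syntenic-block preparation, short-sequence local alignment, conservation.

ACR sequences from the query species are aligned against the orthologous
syntenic block of the partner species with a blastn-short-style seed-and-
extend local aligner: exact 7-mer seeds, affine-gap Smith–Waterman on a
window around each seed cluster (+1 match, −1 mismatch, gap of length k
costs 5 + 2k), Karlin–Altschul E-values with λ = ln 3 for the uniform
±1 scoring system.  Hits passing E ≤ 1e−3 and alignment length > 20 support
the conservation classes: shared (hit overlapping an accessible partner
ACR), variable (hit but no partner ACR), species-specific (no hit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from . import intervals as iv
from .motifs import _revcomp


@dataclass
class AlignParams:
    word_size: int = 7
    match: int = 1
    mismatch: int = -1
    gap_open: int = 5
    gap_extend: int = 2
    e_max: float = 1e-3
    min_len: int = 20
    lam: float = float(np.log(3.0))
    K: float = 0.62
    max_hits: int = 4
    window_pad: int = 120


@dataclass
class AlignmentHit:
    score: int
    q_start: int
    q_end: int  # half-open in query
    s_start: int
    s_end: int  # half-open in oriented subject
    length: int
    identity: float
    evalue: float


# ---------------------------------------------------------------- blocks

def prepare_blocks(blocks: pd.DataFrame, genome_a, genome_b):
    """Validate one-to-one blocks and extract oriented subject sequences.

    Blocks whose species-A or species-B interval duplicates or overlaps
    another block's are dropped (both members of the conflict).  Inverted
    blocks have their B sequence reverse-complemented so alignment runs in
    A orientation.  Returns (blocks, {block_id: subject sequence}, report).
    """
    blk = blocks.reset_index(drop=True).copy()
    drop = np.zeros(len(blk), dtype=bool)
    for side in ("A", "B"):
        for chrom, sub in blk.groupby(f"chrom{side}"):
            s = sub[f"start{side}"].to_numpy()
            e = sub[f"end{side}"].to_numpy()
            idx = sub.index.to_numpy()
            for i in range(len(idx)):
                for j in range(i + 1, len(idx)):
                    if s[i] < e[j] and s[j] < e[i]:
                        drop[idx[i]] = drop[idx[j]] = True
    report = {"dropped": int(drop.sum())}
    blk = blk[~drop].reset_index(drop=True)
    seqs = {}
    for r in blk.itertuples():
        seq = genome_b.sequence[r.chromB][r.startB : r.endB]
        if r.orientation == "inverted":
            seq = _revcomp(seq)
        seqs[r.block_id] = seq
    return blk, seqs, report


def lift_to_b(block_row, s: int, e: int) -> tuple[int, int]:
    """Oriented-subject interval [s,e) → species-B genome coordinates."""
    if block_row.orientation == "same":
        return block_row.startB + s, block_row.startB + e
    length = block_row.endB - block_row.startB
    return block_row.startB + (length - e), block_row.startB + (length - s)


# ---------------------------------------------------------------- aligner

@njit(cache=True)
def _sw_affine(a, b, match, mismatch, gap_first, gap_ext):
    """Affine-gap local alignment with pointer matrices.

    Returns (score, end_i, end_j, ptrH, ptrE, ptrF) where indices are
    1-based into the DP matrices; traceback reconstructs the path.
    """
    n, m = a.size, b.size
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10**6, dtype=np.int32)
    F = np.full((n + 1, m + 1), -10**6, dtype=np.int32)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop,1 diag,2 E,3 F
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 from H, 0 extend
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo = H[i, j - 1] - gap_first
            ee = E[i, j - 1] - gap_ext
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
            fo = H[i - 1, j] - gap_first
            fe = F[i - 1, j] - gap_ext
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
            s = match if a[i - 1] == b[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptrH, ptrE, ptrF


def _traceback(a, b, bi, bj, ptrH, ptrE, ptrF):
    i, j = bi, bj
    state = 0  # H
    length = 0
    matches = 0
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                length += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:  # E: gap consuming subject
            length += 1
            if ptrE[i, j]:
                state = 0
            j -= 1
        else:  # F: gap consuming query
            length += 1
            if ptrF[i, j]:
                state = 0
            i -= 1
    return i, j, length, matches


def _kmer_codes(seq_int: np.ndarray, w: int) -> np.ndarray:
    n = seq_int.size - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    if (seq_int < 0).any():
        seq_int = np.where(seq_int < 0, 0, seq_int)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(w):
        codes = codes * 4 + seq_int[j : j + n]
    return codes


@njit(cache=True)
def _ungapped_scores(q, s, qpos, spos, match, mismatch, x_drop):
    """Best X-drop ungapped extension score for each seed pair."""
    out = np.zeros(qpos.size, dtype=np.int32)
    for k in range(qpos.size):
        i0, j0 = qpos[k], spos[k]
        score = 0
        best = 0
        i, j = i0, j0
        while i < q.size and j < s.size:
            score += match if q[i] == s[j] else mismatch
            if score > best:
                best = score
            if best - score > x_drop:
                break
            i += 1
            j += 1
        total = best
        score = 0
        best = 0
        i, j = i0 - 1, j0 - 1
        while i >= 0 and j >= 0:
            score += match if q[i] == s[j] else mismatch
            if score > best:
                best = score
            if best - score > x_drop:
                break
            i -= 1
            j -= 1
        out[k] = total + best
    return out


def _seq_int(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for b, i in zip(b"ACGT", range(4)):
        out[arr == b] = i
    return out.astype(np.int64)


def align_acr(query: str, subject: str, params: AlignParams = AlignParams()) -> list[AlignmentHit]:
    """Seed-and-extend local alignment of one ACR against one block.

    Exact 7-mer seeds are clustered by diagonal and subject position; each
    cluster defines a subject window on which affine Smith–Waterman runs.
    Locally optimal hits are made non-overlapping greedily (in query
    coordinates) and filtered on E ≤ e_max and length > min_len; the top
    ``max_hits`` by score are returned.
    """
    if not query or not subject:
        return []
    q = _seq_int(query)
    s = _seq_int(subject)
    w = params.word_size
    qc = _kmer_codes(q, w)
    sc = _kmer_codes(s, w)
    if qc.size == 0 or sc.size == 0:
        return []
    index: dict[int, list[int]] = {}
    for pos, code in enumerate(qc):
        index.setdefault(int(code), []).append(pos)
    # vectorized seed finding: only subject positions whose word occurs in
    # the query enter the python loop
    hit_spos = np.flatnonzero(np.isin(sc, qc))
    seeds = []  # (diag, s_pos, q_pos)
    for spos in hit_spos:
        for qpos in index[int(sc[spos])]:
            seeds.append((spos - qpos, int(spos), qpos))
    if not seeds:
        return []
    # cheap ungapped X-drop pre-filter: only seeds whose ungapped extension
    # clears the trigger feed the gapped stage
    qpos_a = np.array([x[2] for x in seeds], dtype=np.int64)
    spos_a = np.array([x[1] for x in seeds], dtype=np.int64)
    ung = _ungapped_scores(q, s, qpos_a, spos_a, params.match, params.mismatch, 8)
    trigger = min(params.word_size + 6, params.min_len - 7)
    keep_mask = ung >= trigger
    if not keep_mask.any():
        return []
    seeds = [sd for sd, k in zip(seeds, keep_mask) if k]
    seeds.sort()
    # cluster seeds: same diagonal band (±32) and close subject positions
    clusters = []
    cur = [seeds[0]]
    for sd in seeds[1:]:
        if sd[0] - cur[-1][0] <= 32 and sd[1] - cur[-1][1] <= 200:
            cur.append(sd)
        else:
            clusters.append(cur)
            cur = [sd]
    clusters.append(cur)
    m_eff, n_eff = len(query), len(subject)
    raw_hits = []
    for cl in clusters:
        # seeds tile any long homology densely, so a modest pad suffices to
        # contain the optimal local alignment
        q_span_lo = min(x[2] for x in cl)
        q_span_hi = max(x[2] for x in cl) + w
        pad = params.window_pad + max(q_span_lo, len(query) - q_span_hi)
        s_lo = max(0, min(x[1] for x in cl) - pad)
        s_hi = min(len(subject), max(x[1] for x in cl) + w + pad)
        win = s[s_lo:s_hi]
        score, bi, bj, pH, pE, pF = _sw_affine(
            q, win, params.match, params.mismatch,
            params.gap_open + params.gap_extend, params.gap_extend,
        )
        if score <= 0:
            continue
        i0, j0, length, matches = _traceback(q, win, bi, bj, pH, pE, pF)
        ev = params.K * m_eff * n_eff * np.exp(-params.lam * score)
        raw_hits.append(
            AlignmentHit(
                score=int(score), q_start=i0, q_end=bi,
                s_start=s_lo + j0, s_end=s_lo + bj,
                length=length, identity=matches / max(length, 1), evalue=float(ev),
            )
        )
    raw_hits.sort(key=lambda h: (-h.score, h.s_start))
    kept: list[AlignmentHit] = []
    for h in raw_hits:
        if h.evalue > params.e_max or h.length <= params.min_len:
            continue
        if any(h.q_start < k.q_end and k.q_start < h.q_end and
               h.s_start < k.s_end and k.s_start < h.s_end for k in kept):
            continue
        kept.append(h)
        if len(kept) >= params.max_hits:
            break
    return kept


# ---------------------------------------------------------------- classes

def classify_conservation(
    queries: pd.DataFrame,
    blocks: pd.DataFrame,
    block_seqs: dict[str, str],
    genome_a,
    acrs_b: pd.DataFrame,
    params: AlignParams = AlignParams(),
) -> pd.DataFrame:
    """Shared / variable / species-specific calls for syntenic query ACRs.

    Each query aligns only against its own syntenic block; hits are lifted
    to species-B coordinates and intersected with the partner ACR set.
    Queries outside every block are reported as non-syntenic.
    """
    rows = []
    for r in queries.itertuples():
        mid = (r.start + r.end) // 2
        blk = blocks[
            (blocks["chromA"] == r.chrom) & (blocks["startA"] <= mid) & (blocks["endA"] > mid)
        ]
        if len(blk) == 0:
            rows.append((r.id, "non-syntenic", "", 0, 0.0, np.nan, ""))
            continue
        b = blk.iloc[0]
        qseq = genome_a.sequence[r.chrom][r.start : r.end]
        hits = align_acr(qseq, block_seqs[b["block_id"]], params)
        if not hits:
            rows.append((r.id, "species_specific", b["block_id"], 0, 0.0, np.nan, ""))
            continue
        partner = ""
        cls = "variable"
        best = hits[0]
        sub_b = acrs_b[acrs_b["chrom"] == b["chromB"]]
        for h in hits:
            gs, ge = lift_to_b(b, h.s_start, h.s_end)
            ov = iv.overlaps_any([gs], [ge], sub_b["start"].to_numpy(), sub_b["end"].to_numpy())[0]
            if ov:
                cls = "shared"
                gaps, idx = iv.nearest_gap([gs], [ge], sub_b["start"].to_numpy(), sub_b["end"].to_numpy())
                partner = str(sub_b.iloc[int(idx[0])]["id"])
                best = h
                break
        rows.append(
            (r.id, cls, b["block_id"], best.score, best.identity, best.evalue, partner)
        )
    return pd.DataFrame(
        rows, columns=["id", "class", "block_id", "score", "identity", "evalue", "partner"]
    )


def celltype_retention(
    calls: pd.DataFrame, labels_a: dict[str, str], labels_b: dict[str, str]
) -> pd.DataFrame:
    """Do shared cell-type-specific ACRs keep their cell type across species?

    ``labels_*`` map ACR id → cell type ("broad" for broadly accessible).
    Outcomes: retained, switched (partner cell type recorded), broadened,
    unknown (unlabeled partner).
    """
    rows = []
    shared = calls[calls["class"] == "shared"]
    for r in shared.itertuples():
        la = labels_a.get(r.id)
        lb = labels_b.get(r.partner)
        if la is None or la == "broad":
            continue
        if lb is None:
            out = "unknown"
        elif lb == "broad":
            out = "broadened"
        elif lb == la:
            out = "retained"
        else:
            out = "switched"
        rows.append((r.id, r.partner, la, lb or "", out))
    return pd.DataFrame(rows, columns=["id", "partner", "cell_type_a", "cell_type_b", "outcome"])


# ---------------------------------------------------------------- overlaps

def region_overlap_enrichment(
    regions_a: pd.DataFrame,
    regions_b: pd.DataFrame,
    genome,
    n_sim: int = 100,
    seed: int = 0,
):
    """Observed vs simulated capture of B by A with an exact binomial p.

    Observed = fraction of A regions overlapping B; the null is the mean
    capture over ``n_sim`` length-matched placements of A.
    """
    from .motifs import capture_ratio, simulate_control_regions, binomial_enrichment

    obs = capture_ratio(regions_a, regions_b)
    sets = simulate_control_regions(regions_a, genome, n_sets=n_sim, seed=seed)
    null = [capture_ratio(s, regions_b) for s in sets]
    k = int(round(obs * len(regions_a)))
    p0, p = binomial_enrichment(k, len(regions_a), null)
    return {"observed": obs, "null_mean": float(np.mean(null)), "p": p, "n": len(regions_a)}


def overlap_fisher(k_in: int, n_in: int, k_out: int, n_out: int):
    """One-tailed Fisher 2×2 contrast (greater)."""
    from scipy.stats import fisher_exact

    table = [[k_in, n_in - k_in], [k_out, n_out - k_out]]
    odds, p = fisher_exact(table, alternative="greater")
    return float(odds), float(p)
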