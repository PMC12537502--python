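"""Pileup, candidate calling, permutation FDR, refinement, peak matrix."""

import numpy as np
import pandas as pd

from creevo import acr
from creevo.core import GenomeRef
from oracles import count_in_intervals_bruteforce, fdr_threshold_bruteforce


# ---------------------------------------------------------------- pileup

def test_pileup_single_insertion_extent():
    cov = acr.pseudobulk_pileup(np.array([1000]), 2000)
    assert cov[925] == 1 and cov[1074] == 1
    assert cov[924] == 0 and cov[1075] == 0
    assert cov.sum() == 150


def test_pileup_additive_and_integral_identity(rng):
    pos = rng.integers(200, 1800, 40)
    cov = acr.pseudobulk_pileup(pos, 2000)
    assert cov.sum() == 150 * 40  # interior insertions: full extension fits
    cov2 = acr.pseudobulk_pileup(np.array([500, 500]), 2000)
    assert cov2[500] == 2


def test_pileup_empty_is_zero_track():
    assert acr.pseudobulk_pileup(np.array([]), 100).sum() == 0


# ---------------------------------------------------------------- candidates

def test_candidate_caller_finds_planted_spike(rng):
    n_bg = 2000
    chrom_len = 100_000
    pos = rng.integers(0, chrom_len, n_bg)
    spike = np.full(200, 50_000) + rng.integers(-100, 100, 200)
    allpos = np.concatenate([pos, spike])
    cov = {"chr1": acr.pseudobulk_pileup(allpos, chrom_len)}
    cand = acr.call_candidate_peaks(cov, allpos.size, chrom_len)
    assert len(cand) == 1
    assert cand["start"].iloc[0] < 50_000 < cand["end"].iloc[0]


def test_candidate_caller_flat_zero():
    cov = {"chr1": np.zeros(1000, dtype=np.int64)}
    assert len(acr.call_candidate_peaks(cov, 0, 1000)) == 0


def test_candidate_caller_merges_close_spikes(rng):
    chrom_len = 50_000
    # runs end up 100 bp apart (each spike extends ±75), within the merge gap
    spikes = np.concatenate([np.full(100, 20_000), np.full(100, 20_250)])
    bg = rng.integers(0, chrom_len, 500)
    allpos = np.concatenate([spikes, bg])
    cov = {"chr1": acr.pseudobulk_pileup(allpos, chrom_len)}
    cand = acr.call_candidate_peaks(cov, allpos.size, chrom_len)
    assert len(cand) == 1  # runs 100 bp apart merged


# ---------------------------------------------------------------- FDR

def test_fdr_threshold_worked_example():
    # real {5,4,3,2} vs permuted {2,1,1,1}: FDR stays <0.05 down to t=3
    # (0 permuted ≥ 3) and fails at t=2 (1/4 = 0.25), so t* = 3
    assert acr.fdr_threshold([5, 4, 3, 2], [2, 1, 1, 1], fdr=0.05) == 3
    assert fdr_threshold_bruteforce([5, 4, 3, 2], [2, 1, 1, 1], fdr=0.05) == 3
    real = np.array([5, 4, 3, 2])
    assert (real[real >= 3]).tolist() == [5, 4, 3]


def test_fdr_threshold_matches_bruteforce_on_random_fixtures(rng):
    for _ in range(100):
        real = rng.integers(0, 30, rng.integers(1, 40)) / 10
        perm = rng.integers(0, 30, real.size) / 10
        for fdr in (0.05, 0.2, 0.5):
            assert acr.fdr_threshold(real, perm, fdr) == fdr_threshold_bruteforce(real, perm, fdr)


def test_fdr_threshold_permuted_all_zero():
    real = np.array([0.5, 0.2, 0.1])
    t = acr.fdr_threshold(real, np.zeros(3), fdr=0.05)
    assert t == 0.1  # smallest positive real density; all retained


def _toy_genome(chrom_len=200_000):
    return GenomeRef(
        chrom_sizes={"chr1": chrom_len},
        mappable={"chr1": (np.array([0]), np.array([chrom_len]))},
    )


def test_permutation_filter_exchangeable_null_retains_few(rng):
    genome = _toy_genome()
    retained_frac = []
    for seed in range(6):
        r = np.random.default_rng(seed)
        ins = pd.DataFrame({"chrom": "chr1", "pos": np.sort(r.integers(0, 200_000, 5000))})
        cand = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(40) * 5000,
            "end": np.arange(40) * 5000 + 400,
            "summit": np.arange(40) * 5000 + 200,
        })
        kept, _t = acr.permutation_fdr_filter(cand, ins, genome, seed=seed)
        retained_frac.append(len(kept) / len(cand))
    assert np.mean(retained_frac) <= 0.05 + 0.03


def test_permutation_filter_monotone_in_density(rng):
    genome = _toy_genome()
    r = np.random.default_rng(0)
    ins = pd.DataFrame({"chrom": "chr1", "pos": np.sort(r.integers(0, 200_000, 3000))})
    strong = pd.DataFrame({"chrom": "chr1", "pos": np.full(300, 100_100)})
    ins_all = pd.concat([ins, strong]).sort_values("pos")
    cand = pd.DataFrame({"chrom": ["chr1"], "start": [100_000], "end": [100_400], "summit": [100_100]})
    kept, _ = acr.permutation_fdr_filter(cand, ins_all, genome, seed=1)
    assert len(kept) == 1
    more = pd.concat([ins_all, pd.DataFrame({"chrom": "chr1", "pos": np.full(100, 100_200)})]).sort_values("pos")
    kept2, _ = acr.permutation_fdr_filter(cand, more, genome, seed=1)
    assert len(kept2) == 1  # adding in-peak insertions never drops the peak


# ---------------------------------------------------------------- refinement

NUC = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [600]})


def _peak(start=0, end=1000, summit=300):
    return pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end], "summit": [summit]})


def _ins(n, pos, frag):
    return pd.DataFrame({"chrom": "chr1", "pos": np.full(n, pos), "frag_size": np.full(n, frag)})


def test_refine_drops_nucleosome_covered_peak():
    genome = _toy_genome()
    out = acr.refine_and_filter(_peak(), NUC, _ins(10, 300, 100), genome)
    assert len(out) == 0  # 60% coverage > 50%


def test_refine_fragment_size_boundary():
    genome = _toy_genome()
    empty_nuc = pd.DataFrame(columns=["chrom", "start", "end"])
    assert len(acr.refine_and_filter(_peak(), empty_nuc, _ins(10, 300, 151), genome)) == 0
    out = acr.refine_and_filter(_peak(), empty_nuc, _ins(10, 300, 150), genome)
    assert len(out) == 1


def test_refine_summit_window_arithmetic():
    genome = _toy_genome()
    empty_nuc = pd.DataFrame(columns=["chrom", "start", "end"])
    out = acr.refine_and_filter(_peak(summit=300), empty_nuc, _ins(5, 300, 80), genome)
    assert (out["start"].iloc[0], out["end"].iloc[0]) == (50, 550)
    # summit near the chromosome start clips with a flag
    out2 = acr.refine_and_filter(_peak(summit=100), empty_nuc, _ins(5, 100, 80), genome)
    assert out2["clipped"].iloc[0] and out2["start"].iloc[0] == 0


# ---------------------------------------------------------------- matrix

def test_peak_matrix_boundary_conventions():
    acrs = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [600]})
    ins = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [100, 599, 600], "barcode": ["b1"] * 3})
    cells = pd.DataFrame({"barcode": ["b1"]})
    mat, n_skip = acr.build_peak_matrix(acrs, ins, cells)
    assert mat[0, 0] == 2  # start inclusive, end exclusive
    assert n_skip == 0


def test_peak_matrix_skips_unknown_barcodes_and_sums(rng):
    acrs = pd.DataFrame({"chrom": "chr1", "start": [0, 1000], "end": [500, 1500]})
    pos = rng.integers(0, 2000, 300)
    bcs = rng.choice(["b1", "b2", "ghost"], 300)
    ins = pd.DataFrame({"chrom": "chr1", "pos": pos, "barcode": bcs})
    cells = pd.DataFrame({"barcode": ["b1", "b2"]})
    mat, n_skip = acr.build_peak_matrix(acrs, ins, cells)
    known = ins[ins["barcode"] != "ghost"]
    expect = sum(count_in_intervals_bruteforce(known["pos"].tolist(), acrs["start"], acrs["end"]))
    assert mat.sum() == expect
    assert n_skip == sum(count_in_intervals_bruteforce(
        ins.loc[ins["barcode"] == "ghost", "pos"].tolist(), acrs["start"], acrs["end"]))


# ---------------------------------------------------------------- end to end

def test_full_calling_recall_fdr_and_widths(study, called_atlas):
    from creevo import intervals as iv

    atlas = called_atlas["atlas"]
    truth = study["truth"]
    assert ((atlas["end"] - atlas["start"]) == 500).all()
    tp = truth.peaks[truth.peaks["kind"] == "true"]
    rec = 0
    for chrom, sub in tp.groupby("chrom"):
        a = atlas[atlas["chrom"] == chrom]
        rec += iv.overlaps_any(sub["start"].to_numpy(), sub["end"].to_numpy(),
                               a["start"].to_numpy(), a["end"].to_numpy()).sum()
    assert rec / len(tp) >= 0.95
    fp = 0
    for chrom, sub in atlas.groupby("chrom"):
        t = truth.peaks[truth.peaks["chrom"] == chrom]
        fp += (~iv.overlaps_any(sub["start"].to_numpy(), sub["end"].to_numpy(),
                                t["start"].to_numpy(), t["end"].to_numpy())).sum()
    assert fp / len(atlas) <= 0.08


def test_full_calling_deterministic(study):
    sub_cells = study["cells"].groupby("cell_type").head(40)
    ins = study["insertions"]
    ins_sub = ins[ins["barcode"].isin(set(sub_cells["barcode"]))]
    a1, m1, _ = acr.call_acrs(ins_sub, sub_cells, study["genome"], study["nucleosomes"], seed=9)
    a2, m2, _ = acr.call_acrs(ins_sub, sub_cells, study["genome"], study["nucleosomes"], seed=9)
    pd.testing.assert_frame_equal(a1, a2)
    assert (m1 != m2).nnz == 0
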