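"""PWM thresholds, scanning, control regions, and the three enrichment tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from creevo import motifs as mot
from creevo.core import GenomeRef
from creevo.motifs import MotifModel
from oracles import pwm_threshold_enumeration


# ---------------------------------------------------------------- thresholds

@pytest.mark.parametrize("length", [4, 5, 6, 7, 8])
@pytest.mark.parametrize("p_thresh", [1e-2, 1e-3, 1e-5])
def test_pwm_threshold_matches_enumeration(length, p_thresh, rng):
    counts = rng.integers(1, 60, (4, length))
    m = MotifModel.from_counts("x", counts)
    t_dp = mot.pwm_threshold(m.pwm, p_thresh)
    t_enum = pwm_threshold_enumeration(m.pwm, p_thresh)
    if np.isinf(t_enum):
        assert np.isinf(t_dp)
    else:
        assert t_dp == pytest.approx(t_enum, abs=1e-3)
        # identical achieved false-positive rate
        sc = mot.pwm_scores(m.pwm)
        tot = np.zeros(1)
        for j in range(length):
            tot = (tot[:, None] + sc[:, j][None, :]).ravel()
        assert (tot >= t_dp - 1e-7).sum() == (tot >= t_enum - 1e-7).sum()


def test_threshold_unattainable_for_short_motifs():
    # max-score tail probability is ≥ 4^-L > 1e-5 for L ≤ 8
    m = MotifModel.from_counts("x", np.eye(4, 6) * 100 + 1)
    assert np.isinf(mot.pwm_threshold(m.pwm, 1e-5))


# ---------------------------------------------------------------- scanning

def _consensus_pwm(word, motif_id="m"):
    counts = np.full((4, len(word)), 1.0)
    for j, ch in enumerate(word):
        counts["ACGT".index(ch), j] = 200
    return MotifModel.from_counts(motif_id, counts)


def test_scan_finds_planted_consensus_both_orientations():
    word = "ACGTACGTACGT"
    m = _consensus_pwm(word)
    rc = word.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    seqs = {
        "fwd": "TTGGCC" + word + "GGTTCC",
        "rev": "TTGGCC" + rc + "GGTTCC",
    }
    hits, binmat = mot.scan_motifs(seqs, [m])
    assert binmat.loc["fwd", "m"] and binmat.loc["rev", "m"]
    assert set(hits.loc[hits["seq_id"] == "fwd", "strand"]) >= {"+"}
    assert set(hits.loc[hits["seq_id"] == "rev", "strand"]) >= {"-"}


def test_pattern_scan_ga_repeat():
    m = MotifModel.from_pattern("GA", "GAGAGAGA")
    hits, binmat = mot.scan_motifs({"pos": "ttGAGAGAGAtt", "neg": "C" * 20}, [m])
    assert binmat.loc["pos", "GA"] and not binmat.loc["neg", "GA"]


def test_scan_strand_symmetric(rng):
    word = "ACGGTTACGGTA"
    m = _consensus_pwm(word)
    seqs = {}
    for i in range(12):
        s = "".join(rng.choice(list("ACGT"), 80))
        if i % 3 == 0:
            s = s[:30] + word + s[30:]
        seqs[f"s{i}"] = s
    hits_f, _ = mot.scan_motifs(seqs, [m])
    rc = {k: v.translate(str.maketrans("ACGT", "TGCA"))[::-1] for k, v in seqs.items()}
    hits_r, _ = mot.scan_motifs(rc, [m])
    assert len(hits_f) == len(hits_r)


def test_motif_longer_than_sequence_no_hits():
    m = _consensus_pwm("ACGTACGTACGT")
    hits, binmat = mot.scan_motifs({"tiny": "ACG"}, [m])
    assert len(hits) == 0 and not binmat.loc["tiny"].any()


# ---------------------------------------------------------------- controls

def _genome(length=100_000):
    return GenomeRef(chrom_sizes={"chr1": length},
                     mappable={"chr1": (np.array([0]), np.array([length]))})


def test_control_sets_preserve_width_multiset():
    targets = pd.DataFrame({"chrom": "chr1", "start": [1000, 5000, 9000],
                            "end": [1500, 5500, 9300]})
    sets = mot.simulate_control_regions(targets, _genome(), n_sets=10, seed=0)
    for s in sets:
        assert sorted(s["end"] - s["start"]) == [300, 500, 500]
        # never overlapping the targets
        from creevo import intervals as iv
        assert not iv.overlaps_any(s["start"].to_numpy(), s["end"].to_numpy(),
                                   targets["start"].to_numpy(), targets["end"].to_numpy()).any()


def test_control_sets_respect_exclusions():
    targets = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [700]})
    excl = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [90_000]})
    sets = mot.simulate_control_regions(targets, _genome(), n_sets=20, exclusions=excl, seed=1)
    for s in sets:
        assert (s["start"] >= 90_000).all()


def test_control_capture_matches_feature_density(rng):
    genome = _genome(1_000_000)
    # features tile 10% of the genome
    feats = pd.DataFrame({"chrom": "chr1", "start": np.arange(100) * 10_000,
                          "end": np.arange(100) * 10_000 + 1000})
    targets = pd.DataFrame({"chrom": "chr1", "start": [500_000], "end": [500_200]})
    sets = mot.simulate_control_regions(targets, genome, n_sets=400, seed=2)
    caps = [mot.capture_ratio(s, feats) for s in sets]
    # expected capture ≈ P(200 bp window hits a 1 kb feature every 10 kb)
    p_exp = (1000 + 200 - 1) / 10_000
    lo, hi = stats.binom.ppf([0.005, 0.995], 400, p_exp) / 400
    assert lo <= np.mean(caps) <= hi


# ---------------------------------------------------------------- binomial

def test_binomial_enrichment_closed_form():
    p0, p = mot.binomial_enrichment(50, 100, [0.3] * 100)
    exact = stats.binom.sf(49, 100, 0.3)
    assert p == pytest.approx(exact, abs=1e-12)
    assert p == pytest.approx(2.1e-5, rel=0.1)


def test_binomial_enrichment_null_and_edge_cases():
    _, p_mid = mot.binomial_enrichment(30, 100, [0.3] * 100)
    assert 0.2 < p_mid < 0.7
    _, p_zero = mot.binomial_enrichment(0, 100, [0.3] * 100)
    assert p_zero == 1.0
    p0, _ = mot.binomial_enrichment(5, 100, [0.0] * 100)  # degenerate p0 clamped
    assert p0 > 0


# ---------------------------------------------------------------- NB model

def _nb_fixture(rng, n_motifs=50, n_types=2, n_per=600, beta=0.5):
    cells = pd.DataFrame({
        "barcode": [f"c{i}" for i in range(n_types * n_per)],
        "cell_type": np.repeat([f"t{k}" for k in range(n_types)], n_per),
    })
    nonzero = rng.integers(200, 800, len(cells))
    Y = np.zeros((n_motifs, len(cells)))
    for mi in range(n_motifs):
        base = rng.uniform(1.0, 2.0)
        mu = np.exp(base + beta * (cells["cell_type"] == "t0").to_numpy()
                    + 0.5 * np.log(nonzero))
        Y[mi] = rng.negative_binomial(10, 10 / (10 + mu))
    return pd.DataFrame(Y, index=[f"m{i}" for i in range(n_motifs)]), cells, nonzero


def test_nb_recovers_planted_beta(rng):
    Y, cells, nonzero = _nb_fixture(rng, beta=0.5)
    res = mot.nb_enrichment(Y, cells, nonzero, seed=0)
    b = res.loc[res["cell_type"] == "t0", "beta"]
    assert abs(b.mean() - 0.5) <= 0.1


def test_nb_null_label_permutation_rate(rng):
    Y, cells, nonzero = _nb_fixture(rng, n_motifs=200, beta=0.0)
    perm = cells.copy()
    perm["cell_type"] = rng.permutation(perm["cell_type"].to_numpy())
    res = mot.nb_enrichment(Y, perm, nonzero, seed=1)
    frac = res.groupby("cell_type")["enriched"].mean()
    assert (frac <= 0.015).all()


def test_nb_identical_counts_zero_beta():
    cells = pd.DataFrame({"barcode": [f"c{i}" for i in range(40)],
                          "cell_type": ["t0"] * 20 + ["t1"] * 20})
    Y = pd.DataFrame(np.full((3, 40), 7.0), index=["m0", "m1", "m2"])
    res = mot.nb_enrichment(Y, cells, np.full(40, 100), downsample=20, seed=2)
    assert np.allclose(res["beta"], 0.0, atol=1e-6)


def test_nb_small_population_flagged(rng):
    Y, cells, nonzero = _nb_fixture(rng, n_per=100)
    res = mot.nb_enrichment(Y.head(3), cells, nonzero, downsample=412, seed=3)
    assert all(res.attrs["downsample_with_replacement"].values())


# ---------------------------------------------------------------- families

def test_family_hypergeom_closed_forms():
    hits = pd.DataFrame(
        {"m1": [True] * 6 + [False] * 4},
        index=[f"a{i}" for i in range(10)],
    )
    fams = {"F": ["m1"]}
    # all-success tail: k = n = 3 targets all carrying the motif
    out = mot.family_hypergeom(["a0", "a1", "a2"], list(hits.index), fams, hits)
    from math import comb
    assert out["p"].iloc[0] == pytest.approx(comb(6, 3) / comb(10, 3), abs=1e-12)
    # zero hits in target → p = 1
    out0 = mot.family_hypergeom(["a6", "a7"], list(hits.index), fams, hits)
    assert out0["p"].iloc[0] == pytest.approx(1.0)
    # family without motifs in the universe → p = 1
    out_k0 = mot.family_hypergeom(["a0"], list(hits.index), {"E": ["zz"]}, hits)
    assert out_k0["p"].iloc[0] == 1.0


def test_family_hypergeom_null_uniform(rng):
    n_univ = 400
    hits = pd.DataFrame({"m1": rng.random(n_univ) < 0.3},
                        index=[f"a{i}" for i in range(n_univ)])
    fams = {"F": ["m1"]}
    ps = []
    for _ in range(300):
        target = list(rng.choice(hits.index, 50, replace=False))
        ps.append(mot.family_hypergeom(target, list(hits.index), fams, hits)["p"].iloc[0])
    # discrete upper-tail p-values are super-uniform; check the type-I bound
    assert np.mean(np.array(ps) <= 0.05) <= 0.075
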