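"""Block preparation, the short-sequence aligner, conservation classes."""

import numpy as np
import pandas as pd
import pytest

from creevo import synteny as syn
from creevo.core import GenomeRef
from creevo.synteny import AlignParams
from oracles import smith_waterman_score

BASES = np.array(list("ACGT"))


def _rand_seq(rng, n):
    return "".join(rng.choice(BASES, n))


# ---------------------------------------------------------------- blocks

def _blocks(*rows):
    return pd.DataFrame(rows, columns=["block_id", "chromA", "startA", "endA",
                                       "chromB", "startB", "endB", "orientation"])


def _genomes(rng, n=2000):
    sa = _rand_seq(rng, n)
    sb = _rand_seq(rng, n)
    return (GenomeRef({"c": n}, sequence={"c": sa}),
            GenomeRef({"c": n}, sequence={"c": sb}))


def test_prepare_blocks_drops_conflicting_pairs(rng):
    ga, gb = _genomes(rng)
    blocks = _blocks(
        ("b1", "c", 0, 500, "c", 0, 500, "same"),
        ("b2", "c", 0, 500, "c", 600, 1100, "same"),  # same A interval twice
        ("b3", "c", 1000, 1500, "c", 1200, 1700, "same"),
    )
    blk, seqs, report = syn.prepare_blocks(blocks, ga, gb)
    assert report["dropped"] == 2
    assert blk["block_id"].tolist() == ["b3"]


def test_prepare_blocks_inverted_reverse_complemented(rng):
    ga, gb = _genomes(rng)
    blocks = _blocks(("b1", "c", 0, 300, "c", 100, 400, "inverted"))
    _blk, seqs, _ = syn.prepare_blocks(blocks, ga, gb)
    raw = gb.sequence["c"][100:400]
    rc = raw.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    assert seqs["b1"] == rc


def test_lift_through_inverted_block():
    row = pd.Series({"startB": 100, "endB": 400, "orientation": "inverted"})
    gs, ge = syn.lift_to_b(row, 0, 10)  # first 10 bases of the oriented seq
    assert (gs, ge) == (390, 400)  # map to the end of the genomic interval


# ---------------------------------------------------------------- aligner

def test_lambda_identity_for_unit_scoring():
    # Karlin sum equation (1/4)e^λ·1 + (3/4)e^λ·(−1) = 1 has λ = ln 3 exactly
    lam = AlignParams().lam
    assert lam == pytest.approx(np.log(3.0), abs=1e-12)
    assert 0.25 * np.exp(lam * 1) + 0.75 * np.exp(-lam * 1) == pytest.approx(1.0, abs=1e-9)


def test_identical_embedded_word_scores_its_length():
    # flanks are homopolymers of different bases, so the local alignment
    # cannot profitably extend past the identical 25-mer core
    core = "ACGTACGTTGCAACGTTGCATGCAC"
    q = "A" * 20 + core + "A" * 20
    s = "G" * 200 + core + "G" * 200
    hits = syn.align_acr(q, s, AlignParams())
    assert hits, "embedded 25-mer must be found"
    best = hits[0]
    assert best.score == 25 and best.length == 25 and best.identity == 1.0


def test_empty_sequences_no_hits():
    assert syn.align_acr("", "ACGT" * 30) == []
    assert syn.align_acr("ACGT" * 30, "") == []


def test_scores_match_smith_waterman_oracle(rng):
    agree = 0
    n_pairs = 200
    for _ in range(n_pairs):
        core = _rand_seq(rng, 30)
        a = _rand_seq(rng, 35) + core + _rand_seq(rng, 35)
        b = _rand_seq(rng, 35) + core + _rand_seq(rng, 35)
        hits = syn.align_acr(a, b)
        s_impl = max((h.score for h in hits), default=0)
        agree += s_impl == smith_waterman_score(a, b)
    assert agree / n_pairs >= 0.95


def test_null_evalue_calibration(rng):
    # on random pairs the expected number of hits with E ≤ e is ≤ 2e
    params = AlignParams(e_max=2.0, min_len=0)
    thresholds = {0.01: 0, 0.1: 0, 1.0: 0}
    n_pairs = 1000
    for _ in range(n_pairs):
        a = _rand_seq(rng, 100)
        b = _rand_seq(rng, 100)
        for h in syn.align_acr(a, b, params):
            for e in thresholds:
                if h.evalue <= e:
                    thresholds[e] += 1
    for e, count in thresholds.items():
        assert count / n_pairs <= 2 * e


def test_alignment_query_subject_symmetric_score(rng):
    core = _rand_seq(rng, 40)
    a = _rand_seq(rng, 30) + core + _rand_seq(rng, 30)
    b = _rand_seq(rng, 50) + core + _rand_seq(rng, 50)
    s_ab = max(h.score for h in syn.align_acr(a, b))
    s_ba = max(h.score for h in syn.align_acr(b, a))
    assert s_ab == s_ba


# ---------------------------------------------------------------- classes

def test_classify_conservation_three_classes(rng):
    n = 3000
    sa = _rand_seq(rng, n)
    # block B: copy of A with a variable region and an ablated region
    sb = list(sa)
    sb[2000:2500] = rng.choice(BASES, 500)  # ACR at 2000 ablated in B
    sb = "".join(sb)
    ga = GenomeRef({"c": n}, sequence={"c": sa})
    gb = GenomeRef({"c": n}, sequence={"c": sb})
    blocks = _blocks(("b1", "c", 0, n, "c", 0, n, "same"))
    blk, seqs, _ = syn.prepare_blocks(blocks, ga, gb)
    queries = pd.DataFrame({
        "id": ["shared", "variable", "specific", "nonsyn"],
        "chrom": ["c", "c", "c", "cX"],
        "start": [200, 1000, 2050, 0],
        "end": [500, 1300, 2350, 300],
    })
    acrs_b = pd.DataFrame({"id": ["pB"], "chrom": ["c"], "start": [150], "end": [550],
                           "label": ["phloem"]})
    calls = syn.classify_conservation(queries, blk, seqs, ga, acrs_b)
    by_id = dict(zip(calls["id"], calls["class"]))
    assert by_id == {"shared": "shared", "variable": "variable",
                     "specific": "species_specific", "nonsyn": "non-syntenic"}
    assert calls.loc[calls["id"] == "shared", "partner"].iloc[0] == "pB"


def test_celltype_retention_outcomes():
    calls = pd.DataFrame({
        "id": ["q1", "q2", "q3", "q4"],
        "class": ["shared"] * 4,
        "partner": ["p1", "p2", "p3", "p4"],
    })
    labels_a = {"q1": "phloem", "q2": "mesophyll", "q3": "xylem", "q4": "broad"}
    labels_b = {"p1": "phloem", "p2": "bundle_sheath", "p3": "broad"}
    out = syn.celltype_retention(calls, labels_a, labels_b)
    by_id = dict(zip(out["id"], out["outcome"]))
    assert by_id == {"q1": "retained", "q2": "switched", "q3": "broadened"}
    assert "q4" not in by_id  # broad queries are out of scope for retention


def test_species_pair_classes_recovered(study):
    from creevo import simulate as sim

    genome = study["genome"]
    truth = study["truth"]
    genome_b, blocks, acrs_b = sim.simulate_species_pair(genome, truth, divergence=0.12, seed=21)
    blk, seqs, _ = syn.prepare_blocks(blocks, genome, genome_b)
    tp = truth.peaks[truth.peaks["kind"] == "true"]
    mid = (tp["start"] + tp["end"]) // 2
    queries = pd.DataFrame({"id": [f"A{i}" for i in tp.index], "chrom": tp["chrom"].to_numpy(),
                            "start": (mid - 250).to_numpy(), "end": (mid + 250).to_numpy()})
    calls = syn.classify_conservation(queries, blk, seqs, genome, acrs_b)
    tr = {f"A{i}": c for i, c in truth.conservation.items()}
    acc = np.mean([tr[r.id] == r["class"] for _, r in calls.iterrows()])
    assert acc >= 0.95


# ---------------------------------------------------------------- overlaps

def test_region_overlap_whole_genome_and_empty(rng):
    genome = GenomeRef({"c": 100_000},
                       mappable={"c": (np.array([0]), np.array([100_000]))})
    a = pd.DataFrame({"chrom": "c", "start": [100, 5000], "end": [300, 5200]})
    whole = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100_000]})
    res = syn.region_overlap_enrichment(a, whole, genome, n_sim=20, seed=0)
    assert res["observed"] == 1.0 and res["p"] == pytest.approx(1.0)
    empty = pd.DataFrame(columns=["chrom", "start", "end"])
    res0 = syn.region_overlap_enrichment(a, empty, genome, n_sim=20, seed=0)
    assert res0["p"] == pytest.approx(1.0)


def test_region_overlap_detects_planted_enrichment(rng):
    genome = GenomeRef({"c": 1_000_000},
                       mappable={"c": (np.array([0]), np.array([1_000_000]))})
    b = pd.DataFrame({"chrom": "c", "start": np.arange(50) * 20_000,
                      "end": np.arange(50) * 20_000 + 1_000})  # 5% of genome
    # place most A regions inside B: ~3× the area fraction would be 15%;
    # use 60% to plant a strong enrichment
    starts = [i * 20_000 + 200 for i in range(30)] + list(rng.integers(0, 990_000, 20))
    a = pd.DataFrame({"chrom": "c", "start": starts, "end": np.array(starts) + 300})
    res = syn.region_overlap_enrichment(a, b, genome, n_sim=100, seed=1)
    assert res["p"] < 0.01
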