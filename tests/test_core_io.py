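"""Tn5 shifting, nucleus QC, context classes, loop linking, format round-trips."""

import numpy as np
import pandas as pd
import pytest

from creevo import core, io as cio
from creevo.core import QCParams


# ---------------------------------------------------------------- Tn5 shift

def test_shift_tn5_strand_rules():
    pos, keep, n_rej = core.shift_tn5([100], [200], ["+"], [10**6])
    assert pos[0] == 104 and keep[0] and n_rej == 0
    pos, keep, _ = core.shift_tn5([100], [200], ["-"], [10**6])
    assert pos[0] == 194  # 5' end of minus read (end-1) shifted by -5


def test_shift_tn5_rejects_out_of_range():
    pos, keep, n_rej = core.shift_tn5([0], [2], ["-"], [3])
    assert not keep[0] and n_rej == 1
    # plus-strand site past the chromosome end
    _, keep, _ = core.shift_tn5([1], [3], ["+"], [3])
    assert not keep[0]


# ---------------------------------------------------------------- nucleus QC

def _cell(depth=2000, tss=0.3, frip=0.2, org=0.01):
    return {"barcode": "x", "depth": depth, "tss_frac": tss, "frip": frip,
            "organelle_frac": org}


def test_qc_depth_threshold_inclusive():
    cells = pd.DataFrame([_cell(depth=999), _cell(depth=1000)])
    kept = core.qc_filter_nuclei(cells)
    assert kept["depth"].tolist() == [1000]


def test_qc_strict_tss_frip_boundaries():
    cells = pd.DataFrame([_cell(tss=0.2), _cell(frip=0.1), _cell()])
    kept = core.qc_filter_nuclei(cells)
    assert len(kept) == 1  # exact-threshold cells removed (strict >)


def test_qc_caps_cells_by_depth():
    cells = pd.DataFrame([_cell(depth=1000 + i) for i in range(100)])
    kept = core.qc_filter_nuclei(cells, QCParams(max_cells=40))
    assert len(kept) == 40
    assert kept["depth"].min() == 1000 + 60


def test_qc_organelle_high_tail():
    cells = pd.DataFrame([_cell(org=0.01) for _ in range(50)] + [_cell(org=0.9)])
    kept = core.qc_filter_nuclei(cells)
    assert len(kept) == 50


def test_qc_empty_input():
    out = core.qc_filter_nuclei(pd.DataFrame(columns=["depth", "tss_frac", "frip", "organelle_frac"]))
    assert len(out) == 0


# ---------------------------------------------------------------- context

GENES = pd.DataFrame(
    {"chrom": ["chr1", "chr1"], "start": [1800, 2500], "end": [3000, 4000],
     "strand": ["+", "+"], "gene_id": ["g1", "g2"]}
)


@pytest.mark.parametrize(
    "start,end,expected",
    [(1500, 2000, "genic"), (0, 500, "proximal"), (5990, 6010, "proximal")],
)
def test_classify_context_classes(start, end, expected):
    acrs = pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [end]})
    out = core.classify_context(acrs, GENES)
    assert out["context"].iloc[0] == expected


def test_classify_context_distal_beyond_2kb():
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [2501], "end": [4000],
                          "strand": ["+"], "gene_id": ["g"]})
    out = core.classify_context(pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]}), genes)
    assert out["context"].iloc[0] == "distal"  # gap 2001 > 2000


def test_classify_context_missing_chrom_flags_distal():
    out = core.classify_context(pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [500]}), GENES)
    assert out["context"].iloc[0] == "distal" and out["no_annotation"].iloc[0]


# ---------------------------------------------------------------- round trips

def test_bed_round_trip(tmp_path):
    df = pd.DataFrame({"chrom": ["chr1", "chr2"], "start": [0, 10], "end": [500, 40]})
    cio.write_bed(df, tmp_path / "x.bed")
    back = cio.read_bed(tmp_path / "x.bed")
    pd.testing.assert_frame_equal(back, df)


def test_gff3_coordinate_convention(tmp_path):
    genes = pd.DataFrame({"chrom": ["chr1"], "start": [99], "end": [200],
                          "strand": ["+"], "gene_id": ["g1"]})
    cio.write_gff3_genes(genes, tmp_path / "g.gff3")
    text = (tmp_path / "g.gff3").read_text()
    assert "\t100\t200\t" in text  # 1-based inclusive on disk
    back = cio.read_gff3_genes(tmp_path / "g.gff3")
    pd.testing.assert_frame_equal(back, genes)


def test_fasta_round_trip(tmp_path):
    seqs = {"chr1": "ACGT" * 50, "chr2": "TTTTACGT"}
    cio.write_fasta(seqs, tmp_path / "g.fa", width=13)
    assert cio.read_fasta(tmp_path / "g.fa") == seqs


def test_fragments_round_trip_and_count_expansion(tmp_path):
    from creevo.simulate import fragments_to_insertions

    df = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [110],
                       "barcode": ["bc1"], "count": [3]})
    cio.write_fragments(df, tmp_path / "f.tsv")
    back = cio.read_fragments(tmp_path / "f.tsv")
    pd.testing.assert_frame_equal(back, df)
    ins = fragments_to_insertions(back)
    assert len(ins) == 3 and (ins["frag_size"] == 100).all()


def test_jaspar_round_trip(tmp_path):
    pfms = {"MA0001.1": np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9], [10, 11, 12]], dtype=float)}
    cio.write_jaspar_pfms(pfms, tmp_path / "m.pfm")
    back = cio.read_jaspar_pfms(tmp_path / "m.pfm")
    np.testing.assert_array_equal(back["MA0001.1"], pfms["MA0001.1"])


def test_sparse_matrix_round_trip(tmp_path):
    from scipy import sparse

    mat = sparse.random(8, 5, density=0.4, random_state=0, data_rvs=lambda n: np.arange(1, n + 1))
    cio.write_sparse_matrix(mat, [f"r{i}" for i in range(8)], [f"c{j}" for j in range(5)],
                            tmp_path / "m")
    back, rows, cols = cio.read_sparse_matrix(tmp_path / "m")
    np.testing.assert_allclose(back.toarray(), mat.toarray())
    assert rows == [f"r{i}" for i in range(8)]


def test_malformed_bed_reports_line():
    import io as _stdio

    with pytest.raises(cio.FormatError, match="line"):
        cio.read_bed(_stdio.StringIO("chr1\t10\t5\n"))


# ---------------------------------------------------------------- loops

def _loops(*rows):
    return pd.DataFrame(rows, columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "name", "fdr"])


GENE_PLUS = pd.DataFrame({"chrom": ["chr1"], "start": [11000], "end": [13000],
                          "strand": ["+"], "gene_id": ["g1"]})


def test_link_loops_promoter_geometry():
    loops = _loops(("chr1", 0, 5000, "chr1", 10000, 15000, ".", 0.01))
    acrs = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [600], "id": ["a1"],
                         "cell_type": ["phloem"]})
    out = core.link_loops(loops, acrs, GENE_PLUS)
    assert len(out) == 1 and out["gene_id"].iloc[0] == "g1"


def test_link_loops_distant_tss_not_linked():
    genes = GENE_PLUS.assign(start=20000, end=22000)
    loops = _loops(("chr1", 0, 5000, "chr1", 10000, 15000, ".", 0.01))
    acrs = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [600], "id": ["a1"]})
    assert len(core.link_loops(loops, acrs, genes)) == 0


def test_link_loops_self_loop_deduplicated():
    loops = _loops(("chr1", 10000, 15000, "chr1", 10000, 15000, ".", 0.01))
    acrs = pd.DataFrame({"chrom": ["chr1"], "start": [10100], "end": [10600], "id": ["a1"]})
    out = core.link_loops(loops, acrs, GENE_PLUS)
    assert len(out) == 1  # both bin orders hit; collapsed to one triple


def test_link_loops_rejects_wrong_resolution():
    loops = _loops(("chr1", 0, 4000, "chr1", 10000, 15000, ".", 0.01))
    with pytest.raises(ValueError, match="resolution"):
        core.link_loops(loops, pd.DataFrame(columns=["chrom", "start", "end", "id"]), GENE_PLUS)


def test_link_loops_celltype_match_flag():
    loops = _loops(("chr1", 0, 5000, "chr1", 10000, 15000, ".", 0.01))
    acrs = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [600], "id": ["a1"],
                         "cell_type": ["phloem"]})
    spec = pd.DataFrame({"gene_id": ["g1"], "cell_type": ["phloem"]})
    out = core.link_loops(loops, acrs, GENE_PLUS, specific_genes=spec)
    assert out["celltype_match"].iloc[0]
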