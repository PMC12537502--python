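"""Core domain objects and single-cell ATAC primitives.

Tn5 strand shifting, nucleus quality control, genomic-context classification
of accessible chromatin regions (ACRs), and Hi-C loop linking of distal
cell-type-specific ACRs to promoters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv


@dataclass
class GenomeRef:
    """Reference genome: sizes, optional sequence, mappability and exon masks.

    ``mappable`` and ``exons`` map chrom → (starts, ends) arrays in 0-based
    half-open coordinates.  Permutation sampling operates on
    mappable ∖ exonic space.
    """

    chrom_sizes: dict[str, int]
    sequence: dict[str, str] | None = None
    mappable: dict[str, tuple] = field(default_factory=dict)
    exons: dict[str, tuple] = field(default_factory=dict)

    def sampling_space(self, chrom: str):
        """Mappable minus exonic intervals for one chromosome."""
        if chrom in self.mappable:
            ms, me = self.mappable[chrom]
        else:
            ms, me = np.array([0]), np.array([self.chrom_sizes[chrom]])
        if chrom in self.exons:
            es, ee = self.exons[chrom]
            return iv.subtract(ms, me, es, ee)
        return (np.asarray(ms, dtype=np.int64), np.asarray(me, dtype=np.int64))


# ---------------------------------------------------------------- Tn5 shift

def shift_tn5(starts, ends, strands, chrom_lengths=None):
    """Tn5 integration sites from aligned read coordinates (+4 / −5 rule).

    Plus-strand reads yield ``start + 4``; minus-strand reads yield the 5′ end
    of the read (``end − 1``) shifted by −5.  Returns (positions, keep_mask,
    n_rejected): positions outside ``[0, chrom_length)`` are rejected.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    strands = np.asarray(strands)
    pos = np.where(strands == "+", starts + 4, ends - 1 - 5)
    keep = pos >= 0
    if chrom_lengths is not None:
        keep &= pos < np.asarray(chrom_lengths, dtype=np.int64)
    return pos, keep, int((~keep).sum())


# ---------------------------------------------------------------- nucleus QC

@dataclass
class QCParams:
    min_depth: int = 1000
    max_cells: int = 16000
    min_tss_frac: float = 0.2
    min_frip: float = 0.1
    organelle_sd: float = 2.0


def qc_filter_nuclei(cells: pd.DataFrame, params: QCParams = QCParams()) -> pd.DataFrame:
    """Filter barcodes to high-quality nuclei.

    Keeps cells with depth ≥ 1,000 insertions, TSS fraction > 0.2 and FRiP
    > 0.1 (both strict), organelle fraction within mean + 2 sd of the
    library, then caps the library at 16,000 cells by depth.  Returns a copy
    with ``pass_qc`` set on all input rows plus the filtered subset flag.
    """
    cells = cells.copy()
    if len(cells) == 0:
        cells["pass_qc"] = pd.Series(dtype=bool)
        return cells
    org = cells["organelle_frac"]
    org_cut = org.mean() + params.organelle_sd * org.std(ddof=1)
    if not np.isfinite(org_cut):  # single-cell library: sd undefined
        org_cut = np.inf
    ok = (
        (cells["depth"] >= params.min_depth)
        & (cells["tss_frac"] > params.min_tss_frac)
        & (cells["frip"] > params.min_frip)
        & (org <= org_cut)
    )
    if ok.sum() > params.max_cells:
        keep_idx = cells.loc[ok, "depth"].nlargest(params.max_cells).index
        ok = ok & cells.index.isin(keep_idx)
    cells["pass_qc"] = ok
    return cells[cells["pass_qc"]].copy()


# ---------------------------------------------------------------- ACR context

def classify_context(acrs: pd.DataFrame, genes: pd.DataFrame, proximal_bp: int = 2000) -> pd.DataFrame:
    """Label each ACR genic / proximal / distal relative to gene bodies.

    Genic: ≥1 bp overlap with a gene body.  Proximal: nearest gene edge
    within ``proximal_bp`` (boundary-inclusive).  Distal: farther, or on a
    chromosome absent from the annotation (flagged).  Adds ``context``,
    ``nearest_gene``, ``signed_dist`` (negative = ACR upstream of gene start).
    """
    acrs = acrs.copy()
    acrs["context"] = "distal"
    acrs["nearest_gene"] = ""
    acrs["signed_dist"] = np.int64(0)
    acrs["no_annotation"] = False
    for chrom, sub in acrs.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if len(g) == 0:
            acrs.loc[sub.index, "no_annotation"] = True
            continue
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        ov = iv.overlaps_any(sub["start"].to_numpy(), sub["end"].to_numpy(), gs, ge)
        gaps, idx = iv.nearest_gap(sub["start"].to_numpy(), sub["end"].to_numpy(), gs, ge)
        ctx = np.where(ov, "genic", np.where(gaps <= proximal_bp, "proximal", "distal"))
        acrs.loc[sub.index, "context"] = ctx
        acrs.loc[sub.index, "nearest_gene"] = g["gene_id"].to_numpy()[idx]
        before = sub["end"].to_numpy() <= gs[idx]
        signed = np.where(before, -gaps, gaps)
        acrs.loc[sub.index, "signed_dist"] = np.where(ov, 0, signed)
    return acrs


# ---------------------------------------------------------------- loop linking

def promoter_intervals(genes: pd.DataFrame, upstream: int = 2000) -> pd.DataFrame:
    """Promoters as the 2 kb upstream of the TSS (strand-aware), half-open."""
    plus = genes["strand"] == "+"
    tss = np.where(plus, genes["start"], genes["end"])
    start = np.where(plus, tss - upstream, tss)
    end = np.where(plus, tss, tss + upstream)
    return pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy(),
            "start": np.maximum(start, 0),
            "end": end,
            "gene_id": genes["gene_id"].to_numpy(),
        }
    )


def link_loops(
    loops: pd.DataFrame,
    acrs: pd.DataFrame,
    genes: pd.DataFrame,
    specific_genes: pd.DataFrame | None = None,
    resolution: int = 5000,
    upstream: int = 2000,
) -> pd.DataFrame:
    """Link distal cell-type-specific ACRs to genes through Hi-C loops.

    A link exists when one 5 kb loop bin overlaps the ACR and the partner bin
    overlaps the gene's 2 kb upstream promoter; both bin orders are tried and
    duplicate (ACR, gene, loop) triples are collapsed.  ``celltype_match``
    flags links where the ACR's cell type equals the gene's specific cell
    type (requires ``specific_genes`` with gene_id, cell_type).
    """
    widths_ok = ((loops["endA"] - loops["startA"]) == resolution) & (
        (loops["endB"] - loops["startB"]) == resolution
    )
    if not widths_ok.all():
        raise ValueError("loop bin width differs from configured resolution")
    proms = promoter_intervals(genes, upstream)
    gene_ct = {}
    if specific_genes is not None:
        gene_ct = dict(zip(specific_genes["gene_id"], specific_genes["cell_type"]))
    out = []
    for li, loop in enumerate(loops.itertuples()):
        bins = [
            (loop.chromA, loop.startA, loop.endA),
            (loop.chromB, loop.startB, loop.endB),
        ]
        for a_bin, p_bin in ((0, 1), (1, 0)):
            ca, sa, ea = bins[a_bin]
            cp, sp, ep = bins[p_bin]
            hit_acrs = acrs[(acrs["chrom"] == ca) & (acrs["start"] < ea) & (acrs["end"] > sa)]
            hit_proms = proms[(proms["chrom"] == cp) & (proms["start"] < ep) & (proms["end"] > sp)]
            for acr in hit_acrs.itertuples():
                for pr in hit_proms.itertuples():
                    out.append(
                        {
                            "loop": li,
                            "acr_id": acr.id,
                            "gene_id": pr.gene_id,
                            "acr_cell_type": getattr(acr, "cell_type", ""),
                            "gene_cell_type": gene_ct.get(pr.gene_id, ""),
                        }
                    )
    df = pd.DataFrame(out, columns=["loop", "acr_id", "gene_id", "acr_cell_type", "gene_cell_type"])
    df = df.drop_duplicates(subset=["loop", "acr_id", "gene_id"]).reset_index(drop=True)
    df["celltype_match"] = (df["acr_cell_type"] == df["gene_cell_type"]) & (
        df["gene_cell_type"] != ""
    )
    return df
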