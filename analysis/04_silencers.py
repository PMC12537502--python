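"""Classify H3K27me3-associated ACRs, recover planted silencers, call BMRs.

Accessibility calls (coverage > 2 per million, ≥20 insertions, quantile-
normalized CPM > 2) feed the broad (≥ n−1 of n cell types) vs cell-type-
specific (< 3) split; candidate silencers are the H3K27me3-associated broad
ACRs.  PRE-motif capture in candidate silencers is tested against
length-matched simulated controls with the exact binomial test.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location("config", Path(__file__).parent / "00_config.py")
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

from creevo import acr, intervals as iv, motifs as mot, silencer as sil  # noqa: E402
from creevo import io as cio  # noqa: E402
from creevo.simulate import PRE_PATTERNS  # noqa: E402



def main() -> None:
    call_mod = importlib.util.spec_from_file_location(
        "call_acrs", Path(__file__).parent / "02_call_acrs.py"
    )
    call = importlib.util.module_from_spec(call_mod)
    call_mod.loader.exec_module(call)
    genome, genes, ins, cells, nuc, truth = call.load_inputs()
    atlas = pd.read_csv(cfg.RESULTS / "acr_atlas.tsv", sep="\t")
    h3k = cio.read_bed(cfg.DATA / "h3k27me3.bed")

    counts, max_cov, totals = acr.per_celltype_acr_stats(atlas, ins, genome)
    acc = sil.accessible_call_matrix(max_cov, counts, totals)
    ann = sil.classify_h3k27me3_acrs(atlas, acc, h3k)
    ann.to_csv(cfg.RESULTS / "silencer_annotation.tsv", sep="\t", index=False)

    cand = ann[(ann["h3k27me3_status"] == "associated") & (ann["breadth"] == "broad")]
    sil_peaks = truth.peaks.loc[truth.silencer_peaks]
    rec = 0
    for chrom, sub in sil_peaks.groupby("chrom"):
        c = cand[cand["chrom"] == chrom]
        rec += iv.overlaps_any(sub["start"].to_numpy(), sub["end"].to_numpy(),
                               c["start"].to_numpy(), c["end"].to_numpy()).sum()
    print(f"candidate silencers: {len(cand)}; planted recovered {rec}/{len(sil_peaks)}")

    # PRE motif capture vs length-matched genomic controls
    pats = [mot.MotifModel.from_pattern(k, v) for k, v in PRE_PATTERNS.items()]
    seqs = {r.id: genome.sequence[r.chrom][r.start:r.end] for r in cand.itertuples()}
    _, binmat = mot.scan_motifs(seqs, pats)
    ctrl_sets = mot.simulate_control_regions(
        cand[["chrom", "start", "end"]], genome, n_sets=100, seed=cfg.SEED
    )
    print("PRE capture in candidate silencers (binomial vs 100 simulated controls):")
    for pat in binmat.columns:
        k = int(binmat[pat].sum())
        null = []
        for cs in ctrl_sets[:100]:
            cseqs = {f"c{i}": genome.sequence[r.chrom][r.start:r.end]
                     for i, r in enumerate(cs.itertuples())}
            _, cb = mot.scan_motifs(cseqs, [m for m in pats if m.id == pat])
            null.append(cb[pat].mean())
        p0, p = mot.binomial_enrichment(k, len(cand), null)
        print(f"  {pat}: {k}/{len(cand)} captured, null {p0:.3f}, p = {p:.2e}")

    meth = pd.read_csv(cfg.DATA / "methylation.tsv", sep="\t")
    bmrs = sil.call_bmrs(meth)
    cio.write_bed(bmrs, cfg.RESULTS / "bmrs.bed")
    rec_b = 0
    for chrom, sub in truth.bmrs.groupby("chrom"):
        b = bmrs[bmrs["chrom"] == chrom]
        rec_b += iv.overlaps_any(sub["start"].to_numpy(), sub["end"].to_numpy(),
                                 b["start"].to_numpy(), b["end"].to_numpy()).sum()
    print(f"BMRs: {len(bmrs)} called; planted recovered {rec_b}/{len(truth.bmrs)}")


if __name__ == "__main__":
    sys.exit(main())
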