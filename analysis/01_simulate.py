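"""Generate the synthetic study: genome, genes, epigenome, fragments, truth.

Writes FASTA/GFF3/BED/TSV inputs under results/data/ exactly as a real
experiment would provide them; downstream stages only read these files.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location("config", Path(__file__).parent / "00_config.py")
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

from creevo import io as cio  # noqa: E402
from creevo import simulate as sim  # noqa: E402


def main() -> None:
    cfg.DATA.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = sim.simulate_reference(seed=cfg.SEED)
    h3k, nuc, meth = sim.simulate_epigenome(genome, truth, seed=cfg.SEED + 1)
    cell_types = sorted(set(truth.peaks["peak_class"]) - {"broad"})
    plan = {ct: cfg.CELLS_PER_TYPE for ct in cell_types}
    ins, cells = sim.simulate_fragments(genome, truth, plan, snr=cfg.SNR, seed=cfg.SEED + 2)
    genome_b, blocks, acrs_b = sim.simulate_species_pair(genome, truth, seed=cfg.SEED + 3)

    cio.write_fasta(genome.sequence, cfg.DATA / "genomeA.fa")
    cio.write_fasta(genome_b.sequence, cfg.DATA / "genomeB.fa")
    cio.write_gff3_genes(genes, cfg.DATA / "genes.gff3")
    cio.write_fragments(sim.insertions_to_fragments(ins), cfg.DATA / "fragments.tsv")
    cells.to_csv(cfg.DATA / "cells.tsv", sep="\t", index=False)
    cio.write_bed(h3k, cfg.DATA / "h3k27me3.bed")
    cio.write_bed(nuc, cfg.DATA / "nucleosomes.bed")
    meth.to_csv(cfg.DATA / "methylation.tsv", sep="\t", index=False)
    blocks.to_csv(cfg.DATA / "syntenic_blocks.tsv", sep="\t", index=False)
    acrs_b.to_csv(cfg.DATA / "acrs_speciesB.tsv", sep="\t", index=False)
    truth.to_json(cfg.DATA / "truth.json")

    print(f"genome: {len(genome.chrom_sizes)} chromosomes, {sum(genome.chrom_sizes.values()):,} bp")
    print(f"planted peaks: {int((truth.peaks.kind == 'true').sum())} true, "
          f"{int((truth.peaks.kind == 'decoy').sum())} nucleosomal decoys")
    print(f"candidate silencers (broad peaks in H3K27me3): {len(truth.silencer_peaks)}")
    print(f"cells: {len(cells)} across {len(cell_types)} cell types; insertions: {len(ins):,}")


if __name__ == "__main__":
    sys.exit(main())
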