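"""Cross-species conservation classes and cell-type retention.

ACR windows around the planted peaks are aligned into their syntenic blocks
of the sister genome; hits (E ≤ 1e−3, length > 20) plus the partner ACR set
yield shared / variable / species-specific calls, compared against the
planted conservation truth.
"""

import importlib.util
import sys
from pathlib import Path

import numpy as np
import pandas as pd

spec = importlib.util.spec_from_file_location("config", Path(__file__).parent / "00_config.py")
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

from creevo import io as cio  # noqa: E402
from creevo import synteny as syn  # noqa: E402
from creevo.core import GenomeRef  # noqa: E402
from creevo.simulate import SimTruth  # noqa: E402


def main() -> None:
    seqs_a = cio.read_fasta(cfg.DATA / "genomeA.fa")
    seqs_b = cio.read_fasta(cfg.DATA / "genomeB.fa")
    genome_a = GenomeRef({c: len(s) for c, s in seqs_a.items()}, sequence=seqs_a)
    genome_b = GenomeRef({c: len(s) for c, s in seqs_b.items()}, sequence=seqs_b)
    blocks = pd.read_csv(cfg.DATA / "syntenic_blocks.tsv", sep="\t")
    acrs_b = pd.read_csv(cfg.DATA / "acrs_speciesB.tsv", sep="\t")
    truth = SimTruth.from_json(cfg.DATA / "truth.json")

    blk, bseqs, report = syn.prepare_blocks(blocks, genome_a, genome_b)
    tp = truth.peaks[truth.peaks["kind"] == "true"]
    mid = (tp["start"] + tp["end"]) // 2
    queries = pd.DataFrame({
        "id": [f"A{i}" for i in tp.index],
        "chrom": tp["chrom"].to_numpy(),
        "start": (mid - 250).to_numpy(),
        "end": (mid + 250).to_numpy(),
    })
    calls = syn.classify_conservation(queries, blk, bseqs, genome_a, acrs_b)
    calls.to_csv(cfg.RESULTS / "conservation_calls.tsv", sep="\t", index=False)

    tr = {f"A{i}": c for i, c in truth.conservation.items()}
    acc = float(np.mean([tr[r.id] == r["class"] for _, r in calls.iterrows()]))
    print(f"blocks kept: {len(blk)} (dropped {report['dropped']})")
    print("classes:", calls["class"].value_counts().to_dict())
    print(f"accuracy vs planted truth: {acc:.3f}")

    labels_a = {f"A{i}": truth.peaks.loc[i, "peak_class"] for i in tp.index}
    labels_b = dict(zip(acrs_b["id"], acrs_b["label"]))
    ret = syn.celltype_retention(calls, labels_a, labels_b)
    ret.to_csv(cfg.RESULTS / "celltype_retention.tsv", sep="\t", index=False)
    correct = sum(
        1 for r in ret.itertuples()
        if truth.retention.get(int(r.id[1:])) == (r.cell_type_a if r.outcome == "retained" else r.cell_type_b)
    )
    print(f"retention outcomes: {ret['outcome'].value_counts().to_dict()}; "
          f"truth matched {correct}/{len(ret)}")


if __name__ == "__main__":
    sys.exit(main())
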