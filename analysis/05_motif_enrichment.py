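"""Motif scanning over the ACR atlas and the three enrichment tests.

PWM/pattern scanning at the exact p < 1e−5 threshold builds the binarized
peak×motif matrix; the motif-by-cell count matrix (peak×motif ᵀ × peak×cell)
feeds the negative-binomial regression per cell type (412 cells each);
family enrichment of cell-type-specific ACRs uses the one-tailed
hypergeometric test.
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
from creevo import motifs as mot  # noqa: E402
from creevo.simulate import PRE_PATTERNS  # noqa: E402


def main() -> None:
    atlas = pd.read_csv(cfg.RESULTS / "acr_atlas.tsv", sep="\t")
    labels = pd.read_csv(cfg.RESULTS / "specificity_labels.tsv", sep="\t")
    mat, acr_ids, barcodes = cio.read_sparse_matrix(cfg.RESULTS / "peak_by_cell")
    cells = pd.read_csv(cfg.DATA / "cells.tsv", sep="\t")
    seqs = cio.read_fasta(cfg.DATA / "genomeA.fa")

    models = [mot.MotifModel.from_pattern(k, v, family=k.split("-")[0])
              for k, v in PRE_PATTERNS.items()]
    acr_seqs = {r.id: seqs[r.chrom][r.start:r.end] for r in atlas.itertuples()}
    hits, binmat = mot.scan_motifs(acr_seqs, models)
    hits.to_csv(cfg.RESULTS / "motif_hits.tsv", sep="\t", index=False)
    print(f"scanned {len(acr_seqs)} ACRs × {len(models)} motifs: {len(hits)} hits")

    # motif-by-cell counts = (peak×motif)ᵀ · (peak×cell)
    M = binmat.loc[acr_ids].to_numpy().astype(float)
    Y = pd.DataFrame(M.T @ mat.toarray(), index=binmat.columns)
    nonzero = np.asarray((mat > 0).sum(axis=0)).ravel()
    res = mot.nb_enrichment(Y, cells, nonzero, seed=cfg.SEED)
    res.to_csv(cfg.RESULTS / "nb_enrichment.tsv", sep="\t", index=False)
    print("NB-enriched (q<0.01, beta>0.05):",
          res.loc[res["enriched"], ["motif", "cell_type"]].to_records(index=False).tolist())

    specific_ids = labels.loc[labels["label"] == "cell-type-specific", "acr_id"].tolist()
    fams = {}
    for m in models:
        fams.setdefault(m.family, []).append(m.id)
    famres = mot.family_hypergeom(specific_ids, list(binmat.index), fams, binmat)
    famres.to_csv(cfg.RESULTS / "family_enrichment.tsv", sep="\t", index=False)
    print(f"family hypergeometric tests written for {len(famres)} families")


if __name__ == "__main__":
    sys.exit(main())
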