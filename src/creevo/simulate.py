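"""Seeded generators for every input the pipeline consumes.

The generators emulate a multi-organ single-cell ATAC experiment at desk
scale: a two-chromosome genome with non-overlapping gene models, planted
accessible chromatin regions (ACRs) that are either broad (active in all
cell types) or specific to one cell type, nucleosomal decoy peaks that the
fragment-size and nucleosome filters must remove, H3K27me3 domains over a
subset of broad peaks (candidate silencers, PRE motifs planted in their
sequence), a diverged sister genome with syntenic blocks carrying
shared / variable / species-specific ACR truth, and paired pseudotime
motif-deviation trajectories with planted early-shifts.

Every generator takes an integer seed and is byte-deterministic under it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeRef

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

# The six Polycomb-response-element motif classes, shipped as IUPAC-free
# consensus patterns (replaceable assets; see docs/methods.md).
PRE_PATTERNS = {
    "CTCC": "CTCCTCC",
    "CCG": "CCGCCGCC",
    "G-box": "CACGTG",
    "GA-repeat": "GAGAGAGA",
    "AC-rich": "ACACACAC",
    "Telobox": "AAACCCTA",
}


@dataclass
class SimTruth:
    """Planted ground truth for recovery tests; JSON round-trippable."""

    peaks: pd.DataFrame  # chrom,start,end,peak_class,strength,kind(true/decoy)
    motif_sites: pd.DataFrame  # motif,chrom,pos,strand
    h3k27me3: pd.DataFrame  # chrom,start,end
    silencer_peaks: list = field(default_factory=list)  # indices into peaks
    conservation: dict = field(default_factory=dict)  # peak idx -> class
    retention: dict = field(default_factory=dict)  # peak idx -> partner cell type
    shift: dict = field(default_factory=dict)  # motif -> label
    bmrs: pd.DataFrame | None = None  # chrom,start,end
    seed: int = 0

    def to_json(self, path) -> None:
        obj = {
            "peaks": self.peaks.to_dict("list"),
            "motif_sites": self.motif_sites.to_dict("list"),
            "h3k27me3": self.h3k27me3.to_dict("list"),
            "silencer_peaks": list(map(int, self.silencer_peaks)),
            "conservation": {str(k): v for k, v in self.conservation.items()},
            "retention": {str(k): v for k, v in self.retention.items()},
            "shift": self.shift,
            "bmrs": None if self.bmrs is None else self.bmrs.to_dict("list"),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            peaks=pd.DataFrame(obj["peaks"]),
            motif_sites=pd.DataFrame(obj["motif_sites"]),
            h3k27me3=pd.DataFrame(obj["h3k27me3"]),
            silencer_peaks=obj["silencer_peaks"],
            conservation={int(k): v for k, v in obj["conservation"].items()},
            retention={int(k): v for k, v in obj["retention"].items()},
            shift=obj["shift"],
            bmrs=None if obj["bmrs"] is None else pd.DataFrame(obj["bmrs"]),
            seed=obj["seed"],
        )


def _random_seq(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


# ---------------------------------------------------------------- reference

def simulate_reference(
    n_chrom: int = 2,
    chrom_len: int = 1_000_000,
    cell_types: tuple = ("mesophyll", "epidermis", "phloem", "xylem", "cortex", "guard"),
    n_peaks: int = 60,
    n_decoys: int = 10,
    frac_broad: float = 0.4,
    context_ratio: tuple = (0.19, 0.52, 0.29),
    motif_plant: dict | None = None,
    seed: int = 0,
):
    """Uniform-background genome with genes and planted peaks.

    The genome is tiled into 14 kb slots, each carrying one 2 kb gene; a
    random subset of slots also receives one 300 bp peak whose genomic
    context (genic / proximal / distal) follows ``context_ratio`` (default
    mirrors the observed atlas 19/52/29% split).  Broad peaks are active in
    every cell type, the rest in exactly one.  ``motif_plant`` maps motif id
    → (consensus, n_sites) and embeds the consensus at random positions.

    Returns (GenomeRef, genes DataFrame, SimTruth).
    """
    if chrom_len < 50_000:
        raise ValueError("chrom_len must be ≥ 50 kb")
    rng = np.random.default_rng(seed)
    slot = 14_000
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    sizes = {c: chrom_len for c in chroms}
    seqs = {c: _random_seq(rng, chrom_len) for c in chroms}

    gene_rows = []
    slots = []  # (chrom, slot_start)
    for c in chroms:
        for s0 in range(0, chrom_len - slot, slot):
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((c, s0 + 4000, s0 + 6000, strand, f"{c}_g{s0 // slot}"))
            slots.append((c, s0))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "gene_id"])

    total = n_peaks + n_decoys
    if total > len(slots):
        raise ValueError("requested peaks exceed genome capacity")
    chosen = rng.choice(len(slots), size=total, replace=False)
    contexts = rng.choice(["genic", "proximal", "distal"], size=n_peaks, p=list(context_ratio))
    n_broad = int(round(frac_broad * n_peaks))
    classes = ["broad"] * n_broad + [
        cell_types[i % len(cell_types)] for i in range(n_peaks - n_broad)
    ]
    rng.shuffle(classes)

    peak_rows = []
    width = 300
    for i in range(total):
        c, s0 = slots[chosen[i]]
        if i < n_peaks:
            ctx = contexts[i]
            if ctx == "genic":
                off = 4500
            elif ctx == "proximal":
                off = 6500
            else:
                off = 10_000
            start = s0 + off + int(rng.integers(0, 100))
            peak_rows.append((c, start, start + width, classes[i], float(rng.uniform(0.8, 1.2)), "true"))
        else:
            start = s0 + 10_500 + int(rng.integers(0, 100))
            peak_rows.append((c, start, start + width, "broad", float(rng.uniform(0.8, 1.2)), "decoy"))
    peaks = pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "peak_class", "strength", "kind"]
    )

    motif_rows = []
    if motif_plant:
        for motif_id, (consensus, n_sites) in motif_plant.items():
            L = len(consensus)
            for _ in range(n_sites):
                c = chroms[rng.integers(0, n_chrom)]
                pos = int(rng.integers(0, chrom_len - L))
                strand = "+" if rng.random() < 0.5 else "-"
                word = consensus if strand == "+" else _revcomp(consensus)
                seqs[c] = seqs[c][:pos] + word + seqs[c][pos + L:]
                motif_rows.append((motif_id, c, pos, strand))
    motif_sites = pd.DataFrame(motif_rows, columns=["motif", "chrom", "pos", "strand"])

    genome = GenomeRef(
        chrom_sizes=sizes,
        sequence=seqs,
        mappable={c: (np.array([0]), np.array([chrom_len])) for c in chroms},
        exons={
            c: (
                genes.loc[genes.chrom == c, "start"].to_numpy(),
                genes.loc[genes.chrom == c, "end"].to_numpy(),
            )
            for c in chroms
        },
    )
    truth = SimTruth(
        peaks=peaks,
        motif_sites=motif_sites,
        h3k27me3=pd.DataFrame(columns=["chrom", "start", "end"]),
        seed=seed,
    )
    return genome, genes, truth


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------- fragments

def simulate_fragments(
    genome: GenomeRef,
    truth: SimTruth,
    cell_plan: dict[str, int],
    depth_mean: int = 2000,
    depth_dispersion: float = 10.0,
    snr: float = 5.0,
    seed: int = 0,
):
    """Per-barcode Tn5 insertions from a peak/background mixture.

    Depth per cell is negative binomial; each insertion falls in a planted
    peak active for the cell's type with probability
    ``snr·L_peak / (snr·L_peak + L_rest)`` (per-bp in-peak rate ``snr``-fold
    the background), positioned triangularly around the peak midpoint so the
    summit is well defined.  Fragment sizes are bimodal: subnucleosomal
    (<150 bp) in true peaks, nucleosomal (>150 bp) in decoy peaks.

    Returns (insertions DataFrame [chrom,pos,barcode,frag_size,cell_type],
    cells DataFrame).
    """
    if snr <= 1:
        raise ValueError("snr must exceed 1")
    rng = np.random.default_rng(seed)
    chroms = list(genome.chrom_sizes)
    clen = np.array([genome.chrom_sizes[c] for c in chroms], dtype=np.int64)
    genome_len = int(clen.sum())
    peaks = truth.peaks
    known = set(peaks["peak_class"]) - {"broad"}
    unknown = [ct for ct in cell_plan if ct not in known]
    if unknown:
        raise ValueError(f"unknown cell type in plan: {unknown}")
    all_rows = []
    cell_rows = []
    p_nb = depth_dispersion / (depth_dispersion + depth_mean)
    for ct, n_cells in cell_plan.items():
        active = peaks[(peaks["peak_class"] == "broad") | (peaks["peak_class"] == ct)]
        pw = (active["end"] - active["start"]).to_numpy()
        strength = active["strength"].to_numpy()
        l_peak = float((pw * strength).sum())
        w_peak = snr * l_peak / (snr * l_peak + (genome_len - pw.sum()))
        p_choice = pw * strength / (pw * strength).sum()
        is_decoy = (active["kind"] == "decoy").to_numpy()
        a_chrom = active["chrom"].to_numpy()
        a_start = active["start"].to_numpy()
        depths = rng.negative_binomial(depth_dispersion, p_nb, size=n_cells)
        for j in range(n_cells):
            bc = f"{ct}-{j:04d}"
            d = int(depths[j])
            n_in = rng.binomial(d, w_peak)
            # in-peak insertions
            pk = rng.choice(len(active), size=n_in, p=p_choice)
            frac = (rng.random(n_in) + rng.random(n_in)) / 2  # triangular
            pos_in = a_start[pk] + (frac * pw[pk]).astype(np.int64)
            fs_in = np.where(
                is_decoy[pk],
                rng.normal(230, 40, n_in).clip(152, 400),
                rng.normal(80, 25, n_in).clip(35, 147),
            ).astype(np.int64)
            # background insertions
            n_bg = d - n_in
            gpos = rng.integers(0, genome_len, n_bg)
            ci = np.searchsorted(np.cumsum(clen), gpos, side="right")
            pos_bg = gpos - np.concatenate([[0], np.cumsum(clen)])[ci]
            fs_bg = np.where(
                rng.random(n_bg) < 0.5,
                rng.normal(80, 25, n_bg).clip(35, 147),
                rng.normal(230, 40, n_bg).clip(152, 400),
            ).astype(np.int64)
            chrom_arr = np.concatenate([a_chrom[pk], np.array(chroms, dtype=object)[ci]])
            pos_arr = np.concatenate([pos_in, pos_bg])
            fs_arr = np.concatenate([fs_in, fs_bg])
            all_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom_arr,
                        "pos": pos_arr,
                        "barcode": bc,
                        "frag_size": fs_arr,
                        "cell_type": ct,
                    }
                )
            )
            cell_rows.append(
                {
                    "barcode": bc,
                    "cell_type": ct,
                    "organ": "leaf",
                    "depth": d,
                    "tss_frac": float(rng.uniform(0.25, 0.5)),
                    "frip": float(rng.uniform(0.15, 0.5)),
                    "organelle_frac": float(rng.uniform(0.0, 0.05)),
                }
            )
    ins = pd.concat(all_rows, ignore_index=True)
    ins = ins.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    cells = pd.DataFrame(cell_rows)
    return ins, cells


def insertions_to_fragments(ins: pd.DataFrame) -> pd.DataFrame:
    """Insertions → fragments-TSV rows (chrom, start, end, barcode, count)."""
    return pd.DataFrame(
        {
            "chrom": ins["chrom"],
            "start": ins["pos"],
            "end": ins["pos"] + ins["frag_size"].clip(lower=1),
            "barcode": ins["barcode"],
            "count": 1,
        }
    )


def fragments_to_insertions(frags: pd.DataFrame) -> pd.DataFrame:
    """Fragments rows → one insertion per count at the fragment start."""
    rep = frags.loc[frags.index.repeat(frags["count"])]
    return pd.DataFrame(
        {
            "chrom": rep["chrom"].to_numpy(),
            "pos": rep["start"].to_numpy(),
            "barcode": rep["barcode"].to_numpy(),
            "frag_size": (rep["end"] - rep["start"]).to_numpy(),
        }
    )


# ---------------------------------------------------------------- epigenome

def simulate_epigenome(
    genome: GenomeRef,
    truth: SimTruth,
    frac_silencer: float = 0.4,
    n_bmr: int = 8,
    bmr_windows: int = 5,
    window: int = 500,
    seed: int = 0,
):
    """H3K27me3 domains, nucleosome calls and methylation windows.

    A fraction of planted broad peaks is embedded in H3K27me3 domains; these
    become the candidate-silencer truth and receive two planted PRE motif
    copies in their sequence.  Nucleosome intervals cover the decoy peaks.
    Methylation windows tile the genome at 500 bp with low background and
    ``n_bmr`` planted runs of ``bmr_windows`` high windows.

    Returns (h3k27me3 DataFrame, nucleosomes DataFrame, methyl DataFrame);
    also updates ``truth`` (h3k27me3, silencer_peaks, bmrs) and the genome
    sequence in place.
    """
    if not 0 <= frac_silencer <= 1:
        raise ValueError("frac_silencer must be in [0,1]")
    rng = np.random.default_rng(seed)
    peaks = truth.peaks
    broad_idx = peaks.index[(peaks["peak_class"] == "broad") & (peaks["kind"] == "true")]
    n_sil = int(round(frac_silencer * len(broad_idx)))
    sil = list(rng.choice(broad_idx, size=n_sil, replace=False)) if n_sil else []
    dom_rows = []
    pre_names = list(PRE_PATTERNS)
    for pi in sil:
        p = peaks.loc[pi]
        pad_l = int(rng.integers(800, 1500))
        pad_r = int(rng.integers(800, 1500))
        dom_rows.append((p["chrom"], max(0, p["start"] - pad_l), p["end"] + pad_r))
        # plant two PRE motif copies near the peak midpoint
        mid = (p["start"] + p["end"]) // 2
        for k, off in enumerate((-40, 20)):
            pat = PRE_PATTERNS[pre_names[int(rng.integers(0, len(pre_names)))]]
            pos = int(mid + off)
            seq = genome.sequence[p["chrom"]]
            genome.sequence[p["chrom"]] = seq[:pos] + pat + seq[pos + len(pat):]
    h3k = pd.DataFrame(dom_rows, columns=["chrom", "start", "end"])

    dec = peaks[peaks["kind"] == "decoy"]
    nuc = pd.DataFrame(
        {
            "chrom": dec["chrom"].to_numpy(),
            "start": dec["start"].to_numpy() - 100,
            "end": dec["end"].to_numpy() + 100,
        }
    )

    meth_rows = []
    bmr_rows = []
    for chrom, size in genome.chrom_sizes.items():
        n_win = size // window
        levels = rng.beta(2, 18, n_win)
        meth_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.arange(n_win) * window,
                    "end": (np.arange(n_win) + 1) * window,
                    "context": "CG",
                    "level": levels,
                }
            )
        )
    meth = pd.concat(meth_rows, ignore_index=True)
    # plant BMRs: runs of consecutive high windows
    n_total = len(meth)
    starts = rng.choice(n_total - bmr_windows, size=n_bmr, replace=False)
    starts = np.sort(starts)
    keep = np.concatenate([[True], np.diff(starts) > bmr_windows + 2])
    for s in starts[keep]:
        if meth.loc[s, "chrom"] != meth.loc[s + bmr_windows - 1, "chrom"]:
            continue
        meth.loc[s : s + bmr_windows - 1, "level"] = rng.uniform(0.7, 0.95, bmr_windows)
        bmr_rows.append(
            (meth.loc[s, "chrom"], int(meth.loc[s, "start"]), int(meth.loc[s + bmr_windows - 1, "end"]))
        )
    truth.h3k27me3 = h3k
    truth.silencer_peaks = [int(x) for x in sil]
    truth.bmrs = pd.DataFrame(bmr_rows, columns=["chrom", "start", "end"])
    return h3k, nuc, meth


# ---------------------------------------------------------------- species pair

def simulate_species_pair(
    genome_a: GenomeRef,
    truth: SimTruth,
    class_fracs: tuple = (0.5, 0.25, 0.25),
    divergence: float = 0.08,
    core_bp: int = 60,
    acr_halfwidth: int = 250,
    frac_retained: float = 0.8,
    blocks_per_chrom: int = 4,
    seed: int = 0,
):
    """Sister genome with syntenic blocks and conservation truth.

    Species B copies species A block by block (one block per chromosome
    inverted), substituting bases at ``divergence`` per bp except inside the
    ``core_bp`` conserved core of shared and variable query ACRs; the cores
    of species-specific ACRs are fully randomized.  Shared ACRs get an
    accessible partner ACR in B whose cell-type label is retained with
    probability ``frac_retained`` (otherwise switched; broad stays broad).

    Returns (genome_b, blocks DataFrame, acrs_b DataFrame); updates
    ``truth.conservation`` and ``truth.retention``.
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0,1)")
    rng = np.random.default_rng(seed)
    peaks = truth.peaks
    q_idx = peaks.index[peaks["kind"] == "true"].to_numpy()
    classes = rng.choice(
        ["shared", "variable", "species_specific"], size=len(q_idx), p=list(class_fracs)
    )
    truth.conservation = {int(i): c for i, c in zip(q_idx, classes)}

    cell_types = sorted(set(peaks["peak_class"]) - {"broad"})
    seqs_b: dict[str, str] = {}
    block_rows = []
    bid = 0
    for ci, (chrom, size) in enumerate(genome_a.chrom_sizes.items()):
        seq = np.frombuffer(genome_a.sequence[chrom].encode(), dtype="S1").astype("U1").copy()
        # substitutions everywhere; cores restored below
        n_sub = rng.binomial(size, divergence)
        sub_pos = rng.choice(size, size=n_sub, replace=False)
        offsets = rng.integers(1, 4, n_sub)
        base_idx = np.searchsorted(BASES, seq[sub_pos])
        seq[sub_pos] = BASES[(base_idx + offsets) % 4]
        # per-query-ACR handling on this chromosome
        for i, cls in zip(q_idx, classes):
            p = peaks.loc[i]
            if p["chrom"] != chrom:
                continue
            mid = (p["start"] + p["end"]) // 2
            w0, w1 = mid - acr_halfwidth, mid + acr_halfwidth
            if cls == "species_specific":
                seq[w0:w1] = BASES[rng.integers(0, 4, w1 - w0)]
            else:
                c0, c1 = mid - core_bp // 2, mid + core_bp // 2
                orig = genome_a.sequence[chrom][c0:c1]
                seq[c0:c1] = np.frombuffer(orig.encode(), dtype="S1").astype("U1")
        seqs_b[chrom] = "".join(seq)
        # blocks: equal partition, last block inverted
        edges = np.linspace(0, size, blocks_per_chrom + 1).astype(np.int64)
        for k in range(blocks_per_chrom):
            orient = "inverted" if k == blocks_per_chrom - 1 else "same"
            block_rows.append(
                (f"blk{bid}", chrom, int(edges[k]), int(edges[k + 1]), chrom,
                 int(edges[k]), int(edges[k + 1]), orient)
            )
            bid += 1
        if blocks_per_chrom and "inverted" in [r[7] for r in block_rows[-blocks_per_chrom:]]:
            s0, s1 = int(edges[-2]), int(edges[-1])
            seqs_b[chrom] = seqs_b[chrom][:s0] + _revcomp(seqs_b[chrom][s0:s1]) + seqs_b[chrom][s1:]
    blocks = pd.DataFrame(
        block_rows,
        columns=["block_id", "chromA", "startA", "endA", "chromB", "startB", "endB", "orientation"],
    )

    acr_rows = []
    for i, cls in zip(q_idx, classes):
        if cls != "shared":
            continue
        p = peaks.loc[i]
        mid = (p["start"] + p["end"]) // 2
        blk = blocks[
            (blocks["chromA"] == p["chrom"]) & (blocks["startA"] <= mid) & (blocks["endA"] > mid)
        ].iloc[0]
        midB = (
            blk["startB"] + (mid - blk["startA"])
            if blk["orientation"] == "same"
            else blk["startB"] + (blk["endA"] - 1 - mid)
        )
        label = p["peak_class"]
        if label != "broad":
            if rng.random() < frac_retained:
                truth.retention[int(i)] = label
            else:
                other = [c for c in cell_types if c != label]
                label = other[int(rng.integers(0, len(other)))]
                truth.retention[int(i)] = label
        acr_rows.append(
            (f"B_acr{i}", p["chrom"], int(midB) - acr_halfwidth, int(midB) + acr_halfwidth, label)
        )
    acrs_b = pd.DataFrame(acr_rows, columns=["id", "chrom", "start", "end", "label"])
    genome_b = GenomeRef(chrom_sizes=dict(genome_a.chrom_sizes), sequence=seqs_b)
    return genome_b, blocks, acrs_b


# ---------------------------------------------------------------- trajectories

def simulate_trajectories(
    n_motifs: int = 40,
    n_cells: int = 300,
    frac_conserved: float = 0.5,
    delta: float = 0.3,
    noise_sd: float = 0.1,
    seed: int = 0,
):
    """Paired pseudotime motif-deviation trajectories with planted shifts.

    Each motif follows a sigmoid deviation profile in pseudotime; conserved
    motifs share it in both species, shifted motifs reach half-maximum
    ``delta`` pseudotime units earlier in one species (shiftEarlyA /
    shiftEarlyB split evenly).  Gaussian noise of sd ``noise_sd`` is added.

    Returns (devA, devB: motif×cell DataFrames, pseudotime arrays, truth
    dict motif → label).
    """
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0,1)")
    rng = np.random.default_rng(seed)
    n_cons = int(round(frac_conserved * n_motifs))
    labels = (["conserved"] * n_cons
              + ["shiftEarlyA", "shiftEarlyB"] * ((n_motifs - n_cons) // 2 + 1))[:n_motifs]
    rng.shuffle(labels)
    motifs = [f"M{i:03d}" for i in range(n_motifs)]
    truth = dict(zip(motifs, labels))
    tA = np.sort(rng.random(n_cells))
    tB = np.sort(rng.random(n_cells))

    def sigmoid(t, t0, s, sign):
        return sign / (1.0 + np.exp(-(t - t0) / s))

    rowsA, rowsB = [], []
    for m in motifs:
        t0 = rng.uniform(0.35, 0.65)
        s = rng.uniform(0.05, 0.1)
        sign = 1.0 if rng.random() < 0.7 else -1.0
        lab = truth[m]
        offA = delta if lab == "shiftEarlyA" else 0.0
        offB = delta if lab == "shiftEarlyB" else 0.0
        rowsA.append(sigmoid(tA + offA, t0, s, sign) + rng.normal(0, noise_sd, n_cells))
        rowsB.append(sigmoid(tB + offB, t0, s, sign) + rng.normal(0, noise_sd, n_cells))
    devA = pd.DataFrame(rowsA, index=motifs)
    devB = pd.DataFrame(rowsB, index=motifs)
    return devA, devB, tA, tB, truth
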