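"""Seeded synthetic-data generator with planted ground truth.

Emulates the statistical structure of a plant heat-stress 3D-genomics study
at desk scale: chromosomes split into gene-rich arms and a gene-poor
pericentromere, a two-compartment checkerboard on a power-law distance decay,
a heat condition (1 h) that strengthens A-A and weakens B-B contacts and adds
transient promoter-RE loops at accessible anchors (reverting at 6 h),
histone-mark signatures separating proximal and distal regulatory elements,
accessibility archetypes coupled to expression, a two-layer TF cascade, and
planted qPCR/luciferase effect sizes.

Contacts are multinomial draws over intrachromosomal bin pairs with
probability proportional to s^-gamma x (1 + amplitude x checkerboard) x
loop folds x condition modifiers, so generated totals equal the requested
depth exactly. All randomness flows from one master seed through fixed
per-component substreams, so adding a component never perturbs existing
draws.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ContactMatrix, GeneAnnotation, GenomeLayout, SignalTrack
from .motifs import HSF_CONSENSUS, MotifModel

__all__ = [
    "SynthConfig",
    "Loop",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_expression",
    "simple_de",
    "WRKY_TANDEM",
]

# Tandem W-box; a synthetic 12-mer stand-in for the short WRKY site so chance
# hits in a random desk-scale genome are negligible.
WRKY_TANDEM = "TTGACTTTGACT"

TIMEPOINTS = ("0h", "1h", "6h")

# accessibility/expression time-course archetypes (log2 shifts at 0h, 1h, 6h)
ARCHETYPES: dict[str, tuple[float, float, float]] = {
    # the small 0.25 offsets break rank ties between time points (so rank
    # correlations are well-defined) while keeping transient genes reverted
    # at 6 h (|log2FC| < 0.3) and sub-threshold for DE calls
    "up-transient": (0.0, 2.0, 0.25),
    "up-sustained": (0.0, 2.0, 2.25),
    "down-transient": (0.0, -2.0, -0.25),
    "down-sustained": (0.0, -2.0, -2.25),
    "late-up": (0.0, 0.25, 2.0),
}


@dataclass
class Loop:
    chrom: str
    bin1: int                  # promoter-side anchor
    bin2: int                  # RE-side anchor
    folds: dict[str, float]    # condition -> fold over background
    hsfa1a: bool = False
    rnapii: bool = True
    category: int | None = None   # planted accessibility category (strata mode)


@dataclass
class SynthConfig:
    """Study conditions of the paper-like preset; see the methods note."""

    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    bin_size: int = 20_000
    peri: tuple[int, int] = (2_200_000, 2_800_000)
    block_bins: int = 25              # 500 kb checkerboard blocks
    depth: int = 1_000_000            # valid pairs per chromosome
    gamma: float = 1.0
    amplitude: float = 0.4
    aa_boost: float = 1.3
    bb_damp: float = 0.7
    n_gained_loops: int = 10          # genome-wide; fold gained_fold at 1h only
    n_stable_loops: int = 10          # present at all time points
    gained_fold: float = 3.0
    stable_fold: float = 3.0
    loop_categories: tuple[tuple[int, float, int], ...] | None = None
    #   strata mode: ((n, fold, category), ...) replaces the default loop plan
    capture_bait_factor: float = 5.0  # C-Hi-C enrichment of promoter-anchored pairs
    hichip_loop_fold: float = 3.0     # extra RNAPII-HiChIP weight at RNAPII loops
    contact_assays: tuple[tuple[str, str], ...] = (
        ("HiC", "0h"), ("HiC", "1h"), ("HiC", "6h"),
        ("CHiC", "0h"), ("CHiC", "1h"), ("HiChIP", "1h"),
    )
    # annotation / peaks
    n_genes_per_chrom: int = 130
    gene_length: int = 2_000
    n_distal: int = 300
    n_genic: int = 40
    n_signature: int = 30
    track_bin: int = 100              # fine histone-mark track resolution
    # expression
    expr_depth: int = 1_000_000
    dispersion: float = 0.05
    n_reps: int = 2
    # TF cascade
    n_layer1: int = 15
    n_layer2: int = 15
    n_dap_targets: int = 80
    # knock-down DE split (printed-table input)
    kd_n_down: int = 186
    kd_n_up: int = 61
    # assays
    qpcr_wt_fold: float = 2.5
    qpcr_kd_fold: float = 0.6
    ct_noise_sd: float = 0.15
    n_bio: int = 3
    n_tech: int = 3
    luc_folds: tuple[tuple[str, float], ...] = (("RE-mini35S-A", 2.5), ("RE-mini35S-B", 3.5))
    luc_reps: int = 3
    generate_sequences: bool = True
    generate_fine_tracks: bool = True


@dataclass
class SyntheticTruth:
    labels: dict[str, np.ndarray]          # +1 A / -1 B per bin
    loops: list[Loop]
    gamma: float
    amplitude: float
    aa_boost: float
    bb_damp: float
    cascade: dict[str, dict]
    de_plan: dict[str, dict[str, float]]   # gene -> {time: log2FC}
    signature_peaks: list[int]             # peak row indices with enhancer signature
    archetype_of_peak: dict[int, str]
    kd_split: tuple[int, int]              # (n_down, n_up)
    qpcr_truth: dict
    luc_truth: dict
    seed: int = 0

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=1)


@dataclass
class SyntheticDataset:
    config: SynthConfig
    layout: GenomeLayout
    genes: GeneAnnotation
    contacts: dict[tuple[str, str], ContactMatrix]
    tracks: dict[str, SignalTrack]         # coarse activity tracks
    marks: dict[str, SignalTrack]          # fine histone-mark tracks
    peaks: pd.DataFrame
    genome: dict[str, str]
    expr: pd.DataFrame
    sample_meta: pd.DataFrame
    tf_table: pd.DataFrame
    dap_peaks: pd.DataFrame
    halo_peaks: pd.DataFrame
    kd_de: pd.DataFrame
    qpcr: pd.DataFrame
    luc: pd.DataFrame
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# seeding


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# genome structure


def _compartment_labels(cfg: SynthConfig) -> np.ndarray:
    """+1 (A) / -1 (B) per bin; pericentromere all B, arms in alternating
    blocks with the block adjacent to the pericentromere always A."""
    n = -(-cfg.chrom_length // cfg.bin_size)
    mids = np.arange(n) * cfg.bin_size + cfg.bin_size // 2
    peri = (mids >= cfg.peri[0]) & (mids < cfg.peri[1])
    lo = int(np.argmax(peri))
    hi = int(n - np.argmax(peri[::-1]))
    lab = np.empty(n, dtype=int)
    lab[peri] = -1
    b = cfg.block_bins
    # partial blocks at the chromosome ends stay B so A-A boost and B-B damp
    # balance within arms (the spec of the heat modifiers assumes ~50/50 arms)
    left = np.arange(lo)
    k = (lo - 1 - left) // b
    lab[left] = np.where((k % 2 == 0) & ((k + 1) * b <= lo), 1, -1)
    right = np.arange(hi, n)
    k = (right - hi) // b
    lab[right] = np.where((k % 2 == 0) & (hi + (k + 1) * b <= n), 1, -1)
    return lab


def _anchor_slots(cfg: SynthConfig) -> list[list[int]]:
    """Interior bin positions (>= 7 bins from block edges, so APA windows stay
    in uniform A-A context) of the full-size A blocks, ordered left arm
    outward-in then right arm inward-out."""
    lab = _compartment_labels(cfg)
    b = cfg.block_bins
    blocks = []
    start = None
    for i, v in enumerate(np.append(lab, -1)):
        if v == 1 and start is None:
            start = i
        elif v != 1 and start is not None:
            if i - start == b:
                blocks.append(list(range(start + 7, i - 7)))
            start = None
    return [blk for blk in blocks if len(blk) >= 5]


def _plan_loops(cfg: SynthConfig, chroms: list[str]) -> list[Loop]:
    loops: list[Loop] = []
    slots = _anchor_slots(cfg)
    if len(slots) < 4:
        raise ValueError("chromosome too short for the loop plan")
    if cfg.loop_categories is not None:
        plan = [(fold, cat) for n_l, fold, cat in cfg.loop_categories for _ in range(n_l)]
        per_chrom = -(-len(plan) // len(chroms))
        k = 0
        for chrom in chroms:
            pairs = list(zip(slots[0], slots[1])) + list(zip(slots[2], slots[3]))
            for p, e in pairs:
                if k >= len(plan) or k >= (chroms.index(chrom) + 1) * per_chrom:
                    break
                fold, cat = plan[k]
                loops.append(Loop(chrom, p, e, {t: fold for t in TIMEPOINTS},
                                  hsfa1a=False, category=cat))
                k += 1
        if k < len(plan):
            raise ValueError("not enough anchor slots for the requested strata loops")
        return loops
    n_g, n_s = cfg.n_gained_loops, cfg.n_stable_loops
    g_per, s_per = -(-n_g // len(chroms)), -(-n_s // len(chroms))
    def lattice_pairs(sa, sb):
        # (k, 2k) lattice: varies anchor separation (2 bins per step) while
        # keeping inter-loop offsets off the APA background corner
        return [(sa[k], sb[2 * k]) for k in range((len(sb) + 1) // 2)]

    for ci, chrom in enumerate(chroms):
        gained_pairs = lattice_pairs(slots[0], slots[1])[:g_per]
        stable_pairs = lattice_pairs(slots[2], slots[3])[:s_per]
        if len(gained_pairs) < g_per or len(stable_pairs) < s_per:
            raise ValueError("not enough anchor slots for the requested loops")
        for p, e in gained_pairs:
            loops.append(Loop(chrom, p, e,
                              {"0h": 1.0, "1h": cfg.gained_fold, "6h": 1.0}, hsfa1a=True))
        for p, e in stable_pairs:
            loops.append(Loop(chrom, p, e, {t: cfg.stable_fold for t in TIMEPOINTS}))
    return loops[: n_g + n_s]


# ---------------------------------------------------------------------------
# contacts


def _contact_weights(cfg: SynthConfig, labels: np.ndarray, condition: str,
                     loops: list[Loop], chrom: str, assay: str,
                     promoter_bins: np.ndarray) -> np.ndarray:
    n = len(labels)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(divide="ignore"):
        w = np.where(d > 0, d.astype(float) ** (-cfg.gamma), 1.0)
    same = np.equal.outer(labels, labels)
    w *= np.where(same, 1.0 + cfg.amplitude, 1.0 - cfg.amplitude)
    if condition == "1h":
        a = labels == 1
        w[np.ix_(a, a)] *= cfg.aa_boost
        w[np.ix_(~a, ~a)] *= cfg.bb_damp
    for lp in loops:
        if lp.chrom != chrom:
            continue
        f = lp.folds.get(condition, 1.0)
        if assay == "HiChIP" and lp.rnapii:
            f *= cfg.hichip_loop_fold
        w[lp.bin1, lp.bin2] *= f
        w[lp.bin2, lp.bin1] *= f
    if assay == "CHiC" and len(promoter_bins):
        # per-end capture efficiency (multiplicative), as for independent
        # hybridization of each ligation end
        eff = np.ones(n)
        eff[promoter_bins] = cfg.capture_bait_factor
        w *= np.outer(eff, eff)
    return w


def _draw_contacts(cfg: SynthConfig, layout: GenomeLayout, truth: SyntheticTruth,
                   assay: str, condition: str, promoter_bins: dict[str, np.ndarray],
                   seed: int) -> ContactMatrix:
    mats = {}
    for chrom in layout.names:
        rng = _rng(seed, f"contacts/{assay}/{condition}/{chrom}")
        w = _contact_weights(cfg, truth.labels[chrom], condition, truth.loops, chrom,
                             assay, promoter_bins.get(chrom, np.empty(0, dtype=int)))
        n = w.shape[0]
        iu, ju = np.triu_indices(n)
        p = w[iu, ju]
        p = p / p.sum()
        counts = rng.multinomial(cfg.depth, p)
        m = np.zeros((n, n))
        m[iu, ju] = counts
        m += np.triu(m, 1).T
        mats[chrom] = m
    return ContactMatrix(layout, mats, assay=assay, condition=condition)


# ---------------------------------------------------------------------------
# annotation, peaks, tracks, sequences


def _place_genes_and_peaks(cfg: SynthConfig, layout: GenomeLayout,
                           truth_labels: dict[str, np.ndarray],
                           loops: list[Loop], seed: int):
    bs = cfg.bin_size
    rng = _rng(seed, "annotation")
    gene_rows, peak_rows = [], []
    arch_names = list(ARCHETYPES)
    gid = 0
    loop_by_chrom: dict[str, list[Loop]] = {}
    for lp in loops:
        loop_by_chrom.setdefault(lp.chrom, []).append(lp)
    for chrom in layout.names:
        lab = truth_labels[chrom]
        prom_anchor = sorted({lp.bin1 for lp in loop_by_chrom.get(chrom, [])})
        re_anchor = sorted({lp.bin2 for lp in loop_by_chrom.get(chrom, [])})
        a_bins = [b for b in np.flatnonzero(lab == 1)
                  if b not in prom_anchor and b not in re_anchor]
        rng.shuffle(a_bins)
        n_extra = cfg.n_genes_per_chrom - len(prom_anchor)
        n_gene_bins = -(-n_extra // 3)
        gene_bins = a_bins[:n_gene_bins]
        desert_bins = sorted(a_bins[n_gene_bins:])
        # one gene centered in each promoter-anchor bin
        for b in prom_anchor:
            tss = b * bs + bs // 2
            gene_rows.append((f"gene{gid:04d}", chrom, tss, tss + cfg.gene_length, "+", b, True))
            gid += 1
        # two genes per ordinary gene bin
        placed = 0
        for b in gene_bins:
            for off in (3_000, 9_000, 15_000):
                if placed >= n_extra:
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                s = b * bs + off
                gene_rows.append((f"gene{gid:04d}", chrom, s, s + cfg.gene_length, strand, b, False))
                gid += 1
                placed += 1
        # distal peaks: RE anchors first, then desert bins
        for b in re_anchor:
            s = b * bs + bs // 2 - 200
            peak_rows.append((chrom, s, s + 400, s + 200, "distal", None, b, True))
        cap = cfg.n_distal // cfg.n_chromosomes - len(re_anchor)
        placed = 0
        for b in desert_bins:
            for off in (3_000, 8_000, 13_000, 18_000):
                if placed >= cap:
                    break
                s = b * bs + off
                peak_rows.append((chrom, s, s + 400, s + 200, "distal", None, b, False))
                placed += 1
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end",
                                             "strand", "bin", "is_anchor"])
    # proximal peak for every gene, strand-aware upstream of the TSS
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            s, e = g["start"] - 600, g["start"] - 200
        else:
            s, e = g["end"] + 200, g["end"] + 600
        peak_rows.append((g["chrom"], s, e, (s + e) // 2, "proximal", g["gene_id"],
                          g["bin"], False))
    # genic peaks inside gene bodies
    genic_genes = genes.iloc[:: max(1, len(genes) // max(cfg.n_genic, 1))][: cfg.n_genic]
    for _, g in genic_genes.iterrows():
        s = g["start"] + 500
        peak_rows.append((g["chrom"], s, s + 400, s + 200, "genic", None, g["bin"], False))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "summit",
                                             "kind", "linked_gene_true", "bin", "is_re_anchor"])
    peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    return genes, peaks


def _assign_archetypes(cfg: SynthConfig, peaks: pd.DataFrame, loops: list[Loop],
                       seed: int) -> dict[int, str]:
    """Round-robin archetypes over proximal peaks; loop anchors transiently open."""
    arch: dict[int, str] = {}
    names = list(ARCHETYPES)
    prox_idx = peaks.index[peaks["kind"] == "proximal"].tolist()
    for i, idx in enumerate(prox_idx):
        arch[idx] = names[i % len(names)]
    anchor_bins = {(lp.chrom, lp.bin1) for lp in loops if lp.hsfa1a}
    anchor_bins |= {(lp.chrom, lp.bin2) for lp in loops if lp.hsfa1a}
    for idx, r in peaks.iterrows():
        if (r["chrom"], r["bin"]) in anchor_bins:
            arch[idx] = "up-transient"
    return arch


def _accessibility(cfg: SynthConfig, peaks: pd.DataFrame, arch: dict[int, str],
                   loops: list[Loop], seed: int) -> pd.DataFrame:
    rng = _rng(seed, "accessibility")
    df = peaks.copy()
    base = rng.lognormal(np.log(5.0), 0.3, len(df))
    profiles = np.array([ARCHETYPES[arch[i]] if i in arch else (0.0, 0.0, 0.0)
                         for i in df.index])
    for t_i, t in enumerate(TIMEPOINTS):
        noise = rng.gamma(16.0, 1.0 / 16.0, len(df))
        df[f"acc_{t}"] = base * 2.0 ** profiles[:, t_i] * noise
        # accessible when open relative to the profile: flat peaks always,
        # up-archetypes only where shifted up, down-archetypes where not shut
        has_up = (profiles > 0).any(axis=1)
        has_down = (profiles < 0).any(axis=1)
        acc = np.where(has_up, profiles[:, t_i] > 0,
                       np.where(has_down, profiles[:, t_i] >= 0, True))
        df[f"accessible_{t}"] = acc.astype(bool)
    # strata mode: planted categories override anchor accessibility
    if cfg.loop_categories is not None:
        bin_of = {(r["chrom"], r["bin"], r["kind"]): i for i, r in df.iterrows()}
        for lp in loops:
            if lp.category is None:
                continue
            p_idx = bin_of.get((lp.chrom, lp.bin1, "proximal"))
            e_idx = bin_of.get((lp.chrom, lp.bin2, "distal"))
            for t in TIMEPOINTS:
                if p_idx is not None:
                    df.loc[p_idx, f"accessible_{t}"] = lp.category >= 1
                if e_idx is not None:
                    df.loc[e_idx, f"accessible_{t}"] = lp.category >= 2
    return df


def _mark_tracks(cfg: SynthConfig, layout: GenomeLayout, peaks: pd.DataFrame,
                 signature_idx: list[int], seed: int) -> dict[str, SignalTrack]:
    """Fine-resolution H3K9ac / H3K18ac / H3K4me3 tracks with planted flank
    signatures: proximal flanks high in all three, signature distal flanks
    high in the acetylation marks and devoid of H3K4me3, other distal flanks
    drawn from a common moderate background."""
    rng = _rng(seed, "marks")
    tb = cfg.track_bin
    tracks = {}
    vals = {m: {c: rng.gamma(4.0, 0.25, -(-l // tb)) for c, l in layout.chromosomes}
            for m in ("H3K9ac", "H3K18ac", "H3K4me3")}
    sig = set(signature_idx)
    for idx, r in peaks.iterrows():
        if r["kind"] == "proximal":
            levels = {"H3K9ac": 6.0, "H3K18ac": 6.0, "H3K4me3": 6.0}
        elif r["kind"] == "distal" and idx in sig:
            # acetylation-high, H3K4me3-devoid enhancer signature
            levels = {"H3K9ac": 8.0, "H3K18ac": 8.0, "H3K4me3": 0.15}
        elif r["kind"] == "distal":
            levels = {m: rng.gamma(2.0, 0.75) for m in vals}
        else:
            continue
        for m, lv in levels.items():
            v = vals[m][r["chrom"]]
            for fs, fe in ((r["start"] - 500, r["start"]), (r["end"], r["end"] + 500)):
                b0, b1 = max(fs // tb, 0), min(-(-fe // tb), len(v))
                v[b0:b1] = lv * rng.gamma(16.0, 1.0 / 16.0, b1 - b0)
    for m, per_chrom in vals.items():
        tracks[m] = SignalTrack(name=m, bin_size=tb, values=per_chrom)
    return tracks


def _coarse_tracks(cfg: SynthConfig, layout: GenomeLayout,
                   labels: dict[str, np.ndarray], seed: int) -> dict[str, SignalTrack]:
    rng = _rng(seed, "coarse-tracks")
    out = {}
    for name, a_mean, b_mean in (("H3K9ac", 3.0, 0.5), ("H3K27me1", 0.5, 3.0)):
        vals = {}
        for chrom in layout.names:
            lab = labels[chrom]
            mean = np.where(lab == 1, a_mean, b_mean)
            vals[chrom] = mean * rng.gamma(4.0, 0.25, len(lab))
        out[name] = SignalTrack(name=name, bin_size=cfg.bin_size, values=vals)
    return out


def _sequences(cfg: SynthConfig, layout: GenomeLayout, peaks: pd.DataFrame,
               cascade: dict, dap_peaks: pd.DataFrame, seed: int) -> dict[str, str]:
    rng = _rng(seed, "sequence")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for chrom, length in layout.chromosomes:
        genome[chrom] = rng.integers(0, 4, length).astype(np.uint8)
    def plant(chrom, pos, consensus):
        s = np.frombuffer(consensus.encode(), dtype=np.uint8).copy()
        arr = np.empty(len(s), dtype=np.uint8)
        lut = {65: 0, 67: 1, 71: 2, 84: 3}
        for k, ch in enumerate(s):
            arr[k] = lut.get(ch, rng.integers(0, 4))   # N -> random base
        genome[chrom][pos: pos + len(arr)] = arr
    by_gene = {r["linked_gene_true"]: (r["chrom"], int(r["summit"]))
               for _, r in peaks.iterrows() if r["linked_gene_true"] is not None}
    for t, layer in cascade.items():
        consensus = HSF_CONSENSUS if layer["tf"] == "HSF-like" else WRKY_TANDEM
        for gene in layer["targets"]:
            chrom, summit = by_gene[gene]
            plant(chrom, summit - len(consensus) // 2, consensus)
    for _, r in dap_peaks.iterrows():
        plant(r["chrom"], int(r["summit"]) - len(HSF_CONSENSUS) // 2, HSF_CONSENSUS)
    return {c: bases[v].tobytes().decode() for c, v in genome.items()}


# ---------------------------------------------------------------------------
# expression


def generate_expression(de_plan: dict[str, dict[str, float]], genes: list[str],
                        depth: int = 1_000_000, dispersion: float = 0.05,
                        n_reps: int = 2, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial gene x sample counts around condition means shifted by
    the planted log2 fold changes; transient genes revert at 6 h by plan."""
    rng = _rng(seed, "expression")
    base = rng.lognormal(np.log(depth / max(len(genes), 1)), 0.7, len(genes))
    base *= depth / base.sum()
    cols, meta = [], []
    counts = np.zeros((len(genes), len(TIMEPOINTS) * n_reps))
    col = 0
    for t in TIMEPOINTS:
        lfc = np.array([de_plan.get(g, {}).get(t, 0.0) for g in genes])
        mu = base * 2.0 ** lfc
        for rep in range(1, n_reps + 1):
            if dispersion > 1e-8:
                r = 1.0 / dispersion
                counts[:, col] = rng.negative_binomial(r, r / (r + mu))
            else:
                counts[:, col] = rng.poisson(mu)
            cols.append(f"{t}_rep{rep}")
            meta.append((f"{t}_rep{rep}", t, rep))
            col += 1
    expr = pd.DataFrame(counts.astype(int), index=pd.Index(genes, name="gene_id"), columns=cols)
    sample_meta = pd.DataFrame(meta, columns=["sample", "condition", "replicate"])
    return expr, sample_meta


def simple_de(expr: pd.DataFrame, sample_meta: pd.DataFrame,
              contrast: tuple[str, str] = ("1h", "0h"), alpha: float = 0.05,
              lfc_min: float = 1.0) -> pd.DataFrame:
    """Declared-simple differential expression: median-of-ratios size factors,
    log2FC of normalized means, per-gene two-sample t on log2(normalized + 1),
    BH adjustment; direction up/down at padj <= alpha and |log2FC| >= lfc_min.
    All-zero genes are excluded (count in ``df.attrs['n_excluded']``).
    """
    from scipy import stats

    b, a = contrast  # b vs a: up = higher in b
    counts = expr.to_numpy(dtype=float)
    nonzero = counts.sum(axis=1) > 0
    pos = (counts > 0).all(axis=1)
    logm = np.log(counts[pos]).mean(axis=1)
    sf = np.exp(np.median(np.log(counts[pos]) - logm[:, None], axis=0))
    norm = counts / sf
    cond = sample_meta.set_index("sample").loc[expr.columns, "condition"].to_numpy()
    ia, ib = cond == a, cond == b
    if ia.sum() < 2 or ib.sum() < 2:
        raise ValueError("need >= 2 replicates per contrast group")
    la, lb = np.log2(norm[:, ia] + 1), np.log2(norm[:, ib] + 1)
    lfc = np.log2(norm[:, ib].mean(axis=1) + 0.5) - np.log2(norm[:, ia].mean(axis=1) + 0.5)
    res = stats.ttest_ind(lb, la, axis=1, equal_var=True)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    keep = nonzero
    padj = np.full(len(p), np.nan)
    padj[keep] = stats.false_discovery_control(p[keep], method="bh")
    direction = np.where((padj <= alpha) & (np.abs(lfc) >= lfc_min),
                         np.where(lfc > 0, "up", "down"), "ns")
    direction[~keep] = "excluded"
    df = pd.DataFrame({
        "gene_id": expr.index, "baseMean": norm.mean(axis=1), "log2fc": lfc,
        "pvalue": p, "padj": padj, "direction": direction,
    })
    df = df[keep].reset_index(drop=True)
    df.attrs["n_excluded"] = int((~keep).sum())
    return df


# ---------------------------------------------------------------------------
# assays


def _qpcr_table(cfg: SynthConfig, seed: int) -> tuple[pd.DataFrame, dict]:
    rng = _rng(seed, "qpcr")
    folds = {("WT", "0h"): 1.0, ("WT", "1h"): cfg.qpcr_wt_fold,
             ("hsfa1a-1", "0h"): 1.0, ("hsfa1a-1", "1h"): cfg.qpcr_kd_fold,
             ("hsfa1a-2", "0h"): 1.0, ("hsfa1a-2", "1h"): cfg.qpcr_kd_fold}
    rows = []
    for loop_id in ("loop1", "loop2"):
        for (geno, cond), rel in folds.items():
            for bio in range(1, cfg.n_bio + 1):
                for tech in range(1, cfg.n_tech + 1):
                    ct_n = 20.0 + rng.normal(0, cfg.ct_noise_sd)
                    ct_t = 25.0 - np.log2(rel) + rng.normal(0, cfg.ct_noise_sd)
                    rows.append((f"{geno}_{cond}_b{bio}", geno, cond, loop_id,
                                 bio, tech, ct_t, ct_n))
    df = pd.DataFrame(rows, columns=["sample", "genotype", "condition", "loop_id",
                                     "bio_rep", "tech_rep", "ct_target", "ct_norm"])
    return df, {str(k): v for k, v in folds.items()}


def _luc_table(cfg: SynthConfig, seed: int) -> tuple[pd.DataFrame, dict]:
    rng = _rng(seed, "luciferase")
    rows = []
    truth = {"mini35S": 1.0, **dict(cfg.luc_folds)}
    for construct, fold in truth.items():
        for rep in range(1, cfg.luc_reps + 1):
            ren = max(rng.normal(1000.0, 100.0), 1.0)
            luc = ren * 0.2 * fold * rng.lognormal(0.0, 0.1)
            rows.append((construct, rep, luc, ren))
    return pd.DataFrame(rows, columns=["construct", "replicate", "LUC", "REN"]), truth


# ---------------------------------------------------------------------------
# top level


def generate_dataset(config: SynthConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate the full synthetic study (see module docstring)."""
    cfg = config or SynthConfig()
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    layout = GenomeLayout(tuple((c, cfg.chrom_length) for c in chroms),
                          {c: cfg.peri for c in chroms}, cfg.bin_size)
    labels = {c: _compartment_labels(cfg) for c in chroms}
    loops = _plan_loops(cfg, chroms)
    genes_df, peaks = _place_genes_and_peaks(cfg, layout, labels, loops, seed)
    arch = _assign_archetypes(cfg, peaks, loops, seed)
    peaks = _accessibility(cfg, peaks, arch, loops, seed)

    # planted enhancer signatures on distal peaks (RE anchors first)
    distal_idx = peaks.index[peaks["kind"] == "distal"].tolist()
    anchors_first = sorted(distal_idx, key=lambda i: not peaks.loc[i, "is_re_anchor"])
    signature_idx = anchors_first[: cfg.n_signature]
    peaks["signature_true"] = peaks.index.isin(signature_idx)

    # TF cascade: layer 1 (HSF-like, 1 h) and layer 2 (WRKY-like, 6 h)
    prox = peaks[peaks["kind"] == "proximal"]
    l1_genes = sorted(prox.loc[[i for i in prox.index if arch.get(i) == "up-transient"],
                               "linked_gene_true"])[: cfg.n_layer1]
    l2_genes = sorted(prox.loc[[i for i in prox.index if arch.get(i) == "late-up"],
                               "linked_gene_true"])[: cfg.n_layer2]
    cascade = {"1h": {"tf": "HSF-like", "family": "HSF", "targets": l1_genes},
               "6h": {"tf": "WRKY-like", "family": "WRKY", "targets": l2_genes}}

    # DE plan from peak archetypes (proximal accessibility drives expression)
    de_plan: dict[str, dict[str, float]] = {}
    for idx, r in prox.iterrows():
        prof = ARCHETYPES[arch[idx]]
        de_plan[r["linked_gene_true"]] = {t: prof[i] for i, t in enumerate(TIMEPOINTS)}

    genes = GeneAnnotation(genes_df[["gene_id", "chrom", "start", "end", "strand"]])
    gene_ids = list(genes_df["gene_id"])

    # DAP-seq peaks at the TSS of target genes + Halo-tag control peaks
    rng = _rng(seed, "dap")
    targets = gene_ids[: cfg.n_dap_targets]
    dap_rows = []
    tss = genes.tss()
    for g in targets:
        # summit upstream of the proximal ATAC peak (which spans TSS-600..-200)
        # but well inside the promoter and the TSS association window
        i = gene_ids.index(g)
        s = int(tss.iloc[i]) - 800
        dap_rows.append((genes_df["chrom"].iloc[i], s - 100, s + 100, s))
    dap_peaks = pd.DataFrame(dap_rows, columns=["chrom", "start", "end", "summit"])
    halo_rows = []
    desert = peaks[(peaks["kind"] == "distal") & ~peaks["is_re_anchor"]].tail(20)
    for _, r in desert.iterrows():
        halo_rows.append((r["chrom"], r["start"] + 1000, r["end"] + 1000, r["summit"] + 1000))
    halo_peaks = pd.DataFrame(halo_rows, columns=["chrom", "start", "end", "summit"])

    # knock-down DE table with the configured printed split
    kd_genes = list(gene_ids)
    rng.shuffle(kd_genes)
    n_total = cfg.kd_n_down + cfg.kd_n_up
    if n_total > len(kd_genes):
        raise ValueError("knock-down split larger than the gene catalogue")
    kd_de = pd.DataFrame({
        "gene_id": kd_genes[:n_total],
        "direction": ["down"] * cfg.kd_n_down + ["up"] * cfg.kd_n_up,
    })

    truth = SyntheticTruth(
        labels=labels, loops=loops, gamma=cfg.gamma, amplitude=cfg.amplitude,
        aa_boost=cfg.aa_boost, bb_damp=cfg.bb_damp, cascade=cascade, de_plan=de_plan,
        signature_peaks=list(signature_idx), archetype_of_peak=arch,
        kd_split=(cfg.kd_n_down, cfg.kd_n_up), qpcr_truth={}, luc_truth={}, seed=seed,
    )

    promoter_bins = {c: genes_df.loc[genes_df["chrom"] == c, "bin"].unique() for c in chroms}
    contacts = {
        (assay, cond): _draw_contacts(cfg, layout, truth, assay, cond, promoter_bins, seed)
        for assay, cond in cfg.contact_assays
    }
    tracks = _coarse_tracks(cfg, layout, labels, seed)
    marks = (_mark_tracks(cfg, layout, peaks, signature_idx, seed)
             if cfg.generate_fine_tracks else {})
    genome = (_sequences(cfg, layout, peaks, cascade, dap_peaks, seed)
              if cfg.generate_sequences else {})
    expr, sample_meta = generate_expression(de_plan, gene_ids, cfg.expr_depth,
                                            cfg.dispersion, cfg.n_reps, seed)
    qpcr, qpcr_truth = _qpcr_table(cfg, seed)
    luc, luc_truth = _luc_table(cfg, seed)
    truth.qpcr_truth, truth.luc_truth = qpcr_truth, luc_truth

    tf_table = pd.DataFrame({
        "tf_id": ["HSF-like", "WRKY-like"],
        "family": ["HSF", "WRKY"],
        "motif": [MotifModel.from_consensus("HSF", HSF_CONSENSUS),
                  MotifModel.from_consensus("WRKY", WRKY_TANDEM)],
        "direction": ["up@1h", "up@6h"],
    })

    return SyntheticDataset(
        config=cfg, layout=layout, genes=genes, contacts=contacts, tracks=tracks,
        marks=marks, peaks=peaks, genome=genome, expr=expr, sample_meta=sample_meta,
        tf_table=tf_table, dap_peaks=dap_peaks, halo_peaks=halo_peaks, kd_de=kd_de,
        qpcr=qpcr, luc=luc, truth=truth,
    )
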