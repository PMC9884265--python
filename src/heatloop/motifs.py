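"""PWM scanning, motif enrichment, TF-target association and TF-network inference.

Motif models are position weight matrices built either from probability
matrices or from IUPAC consensus strings (the heat-shock element consensus
TCTAGAANNTTCT ships as the built-in example). Scanning is exhaustive log-odds
scoring on both strands; enrichment compares the fraction of peaks with a hit
against length-matched random genomic windows with a binomial upper tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneAnnotation

__all__ = [
    "MotifModel",
    "pwm_scan",
    "motif_enrichment",
    "associate_dap_targets",
    "target_regulation_split",
    "build_tf_network",
    "EnrichmentResult",
    "RegulationSplit",
    "HSF_CONSENSUS",
]

HSF_CONSENSUS = "TCTAGAANNTTCT"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifModel:
    """A PWM with background composition and a log-odds hit threshold."""

    name: str
    pwm: np.ndarray                       # 4 x L probabilities (A, C, G, T rows)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float = 0.0
    pseudocount: float = 0.01

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.shape[0] != 4 or self.pwm.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        colsums = self.pwm.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.pwm.shape[1]

    def log_odds(self) -> np.ndarray:
        p = self.pwm + self.pseudocount
        p /= p.sum(axis=0, keepdims=True)
        return np.log2(p / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    @classmethod
    def from_consensus(cls, name: str, consensus: str, pseudocount: float = 0.01,
                       threshold_frac: float = 0.75) -> "MotifModel":
        """Build a sharp PWM from an IUPAC consensus; N columns are background.

        The hit threshold defaults to ``threshold_frac`` of the maximal
        attainable log-odds score.
        """
        cols = []
        for ch in consensus.upper():
            bases = _IUPAC.get(ch)
            if bases is None:
                raise ValueError(f"invalid IUPAC symbol {ch!r}")
            col = np.zeros(4)
            for b in bases:
                col[_BASE_IDX[b]] = 1.0 / len(bases)
            cols.append(col)
        m = cls(name=name, pwm=np.column_stack(cols), pseudocount=pseudocount)
        m.threshold = threshold_frac * m.max_score()
        return m


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)   # 4 = N / other
    for b, i in _BASE_IDX.items():
        out[arr == ord(b)] = i
    return out


def _scan_scores(enc: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score of every window start; N positions contribute 0."""
    L = lo.shape[1]
    n = enc.shape[0] - L + 1
    if n <= 0:
        return np.empty(0)
    lo5 = np.vstack([lo, np.zeros(L)])           # row 4: N scores as background
    scores = np.zeros(n)
    for k in range(L):
        scores += lo5[enc[k: k + n], k]
    return scores


def pwm_scan(seq: str, motif: MotifModel) -> list[tuple[int, str, float]]:
    """All hits (score >= threshold) on both strands.

    Returns ``(position, strand, score)`` with the position the 0-based start
    of the L-mer on the forward strand.
    """
    enc = _encode(seq)
    lo = motif.log_odds()
    fwd = _scan_scores(enc, lo)
    rev = _scan_scores(enc, lo[::-1, ::-1])      # reverse-complement PWM
    hits = [(int(p), "+", float(s)) for p, s in enumerate(fwd) if s >= motif.threshold]
    hits += [(int(p), "-", float(s)) for p, s in enumerate(rev) if s >= motif.threshold]
    return sorted(hits)


@dataclass
class EnrichmentResult:
    fold: float
    pvalue: float
    n_peaks: int
    n_hits: int
    background_rate: float
    background_floor: bool = False   # true background rate was 0; floored at 1/bg_draws


def motif_enrichment(
    peaks: pd.DataFrame,
    genome: dict[str, str],
    motif: MotifModel,
    bg_draws: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Binomial enrichment of a motif in peak sequences vs random windows.

    ``m`` peaks (of ``n``) contain a hit; the background rate ``q`` is the
    fraction of ``bg_draws`` length-matched random genomic windows (excluding
    peak-overlapping draws) with a hit; p = P(X >= m), X ~ Binomial(n, q).
    """
    rng = np.random.default_rng(seed)
    n = len(peaks)
    if n == 0:
        raise ValueError("empty peak set")
    m = 0
    lengths = []
    for _, r in peaks.iterrows():
        seq = genome[r["chrom"]][int(r["start"]): int(r["end"])]
        lengths.append(len(seq))
        if pwm_scan(seq, motif):
            m += 1
    peak_iv = {c: peaks.loc[peaks["chrom"] == c, ["start", "end"]].to_numpy()
               for c in peaks["chrom"].unique()}
    chroms = list(genome)
    sizes = np.array([len(genome[c]) for c in chroms], dtype=float)
    bg_hits = 0
    drawn = 0
    while drawn < bg_draws:
        c = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
        ln = int(lengths[rng.integers(len(lengths))])
        if len(genome[c]) <= ln:
            continue
        s = int(rng.integers(0, len(genome[c]) - ln))
        iv = peak_iv.get(c)
        if iv is not None and np.any((iv[:, 0] < s + ln) & (iv[:, 1] > s)):
            continue
        drawn += 1
        if pwm_scan(genome[c][s: s + ln], motif):
            bg_hits += 1
    q = bg_hits / bg_draws
    floor = False
    if q == 0.0:
        q = 1.0 / bg_draws
        floor = m > 0
    pvalue = float(stats.binom.sf(m - 1, n, q))
    fold = (m / n) / q
    return EnrichmentResult(fold=float(fold), pvalue=pvalue, n_peaks=n, n_hits=m,
                            background_rate=q, background_floor=floor)


# ---------------------------------------------------------------------------


def associate_dap_targets(
    dap_peaks: pd.DataFrame,
    genes: GeneAnnotation,
    window_bp: int = 1000,
    control_peaks: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign each DAP peak to every gene whose TSS +/- window contains the
    peak summit; peaks overlapping control (Halo-tag) peaks are removed first.
    Unassigned peaks keep an empty target list.
    """
    df = dap_peaks.copy().reset_index(drop=True)
    if control_peaks is not None and len(control_peaks):
        keep = []
        for _, r in df.iterrows():
            cp = control_peaks[control_peaks["chrom"] == r["chrom"]]
            ov = np.any((cp["start"].to_numpy() < r["end"]) & (cp["end"].to_numpy() > r["start"]))
            keep.append(not ov)
        df = df[keep].reset_index(drop=True)
    tss = genes.tss().to_numpy()
    gchrom = genes.df["chrom"].to_numpy()
    gid = genes.df["gene_id"].to_numpy()
    targets = []
    for _, r in df.iterrows():
        summit = int(r["summit"]) if "summit" in r and not pd.isna(r["summit"]) else int(
            (r["start"] + r["end"]) // 2)
        hit = (gchrom == r["chrom"]) & (np.abs(tss - summit) <= window_bp)
        targets.append(sorted(gid[hit]))
    df["targets"] = targets
    return df


@dataclass
class RegulationSplit:
    n_up: int
    n_down: int
    pct_up: float
    pct_down: float


def _round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0." + "0" * digits), rounding=ROUND_HALF_UP))


def target_regulation_split(targets, de: pd.DataFrame) -> RegulationSplit:
    """Count up/down-regulated target genes and report round-half-up
    percentages at one decimal; targets absent from the DE table or not
    DE count as unchanged and leave the percentage denominator.
    """
    de_dir = de.set_index("gene_id")["direction"] if "gene_id" in de.columns else de["direction"]
    dirs = [de_dir.get(g, "ns") for g in targets]
    n_up = sum(d == "up" for d in dirs)
    n_down = sum(d == "down" for d in dirs)
    denom = n_up + n_down
    if denom == 0:
        return RegulationSplit(0, 0, float("nan"), float("nan"))
    return RegulationSplit(
        n_up=n_up,
        n_down=n_down,
        pct_up=_round_half_up(100.0 * n_up / denom),
        pct_down=_round_half_up(100.0 * n_down / denom),
    )


# ---------------------------------------------------------------------------


def build_tf_network(
    tf_table: pd.DataFrame,
    peaks: pd.DataFrame,
    de: pd.DataFrame,
    genes: GeneAnnotation,
    genome: dict[str, str],
    times: tuple[str, ...] = ("1h", "6h"),
    prom_bp: int = 1500,
):
    """Time-layered TF -> gene network from motifs, accessibility and DE.

    An edge TF -> gene exists at time t iff (a) the TF's motif hits inside a
    peak overlapping the gene's promoter, (b) that peak is accessible at t
    (boolean column ``accessible_<t>``), and (c) the gene is DE at t
    (DE table columns ``gene_id, time, direction``). TF nodes carry their
    family and own DE direction; output is a networkx DiGraph whose edges
    carry the time layer, independent of input record order.
    """
    import networkx as nx

    g = nx.MultiDiGraph()   # keyed by time layer: one edge per (TF, gene, time)
    promoters = genes.promoters(prom_bp)
    de_idx = {(r["gene_id"], r["time"]): r["direction"] for _, r in de.iterrows()
              if r["direction"] in ("up", "down")}
    tf_rows = tf_table.sort_values("tf_id")
    for _, tf in tf_rows.iterrows():
        g.add_node(tf["tf_id"], kind="tf", family=tf.get("family", ""),
                   direction=tf.get("direction", ""))
        motif = tf.get("motif")
        if motif is None:
            warnings.warn(f"TF {tf['tf_id']} has no motif; node retained without edges")
            continue
        for pidx in sorted(peaks.index):
            r = peaks.loc[pidx]
            seq = genome[r["chrom"]][int(r["start"]): int(r["end"])]
            if not pwm_scan(seq, motif):
                continue
            prom = promoters[(promoters["chrom"] == r["chrom"])
                             & (promoters["start"] < r["end"])
                             & (promoters["end"] > r["start"])]
            for gene in sorted(prom["gene_id"]):
                for t in times:
                    if not bool(r.get(f"accessible_{t}", False)):
                        continue
                    direction = de_idx.get((gene, t))
                    if direction is None:
                        continue
                    g.add_node(gene, kind="gene")
                    g.add_edge(tf["tf_id"], gene, key=t, time=t,
                               gene_direction=direction,
                               motif_in_accessible_peak=True, gene_de=True)
    return g
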