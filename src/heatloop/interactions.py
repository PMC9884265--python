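"""Significant-interaction calling and downstream loop analyses.

The caller follows the cumulative-binomial family of Hi-C/C-Hi-C loop callers:
for each intrachromosomal bin pair (i, j) within a distance range the expected
probability is the product of the two bin marginal frequencies times an
empirical distance-decay factor, renormalized so the expected probabilities of
all tested pairs sum to one; the p-value for an observed count k is the upper
binomial tail P(X >= k) with X ~ Binomial(N, p0), N the total count over the
tested pairs. Marginal terms absorb capture/antibody bias in C-Hi-C and
HiChIP libraries, the decay term absorbs the polymer background.

Downstream: anchor annotation with genes/promoters/REs (with the self-loop,
duplicate and no-gene filters), accessibility stratification, promoter- and
RE-centric hub detection, Fisher-exact differential calls, and APA pileups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ContactMatrix, GeneAnnotation

__all__ = [
    "call_interactions",
    "annotate_anchors",
    "accessibility_strata",
    "detect_hubs",
    "differential_interactions",
    "apa",
    "HubReport",
    "APAResult",
]


def binomial_tail_pvalue(k, n, p0):
    """Cumulative binomial upper tail P(X >= k), X ~ Binomial(n, p0), computed
    through the regularized incomplete beta (survival) function."""
    return stats.binom.sf(np.asarray(k) - 1, n, p0)


@dataclass
class HubReport:
    """Promoter-centric and RE-centric hubs in the significant P-RE graph."""

    promoter_hubs: dict[tuple, set] = field(default_factory=dict)
    re_hubs: dict[tuple, set] = field(default_factory=dict)
    hub_min: int = 2


@dataclass
class APAResult:
    matrix: np.ndarray      # (2w+1) x (2w+1) mean O/E pileup
    score: float            # center pixel / mean of 3x3 lower-left corner
    n_loops: int
    n_excluded: int
    w: int


# ---------------------------------------------------------------------------


def _tested_pairs(cm, min_dist_bins, max_dist_bins, candidates):
    """Yield per-chromosome (i, j, k) arrays for the tested bin pairs."""
    out = {}
    if candidates is not None:
        cand = pd.DataFrame(candidates, columns=["chrom", "bin1", "bin2"])
        for chrom, sub in cand.groupby("chrom", sort=False):
            m = cm.matrices[chrom]
            i = np.minimum(sub["bin1"].to_numpy(), sub["bin2"].to_numpy())
            j = np.maximum(sub["bin1"].to_numpy(), sub["bin2"].to_numpy())
            out[chrom] = (i, j, m[i, j])
        return out
    for chrom, m in cm.matrices.items():
        n = m.shape[0]
        iu, ju = np.triu_indices(n, k=min_dist_bins)
        keep = (ju - iu) <= max_dist_bins
        out[chrom] = (iu[keep], ju[keep], m[iu[keep], ju[keep]])
    return out


def call_interactions(
    cm: ContactMatrix,
    min_dist_bins: int = 2,
    max_dist_bins: int = 100,
    alpha: float = 0.05,
    correction: str = "BH",
    candidates: list[tuple] | None = None,
    return_all: bool = False,
) -> pd.DataFrame:
    """Call significant interactions by the cumulative binomial model.

    Parameters
    ----------
    cm
        Raw (unbalanced) contact matrix.
    min_dist_bins, max_dist_bins
        Tested distance range in bins (ignored when ``candidates`` is given).
    correction
        ``"none"`` (raw p <= alpha, the threshold the calling family uses) or
        ``"BH"`` (Benjamini-Hochberg adjusted p <= alpha).
    candidates
        Optional explicit list of ``(chrom, bin1, bin2)`` pairs to test.
    return_all
        Return all tested pairs (with a ``significant`` column) instead of
        only the calls.
    """
    if cm.balanced:
        raise ValueError("interaction calling requires raw counts")
    if correction not in {"none", "BH"}:
        raise ValueError("correction must be 'none' or 'BH'")
    tested = _tested_pairs(cm, min_dist_bins, max_dist_bins, candidates)
    bias, decay = _bias_and_decay(cm)
    rows = []
    for chrom, (i, j, k) in tested.items():
        b = bias[chrom]
        w = b[i] * b[j] * decay[j - i]
        for bin1, bin2, kk, ww in zip(i, j, k, w):
            rows.append((chrom, int(bin1), int(bin2), float(kk), ww))
    df = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "count", "w"])
    df = df.sort_values(["chrom", "bin1", "bin2"]).reset_index(drop=True)
    N = df["count"].sum()
    if N == 0:
        raise ValueError("no counts in the tested pairs (N = 0)")
    wsum = df["w"].sum()
    if wsum <= 0:
        raise ValueError("degenerate expected model: zero total weight")
    df["p0"] = df["w"] / wsum
    if (df["p0"] >= 1).any():
        raise ValueError("expected probability >= 1 for a pair (model violation)")
    df["expected"] = df["p0"] * N
    df["pvalue"] = binomial_tail_pvalue(df["count"].to_numpy(), int(round(N)), df["p0"].to_numpy())
    if correction == "BH":
        df["padj"] = stats.false_discovery_control(df["pvalue"], method="bh")
    else:
        df["padj"] = df["pvalue"]
    df["significant"] = df["padj"] <= alpha
    bs = cm.bin_size
    df["start1"], df["end1"] = df["bin1"] * bs, (df["bin1"] + 1) * bs
    df["start2"], df["end2"] = df["bin2"] * bs, (df["bin2"] + 1) * bs
    df["condition"] = cm.condition
    df = df.drop(columns=["w", "p0"])
    if return_all:
        return df
    return df[df["significant"]].reset_index(drop=True)


def _bias_and_decay(cm: ContactMatrix, n_iter: int = 20) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Jointly estimate per-bin biases and the distance-decay curve.

    Solves ``E[k_ij] = b_i * b_j * f(|i - j|)`` by alternating updates: ``f``
    as the pooled per-distance ratio of observed counts to the current bias
    product, then ``b_i`` matched to each bin's off-diagonal marginal. Raw
    marginals alone would smear clustered capture/antibody bias onto unbiased
    neighbouring bins; the fixed point factorizes any multiplicative bin bias
    exactly. The off-diagonal marginal is used because the diagonal scales
    with the squared bias.
    """
    chroms = list(cm.matrices)
    n_max = max(m.shape[0] for m in cm.matrices.values())
    covs = {c: np.nansum(np.nan_to_num(m), axis=1) - np.nan_to_num(np.diag(m))
            for c, m in cm.matrices.items()}
    bias = {c: covs[c].copy() for c in chroms}
    ksum = np.zeros(n_max)
    for c, m in cm.matrices.items():
        n = m.shape[0]
        mm = np.nan_to_num(m)
        for d in range(1, n):
            ksum[d] += np.sum(np.diagonal(mm, d))
    decay = np.zeros(n_max)
    for _ in range(n_iter):
        bsum = np.zeros(n_max)
        for c in chroms:
            b = bias[c]
            n = len(b)
            for d in range(1, n):
                bsum[d] += np.sum(b[:-d] * b[d:])
        with np.errstate(invalid="ignore", divide="ignore"):
            decay = np.where(bsum > 0, ksum / bsum, 0.0)
        for c in chroms:
            b = bias[c]
            n = len(b)
            f_mat = decay[np.abs(np.subtract.outer(np.arange(n), np.arange(n)))]
            np.fill_diagonal(f_mat, 0.0)
            s = f_mat @ b
            new = np.where(s > 0, covs[c] / np.where(s > 0, s, 1.0), 0.0)
            bias[c] = new
    return bias, decay


def _sum_by_distance(d, k):
    d = np.asarray(d)
    k = np.asarray(k, dtype=float)
    uniq = np.unique(d)
    sums = np.array([k[d == x].sum() for x in uniq])
    ns = np.array([(d == x).sum() for x in uniq], dtype=float)
    return uniq, sums, ns


# ---------------------------------------------------------------------------


def _overlaps(starts, ends, qs, qe):
    """Boolean: does interval [qs, qe) overlap any of the given intervals?"""
    return bool(np.any((starts < qe) & (ends > qs)))


def _anchor_annotation(chrom, s, e, promoters, peaks, genes_df):
    prom = promoters[promoters["chrom"] == chrom]
    is_prom = _overlaps(prom["start"].to_numpy(), prom["end"].to_numpy(), s, e)
    is_re = False
    if peaks is not None:
        pk = peaks[(peaks["chrom"] == chrom)]
        if "class" in pk.columns:
            pk = pk[pk["class"] == "distal"]
        is_re = _overlaps(pk["start"].to_numpy(), pk["end"].to_numpy(), s, e)
    g = genes_df[genes_df["chrom"] == chrom]
    hit_body = (g["start"].to_numpy() < e) & (g["end"].to_numpy() > s)
    hit_prom = (prom["start"].to_numpy() < e) & (prom["end"].to_numpy() > s)
    gene_ids = set(g["gene_id"].to_numpy()[hit_body]) | set(prom["gene_id"].to_numpy()[hit_prom])
    if is_prom:
        cls = "promoter"
    elif is_re:
        cls = "RE"
    else:
        cls = "other"
    return cls, gene_ids


def annotate_anchors(
    ints: pd.DataFrame,
    genes: GeneAnnotation,
    re_peaks: pd.DataFrame | None = None,
    require_both: bool = False,
) -> pd.DataFrame:
    """Label anchors (promoter / RE / other) and apply the standard filters:
    self-loops removed, duplicate unordered pairs collapsed (first record
    kept), interactions with no gene annotation on any anchor removed
    (``require_both=True`` demands genes on both anchors).
    """
    if ints.empty:
        out = ints.copy()
        for c in ("anchor1_class", "anchor2_class", "genes1", "genes2"):
            out[c] = pd.Series(dtype=object)
        return out
    promoters = genes.promoters()
    df = ints.copy()
    df = df[df["bin1"] != df["bin2"]]                      # self-loops
    key = df.apply(lambda r: (r["chrom"], min(r["bin1"], r["bin2"]), max(r["bin1"], r["bin2"])), axis=1)
    df = df.loc[~key.duplicated()].reset_index(drop=True)  # duplicates
    cls1, cls2, g1, g2 = [], [], [], []
    for _, r in df.iterrows():
        c1, gg1 = _anchor_annotation(r["chrom"], r["start1"], r["end1"], promoters, re_peaks, genes.df)
        c2, gg2 = _anchor_annotation(r["chrom"], r["start2"], r["end2"], promoters, re_peaks, genes.df)
        cls1.append(c1)
        cls2.append(c2)
        g1.append(sorted(gg1))
        g2.append(sorted(gg2))
    df["anchor1_class"], df["anchor2_class"] = cls1, cls2
    df["genes1"], df["genes2"] = g1, g2
    has1 = df["genes1"].map(bool)
    has2 = df["genes2"].map(bool)
    keep = (has1 & has2) if require_both else (has1 | has2)
    return df[keep].reset_index(drop=True)


def accessibility_strata(
    ints: pd.DataFrame,
    atac_peaks: pd.DataFrame,
    oe_maps: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each interaction the number of anchors overlapping an accessible
    peak (category 0/1/2) and summarize normalized strength (O/E at the pixel)
    per category.
    """
    df = ints.copy()
    cats, strengths = [], []
    for _, r in df.iterrows():
        cat = 0
        if atac_peaks is not None and len(atac_peaks):
            pk = atac_peaks[atac_peaks["chrom"] == r["chrom"]]
            st, en = pk["start"].to_numpy(), pk["end"].to_numpy()
            cat = int(_overlaps(st, en, r["start1"], r["end1"])) + int(
                _overlaps(st, en, r["start2"], r["end2"])
            )
        cats.append(cat)
        strengths.append(float(oe_maps[r["chrom"]][int(r["bin1"]), int(r["bin2"])]))
    df["acc_category"] = cats
    df["strength"] = strengths
    summary = (
        df.groupby("acc_category")["strength"]
        .agg(n="size", mean="mean", median="median")
        .reset_index()
    )
    return df, summary


def detect_hubs(ints: pd.DataFrame, hub_min: int = 2) -> HubReport:
    """Bipartite promoter-RE graph from P-RE interactions; hubs have >= hub_min
    distinct partners. Anchors are keyed by (chrom, bin).
    """
    if hub_min < 2:
        raise ValueError("hub_min must be >= 2")
    import networkx as nx

    g = nx.Graph()
    for _, r in ints.iterrows():
        pair = {r["anchor1_class"]: (r["chrom"], int(r["bin1"])),
                r["anchor2_class"]: (r["chrom"], int(r["bin2"]))}
        if set(pair) == {"promoter", "RE"}:
            g.add_node(pair["promoter"], kind="promoter")
            g.add_node(pair["RE"], kind="RE")
            g.add_edge(pair["promoter"], pair["RE"])
    prom_hubs, re_hubs = {}, {}
    for node, data in g.nodes(data=True):
        partners = set(g.neighbors(node))
        if len(partners) >= hub_min:
            if data["kind"] == "promoter":
                prom_hubs[node] = partners
            else:
                re_hubs[node] = partners
    return HubReport(promoter_hubs=prom_hubs, re_hubs=re_hubs, hub_min=hub_min)


def differential_interactions(
    a: pd.DataFrame,
    b: pd.DataFrame,
    Na: float,
    Nb: float,
    alpha: float = 0.05,
    cm_a: ContactMatrix | None = None,
    cm_b: ContactMatrix | None = None,
) -> pd.DataFrame:
    """Fisher's exact test per union pair on depth-conditioned counts.

    ``a`` is the reference condition (e.g. 0h), ``b`` the treatment (e.g. 1h);
    ``direction`` is "gained" when enriched in ``b``, "lost" when depleted.
    Counts for pairs called in only one condition are read from the matching
    matrix when provided, else treated as 0.
    """
    if Na <= 0 or Nb <= 0:
        raise ValueError("library sizes must be positive")

    def keyed(df):
        return {(r["chrom"], int(r["bin1"]), int(r["bin2"])): float(r["count"])
                for _, r in df.iterrows()}

    ka, kb = keyed(a), keyed(b)
    keys = sorted(set(ka) | set(kb))

    def lookup(key, have, cm):
        if key in have:
            return have[key]
        if cm is not None:
            return float(cm.matrices[key[0]][key[1], key[2]])
        return 0.0

    rows = []
    for key in keys:
        xa = lookup(key, ka, cm_a)
        xb = lookup(key, kb, cm_b)
        table = [[int(round(xb)), int(round(Nb - xb))], [int(round(xa)), int(round(Na - xa))]]
        p = stats.fisher_exact(table, alternative="two-sided").pvalue
        rows.append((*key, xa, xb, p))
    df = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "count_a", "count_b", "pvalue"])
    df["padj"] = stats.false_discovery_control(df["pvalue"], method="bh") if len(df) else []
    rate_a = df["count_a"] / Na
    rate_b = df["count_b"] / Nb
    df["direction"] = np.where(~(df["padj"] <= alpha), "ns",
                               np.where(rate_b > rate_a, "gained", "lost"))
    return df


def apa(
    cm: ContactMatrix,
    loops: list[tuple],
    w: int = 5,
    oe_maps: dict[str, np.ndarray] | None = None,
) -> APAResult:
    """Aggregate peak analysis: mean O/E submatrix over (2w+1)^2 windows
    centered on each loop pixel; score = center / mean of the 3x3 lower-left
    (short-distance) background corner.

    Loops closer than ``w`` bins to a matrix edge or with anchor separation
    <= 2w are excluded and counted.
    """
    if w < 3:
        raise ValueError("window half-width w must be >= 3")
    from .compartments import observed_over_expected

    if oe_maps is None:
        oe_maps = {c: observed_over_expected(m) for c, m in cm.matrices.items()}
    size = 2 * w + 1
    stack = np.zeros((size, size))
    n_used = n_excl = 0
    for chrom, b1, b2 in loops:
        i, j = int(min(b1, b2)), int(max(b1, b2))
        oe = oe_maps[chrom]
        n = oe.shape[0]
        if j - i <= 2 * w or i - w < 0 or j + w >= n:
            n_excl += 1
            continue
        stack += oe[i - w: i + w + 1, j - w: j + w + 1]
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable loops for APA")
    stack /= n_used
    corner = stack[-3:, :3]   # rows: i + w side, cols: j - w side (short distance)
    score = float(stack[w, w] / corner.mean())
    return APAResult(matrix=stack, score=score, n_loops=n_used, n_excluded=n_excl, w=w)
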