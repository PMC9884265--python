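"""Regulatory-element classification and time-course clustering.

Accessible peaks are split into TSS-proximal (overlapping the strand-aware
1.0 kb upstream window of a TSS), TSS-distal (at least the proximal distance
from every gene body) and genic-other. Distal peaks get an enhancer-like
chromatin-signature label when their nucleosome flanks carry high H3K9ac and
H3K18ac while being devoid of H3K4me3, with "high"/"devoid" defined as cohort
quantiles. Accessibility time courses are clustered with seeded k-means
(k = 5 by default) or a batch self-organizing map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneAnnotation, SignalTrack, summarize_track

__all__ = [
    "classify_proximal_distal",
    "enhancer_signature",
    "kmeans_timecourse",
    "som_fit",
    "atac_expression_concordance",
    "ClusterAssignment",
    "standardize_rows",
]

REQUIRED_MARKS = ("H3K9ac", "H3K18ac", "H3K4me3")


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    method: str                     # "kmeans" or "som"
    k: int | tuple[int, int]
    error: float                    # inertia (k-means) / quantization error (SOM)
    seed: int
    centers: np.ndarray | None = None
    error_history: np.ndarray | None = None


# ---------------------------------------------------------------------------


def classify_proximal_distal(
    peaks: pd.DataFrame,
    genes: GeneAnnotation,
    prox_bp: int = 1000,
    allow_genic_distal: bool = False,
) -> pd.DataFrame:
    """Partition peaks into proximal / distal / genic-other.

    Proximal: overlaps the strand-aware window [TSS - prox_bp, TSS) (upstream
    in strand direction); linked to the gene with the nearest TSS among the
    overlapped windows. Distal: at least ``prox_bp`` from every gene body
    (``allow_genic_distal`` drops the gene-body exclusion). Everything else is
    genic-other.
    """
    df = peaks.copy().reset_index(drop=True)
    tss = genes.tss().to_numpy()
    plus = (genes.df["strand"] == "+").to_numpy()
    win_s = np.where(plus, tss - prox_bp, tss)
    win_e = np.where(plus, tss, tss + prox_bp)
    gchrom = genes.df["chrom"].to_numpy()
    gs, ge = genes.df["start"].to_numpy(), genes.df["end"].to_numpy()
    gid = genes.df["gene_id"].to_numpy()
    classes, linked = [], []
    for _, r in df.iterrows():
        on = gchrom == r["chrom"]
        ps, pe = r["start"], r["end"]
        ov = on & (win_s < pe) & (win_e > ps)
        if ov.any():
            mid = (ps + pe) / 2.0
            best = np.flatnonzero(ov)[np.argmin(np.abs(tss[ov] - mid))]
            classes.append("proximal")
            linked.append(gid[best])
            continue
        gap = np.where(on, np.maximum(gs - pe, ps - ge), np.inf)
        gap = np.where(on & (gs < pe) & (ge > ps), -1.0, gap)  # overlapping body
        near = np.min(gap, initial=np.inf)
        if allow_genic_distal or near >= prox_bp:
            classes.append("distal")
            linked.append(None)
        else:
            classes.append("genic-other")
            linked.append(None)
    df["class"] = classes
    df["linked_gene"] = linked
    return df


def enhancer_signature(
    peaks: pd.DataFrame,
    marks: dict[str, SignalTrack],
    flank_bp: int = 500,
    hi_q: float = 0.75,
    lo_q: float = 0.25,
) -> pd.DataFrame:
    """Label distal peaks enhancer-like from their nucleosome-flank chromatin.

    Flank signal = mean of the two ``flank_bp`` windows outside the accessible
    interval. A distal peak is enhancer-like iff its H3K9ac AND H3K18ac flank
    means are each at or above the ``hi_q`` cohort quantile AND its H3K4me3
    flank mean is at or below the ``lo_q`` cohort quantile (cohort = distal
    peaks). Proximal and genic peaks are never labeled.
    """
    for mark in REQUIRED_MARKS:
        if mark not in marks:
            raise ValueError(f"missing required mark track: {mark}")
    df = peaks.copy().reset_index(drop=True)
    if "class" not in df.columns:
        raise ValueError("peaks must be classified before signature labeling")
    distal = df["class"] == "distal"
    flank_means = {}
    left = df.assign(start=df["start"] - flank_bp, end=df["start"])
    right = df.assign(start=df["end"], end=df["end"] + flank_bp)
    left["start"] = left["start"].clip(lower=0)
    for mark in REQUIRED_MARKS:
        lv = summarize_track(marks[mark], left, "mean")
        rv = summarize_track(marks[mark], right, "mean")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            flank_means[mark] = np.nanmean(np.vstack([lv, rv]), axis=0)
        df[f"flank_{mark}"] = flank_means[mark]
    hi9 = np.nanquantile(flank_means["H3K9ac"][distal], hi_q)
    hi18 = np.nanquantile(flank_means["H3K18ac"][distal], hi_q)
    lo4 = np.nanquantile(flank_means["H3K4me3"][distal], lo_q)
    sig = (
        distal.to_numpy()
        & (flank_means["H3K9ac"] >= hi9)
        & (flank_means["H3K18ac"] >= hi18)
        & (flank_means["H3K4me3"] <= lo4)
    )
    df["signature"] = np.where(sig, "enhancer-like", "none")
    return df


# ---------------------------------------------------------------------------


def standardize_rows(x: np.ndarray) -> np.ndarray:
    """Per-row mean 0 / sd 1; constant rows become all-zero."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def kmeans_timecourse(
    profiles: np.ndarray,
    k: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> ClusterAssignment:
    """Seeded k-means (k-means++ init, Lloyd iterations) on row-standardized
    time courses; cluster ids are relabeled by descending cluster size.
    """
    from sklearn.cluster import KMeans

    x = np.asarray(profiles, dtype=float)
    if k > x.shape[0]:
        raise ValueError("k exceeds the number of items")
    if standardize:
        x = standardize_rows(x)
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=300, tol=1e-6,
                random_state=seed, algorithm="lloyd").fit(x)
    sizes = np.bincount(km.labels_, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClusterAssignment(labels=relabel[km.labels_], method="kmeans", k=k,
                             error=float(km.inertia_), seed=seed,
                             centers=km.cluster_centers_[order])


def som_fit(
    profiles: np.ndarray,
    grid: tuple[int, int] = (3, 3),
    epochs: int = 50,
    seed: int = 0,
    standardize: bool = True,
) -> ClusterAssignment:
    """Batch self-organizing map on a rectangular grid.

    Prototypes are initialized on the span of the first two principal
    components (plus a tiny seeded jitter to break ties). Each epoch assigns
    every item to its best-matching unit (Euclidean) and replaces prototypes
    by Gaussian-neighborhood-weighted means; the neighborhood radius decays
    linearly from max(grid)/2 to 0.5. Returns per-item unit indices, the unit
    prototype matrix and the per-epoch quantization error.
    """
    x = np.asarray(profiles, dtype=float)
    if x.size == 0:
        raise ValueError("empty profile matrix")
    rows, cols = grid
    if rows * cols < 2 or min(rows, cols) < 1:
        raise ValueError("grid must have at least 2 units")
    if standardize:
        x = standardize_rows(x)
    rng = np.random.default_rng(seed)
    mu = x.mean(axis=0)
    xc = x - mu
    # PCA span initialization
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    n_pc = min(2, vt.shape[0])
    scale = s[:n_pc] / max(np.sqrt(x.shape[0]), 1.0)
    gr, gc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack([gr.ravel(), gc.ravel()], axis=1).astype(float)
    u = (coords[:, 0] / max(rows - 1, 1) - 0.5) * 2.0
    v = (coords[:, 1] / max(cols - 1, 1) - 0.5) * 2.0
    protos = np.tile(mu, (rows * cols, 1))
    protos += np.outer(u, scale[0] * vt[0])
    if n_pc > 1:
        protos += np.outer(v, scale[1] * vt[1])
    protos += rng.normal(0, 1e-6, protos.shape)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    radius = np.linspace(max(rows, cols) / 2.0, 0.5, max(epochs, 2))
    qe_hist = []   # quantization error of the map after each epoch's update
    for epoch in range(epochs):
        d2 = ((x[:, None, :] - protos[None, :, :]) ** 2).sum(-1)
        bmu = d2.argmin(axis=1)
        h = np.exp(-grid_d2 / (2.0 * radius[epoch] ** 2))   # units x units
        wgt = h[:, bmu]                                     # units x items
        denom = wgt.sum(axis=1, keepdims=True)
        upd = denom.squeeze(-1) > 0
        protos[upd] = (wgt @ x)[upd] / denom[upd]
        d2 = ((x[:, None, :] - protos[None, :, :]) ** 2).sum(-1)
        qe_hist.append(float(np.sqrt(d2.min(axis=1)).mean()))
    d2 = ((x[:, None, :] - protos[None, :, :]) ** 2).sum(-1)
    bmu = d2.argmin(axis=1)
    return ClusterAssignment(labels=bmu, method="som", k=grid,
                             error=qe_hist[-1], seed=seed, centers=protos,
                             error_history=np.asarray(qe_hist))


# ---------------------------------------------------------------------------


def atac_expression_concordance(
    peaks: pd.DataFrame,
    expr_means: pd.DataFrame,
    acc_cols: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Spearman correlation between proximal-peak accessibility and linked-gene
    expression across time points.

    ``expr_means`` is a gene x time-point table (same time order as
    ``acc_cols``, default the ``acc_*`` columns of the peak table). Unlinked
    peaks (or linked genes absent from the table) are skipped and counted.
    """
    acc_cols = acc_cols or [c for c in peaks.columns if c.startswith("acc_")]
    if len(acc_cols) < 3:
        raise ValueError("need at least 3 time points for rank correlation")
    rows = []
    n_skipped = 0
    prox = peaks[peaks["class"] == "proximal"] if "class" in peaks.columns else peaks
    for idx, r in prox.iterrows():
        gene = r.get("linked_gene")
        if gene is None or gene not in expr_means.index:
            n_skipped += 1
            continue
        acc = r[acc_cols].to_numpy(dtype=float)
        ex = expr_means.loc[gene].to_numpy(dtype=float)
        rho = stats.spearmanr(acc, ex).statistic
        rows.append((idx, gene, rho))
    df = pd.DataFrame(rows, columns=["peak", "gene", "rho"])
    summary = {
        "n": len(df),
        "n_skipped": n_skipped,
        "median_rho": float(df["rho"].median()) if len(df) else float("nan"),
        "fraction_positive": float((df["rho"] > 0).mean()) if len(df) else float("nan"),
    }
    return df, summary
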