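"""A/B compartment analysis: distance decay, O/E and Pearson maps, PC1 calling,
feature-sorted matrices, saddle plots with compartment strength, P(s) scaling
curves for arms vs pericentromeres, and depth-normalized difference maps.

The expected model is the per-distance mean of the intrachromosomal matrix.
PC1 is the leading eigenvector of the column-centered Pearson map, computed
per chromosome; its sign is oriented so that bins with positive PC1 (the A
compartment) carry the higher mean of an activity track such as H3K9ac.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import ContactMatrix, GenomeLayout, SignalTrack

__all__ = [
    "CompartmentProfile",
    "SaddleResult",
    "ScalingCurve",
    "expected_by_distance",
    "observed_over_expected",
    "oe_by_chrom",
    "correlation_map",
    "compartment_pc1",
    "sort_matrix_by_feature",
    "saddle",
    "scaling_curve",
    "difference_map",
]


@dataclass
class CompartmentProfile:
    """Per-bin PC1 loadings and A/B labels. Labels: +1 = A, -1 = B, 0 = masked."""

    pc1: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]
    orientation: dict[str, str] = field(default_factory=dict)
    degenerate: dict[str, bool] = field(default_factory=dict)


@dataclass
class SaddleResult:
    matrix: np.ndarray          # Q x Q mean O/E between PC1-quantile groups (B -> A)
    Q: int
    corner: int
    strength: float             # (AA * BB) / (AB * BA), corner means
    strength_sum: float         # (AA + BB) / (AB + BA) alternative
    corner_means: dict[str, float] = field(default_factory=dict)


@dataclass
class ScalingCurve:
    s: np.ndarray               # genomic distance (bp), log2-spaced bin midpoints
    frequency: np.ndarray       # mean contacts per bin pair, per million valid pairs
    region_class: str
    condition: str
    slope: float                # log-log slope fitted over the stated range
    fit_range: tuple[float, float] = (0.0, 0.0)


# ---------------------------------------------------------------------------


def expected_by_distance(m: np.ndarray) -> np.ndarray:
    """Mean of unmasked entries at each diagonal offset ``d = |i - j|``."""
    n = m.shape[0]
    exp = np.empty(n)
    for d in range(n):
        diag = np.diagonal(m, d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            exp[d] = np.nanmean(diag) if diag.size else np.nan
    return exp


def observed_over_expected(m: np.ndarray) -> np.ndarray:
    """Divide each entry by the mean of its diagonal; masked (NaN) rows propagate."""
    n = m.shape[0]
    exp = expected_by_distance(m)
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    e = exp[idx]
    if np.any((e == 0) & (np.nan_to_num(m) > 0)):
        raise ValueError("expected value 0 at a distance carrying observations")
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(e > 0, m / e, np.where(np.isnan(m), np.nan, 0.0))
    return oe


def oe_by_chrom(cm: ContactMatrix) -> dict[str, np.ndarray]:
    return {c: observed_over_expected(m) for c, m in cm.matrices.items()}


def correlation_map(oe: np.ndarray) -> np.ndarray:
    """Pearson correlation of O/E rows over unmasked columns; diagonal set to 1.

    Rows with zero variance (or masked rows) come back as NaN rows.
    """
    n = oe.shape[0]
    masked = np.isnan(oe).all(axis=1)
    ok = ~masked
    if ok.sum() < 3:
        raise ValueError("need at least 3 unmasked bins for a correlation map")
    sub = oe[np.ix_(ok, ok)]
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(sub)
    out = np.full((n, n), np.nan)
    out[np.ix_(ok, ok)] = c
    np.fill_diagonal(out, np.where(ok, 1.0, np.nan))
    return out


def compartment_pc1(
    corr_maps: dict[str, np.ndarray],
    activity: SignalTrack,
    degeneracy_tol: float = 1e-8,
) -> CompartmentProfile:
    """Leading eigenvector of the centered correlation map, per chromosome.

    The eigenvector sign is flipped if needed so that the mean activity signal
    over PC1 > 0 bins is at least that over PC1 <= 0 bins; A = PC1 > 0.
    A (near-)degenerate leading eigenvalue masks the whole chromosome with a
    warning, as no stable compartment axis exists.
    """
    pc1s, labels, orient, degen = {}, {}, {}, {}
    for chrom, corr in corr_maps.items():
        n = corr.shape[0]
        pc = np.full(n, np.nan)
        lab = np.zeros(n, dtype=int)
        ok = ~np.isnan(corr).all(axis=1)
        sub = corr[np.ix_(ok, ok)]
        sub = np.nan_to_num(sub, nan=0.0)
        centered = sub - sub.mean(axis=0, keepdims=True)
        # symmetrize: column centering breaks symmetry slightly
        sym = (centered + centered.T) / 2.0
        evals, evecs = np.linalg.eigh(sym)
        lead, second = evals[-1], evals[-2] if len(evals) > 1 else -np.inf
        if abs(lead - second) <= degeneracy_tol * max(abs(lead), 1.0):
            warnings.warn(f"degenerate leading eigenvalue on {chrom}; bins masked")
            degen[chrom] = True
            pc1s[chrom], labels[chrom] = pc, lab
            continue
        degen[chrom] = False
        v = evecs[:, -1]
        act = activity.values.get(chrom)
        if act is None:
            raise ValueError(f"activity track has no values for {chrom}")
        act = act[: n][ok]
        pos, neg = v > 0, v <= 0
        mean_pos = np.nanmean(act[pos]) if pos.any() else -np.inf
        mean_neg = np.nanmean(act[neg]) if neg.any() else -np.inf
        if mean_pos < mean_neg:
            v = -v
            orient[chrom] = f"sign flipped by {activity.name}"
        else:
            orient[chrom] = f"sign kept by {activity.name}"
        pc[ok] = v
        lab[ok] = np.where(v > 0, 1, -1)
        pc1s[chrom], labels[chrom] = pc, lab
    return CompartmentProfile(pc1=pc1s, labels=labels, orientation=orient, degenerate=degen)


def sort_matrix_by_feature(m: np.ndarray, feature: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reorder rows/columns by ascending feature; NaN features go last.

    Ties break by original bin index (stable sort). Returns the reordered
    matrix and the permutation applied.
    """
    feature = np.asarray(feature, dtype=float)
    if feature.shape[0] != m.shape[0]:
        raise ValueError("feature length must equal bin count")
    key = np.where(np.isnan(feature), np.inf, feature)
    perm = np.argsort(key, kind="stable")
    return m[np.ix_(perm, perm)], perm


def saddle(
    oe_maps: dict[str, np.ndarray],
    profile: CompartmentProfile,
    Q: int = 50,
    corner: int = 5,
    min_sep: int = 2,
) -> SaddleResult:
    """Mean O/E between genome-wide PC1-quantile groups (ascending: B -> A).

    Bins are ranked by PC1 across chromosomes into ``Q`` equal-occupancy
    groups; only intrachromosomal pairs separated by at least ``min_sep`` bins
    contribute. Compartment strength is the ratio of corner-mean products.
    """
    chroms, bins, pcs = [], [], []
    for chrom, pc in profile.pc1.items():
        ok = np.flatnonzero(~np.isnan(pc) & (profile.labels[chrom] != 0))
        chroms += [chrom] * len(ok)
        bins.append(ok)
        pcs.append(pc[ok])
    if not pcs or sum(len(p) for p in pcs) < Q:
        raise ValueError("Q exceeds the number of unmasked bins")
    pc_all = np.concatenate(pcs)
    order = np.argsort(pc_all, kind="stable")
    groups = np.empty(len(pc_all), dtype=int)
    for g, chunk in enumerate(np.array_split(order, Q)):
        groups[chunk] = g
    # map back to (chrom, bin) -> group
    group_of: dict[str, np.ndarray] = {}
    offset = 0
    for chrom, ok in zip(profile.pc1.keys(), bins):
        g = np.full(len(profile.pc1[chrom]), -1, dtype=int)
        g[ok] = groups[offset: offset + len(ok)]
        group_of[chrom] = g
        offset += len(ok)
    sums = np.zeros((Q, Q))
    counts = np.zeros((Q, Q))
    for chrom, oe in oe_maps.items():
        g = group_of.get(chrom)
        if g is None:
            continue
        n = oe.shape[0]
        iu, ju = np.triu_indices(n, k=min_sep)
        gi, gj = g[iu], g[ju]
        vals = oe[iu, ju]
        keep = (gi >= 0) & (gj >= 0) & ~np.isnan(vals)
        np.add.at(sums, (gi[keep], gj[keep]), vals[keep])
        np.add.at(counts, (gi[keep], gj[keep]), 1.0)
        np.add.at(sums, (gj[keep], gi[keep]), vals[keep])
        np.add.at(counts, (gj[keep], gi[keep]), 1.0)
    with np.errstate(invalid="ignore"):
        S = sums / counts
    c = corner
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bb = float(np.nanmean(S[:c, :c]))
        aa = float(np.nanmean(S[-c:, -c:]))
        ab = float(np.nanmean(S[:c, -c:]))
        ba = float(np.nanmean(S[-c:, :c]))
    strength = (aa * bb) / (ab * ba)
    strength_sum = (aa + bb) / (ab + ba)
    return SaddleResult(matrix=S, Q=Q, corner=c, strength=strength, strength_sum=strength_sum,
                        corner_means={"AA": aa, "BB": bb, "AB": ab, "BA": ba})


def scaling_curve(
    cm: ContactMatrix,
    region_class: str,
    n_log_bins: int = 24,
    fit_range_bins: tuple[int, float] | None = None,
) -> ScalingCurve:
    """P(s): mean contact frequency per log2-spaced distance bin, arms vs
    pericentromeres, pooled over chromosomes; frequency is per bin pair and
    per million valid pairs so equal-depth conditions compare directly.

    The log-log slope is fitted by least squares over distances from 3 bins to
    a quarter of the largest region span (defaults).
    """
    bs = cm.bin_size
    depth = cm.total_pairs()
    sum_by_d: dict[int, float] = {}
    n_by_d: dict[int, float] = {}
    max_span = 0
    for chrom, m in cm.matrices.items():
        mask = cm.layout.region_mask(chrom, region_class)
        if mask.sum() < 2:
            warnings.warn(f"region class {region_class!r} empty on {chrom}; skipped")
            continue
        # pairs are taken within each contiguous run of the class (e.g. within
        # one arm), so the curve never mixes in centromere-spanning contacts
        boundaries = np.flatnonzero(np.diff(mask.astype(int)) != 0) + 1
        for run in np.split(np.arange(len(mask)), boundaries):
            idx = run[mask[run]]
            if idx.size < 2:
                continue
            max_span = max(max_span, int(idx.max() - idx.min() + 1))
            sub = m[np.ix_(idx, idx)]
            dists = np.abs(np.subtract.outer(idx, idx))
            iu, ju = np.triu_indices(len(idx), k=1)
            d = dists[iu, ju]
            v = sub[iu, ju]
            keep = ~np.isnan(v)
            for dd in np.unique(d[keep]):
                sel = keep & (d == dd)
                sum_by_d[dd] = sum_by_d.get(dd, 0.0) + float(v[sel].sum())
                n_by_d[dd] = n_by_d.get(dd, 0.0) + float(sel.sum())
    if not sum_by_d:
        raise ValueError(f"no bin pairs in region class {region_class!r}")
    dmax = max(sum_by_d)
    edges = np.unique(np.round(np.logspace(0, np.log2(dmax + 1), n_log_bins, base=2.0)).astype(int))
    s_mid, freq = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        tot = sum(sum_by_d.get(d, 0.0) for d in range(lo, hi))
        npair = sum(n_by_d.get(d, 0.0) for d in range(lo, hi))
        if npair == 0:
            continue
        s_mid.append(np.sqrt(lo * max(hi - 1, lo)) * bs)
        freq.append(tot / npair / depth * 1e6)
    s_mid, freq = np.asarray(s_mid), np.asarray(freq)
    lo_bins, hi_bins = fit_range_bins or (3, max_span / 4.0)
    sel = (s_mid >= lo_bins * bs) & (s_mid <= hi_bins * bs) & (freq > 0)
    slope = np.nan
    if sel.sum() >= 2:
        slope = float(np.polyfit(np.log2(s_mid[sel]), np.log2(freq[sel]), 1)[0])
    return ScalingCurve(s=s_mid, frequency=freq, region_class=region_class,
                        condition=cm.condition, slope=slope,
                        fit_range=(lo_bins * bs, hi_bins * bs))


def difference_map(a: ContactMatrix, b: ContactMatrix) -> dict[str, np.ndarray]:
    """Per-chromosome difference of depth-normalized maps: CPM(a) - CPM(b).

    Positive entries mark contacts enriched in ``a`` (e.g. RNAPII HiChIP over
    Hi-C). Both matrices are scaled to counts per million intrachromosomal
    valid pairs before subtraction.
    """
    if a.bin_size != b.bin_size or set(a.matrices) != set(b.matrices):
        raise ValueError("binning mismatch between matrices")
    na, nb = a.total_pairs(), b.total_pairs()
    if na == 0 or nb == 0:
        raise ValueError("cannot depth-normalize an empty matrix")
    out = {}
    for chrom in a.matrices:
        if a.matrices[chrom].shape != b.matrices[chrom].shape:
            raise ValueError(f"binning mismatch on {chrom}")
        out[chrom] = a.matrices[chrom] / na * 1e6 - b.matrices[chrom] / nb * 1e6
    return out
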