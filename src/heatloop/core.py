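"""Core data model: genome layout, gene annotation, signal tracks and contact matrices.

All coordinates are 0-based, half-open. Bin ``b`` of a chromosome covers
``[b * bin_size, min((b + 1) * bin_size, length))``; the last bin may be short.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "GeneAnnotation",
    "SignalTrack",
    "ContactMatrix",
    "bin_pairs",
    "balance_matrix",
    "design_capture_baits",
    "summarize_track",
]

PROMOTER_BP = 1500  # capture design targets 1.5 kb promoters


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with per-chromosome pericentromere intervals and a bin size.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs; order defines bin indexing.
    pericentromere
        ``name -> (start, end)`` half-open interval, strictly inside the chromosome.
    bin_size
        Genomic bin width in bp.
    """

    chromosomes: tuple[tuple[str, int], ...]
    pericentromere: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    bin_size: int = 20_000

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for name, (s, e) in dict(self.pericentromere).items():
            if name not in lengths:
                raise ValueError(f"pericentromere on unknown chromosome {name}")
            if not (0 <= s < e <= lengths[name]):
                raise ValueError(
                    f"pericentromere ({s}, {e}) out of bounds on chromosome {name} "
                    f"(length {lengths[name]})"
                )

    # -- bin arithmetic -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for n, l in self.chromosomes:
            if n == chrom:
                return l
        raise KeyError(chrom)

    def n_bins(self, chrom: str) -> int:
        return -(-self.length(chrom) // self.bin_size)  # ceil division

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(n) for n in self.names)

    def bin_index(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.length(chrom):
            raise ValueError(f"position {pos} outside chromosome {chrom}")
        return pos // self.bin_size

    def bin_interval(self, chrom: str, b: int) -> tuple[int, int]:
        start = b * self.bin_size
        return start, min(start + self.bin_size, self.length(chrom))

    def bin_table(self) -> pd.DataFrame:
        rows = []
        for name in self.names:
            for b in range(self.n_bins(name)):
                s, e = self.bin_interval(name, b)
                rows.append((name, b, s, e))
        return pd.DataFrame(rows, columns=["chrom", "bin", "start", "end"])

    def region_mask(self, chrom: str, region_class: str) -> np.ndarray:
        """Boolean mask over bins: bin belongs to a class if its midpoint does."""
        n = self.n_bins(chrom)
        mids = np.minimum(np.arange(n) * self.bin_size + self.bin_size // 2, self.length(chrom) - 1)
        s, e = dict(self.pericentromere).get(chrom, (0, 0))
        peri = (mids >= s) & (mids < e)
        if region_class == "pericentromere":
            return peri
        if region_class == "arm":
            return ~peri
        raise ValueError(f"unknown region class {region_class!r}")


class GeneAnnotation:
    """Gene records with strand-aware TSS and 1.5 kb upstream promoters.

    Backed by a DataFrame with columns ``gene_id, chrom, start, end, strand``.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"gene_id", "chrom", "start", "end", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"gene table missing columns {sorted(missing)}")
        df = df.reset_index(drop=True).copy()
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].iloc[0]
            raise ValueError(f"gene {bad} has start >= end")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup}")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        self.df = df

    def __len__(self):
        return len(self.df)

    def tss(self) -> pd.Series:
        """Strand-aware TSS: start for +, end for - (half-open convention)."""
        return self.df["start"].where(self.df["strand"] == "+", self.df["end"])

    def promoters(self, prom_bp: int = PROMOTER_BP, layout: GenomeLayout | None = None) -> pd.DataFrame:
        """Upstream promoter windows of ``prom_bp``, clipped to chromosome bounds."""
        tss = self.tss()
        plus = self.df["strand"] == "+"
        start = np.where(plus, tss - prom_bp, tss)
        end = np.where(plus, tss, tss + prom_bp)
        out = pd.DataFrame(
            {
                "gene_id": self.df["gene_id"],
                "chrom": self.df["chrom"],
                "start": np.maximum(start, 0),
                "end": end,
            }
        )
        if layout is not None:
            lengths = out["chrom"].map(dict(layout.chromosomes))
            out["end"] = np.minimum(out["end"], lengths)
        return out


@dataclass
class SignalTrack:
    """A binned, non-negative genomic signal (histone mark, ATAC, RNAPII, DAP...).

    ``values[chrom]`` holds one value per bin of width ``bin_size``; NaN marks
    unmappable bins.
    """

    name: str
    bin_size: int
    values: dict[str, np.ndarray]
    condition: str | None = None

    def __post_init__(self):
        for chrom, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if np.nanmin(v, initial=0.0) < 0:
                raise ValueError(f"negative signal on {chrom} in track {self.name}")
            self.values[chrom] = v


@dataclass
class ContactMatrix:
    """Per-chromosome symmetric intrachromosomal contact matrices.

    ``matrices[chrom]`` is a dense symmetric array of (raw or balanced) counts
    at ``bin_size`` resolution. ``assay`` is one of HiC/CHiC/HiChIP.
    """

    layout: GenomeLayout
    matrices: dict[str, np.ndarray]
    assay: str = "HiC"
    condition: str = "0h"
    balanced: bool = False
    converged: bool = True

    def __post_init__(self):
        for chrom, m in self.matrices.items():
            m = np.asarray(m, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"matrix for {chrom} is not square")
            if m.shape[0] != self.layout.n_bins(chrom):
                raise ValueError(
                    f"matrix for {chrom} has {m.shape[0]} bins, layout expects "
                    f"{self.layout.n_bins(chrom)}"
                )
            self.matrices[chrom] = m

    @property
    def bin_size(self) -> int:
        return self.layout.bin_size

    def total_pairs(self) -> float:
        """Total valid-pair count: upper triangle including the diagonal."""
        tot = 0.0
        for m in self.matrices.values():
            with np.errstate(invalid="ignore"):
                tot += np.nansum(np.triu(np.nan_to_num(m)))
        return float(tot)

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.layout,
            {c: m.copy() for c, m in self.matrices.items()},
            assay=self.assay,
            condition=self.condition,
            balanced=self.balanced,
            converged=self.converged,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def bin_pairs(pairs: pd.DataFrame, layout: GenomeLayout) -> ContactMatrix:
    """Bin valid pairs into per-chromosome symmetric count matrices.

    ``pairs`` has columns ``chrom1, pos1, chrom2, pos2``; unordered pair
    semantics, each record increments exactly one unordered bin pair.
    Interchromosomal records are dropped (trans contacts are outside the
    per-chromosome matrix model) but their count is reported in a warning.
    """
    mats = {c: np.zeros((layout.n_bins(c), layout.n_bins(c))) for c in layout.names}
    known = set(layout.names)
    for col in ("chrom1", "pos1", "chrom2", "pos2"):
        if col not in pairs.columns:
            raise ValueError(f"pairs table missing column {col}")
    bad = ~(pairs["chrom1"].isin(known) & pairs["chrom2"].isin(known))
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"pair record {idx} on unknown chromosome")
    cis = pairs["chrom1"] == pairs["chrom2"]
    n_trans = int((~cis).sum())
    if n_trans:
        warnings.warn(f"dropping {n_trans} interchromosomal pairs")
    for chrom, sub in pairs[cis].groupby("chrom1", sort=False):
        i = sub["pos1"].to_numpy() // layout.bin_size
        j = sub["pos2"].to_numpy() // layout.bin_size
        n = layout.n_bins(chrom)
        if (sub["pos1"].to_numpy() < 0).any() or (i >= n).any() or (sub["pos2"].to_numpy() < 0).any() or (j >= n).any():
            raise ValueError(f"pair position outside chromosome {chrom}")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        np.add.at(mats[chrom], (lo, hi), 1.0)
    for chrom, m in mats.items():
        upper = np.triu(m, 1)
        mats[chrom] = m + upper.T  # mirror to lower triangle; diagonal untouched
    return ContactMatrix(layout, mats)


def _ice_one(m: np.ndarray, max_iter: int, tol: float, mask_frac: float) -> tuple[np.ndarray, bool]:
    w = np.array(m, dtype=float)
    marg = w.sum(axis=1)
    nz = marg[marg > 0]
    cutoff = mask_frac * (np.median(nz) if nz.size else 0.0)
    masked = marg <= cutoff
    w[masked, :] = 0.0
    w[:, masked] = 0.0
    ok = ~masked
    converged = False
    if ok.sum() >= 2:
        for _ in range(max_iter):
            s = w[np.ix_(ok, ok)].sum(axis=1)
            s = s / s.mean()
            if np.max(np.abs(s - 1.0)) < tol:
                converged = True
                break
            b = np.ones(w.shape[0])
            b[ok] = s
            w /= np.outer(b, b)
    else:
        converged = True
    w[masked, :] = np.nan
    w[:, masked] = np.nan
    return w, converged


def balance_matrix(
    cm: ContactMatrix, max_iter: int = 200, tol: float = 1e-3, mask_frac: float = 0.05
) -> ContactMatrix:
    """Iterative proportional fitting (ICE) per chromosome.

    Bins whose raw marginal is below ``mask_frac`` of the median nonzero
    marginal are masked (NaN). On non-convergence the best iterate is returned
    with ``converged=False`` and a warning.
    """
    out = {}
    all_conv = True
    for chrom, m in cm.matrices.items():
        w, conv = _ice_one(m, max_iter, tol, mask_frac)
        out[chrom] = w
        all_conv &= conv
    if not all_conv:
        warnings.warn("matrix balancing did not converge; returning best iterate")
    res = ContactMatrix(
        cm.layout, out, assay=cm.assay, condition=cm.condition, balanced=True, converged=all_conv
    )
    return res


def design_capture_baits(
    genes: GeneAnnotation,
    layout: GenomeLayout,
    probe_len: int = 120,
    step: int | None = None,
    prom_bp: int = PROMOTER_BP,
) -> pd.DataFrame:
    """Tile every promoter with capture probes.

    Probes of ``probe_len`` are laid left-to-right at stride ``step`` (default
    non-overlapping, i.e. ``probe_len``); a final probe is right-aligned so the
    promoter end is covered. Promoters shorter than one probe get a single
    centered probe. Probes are clipped to chromosome bounds and deduplicated by
    coordinate.
    """
    if step is None:
        step = probe_len
    lengths = dict(layout.chromosomes)
    rows = []
    for _, p in genes.promoters(prom_bp, layout).iterrows():
        s, e, chrom = int(p["start"]), int(p["end"]), p["chrom"]
        if e - s <= 0:
            continue
        if probe_len >= e - s:
            mid = (s + e) // 2
            starts = [mid - probe_len // 2]
        else:
            starts = list(range(s, e - probe_len + 1, step))
            if starts[-1] + probe_len < e:
                starts.append(e - probe_len)
        for st in starts:
            st_c = max(0, min(st, lengths[chrom] - probe_len))
            rows.append((chrom, st_c, st_c + probe_len))
    baits = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    baits = baits.drop_duplicates().sort_values(["chrom", "start"]).reset_index(drop=True)
    return baits


def summarize_track(track: SignalTrack, regions: pd.DataFrame, stat: str = "mean") -> np.ndarray:
    """Per-region summary (mean/max/sum) of a binned track over NaN-aware bins.

    Regions fully inside NaN bins yield NaN; partially-NaN regions summarize
    the non-NaN bins only.
    """
    if stat not in {"mean", "max", "sum"}:
        raise ValueError(f"unknown stat {stat!r}")
    fns = {"mean": np.nanmean, "max": np.nanmax, "sum": np.nansum}
    out = np.empty(len(regions))
    for idx, (_, r) in enumerate(regions.iterrows()):
        v = track.values.get(r["chrom"])
        if v is None:
            out[idx] = np.nan
            continue
        b0 = max(int(r["start"]) // track.bin_size, 0)
        b1 = min(-(-int(r["end"]) // track.bin_size), len(v))
        chunk = v[b0:b1]
        if chunk.size == 0 or np.isnan(chunk).all():
            out[idx] = np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[idx] = fns[stat](chunk)
    return out
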