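"""Quantification of the validation assays.

3C-qPCR: the relative interaction frequency of a reaction is
``E^-(Ct_target - Ct_norm)`` (amplification efficiency E, default 2), with the
normalization Ct measured on a restriction-site-free control region; technical
replicates are averaged before biological ones and each loop is scaled so the
reference group (wild type, 0 h by default) has mean 1.

Dual luciferase: per-replicate LUC/REN ratios, construct means normalized to
the minimal-promoter control construct.

Group comparison uses the pooled-variance two-sample Student's t-test
(Welch available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_interaction_frequency",
    "luciferase_activity",
    "two_sample_t",
    "TTestResult",
]


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    underflow: bool = False   # zero pooled variance with unequal means


def relative_interaction_frequency(
    table: pd.DataFrame,
    reference: tuple[str, str] = ("WT", "0h"),
    efficiency: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(genotype, condition, loop) mean +/- sd relative interaction frequency.

    ``table`` columns: genotype, condition, loop_id, bio_rep, tech_rep,
    ct_target, ct_norm. Reactions missing the normalization Ct are dropped
    with a warning. Returns (summary, per-biological-replicate values).
    """
    df = table.copy()
    missing = df["ct_norm"].isna() | df["ct_target"].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} reactions without paired Ct values")
        df = df[~missing]
    df["rif_raw"] = efficiency ** (-(df["ct_target"] - df["ct_norm"]))
    bio = (
        df.groupby(["genotype", "condition", "loop_id", "bio_rep"])["rif_raw"]
        .mean()
        .reset_index(name="rif")
    )
    ref_g, ref_c = reference
    ref = bio[(bio["genotype"] == ref_g) & (bio["condition"] == ref_c)]
    if ref.empty:
        raise ValueError(f"reference group {reference} absent from the table")
    ref_mean = ref.groupby("loop_id")["rif"].mean()
    bio["rif"] = bio.apply(lambda r: r["rif"] / ref_mean[r["loop_id"]], axis=1)
    summary = (
        bio.groupby(["genotype", "condition", "loop_id"])["rif"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    return summary, bio


def luciferase_activity(table: pd.DataFrame, control: str = "mini35S") -> pd.DataFrame:
    """Per-construct LUC/REN activity normalized to the control construct mean.

    ``table`` columns: construct, replicate, LUC, REN (REN > 0).
    """
    df = table.copy()
    if (df["REN"] <= 0).any():
        raise ValueError("REN must be positive")
    if control not in set(df["construct"]):
        raise ValueError(f"control construct {control!r} missing")
    df["ratio"] = df["LUC"] / df["REN"]
    ctrl_mean = df.loc[df["construct"] == control, "ratio"].mean()
    out = (
        df.groupby("construct")["ratio"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    out["normalized_mean"] = out["mean"] / ctrl_mean
    out["normalized_sd"] = out["sd"] / ctrl_mean
    return out


def two_sample_t(a, b, sides: str = "two", welch: bool = False) -> TTestResult:
    """Student's pooled-variance two-sample t-test (Welch behind a flag).

    Zero pooled variance: equal means give (t=0, p=1); unequal means are
    flagged with p at the smallest positive float.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if sides not in {"one", "two"}:
        raise ValueError("sides must be 'one' or 'two'")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        dof = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)) if se2 > 0 else na + nb - 2
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        dof = na + nb - 2
    if se2 == 0:
        if ma == mb:
            return TTestResult(t=0.0, df=float(dof), p=1.0)
        return TTestResult(t=np.inf if ma > mb else -np.inf, df=float(dof),
                           p=np.finfo(float).tiny, underflow=True)
    t = (ma - mb) / np.sqrt(se2)
    if sides == "two":
        p = 2.0 * stats.t.sf(abs(t), dof)
    else:
        p = stats.t.sf(abs(t), dof)
    return TTestResult(t=float(t), df=float(dof), p=float(p))
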