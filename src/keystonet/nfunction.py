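"""Nitrogen-function calculators: PNA slopes, 1-octyne partition, NUE,
fold changes and abundance ratios.

Potential nitrification activity (PNA) is the OLS slope of nitrite
accumulation in a shaken soil slurry.  1-octyne selectively inhibits
bacterial ammonia oxidation, so the slope measured with octyne is
attributed to AOA and the difference (without minus with) to AOB.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PnaAssay",
    "PnaFit",
    "PnaResult",
    "pna_slope",
    "partition_pna",
    "partition_assays",
    "nue",
    "fold_change",
    "abundance_ratio",
    "group_mean_se",
    "read_pna_table",
]

DEFAULT_TIMES_H = (0.0, 8.0, 24.0, 30.0, 48.0, 60.0, 72.0)


@dataclasses.dataclass(frozen=True)
class PnaAssay:
    """A nitrite accumulation time series from one slurry incubation.

    ``times`` in hours (strictly increasing, >= 3 points), ``no2_n`` in
    ug NO2^--N g^-1 dry soil, ``octyne`` flags the 1-octyne treatment.
    """

    sample_id: str
    times: tuple
    no2_n: tuple
    octyne: bool

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.no2_n, dtype=float)
        if len(t) != len(c):
            raise ValueError("times and concentrations must have equal length")
        if len(t) < 3:
            raise ValueError("a PNA assay needs at least 3 time points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")


@dataclasses.dataclass(frozen=True)
class PnaFit:
    """OLS fit of an assay: rate in ug NO2^--N g^-1 h^-1 plus diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    negative_slope: bool


def pna_slope(assay: PnaAssay) -> PnaFit:
    """Ordinary least-squares slope of NO2^--N versus time over all points.

    Negative slopes are returned as-is with the ``negative_slope`` flag set.
    """
    t = np.asarray(assay.times, dtype=float)
    c = np.asarray(assay.no2_n, dtype=float)
    fit = stats.linregress(t, c)
    resid = c - (fit.intercept + fit.slope * t)
    dof = max(len(t) - 2, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))
    ss_tot = float(((c - c.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return PnaFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        residual_sd=residual_sd,
        negative_slope=bool(fit.slope < 0),
    )


@dataclasses.dataclass(frozen=True)
class PnaResult:
    """Guild-partitioned activities; ``pna_total`` is defined as the sum
    ``pna_aoa + pna_aob`` so the additivity identity is exact."""

    pna_aoa: float
    pna_aob: float
    pna_total: float
    negative_aob: bool


def partition_pna(slope_no_octyne: float, slope_octyne: float) -> PnaResult:
    """Attribute the octyne-resistant slope to AOA and the difference to AOB.

    A negative AOB activity (octyne slope above the uninhibited slope) is
    reported as-is with the ``negative_aob`` flag.
    """
    pna_aoa = float(slope_octyne)
    pna_aob = float(slope_no_octyne) - float(slope_octyne)
    return PnaResult(
        pna_aoa=pna_aoa,
        pna_aob=pna_aob,
        pna_total=pna_aoa + pna_aob,
        negative_aob=bool(pna_aob < 0),
    )


def partition_assays(assay_no_octyne: PnaAssay, assay_octyne: PnaAssay) -> PnaResult:
    if assay_no_octyne.octyne or not assay_octyne.octyne:
        raise ValueError("expected (octyne-free, octyne) assays in that order")
    return partition_pna(
        pna_slope(assay_no_octyne).slope, pna_slope(assay_octyne).slope
    )


def nue(uptake_fertilized: float, uptake_unfertilized: float, n_rate: float) -> float:
    """N use efficiency: 100 x (uptake_N - uptake_0) / N application rate."""
    if n_rate <= 0:
        raise ValueError("the N application rate must be positive")
    return 100.0 * (uptake_fertilized - uptake_unfertilized) / n_rate


def fold_change(mean_treatment: float, mean_reference: float) -> float:
    """Ratio of a treatment mean to a (positive) reference mean."""
    if mean_reference <= 0:
        raise ValueError("the reference mean must be positive")
    return mean_treatment / mean_reference


def abundance_ratio(aoa_copies, aob_copies):
    """Per-replicate AOA/AOB *amoA* copy-number ratio.

    Scalars give a scalar; replicate vectors give per-replicate ratios (the
    group mean of ratios generally differs from the ratio of group means,
    which is why summaries average per-replicate ratios).
    """
    aoa = np.asarray(aoa_copies, dtype=float)
    aob = np.asarray(aob_copies, dtype=float)
    if np.any(aob <= 0):
        raise ValueError("AOB copy numbers must be positive")
    ratio = aoa / aob
    return float(ratio) if ratio.ndim == 0 else ratio


def group_mean_se(values) -> tuple[float, float]:
    """Mean and standard error of the mean over replicates (SE uses n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one replicate")
    se = 0.0 if v.size == 1 else float(v.std(ddof=1) / np.sqrt(v.size))
    return float(v.mean()), se


def read_pna_table(path: str | Path) -> list[PnaAssay]:
    """Read assays from a long TSV with columns sample, octyne, time_h,
    no2_ug_g; one assay per (sample, octyne) series."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "octyne", "time_h", "no2_ug_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PNA table missing columns: {sorted(missing)}")
    assays = []
    for (sample, octyne), grp in df.groupby(["sample", "octyne"], sort=True):
        grp = grp.sort_values("time_h")
        assays.append(
            PnaAssay(
                sample_id=str(sample),
                times=tuple(grp["time_h"].astype(float)),
                no2_n=tuple(grp["no2_ug_g"].astype(float)),
                octyne=bool(octyne),
            )
        )
    return assays
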