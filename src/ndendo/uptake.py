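"""Plate-reader quantification of anchored vs internalized nanoparticles.

Cells incubated with fluorescent nanodiamonds at 4 C only anchor
particles to the plasma membrane (energy-dependent internalization is
suppressed); at 37 C particles both anchor and internalize.  The
internalized amount at each time point is therefore estimated by
subtraction of condition means over replicate wells:

    anchored     = mean intensity at 4 C
    total        = mean intensity at 37 C
    internalized = total - anchored

after normalizing raw intensities by each particle type's
photoluminescence calibration slope (emission intensity per ug/mL), so
the two types are comparable per unit mass.  Wells at 4 C and 37 C come
from separate plates, so the subtraction is unpaired and uncertainties
combine in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COND_COLD = "4C"
COND_WARM = "37C"

ASSAY_COLUMNS = ["nd_type", "condition", "time_hr", "replicate", "intensity"]


@dataclass(frozen=True)
class CalibrationSeries:
    """Fluorescence vs concentration series for one particle type."""

    nd_type: str
    concentrations: np.ndarray  # ug/mL
    intensities: np.ndarray     # arbitrary units at the emission peak

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if c.shape != i.shape or c.ndim != 1:
            raise ValueError("concentrations and intensities must be equal-length 1-D")
        if len(np.unique(c)) < 2:
            raise ValueError("need at least two distinct concentrations")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "intensities", i)


def calibration_slope(series: CalibrationSeries, blank_subtract: bool = True) -> float:
    """Ordinary least-squares slope of intensity vs concentration.

    When ``blank_subtract`` is set and a 0 ug/mL point exists, its mean
    intensity is subtracted as the blank first (this shifts the
    intercept only; the slope is unchanged).
    """
    c = series.concentrations
    y = series.intensities.astype(float)
    if blank_subtract and np.any(c == 0):
        y = y - y[c == 0].mean()
    return float(stats.linregress(c, y).slope)


def validate_assay(assay: pd.DataFrame) -> pd.DataFrame:
    missing = [col for col in ASSAY_COLUMNS if col not in assay.columns]
    if missing:
        raise ValueError(f"assay table missing columns: {missing}")
    if (assay["intensity"] < 0).any():
        raise ValueError("intensities must be non-negative")
    bad = assay["condition"].isin([COND_COLD, COND_WARM])
    if not bad.all():
        raise ValueError(f"unknown conditions: {sorted(assay.loc[~bad, 'condition'].unique())}")
    sizes = assay.groupby(["nd_type", "condition", "time_hr"], sort=False).size()
    if (sizes < 2).any():
        raise ValueError("each (nd_type, condition, time_hr) cell needs >= 2 replicates")
    return assay


def normalize(assay: pd.DataFrame, slopes: dict[str, float],
              blanks: dict[str, float] | None = None) -> pd.DataFrame:
    """Divide raw intensities by the per-type calibration slope.

    ``blanks`` (same keys) are subtracted before division; negative
    blank-corrected intensities are clipped to zero.
    """
    validate_assay(assay)
    types = set(assay["nd_type"].unique())
    missing = types - set(slopes)
    if missing:
        raise ValueError(f"no calibration slope for nd_type(s): {sorted(missing)}")
    for t in types:
        if slopes[t] <= 0:
            raise ValueError(f"slope for {t!r} must be positive")
    out = assay.copy()
    blank = out["nd_type"].map(blanks).astype(float) if blanks else 0.0
    slope = out["nd_type"].map(slopes).astype(float)
    out["intensity"] = np.clip(out["intensity"] - blank, 0.0, None) / slope
    return out


def quantify(assay: pd.DataFrame) -> pd.DataFrame:
    """Anchored / total / internalized amounts per (nd_type, time point).

    Returns a tidy frame with one row per (nd_type, time_hr) and columns
    ``anchored_mean/sd``, ``total_mean/sd``, ``internalized_mean/sd``
    (sd of the subtraction by quadrature over the unpaired condition
    means), replicate counts, and a ``negative_internalized`` QC flag.
    A negative internalized estimate is reported, not clipped.
    """
    validate_assay(assay)
    g = (
        assay.groupby(["nd_type", "time_hr", "condition"])["intensity"]
        .agg(["mean", "std", "count"])
        .unstack("condition")
    )
    for cond in (COND_COLD, COND_WARM):
        if cond not in g["mean"].columns or g["mean"][cond].isna().any():
            missing = (
                g.index.tolist() if cond not in g["mean"].columns
                else g.index[g["mean"][cond].isna()].tolist()
            )
            raise ValueError(f"condition {cond} missing at {missing}")
    out = pd.DataFrame({
        "anchored_mean": g["mean"][COND_COLD],
        "anchored_sd": g["std"][COND_COLD],
        "total_mean": g["mean"][COND_WARM],
        "total_sd": g["std"][COND_WARM],
        "n_4c": g["count"][COND_COLD].astype(int),
        "n_37c": g["count"][COND_WARM].astype(int),
    })
    out["internalized_mean"] = out["total_mean"] - out["anchored_mean"]
    out["internalized_sd"] = np.sqrt(out["total_sd"] ** 2 + out["anchored_sd"] ** 2)
    out["negative_internalized"] = out["internalized_mean"] < 0
    return out.reset_index()


def uptake_ratio(
    result: pd.DataFrame,
    quantity: str,
    numerator_type: str,
    denominator_type: str,
    time_hr: float,
) -> tuple[float, float]:
    """Cross-type ratio of a quantified mean, with propagated uncertainty.

    ``quantity`` is one of ``anchored``, ``total``, ``internalized``.
    The standard deviation uses first-order propagation
    ``|r| * sqrt((s_num/m_num)^2 + (s_den/m_den)^2)``.
    """
    if quantity not in ("anchored", "total", "internalized"):
        raise ValueError(f"unknown quantity {quantity!r}")

    def _row(nd_type):
        sel = result[(result["nd_type"] == nd_type)
                     & np.isclose(result["time_hr"], time_hr)]
        if len(sel) != 1:
            raise ValueError(f"no unique row for {nd_type!r} at t={time_hr}")
        return sel.iloc[0]

    num, den = _row(numerator_type), _row(denominator_type)
    m_n, s_n = num[f"{quantity}_mean"], num[f"{quantity}_sd"]
    m_d, s_d = den[f"{quantity}_mean"], den[f"{quantity}_sd"]
    if m_d == 0:
        raise ZeroDivisionError("denominator mean is zero")
    r = m_n / m_d
    sd = abs(r) * np.sqrt((s_n / m_n) ** 2 + (s_d / m_d) ** 2)
    return float(r), float(sd)


def two_sample_p(group_a, group_b, variant: str = "pooled") -> float:
    """Two-sided two-sample t-test p-value from raw replicate values.

    ``pooled`` uses the equal-variance Student test
    (df = n_a + n_b - 2); ``welch`` the unequal-variance form.  If both
    groups have zero variance, equal means give p = 1 and different
    means raise (the statistic is undefined).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=_equal_var(variant))
    return float(res.pvalue)


def two_sample_p_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "pooled",
) -> float:
    """Two-sided two-sample t-test p-value from (mean, sd, n) summaries."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            return 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=_equal_var(variant)
    )
    return float(res.pvalue)


def _equal_var(variant: str) -> bool:
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    return variant == "pooled"


def compare_types(
    assay: pd.DataFrame,
    condition: str,
    type_a: str,
    type_b: str,
    variant: str = "pooled",
) -> pd.DataFrame:
    """Per-time-point cross-type t-tests on replicate wells of one condition."""
    validate_assay(assay)
    sub = assay[assay["condition"] == condition]
    rows = []
    for t, grp in sub.groupby("time_hr"):
        a = grp.loc[grp["nd_type"] == type_a, "intensity"].to_numpy()
        b = grp.loc[grp["nd_type"] == type_b, "intensity"].to_numpy()
        rows.append({"time_hr": t, "p_value": two_sample_p(a, b, variant)})
    return pd.DataFrame(rows)
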