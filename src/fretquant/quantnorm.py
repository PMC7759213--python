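"""Reporter and expression normalization.

Covers the quantitative bookkeeping around the FRET assays:

* rainbow-bead calibration of arbitrary fluorescence units to molecules
  of equivalent fluorophore (MEFL/MEPTR): bead subpopulations are found by
  1-D k-means on log intensity, and MFI is regressed on the
  manufacturer-supplied reference values through the origin, so the slope
  is the a.u.-per-molecule conversion factor;
* reporter summaries: replicate-averaged MFI, autofluorescence
  subtraction, MEFL conversion and ligand/vehicle fold differences with
  propagated standard error;
* dual-luciferase normalization: technical-replicate means, autoluminescence
  subtraction, firefly/renilla ratios, and linear scaling anchored so the
  reporter-only condition means exactly 1;
* western-blot expression normalization: per-exposure percent-of-total
  band intensities (which cancel exposure gain), exposure averaging with
  flagged bands excluded, receptor/loading-control ratios relative to an
  internal control lane, and suggested plasmid-dose scaling factors;
* the ordinary least-squares regression of NFRET fold difference on
  ectodomain C-terminal distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import FoldDifference, fold_difference

__all__ = [
    "BeadCalibration",
    "ReporterMeasurement",
    "RegressionResult",
    "identify_bead_subpops",
    "fit_bead_slope",
    "reporter_summary",
    "luciferase_normalize",
    "western_normalize",
    "distance_regression",
]


@dataclass(frozen=True)
class BeadCalibration:
    """Origin-constrained MFI-vs-reference calibration line."""

    subpop_mfis: tuple[float, ...]
    reference_values: tuple[float, ...]
    slope: float          # a.u. per reference molecule
    slope_se: float

    def to_calibrated(self, mfi, background: float = 0.0):
        """Convert background-subtracted MFI to reference units (MEFL)."""
        return (np.asarray(mfi, dtype=float) - background) / self.slope


@dataclass(frozen=True)
class ReporterMeasurement:
    """One treatment arm's calibrated reporter expression."""

    mfi: float
    autofluorescence: float
    mefl: float
    se: float
    treatment: str
    n_replicates: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def identify_bead_subpops(bead_events, k: int) -> np.ndarray:
    """Per-subpopulation mean MFIs via 1-D k-means on log intensity.

    Initialization places the k centers at evenly spaced quantiles of the
    log-intensity distribution (sorted), which makes the clustering
    deterministic and robust for well-separated bead peaks. Returns the
    arithmetic mean raw MFI of each cluster, sorted ascending.
    """
    if isinstance(bead_events, pd.DataFrame):
        values = bead_events["MFI"].to_numpy(dtype=float)
    else:
        values = np.asarray(bead_events, dtype=float)
    values = values[values > 0]
    if values.size < 10 * k:
        raise ValueError(f"need at least {10 * k} positive events for k={k} subpopulations")
    log = np.log(values)
    if k == 1:
        return np.array([values.mean()])
    from sklearn.cluster import KMeans

    quantiles = (2 * np.arange(k) + 1) / (2 * k)
    init = np.quantile(log, quantiles).reshape(-1, 1)
    km = KMeans(n_clusters=k, init=init, n_init=1).fit(log.reshape(-1, 1))
    labels = km.labels_
    means = []
    for lab in range(k):
        members = values[labels == lab]
        if members.size == 0:
            raise ValueError(f"found fewer than k={k} bead subpopulations")
        means.append(members.mean())
    return np.sort(np.array(means))


def fit_bead_slope(subpop_mfis, reference_values) -> BeadCalibration:
    """Regression of MFI on reference value constrained through the origin.

    slope = sum(x*y) / sum(x^2) with x the manufacturer reference values
    and y the measured subpopulation MFIs (zero MFI corresponds to zero
    molecules by construction). The slope SE comes from the regression
    residuals.
    """
    y = np.asarray(subpop_mfis, dtype=float)
    x = np.asarray(reference_values, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("subpop MFIs and reference values must be matched 1-D lists")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("reference values are all zero; slope undefined")
    slope = float(np.sum(x * y) / sxx)
    if x.size > 1:
        resid = y - slope * x
        slope_se = float(np.sqrt(np.sum(resid**2) / (x.size - 1) / sxx))
    else:
        slope_se = 0.0
    return BeadCalibration(tuple(y), tuple(x), slope, slope_se)


def _mean_sem(values) -> tuple[float, float, int]:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty replicate list")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), sem, v.size


def reporter_summary(
    arm_mfis: dict[str, "list[float]"],
    autofluorescence_mfis,
    calibration: BeadCalibration,
    ligand_arm: str = "ligand",
    vehicle_arm: str = "vehicle",
) -> tuple[dict[str, ReporterMeasurement], FoldDifference]:
    """Calibrated reporter expression per arm plus the fold difference.

    Per arm: average MFI across biological replicates, subtract the mean
    of the autofluorescence control, convert to reference units with the
    bead calibration slope, and propagate the SEs of every step
    (replicates, autofluorescence and calibration slope) to first order.
    """
    af_mean, af_sem, _ = _mean_sem(autofluorescence_mfis)
    measurements: dict[str, ReporterMeasurement] = {}
    for arm, reps in arm_mfis.items():
        mfi, sem, n = _mean_sem(reps)
        net = mfi - af_mean
        net_se = float(np.hypot(sem, af_sem))
        mefl = net / calibration.slope
        if net != 0 and calibration.slope_se:
            se = abs(mefl) * np.sqrt(
                (net_se / net) ** 2 + (calibration.slope_se / calibration.slope) ** 2
            )
        else:
            se = net_se / calibration.slope
        measurements[arm] = ReporterMeasurement(
            mfi=mfi, autofluorescence=af_mean, mefl=float(mefl), se=float(se),
            treatment=arm, n_replicates=n,
        )
    lig, veh = measurements[ligand_arm], measurements[vehicle_arm]
    fold = fold_difference(lig.mefl, lig.se, veh.mefl, veh.se)
    return measurements, fold


def luciferase_normalize(
    plate: pd.DataFrame,
    vector_condition: str = "vector_only",
    reporter_condition: str = "reporter_only",
) -> pd.DataFrame:
    """Dual-luciferase normalization of a plate of wells.

    Expects one row per well with a ``condition`` column and technical
    replicate columns ``firefly_1..n`` and ``renilla_1..n``. Per well, the
    technical replicates are averaged per readout; the autoluminescence
    signal (mean of the vector-only wells, per readout) is subtracted;
    firefly is divided by renilla; and every quotient is scaled so the
    mean quotient of the reporter-only condition equals exactly 1 a.u.
    Wells whose background-subtracted renilla signal is nonpositive are
    flagged invalid. Standard error is propagated through each step.
    """
    ff_cols = sorted(c for c in plate.columns if c.startswith("firefly_"))
    rn_cols = sorted(c for c in plate.columns if c.startswith("renilla_"))
    if not ff_cols or not rn_cols:
        raise ValueError("plate needs firefly_* and renilla_* technical replicate columns")
    for cond, what in ((vector_condition, "vector-only"), (reporter_condition, "reporter-only")):
        if not (plate["condition"] == cond).any():
            raise ValueError(f"plate has no {what} wells (condition {cond!r})")

    out = plate[["condition"]].copy()
    for name, cols in (("firefly", ff_cols), ("renilla", rn_cols)):
        vals = plate[cols].to_numpy(dtype=float)
        out[f"{name}_mean"] = vals.mean(axis=1)
        if vals.shape[1] > 1:
            out[f"{name}_se"] = vals.std(axis=1, ddof=1) / np.sqrt(vals.shape[1])
        else:
            out[f"{name}_se"] = 0.0

    vec = out["condition"] == vector_condition
    for name in ("firefly", "renilla"):
        bg, bg_se, _ = _mean_sem(out.loc[vec, f"{name}_mean"])
        out[f"{name}_net"] = out[f"{name}_mean"] - bg
        out[f"{name}_net_se"] = np.hypot(out[f"{name}_se"], bg_se)

    out["valid"] = out["renilla_net"] > 0
    ratio = np.where(out["valid"], out["firefly_net"] / out["renilla_net"], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_ff = np.where(out["firefly_net"] != 0, out["firefly_net_se"] / out["firefly_net"], 0.0)
        ratio_se = np.abs(ratio) * np.sqrt(
            rel_ff**2 + (out["renilla_net_se"] / out["renilla_net"]) ** 2
        )
        # a zero-firefly well has zero ratio but nonzero absolute uncertainty
        ratio_se = np.where(
            (out["firefly_net"] == 0) & out["valid"],
            out["firefly_net_se"] / out["renilla_net"],
            ratio_se,
        )
    out["ratio"] = ratio
    out["ratio_se"] = ratio_se

    anchor_wells = (out["condition"] == reporter_condition) & out["valid"]
    if not anchor_wells.any():
        raise ValueError("no valid reporter-only wells to anchor the scaling")
    anchor, anchor_sem, _ = _mean_sem(out.loc[anchor_wells, "ratio"])
    if anchor == 0:
        raise ValueError("reporter-only mean ratio is zero; scaling undefined")
    out["normalized"] = out["ratio"] / anchor
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_ratio = np.where(out["ratio"] != 0, out["ratio_se"] / out["ratio"], 0.0)
        out["normalized_se"] = np.abs(out["normalized"]) * np.sqrt(
            rel_ratio**2 + (anchor_sem / anchor) ** 2
        )
    return out


def western_normalize(band_table: pd.DataFrame, control_lane: str) -> pd.DataFrame:
    """Relative receptor expression per lane from multi-exposure band data.

    Expects one row per (exposure, lane) with columns ``mesa_intensity``,
    ``nanoluc_intensity`` and boolean flags ``mesa_excluded`` /
    ``nanoluc_excluded`` marking non-detectable or saturated bands. Per
    exposure, each usable band is expressed as percent of the total signal
    of its kind on the blot (this cancels any gain difference between
    exposures); percents are averaged across exposures per lane; the
    receptor/loading-control ratio is then divided by the internal control
    lane's ratio. Also reports the suggested plasmid-dose scaling factor
    ``1 / relative_expression``.
    """
    required = {"exposure", "lane", "mesa_intensity", "nanoluc_intensity"}
    if not required <= set(band_table.columns):
        raise ValueError(f"band table must contain columns {sorted(required)}")
    table = band_table.copy()
    for flag in ("mesa_excluded", "nanoluc_excluded"):
        if flag not in table.columns:
            table[flag] = False

    pct = {}
    for kind in ("mesa", "nanoluc"):
        usable = ~table[f"{kind}_excluded"].astype(bool)
        intensity = table[f"{kind}_intensity"].where(usable)
        totals = intensity.groupby(table["exposure"]).transform("sum")
        pct[kind] = 100.0 * intensity / totals

    frames = pd.DataFrame(
        {"lane": table["lane"], "mesa_pct": pct["mesa"], "nanoluc_pct": pct["nanoluc"]}
    )
    per_lane = frames.groupby("lane", sort=False).mean()  # NaN (excluded) skipped
    if per_lane[["mesa_pct", "nanoluc_pct"]].isna().any(axis=None):
        bad = per_lane.index[per_lane.isna().any(axis=1)].tolist()
        raise ValueError(f"lanes with no usable exposure: {bad}")
    per_lane["ratio"] = per_lane["mesa_pct"] / per_lane["nanoluc_pct"]
    if control_lane not in per_lane.index:
        raise ValueError(f"internal control lane {control_lane!r} not in table")
    control_ratio = per_lane.loc[control_lane, "ratio"]
    if not np.isfinite(control_ratio) or control_ratio <= 0:
        raise ValueError("internal control lane is unusable (nonpositive ratio)")
    per_lane["relative_expression"] = per_lane["ratio"] / control_ratio
    per_lane["suggested_dose_factor"] = 1.0 / per_lane["relative_expression"]
    return per_lane.reset_index()


def distance_regression(points) -> RegressionResult:
    """OLS of NFRET fold difference on ectodomain C-terminal distance (Å).

    ``points`` is a sequence of (distance, fold_difference) pairs. Returns
    the slope (per Å), intercept, R² and the two-tailed p-value of the
    slope under the t distribution.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (distance, fold difference) pairs")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 points for the distance regression")
    x, y = arr[:, 0], arr[:, 1]
    if np.all(x == x[0]):
        raise ValueError("all distances identical; regression undefined")
    if np.all(y == y[0]):
        # horizontal data: zero slope explains nothing, R^2 defined as 0
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, int(arr.shape[0]))
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(arr.shape[0]),
    )
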