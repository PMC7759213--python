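"""Flow-cytometric FRET quantification.

Implements the per-cell analysis chain for sensitized-emission FRET
measured on a cytometer with three FRET-relevant channels (donor =
Pacific Blue, acceptor = FITC, FRET = AmCyan) plus a transfection marker
(APC):

1. spillover estimation from single-fluorophore controls and linear
   compensation (unmixing);
2. hierarchical gating: cells (FSC-A/SSC-A density) -> singlets
   (FSC-A/FSC-H ratio band) -> transfected -> donor+/acceptor+ double
   positives, with positivity thresholds set so that no more than a
   stated fraction of the matching negative control would be included;
3. the expression-normalized FRET statistic per cell,

       NFRET = Comp AmCyan / sqrt(Comp Pacific Blue * Comp FITC),

   which is invariant to scaling all three channels of a cell;
4. calibration of NFRET between a no-interaction negative control (maps
   to 0) and a covalent-fusion positive control (maps to 1);
5. sample summaries and ligand/vehicle fold differences with
   delta-method standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import FoldDifference, fold_difference
from .synthdata import FLUOR_CHANNELS, PRIMARY_CHANNEL, SOURCES

__all__ = [
    "ROLE_CHANNELS",
    "SpilloverModel",
    "ArmSummary",
    "NFRETSummary",
    "estimate_spillover",
    "compensate",
    "gate_cells",
    "gate_singlets",
    "gate_cells_singlets",
    "positivity_threshold",
    "gate_positive",
    "nfret_per_cell",
    "calibrate_nfret",
    "summarize_sample",
    "flow_fret_pipeline",
    "calibrated_sample_nfret",
]

#: Channel roles on the instrument (donor/acceptor/fret/marker).
ROLE_CHANNELS = {
    "donor": "Pacific Blue",
    "acceptor": "FITC",
    "fret": "AmCyan",
    "marker": "APC",
}

COMP_PREFIX = "Comp "


@dataclass
class SpilloverModel:
    """Square source -> channel spillover matrix (diagonal = 1).

    ``matrix[i, j]`` is the fraction of source ``i`` (identified by its
    primary channel ``channels[i]``) detected in channel ``channels[j]``.
    """

    channels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.channels)
        if self.matrix.shape != (k, k):
            raise ValueError("spillover matrix must be square over the channels")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("spillover matrix diagonal must be 1")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.channels, columns=self.channels)

    @classmethod
    def identity(cls, channels=FLUOR_CHANNELS) -> "SpilloverModel":
        return cls(tuple(channels), np.eye(len(channels)))

    @classmethod
    def from_bleedthrough(cls, a: float, b: float, c: float, d: float) -> "SpilloverModel":
        """Model over the three FRET channels from image-style fractions.

        Donor bleeds ``c`` into FITC and ``d`` into AmCyan; acceptor bleeds
        ``b`` into Pacific Blue and ``a`` into AmCyan; sensitized emission
        appears only in AmCyan.
        """
        channels = ("Pacific Blue", "FITC", "AmCyan")
        m = np.array([[1.0, c, d], [b, 1.0, a], [0.0, 0.0, 1.0]])
        return cls(channels, m)


def _channel_values(events: pd.DataFrame, channel: str) -> np.ndarray:
    if channel not in events.columns:
        raise KeyError(f"channel {channel!r} not present in event table")
    return events[channel].to_numpy(dtype=float)


def estimate_spillover(
    controls: dict[str, pd.DataFrame],
    vector_only: pd.DataFrame | None = None,
    channels=FLUOR_CHANNELS,
    max_false_rate: float = 0.01,
    min_positive: int = 100,
) -> SpilloverModel:
    """Spillover matrix from single-fluorophore controls.

    ``controls`` maps source names (``"donor"``, ``"acceptor"``, optionally
    ``"marker"``) to their single-fluorophore event tables. For each
    control, events positive in the source's primary channel (above the
    positivity threshold derived from ``vector_only``) are
    autofluorescence-subtracted, and the coefficient into every other
    channel is the origin-constrained least-squares slope of that channel
    against the primary channel. Sources without a control (sensitized
    emission has none by construction; it is defined as signal appearing
    in the FRET channel) keep an identity row.
    """
    channels = tuple(ch for ch in channels)
    idx = {ch: j for j, ch in enumerate(channels)}
    matrix = np.eye(len(channels))

    if vector_only is not None:
        autofl = {ch: float(np.mean(_channel_values(vector_only, ch))) for ch in channels}
    else:
        autofl = {ch: 0.0 for ch in channels}

    for source in ("donor", "acceptor", "marker"):
        primary = PRIMARY_CHANNEL[source]
        if primary not in idx:
            continue
        if source not in controls:
            if source == "marker":
                continue
            raise ValueError(f"missing single-fluorophore control for {source!r}")
        table = controls[source]
        if vector_only is not None:
            thr = positivity_threshold(vector_only, primary, max_false_rate)
        else:
            thr = 0.0
        x = _channel_values(table, primary)
        pos = x > max(thr, autofl[primary])
        if pos.sum() < min_positive:
            raise ValueError(
                f"control for {source!r} has only {int(pos.sum())} positive events "
                f"(need >= {min_positive})"
            )
        xs = x[pos] - autofl[primary]
        denom = float(np.sum(xs * xs))
        for ch in channels:
            if ch == primary:
                continue
            ys = _channel_values(table, ch)[pos] - autofl[ch]
            matrix[idx[primary], idx[ch]] = float(np.sum(xs * ys) / denom)
    return SpilloverModel(channels, matrix)


def compensate(events: pd.DataFrame, model: SpilloverModel) -> pd.DataFrame:
    """Linearly unmix the raw channels with the inverse spillover matrix.

    Adds parallel ``Comp <channel>`` columns; negative compensated values
    are preserved (they are legitimate noise around zero, and discarding
    them would bias population means upward).
    """
    raw = np.column_stack([_channel_values(events, ch) for ch in model.channels])
    try:
        inv = np.linalg.inv(model.matrix)
    except np.linalg.LinAlgError as exc:
        raise ValueError("spillover matrix is singular; cannot compensate") from exc
    comp = raw @ inv
    out = events.copy()
    for j, ch in enumerate(model.channels):
        out[COMP_PREFIX + ch] = comp[:, j]
    out.attrs = dict(events.attrs)
    out.attrs["compensated"] = True
    return out


def gate_cells(
    events: pd.DataFrame, keep_fraction: float = 0.75, bins: int = 64
) -> pd.DataFrame:
    """Density gate in (FSC-A, SSC-A): retain the densest scatter region.

    Events are binned on a 2-D histogram and ranked by the density of
    their bin; the densest ``keep_fraction`` of events is kept. This
    stands in for the manual cell gate drawn around the intact-cell cloud.
    """
    if events.empty:
        warnings.warn("cell gate applied to an empty event table", stacklevel=2)
        return events
    x = _channel_values(events, "FSC-A")
    y = _channel_values(events, "SSC-A")
    hist, xe, ye = np.histogram2d(x, y, bins=bins)
    ix = np.clip(np.searchsorted(xe, x, side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ye, y, side="right") - 1, 0, bins - 1)
    density = hist[ix, iy]
    cutoff = np.quantile(density, 1.0 - keep_fraction)
    out = events.loc[density >= cutoff]
    out.attrs = dict(events.attrs)
    return out


def gate_singlets(events: pd.DataFrame, tolerance: float = 0.15) -> pd.DataFrame:
    """Singlet gate: FSC-A/FSC-H ratio within ``tolerance`` of the median.

    Doublets carry roughly twice the forward-scatter area of a singlet at
    single-cell height, so their ratio falls far outside the band.
    """
    if events.empty:
        warnings.warn("singlet gate applied to an empty event table", stacklevel=2)
        return events
    ratio = _channel_values(events, "FSC-A") / _channel_values(events, "FSC-H")
    med = np.median(ratio)
    keep = np.abs(ratio / med - 1.0) <= tolerance
    out = events.loc[keep]
    out.attrs = dict(events.attrs)
    return out


def gate_cells_singlets(
    events: pd.DataFrame,
    keep_fraction: float = 0.75,
    tolerance: float = 0.15,
    bins: int = 64,
) -> pd.DataFrame:
    """Cell gate followed by singlet gate (the fixed gating order)."""
    return gate_singlets(gate_cells(events, keep_fraction, bins), tolerance)


def positivity_threshold(
    negative_control: pd.DataFrame, channel: str, max_false_rate: float = 0.01
) -> float:
    """Channel threshold admitting at most ``max_false_rate`` of the control.

    Returns the linearly interpolated ``1 - max_false_rate`` quantile of
    the channel in the negative control; gating strictly above it
    re-includes at most ``max_false_rate`` of the control events.
    """
    if not 0 < max_false_rate < 1:
        raise ValueError("max_false_rate must lie strictly between 0 and 1")
    values = _channel_values(negative_control, channel)
    if values.size == 0:
        raise ValueError("negative control is empty")
    return float(np.quantile(values, 1.0 - max_false_rate))


def gate_positive(events: pd.DataFrame, channel: str, threshold: float) -> pd.DataFrame:
    """Retain events strictly above the threshold in the given channel."""
    out = events.loc[_channel_values(events, channel) > threshold]
    out.attrs = dict(events.attrs)
    return out


def nfret_per_cell(events: pd.DataFrame, roles: dict[str, str] = ROLE_CHANNELS) -> pd.Series:
    """Per-cell NFRET = comp FRET / sqrt(comp donor * comp acceptor).

    Requires a compensated table. Cells whose donor x acceptor product is
    nonpositive have no defined NFRET and are returned as NaN (and must be
    excluded from summaries).
    """
    comp_cols = [COMP_PREFIX + roles[r] for r in ("donor", "acceptor", "fret")]
    if not events.attrs.get("compensated", False) and not all(
        c in events.columns for c in comp_cols
    ):
        raise ValueError("event table is not compensated; run compensate() first")
    donor = _channel_values(events, comp_cols[0])
    acceptor = _channel_values(events, comp_cols[1])
    fret = _channel_values(events, comp_cols[2])
    prod = donor * acceptor
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(prod > 0, fret / np.sqrt(prod), np.nan)
    return pd.Series(values, index=events.index, name="NFRET")


def calibrate_nfret(values, negative_mean: float, positive_mean: float):
    """Scale NFRET linearly so the control means map to 0 and 1."""
    span = positive_mean - negative_mean
    if span == 0:
        raise ValueError("control means are equal; calibration undefined")
    return (np.asarray(values, dtype=float) - negative_mean) / span


@dataclass(frozen=True)
class ArmSummary:
    """Mean NFRET of one treatment arm across biological replicates."""

    mean_nfret: float
    sem: float
    n_cells: int
    n_replicates: int


@dataclass(frozen=True)
class NFRETSummary:
    """Paired-arm NFRET summary with the ligand/vehicle fold difference."""

    ligand: ArmSummary
    vehicle: ArmSummary
    fold_difference: FoldDifference
    calibrated: bool = False
    method: str = "replicate-mean-first"


def _arm_summary(replicates, method: str) -> ArmSummary:
    reps = [np.asarray(r, dtype=float) for r in replicates]
    reps = [r[np.isfinite(r)] for r in reps]
    if not reps or any(r.size == 0 for r in reps):
        raise ValueError("each replicate must contain at least one defined NFRET value")
    n_cells = int(sum(r.size for r in reps))
    if method == "replicate-mean-first":
        means = np.array([r.mean() for r in reps])
        mean = float(means.mean())
        sem = float(means.std(ddof=1) / np.sqrt(len(means))) if len(means) > 1 else 0.0
    elif method == "pooled":
        pooled = np.concatenate(reps)
        mean = float(pooled.mean())
        sem = float(pooled.std(ddof=1) / np.sqrt(pooled.size)) if pooled.size > 1 else 0.0
    else:
        raise ValueError(f"unknown summary method {method!r}")
    return ArmSummary(mean, sem, n_cells, len(reps))


def summarize_sample(
    ligand_replicates,
    vehicle_replicates,
    calibrated: bool = False,
    method: str = "replicate-mean-first",
) -> NFRETSummary:
    """Summarize a ligand/vehicle pair of replicate NFRET measurements.

    Each argument is a sequence of per-replicate arrays of per-cell NFRET
    values (NaN = undefined, excluded). The default summary averages
    replicate means and takes the SEM across replicates; the fold
    difference divides the ligand-arm mean by the vehicle-arm mean, with
    its standard error propagated to first order.
    """
    ligand = _arm_summary(ligand_replicates, method)
    vehicle = _arm_summary(vehicle_replicates, method)
    fold = fold_difference(ligand.mean_nfret, ligand.sem, vehicle.mean_nfret, vehicle.sem)
    return NFRETSummary(ligand, vehicle, fold, calibrated=calibrated, method=method)


def _gate_and_compensate(
    events: pd.DataFrame,
    model: SpilloverModel,
    keep_fraction: float,
    tolerance: float,
) -> pd.DataFrame:
    return compensate(gate_cells_singlets(events, keep_fraction, tolerance), model)


def flow_fret_pipeline(
    sample: pd.DataFrame,
    controls: dict[str, pd.DataFrame],
    max_false_rate: float = 0.01,
    keep_fraction: float = 0.75,
    tolerance: float = 0.15,
    min_positive: int = 100,
) -> np.ndarray:
    """Full per-sample chain: spillover, gating, compensation, NFRET.

    ``controls`` must contain ``vector_only``, ``donor_only`` and
    ``acceptor_only`` tables. Transfection positivity is gated on the raw
    marker channel against the vector-only control; donor/acceptor double
    positivity is gated on compensated channels against the compensated
    single-color controls (thresholds set to include at most
    ``max_false_rate`` of each). Returns the defined per-cell NFRET values
    of the gated sample.
    """
    for key in ("vector_only", "donor_only", "acceptor_only"):
        if key not in controls:
            raise ValueError(f"missing control table {key!r}")
    model = estimate_spillover(
        {"donor": controls["donor_only"], "acceptor": controls["acceptor_only"]},
        vector_only=controls["vector_only"],
        channels=tuple(ch for ch in FLUOR_CHANNELS if ch in sample.columns),
        max_false_rate=max_false_rate,
        min_positive=min_positive,
    )
    gated = gate_cells_singlets(sample, keep_fraction, tolerance)
    marker_ch = ROLE_CHANNELS["marker"]
    if marker_ch in sample.columns:
        thr_marker = positivity_threshold(controls["vector_only"], marker_ch, max_false_rate)
        gated = gate_positive(gated, marker_ch, thr_marker)
    comp = compensate(gated, model)
    comp_acceptor_only = _gate_and_compensate(
        controls["acceptor_only"], model, keep_fraction, tolerance
    )
    comp_donor_only = _gate_and_compensate(
        controls["donor_only"], model, keep_fraction, tolerance
    )
    donor_col = COMP_PREFIX + ROLE_CHANNELS["donor"]
    acceptor_col = COMP_PREFIX + ROLE_CHANNELS["acceptor"]
    thr_donor = positivity_threshold(comp_acceptor_only, donor_col, max_false_rate)
    thr_acceptor = positivity_threshold(comp_donor_only, acceptor_col, max_false_rate)
    comp = gate_positive(comp, donor_col, thr_donor)
    comp = gate_positive(comp, acceptor_col, thr_acceptor)
    values = nfret_per_cell(comp).to_numpy()
    return values[np.isfinite(values)]


def calibrated_sample_nfret(
    sample: pd.DataFrame,
    controls: dict[str, pd.DataFrame],
    **pipeline_kwargs,
) -> np.ndarray:
    """Per-cell calibrated NFRET of a sample against the control panel.

    Processes the negative and positive FRET controls through the same
    pipeline, then rescales the sample's per-cell NFRET so the negative
    control mean is 0 and the positive control mean is 1.
    """
    for key in ("negative", "positive"):
        if key not in controls:
            raise ValueError(f"missing control table {key!r}")
    raw = flow_fret_pipeline(sample, controls, **pipeline_kwargs)
    neg = flow_fret_pipeline(controls["negative"], controls, **pipeline_kwargs)
    pos = flow_fret_pipeline(controls["positive"], controls, **pipeline_kwargs)
    return calibrate_nfret(raw, float(np.mean(neg)), float(np.mean(pos)))
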