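"""Synthetic flow-cytometry samples, microscopy fields and calibration beads
with known ground truth.

The generator emulates the measurement process of a cell-based FRET
dimerization assay so that every downstream computation (compensation,
gating, NFRET, bleed-through correction, bead calibration) can be verified
against known truth:

* per-cell expression is log-normally heterogeneous; a Bernoulli draw
  decides whether a cell is transfected at all;
* a ligand dose sets the fraction ``f`` of receptor chains in complexes via
  a saturating one-site dose response; complexes form as
  ``C = f * min(D, A)`` (the scarcer partner limits complexation);
* FRET efficiency follows the Förster form
  ``E = 1 / (1 + (r / R0)^6)`` of the donor-acceptor separation ``r``;
* the four physical signal sources per cell are donor emission ``D - E*C``
  (donor quenching), acceptor emission ``A``, sensitized emission ``E*C``
  and a transfection-marker ``R``; observed channels are a linear mixture
  of sources (spectral bleed-through) plus additive log-normal
  autofluorescence, times multiplicative log-normal detector noise,
  clipped at the saturation value;
* scatter channels carry singlet/doublet structure: a doublet is a merged
  pair of cells whose FSC-A and fluorescence add but whose FSC-H does not;
* calibration beads come in discrete subpopulations of known reference
  fluorophore count, observed with a configurable coefficient of variation.

All randomness flows through explicit seeds; identical configuration plus
seed gives bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imagefret import ImageField

__all__ = [
    "SOURCES",
    "FLUOR_CHANNELS",
    "SCATTER_CHANNELS",
    "PRIMARY_CHANNEL",
    "SpilloverTruth",
    "SimConfig",
    "ImageSimTruth",
    "dimer_fraction",
    "fret_efficiency",
    "simulate_flow_sample",
    "control_configs",
    "simulate_control_set",
    "simulate_image_field",
    "simulate_image_fields",
    "simulate_bead_set",
]

SOURCES = ("donor", "acceptor", "sensitized", "marker")
FLUOR_CHANNELS = ("Pacific Blue", "FITC", "AmCyan", "APC")
SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")
#: Which detection channel each signal source primarily feeds:
#: donor emission -> Pacific Blue, acceptor -> FITC, sensitized (FRET)
#: emission -> AmCyan, transfection marker -> APC.
PRIMARY_CHANNEL = {
    "donor": "Pacific Blue",
    "acceptor": "FITC",
    "sensitized": "AmCyan",
    "marker": "APC",
}
#: Image-channel equivalents of the three FRET-relevant flow channels.
IMAGE_CHANNEL_OF = {"Pacific Blue": "dd", "FITC": "aa", "AmCyan": "da"}

_SEED_MOD = 2**31


@dataclass(frozen=True)
class SpilloverTruth:
    """True source -> channel mixing fractions used by the generator.

    ``coefficients[source][channel]`` is the fraction of that source's
    signal detected in the channel; each source's primary channel carries
    coefficient 1 (diagonal), off-diagonal entries lie in [0, 1).
    """

    coefficients: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for src, row in self.coefficients.items():
            for ch, v in row.items():
                if ch == PRIMARY_CHANNEL[src]:
                    if v != 1:
                        raise ValueError(f"diagonal coefficient for {src} must be 1")
                elif not 0 <= v < 1:
                    raise ValueError(
                        f"off-diagonal coefficient {src}->{ch} must lie in [0, 1)"
                    )

    @classmethod
    def identity(cls) -> "SpilloverTruth":
        return cls({src: {PRIMARY_CHANNEL[src]: 1.0} for src in SOURCES})

    @classmethod
    def from_bleedthrough(
        cls, a: float = 0.15, b: float = 0.02, c: float = 0.05, d: float = 0.40
    ) -> "SpilloverTruth":
        """Build the mixing from the four image-style bleed-through fractions.

        ``d`` and ``c`` are donor emission bleeding into the FRET (AmCyan)
        and acceptor (FITC) channels; ``a`` and ``b`` are acceptor emission
        bleeding into the FRET and donor (Pacific Blue) channels.
        """
        return cls(
            {
                "donor": {"Pacific Blue": 1.0, "FITC": c, "AmCyan": d},
                "acceptor": {"FITC": 1.0, "Pacific Blue": b, "AmCyan": a},
                "sensitized": {"AmCyan": 1.0},
                "marker": {"APC": 1.0},
            }
        )

    def matrix(
        self,
        sources: Sequence[str] = SOURCES,
        channels: Sequence[str] = FLUOR_CHANNELS,
    ) -> np.ndarray:
        """Dense mixing matrix, rows = sources, columns = channels."""
        m = np.zeros((len(sources), len(channels)))
        for i, src in enumerate(sources):
            row = self.coefficients.get(src, {})
            for j, ch in enumerate(channels):
                m[i, j] = row.get(ch, 0.0)
        return m


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic measurement process.

    Defaults emulate the assay the pipeline targets: samples of a few
    thousand analyzable cells, log-normal co-expression spanning about two
    orders of magnitude, a saturating rapalog-style dose response, and the
    bleed-through pattern of a cyan/yellow fluorophore pair measured with
    violet/blue excitation (donor emission bleeds strongly into the FRET
    channel).
    """

    seed: int = 0
    n_cells: int = 2500
    p_transfected: float = 0.5
    expr_mu: float = 0.0           # log-scale mean of per-cell expression
    expr_sigma: float = 1.0        # log-scale sd (~2 decades of heterogeneity)
    donor_rate: float = 1000.0     # a.u. per expression unit
    acceptor_rate: float = 1000.0
    marker_rate: float = 800.0
    dimer_fraction_vehicle: float = 0.15
    dimer_fraction_max: float = 0.55
    ec50: float = 10.0             # nM
    ligand_dose: float = 100.0     # nM
    ecd_distance: float = 8.0      # Å between ectodomain C-termini when bound
    forster_radius: float = 50.0   # Å
    efficiency_override: float | None = None  # direct E, bypassing the distance model
    e_fusion: float = 0.6          # FRET efficiency of the fusion positive control
    mixing: SpilloverTruth = field(default_factory=SpilloverTruth.from_bleedthrough)
    autofl_mu: float | None = math.log(50.0)  # log-scale autofluorescence; None = none
    autofl_sigma: float = 0.4
    noise_cv: float = 0.1          # multiplicative detector noise CV
    saturation_value: float = 65535.0
    doublet_fraction: float = 0.1
    image_shape: tuple[int, int] = (256, 256)
    cell_radius_px: int = 12
    n_cells_image: int = 25
    quantize: bool = True          # store images as 16-bit integers

    def __post_init__(self) -> None:
        for name in ("p_transfected", "dimer_fraction_vehicle", "dimer_fraction_max",
                     "doublet_fraction", "noise_cv", "e_fusion"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("donor_rate", "acceptor_rate", "marker_rate", "ligand_dose",
                     "ecd_distance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.forster_radius <= 0:
            raise ValueError("forster_radius must be positive")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.autofl_mu is not None and self.saturation_value <= math.exp(self.autofl_mu):
            raise ValueError("saturation_value must exceed the autofluorescence scale")
        if self.efficiency_override is not None and not 0 <= self.efficiency_override <= 1:
            raise ValueError("efficiency_override must lie in [0, 1]")


@dataclass
class ImageSimTruth:
    """Ground truth for one simulated field: per-cell table and per-pixel
    source maps (donor emission after quenching, acceptor, sensitized)."""

    cells: pd.DataFrame
    donor: np.ndarray
    acceptor: np.ndarray
    sensitized: np.ndarray


def dimer_fraction(config: SimConfig) -> float:
    """Fraction of chains in complexes at the configured ligand dose.

    Saturating one-site binding between the vehicle floor and the maximal
    fraction: ``f = f_veh + (f_max - f_veh) * L / (L + EC50)``.
    """
    dose = config.ligand_dose
    if dose < 0:
        raise ValueError("ligand dose must be nonnegative")
    f0, fmax = config.dimer_fraction_vehicle, config.dimer_fraction_max
    return f0 + (fmax - f0) * dose / (dose + config.ec50)


def fret_efficiency(distance: float, forster_radius: float) -> float:
    """Förster transfer efficiency ``E = 1 / (1 + (r / R0)^6)``.

    Strictly decreasing in distance, E = 1 at contact and E = 0.5 at the
    Förster radius.
    """
    if distance < 0:
        raise ValueError("distance must be nonnegative")
    if forster_radius <= 0:
        raise ValueError("forster_radius must be positive")
    return 1.0 / (1.0 + (distance / forster_radius) ** 6)


def _efficiency(config: SimConfig) -> float:
    if config.efficiency_override is not None:
        return config.efficiency_override
    return fret_efficiency(config.ecd_distance, config.forster_radius)


def _noise_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _cell_amounts(config: SimConfig, rng: np.random.Generator, n: int):
    """Per-cell fluorophore amounts and complexation shared by flow/image sims."""
    expr = rng.lognormal(config.expr_mu, config.expr_sigma, n)
    transfected = rng.random(n) < config.p_transfected
    scale = expr * transfected
    donor = config.donor_rate * scale
    acceptor = config.acceptor_rate * scale
    marker = config.marker_rate * scale
    f = dimer_fraction(config)
    eff = _efficiency(config)
    complexes = f * np.minimum(donor, acceptor)
    return donor, acceptor, marker, complexes, eff, transfected


def _source_matrix(donor, acceptor, marker, complexes, eff) -> np.ndarray:
    sensitized = eff * complexes
    return np.column_stack([donor - sensitized, acceptor, sensitized, marker])


def simulate_flow_sample(
    config: SimConfig, label: str = "", treatment: str = "", replicate: str = ""
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One flow sample: an event table and the matching per-event ground truth.

    Returns ``(events, truth)``. Events carry scatter plus the four named
    fluorescence channels; ``truth`` records per event the donor, acceptor
    and complex amounts, FRET efficiency, and transfection/doublet flags.
    Doublet events are merged cell pairs (summed fluorescence and FSC-A,
    single-cell FSC-H), so the downstream singlet gate has real doublets
    to remove.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    n_doub = int(round(config.doublet_fraction * n))
    m = n + n_doub

    donor, acceptor, marker, complexes, eff, transfected = _cell_amounts(config, rng, m)
    sources = _source_matrix(donor, acceptor, marker, complexes, eff)

    size = rng.lognormal(math.log(1e5), 0.15, m)
    fsch = size
    fsca = size * rng.lognormal(0.0, 0.03, m)
    ssca = 0.5 * size * rng.lognormal(0.0, 0.2, m)

    # merge the last n_doub cells into the first n_doub events
    if n_doub:
        partner = np.arange(n, m)
        target = np.arange(n_doub)
        sources[target] += sources[partner]
        fsca[target] += fsca[partner]
        ssca[target] += ssca[partner]
        fsch[target] = np.maximum(fsch[target], fsch[partner])
        donor[target] += donor[partner]
        acceptor[target] += acceptor[partner]
        complexes[target] += complexes[partner]
        transfected[target] |= transfected[partner]
    is_doublet = np.zeros(n, dtype=bool)
    is_doublet[:n_doub] = True

    clean = sources[:n] @ config.mixing.matrix()
    if config.autofl_mu is not None:
        clean = clean + rng.lognormal(config.autofl_mu, config.autofl_sigma, (n, 4))
    sigma = _noise_sigma(config.noise_cv)
    observed = clean * rng.lognormal(-0.5 * sigma * sigma, sigma, (n, 4))
    observed = np.minimum(observed, config.saturation_value)

    order = rng.permutation(n)
    events = pd.DataFrame(
        np.column_stack([fsca[:n], fsch[:n], ssca[:n], observed])[order],
        columns=list(SCATTER_CHANNELS) + list(FLUOR_CHANNELS),
    )
    truth = pd.DataFrame(
        {
            "donor_amount": donor[:n][order],
            "acceptor_amount": acceptor[:n][order],
            "complex_amount": complexes[:n][order],
            "fret_efficiency": np.full(n, eff)[order],
            "transfected": transfected[:n][order],
            "is_doublet": is_doublet[order],
        }
    )
    events.attrs.update(
        {"sample": label, "treatment": treatment, "replicate": replicate,
         "ligand_dose": config.ligand_dose, "compensated": False}
    )
    return events, truth


def control_configs(config: SimConfig) -> dict[str, SimConfig]:
    """Configurations of the standard control panel for one experiment.

    vector-only (empty vector, autofluorescence only), donor-only,
    acceptor-only (single-fluorophore bleed-through controls), negative
    (donor and acceptor co-expressed with no dimerization) and positive
    (covalent donor-acceptor fusion: every chain in a complex, efficiency
    ``e_fusion``). Controls share the parent's mixing and noise; their
    seeds are derived deterministically from the parent seed.
    """
    s = config.seed
    return {
        "vector_only": replace(
            config, donor_rate=0.0, acceptor_rate=0.0, marker_rate=0.0,
            seed=(s + 11) % _SEED_MOD,
        ),
        # single-fluorophore compensation controls carry no transfection marker
        "donor_only": replace(
            config, acceptor_rate=0.0, marker_rate=0.0, seed=(s + 12) % _SEED_MOD
        ),
        "acceptor_only": replace(
            config, donor_rate=0.0, marker_rate=0.0, seed=(s + 13) % _SEED_MOD
        ),
        "negative": replace(
            config, dimer_fraction_vehicle=0.0, dimer_fraction_max=0.0,
            seed=(s + 14) % _SEED_MOD,
        ),
        "positive": replace(
            config, dimer_fraction_vehicle=1.0, dimer_fraction_max=1.0,
            efficiency_override=config.e_fusion, seed=(s + 15) % _SEED_MOD,
        ),
    }


def simulate_control_set(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Simulate the full control panel as event tables (see control_configs)."""
    out = {}
    for name, cfg in control_configs(config).items():
        events, _ = simulate_flow_sample(cfg, label=name)
        out[name] = events
    return out


def _place_disks(
    rng: np.random.Generator, shape: tuple[int, int], radius: int, n: int
) -> np.ndarray:
    """Non-overlapping disk centers by rejection sampling (bounded retries)."""
    h, w = shape
    margin = radius + 1
    if h < 2 * margin or w < 2 * margin:
        raise ValueError("image_shape must accommodate at least one cell diameter")
    centers: list[tuple[float, float]] = []
    min_d2 = (2 * radius + 2) ** 2
    attempts = 0
    max_attempts = 1000 * max(n, 1)
    while len(centers) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping cells of radius {radius} "
                f"in a {h}x{w} field after {max_attempts} attempts"
            )
        attempts += 1
        r = margin + rng.random() * (h - 2 * margin)
        c = margin + rng.random() * (w - 2 * margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_d2 for r0, c0 in centers):
            centers.append((r, c))
    return np.array(centers).reshape(n, 2)


def simulate_image_field(
    config: SimConfig, field_id: str = "", sample_id: str = ""
) -> tuple[ImageField, ImageSimTruth]:
    """One microscopy field of view: disk-shaped cells on an autofluorescent
    background, imaged in the DD/AA/DA channels.

    Per-cell fluorophore amounts follow the same model as the flow
    generator; within a cell the per-pixel source intensity equals the
    cell's amounts. Channels are mixed per the configured spillover,
    background and multiplicative noise are applied, intensities are
    clipped at the saturation value and (by default) quantized to 16-bit
    integers.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.image_shape)
    n = config.n_cells_image
    donor, acceptor, marker, complexes, eff, transfected = _cell_amounts(config, rng, n)
    centers = _place_disks(rng, shape, config.cell_radius_px, n)

    sources = _source_matrix(donor, acceptor, marker, complexes, eff)
    # flow-channel mixing restricted to the three imaging channels
    chans = ("Pacific Blue", "FITC", "AmCyan")
    mix = config.mixing.matrix(SOURCES, chans)

    src_maps = {k: np.zeros(shape) for k in ("donor", "acceptor", "sensitized")}
    mixed = np.zeros(shape + (3,))
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r2 = config.cell_radius_px**2
    for i in range(n):
        disk = (rr - centers[i, 0]) ** 2 + (cc - centers[i, 1]) ** 2 <= r2
        mixed[disk] += sources[i] @ mix
        src_maps["donor"][disk] += sources[i, 0]
        src_maps["acceptor"][disk] += sources[i, 1]
        src_maps["sensitized"][disk] += sources[i, 2]

    if config.autofl_mu is not None:
        mixed = mixed + rng.lognormal(config.autofl_mu, config.autofl_sigma, shape + (3,))
    sigma = _noise_sigma(config.noise_cv)
    observed = mixed * rng.lognormal(-0.5 * sigma * sigma, sigma, shape + (3,))
    observed = np.minimum(observed, config.saturation_value)
    if config.quantize:
        observed = np.rint(observed)
        if config.saturation_value <= np.iinfo(np.uint16).max:
            observed = observed.astype(np.uint16)

    field_out = ImageField(
        dd=observed[..., 0],
        aa=observed[..., 1],
        da=observed[..., 2],
        saturation_value=config.saturation_value,
        field_id=field_id,
        sample_id=sample_id,
    )
    cells = pd.DataFrame(
        {
            "row": centers[:, 0],
            "col": centers[:, 1],
            "radius_px": config.cell_radius_px,
            "donor_amount": donor,
            "acceptor_amount": acceptor,
            "complex_amount": complexes,
            "fret_efficiency": eff,
            "transfected": transfected,
        }
    )
    return field_out, ImageSimTruth(cells=cells, **src_maps)


def simulate_image_fields(
    config: SimConfig, n_fields: int, sample_id: str = ""
) -> list[tuple[ImageField, ImageSimTruth]]:
    """Several fields of view of one sample, with per-field derived seeds."""
    out = []
    for i in range(n_fields):
        cfg = replace(config, seed=(config.seed + 7919 * (i + 1)) % _SEED_MOD)
        out.append(simulate_image_field(cfg, field_id=f"field{i:02d}", sample_id=sample_id))
    return out


def simulate_bead_set(
    subpop_values: Sequence[float],
    true_slope: float,
    cv: float,
    n_per_subpop: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Calibration-bead events: discrete subpopulations of known brightness.

    Each subpopulation's observed MFI is log-normal centered (in mean) at
    ``true_slope * reference_value`` with coefficient of variation ``cv``.
    The returned table carries no subpopulation labels — identifying the
    subpopulations is the analysis task — and the events are shuffled.
    """
    values = np.asarray(subpop_values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("subpop_values must be a nonempty 1-D sequence")
    if not np.all(values > 0) or not np.all(np.diff(values) > 0):
        raise ValueError("subpop_values must be strictly increasing and positive")
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    rng = np.random.default_rng(seed)
    means = true_slope * values
    if cv == 0:
        mfi = np.repeat(means, n_per_subpop)
    else:
        sigma = _noise_sigma(cv)
        mfi = np.concatenate(
            [rng.lognormal(math.log(m) - 0.5 * sigma * sigma, sigma, n_per_subpop)
             for m in means]
        )
    mfi = mfi[rng.permutation(mfi.size)]
    return pd.DataFrame({"MFI": mfi})
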