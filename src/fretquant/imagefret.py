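"""Pixel-wise sensitized-emission FRET from three-channel microscopy fields.

A field of view is acquired in three excitation/emission configurations:

* ``DD`` — donor excited, donor emission captured;
* ``AA`` — acceptor excited, acceptor emission captured;
* ``DA`` — donor excited, acceptor emission captured (the raw FRET channel).

The raw DA signal contains spectral bleed-through from both fluorophores.
Four scalar bleed-through parameters are estimated from single-fluorophore
control fields (ratios averaged over valid pixels):

    a = I_DA / I_AA   and   b = I_DD / I_AA   on acceptor-only fields,
    c = I_AA / I_DD   and   d = I_DA / I_DD   on donor-only fields.

These correct the FRET channel pixel-by-pixel to a corrected FRET
intensity Fc, which is then expression-normalized:

    NFRET = Fc / sqrt(I_AA * I_DD)

Background pixels are suppressed with per-channel thresholds set at a high
percentile (default 99.9%) of pixel intensity in empty-vector-transfected
fields; saturated pixels are removed from every downstream average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ImageField",
    "BleedthroughParams",
    "PixelNFRETResult",
    "autofluorescence_thresholds",
    "mask_pixels",
    "estimate_bleedthrough",
    "corrected_fret",
    "pixel_nfret",
    "sample_nfret",
    "render_maps",
]

CHANNELS = ("dd", "aa", "da")


@dataclass
class ImageField:
    """One field of view: DD/AA/DA pixel matrices plus saturation metadata.

    ``valid`` is an explicit boolean validity matrix (True = usable pixel);
    ``None`` means every pixel is usable. Removed pixels are never encoded
    as sentinel intensities.
    """

    dd: np.ndarray
    aa: np.ndarray
    da: np.ndarray
    saturation_value: float = 65535.0
    field_id: str = ""
    sample_id: str = ""
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dd = np.asarray(self.dd)
        self.aa = np.asarray(self.aa)
        self.da = np.asarray(self.da)
        if not (self.dd.shape == self.aa.shape == self.da.shape):
            raise ValueError("DD, AA and DA matrices must share one shape")
        if self.valid is not None and self.valid.shape != self.dd.shape:
            raise ValueError("validity mask must match the image shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.dd.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.shape, dtype=bool)
        return self.valid


@dataclass(frozen=True)
class BleedthroughParams:
    """Scalar bleed-through fractions estimated from single-color fields."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"bleed-through parameter {name} must be finite and >= 0")


@dataclass
class PixelNFRETResult:
    """Corrected FRET and pixel NFRET matrices for one field of view."""

    fc: np.ndarray
    nfret: np.ndarray
    defined: np.ndarray
    field_mean: float
    n_defined: int
    variant: str = "nested"
    metadata: dict = field(default_factory=dict)


def _pixels(fields: Iterable[ImageField], channel: str) -> np.ndarray:
    parts = [f.channel(channel).ravel() for f in fields]
    if not parts:
        raise ValueError("at least one field is required")
    pooled = np.concatenate(parts)
    if pooled.size == 0:
        raise ValueError("fields contain no pixels")
    return pooled.astype(float)


def autofluorescence_thresholds(
    vector_only_fields: Sequence[ImageField],
    percentile: float = 0.999,
) -> dict[str, float]:
    """Per-channel autofluorescence ceiling from empty-vector control fields.

    Pixels are pooled across all provided fields (not averaged per field),
    and the threshold is the linearly interpolated ``percentile`` quantile
    of the pooled distribution in each channel.
    """
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie strictly between 0 and 1")
    return {
        ch: float(np.quantile(_pixels(vector_only_fields, ch), percentile))
        for ch in CHANNELS
    }


def mask_pixels(
    f: ImageField,
    thresholds: Mapping[str, float],
    saturation_value: float | None = None,
) -> ImageField:
    """Suppress background and remove saturated pixels.

    Per channel, pixels at or below the autofluorescence threshold are set
    to zero. Pixels at or above the saturation value in *any* channel are
    marked invalid and excluded from every downstream average (the
    bleed-through ratios and all NFRET means). The comparison against the
    threshold is strict (>) so that, with the default percentile, at most
    the complementary fraction of background pixels survives even when
    quantized intensities tie at the threshold.
    """
    missing = [ch for ch in CHANNELS if ch not in thresholds]
    if missing:
        raise ValueError(f"thresholds missing for channels: {missing}")
    sat = f.saturation_value if saturation_value is None else saturation_value
    valid = f.valid_mask().copy()
    out = {}
    for ch in CHANNELS:
        img = f.channel(ch).astype(float)
        valid &= img < sat
        out[ch] = np.where(img > thresholds[ch], img, 0.0)
    return replace(f, dd=out["dd"], aa=out["aa"], da=out["da"], valid=valid)


def _ratio_mean(fields: Sequence[ImageField], num: str, den: str, label: str) -> float:
    """Mean of per-pixel ratios pooled across fields, excluding undefined ones."""
    ratios = []
    for f in fields:
        d = f.channel(den).astype(float)
        n = f.channel(num).astype(float)
        ok = f.valid_mask() & (d > 0)
        ratios.append((n[ok] / d[ok]))
    pooled = np.concatenate(ratios) if ratios else np.empty(0)
    if pooled.size == 0:
        raise ValueError(f"no valid pixels to estimate {label} (all denominators zero)")
    return float(pooled.mean())


def estimate_bleedthrough(
    donor_only: Sequence[ImageField],
    acceptor_only: Sequence[ImageField],
) -> BleedthroughParams:
    """Estimate (a, b, c, d) from masked single-fluorophore control fields.

    Fields should already be passed through :func:`mask_pixels`. Ratios are
    averaged over all valid pixels pooled across the provided fields;
    pixels whose denominator is zero (infinite or undefined ratios) are
    excluded. Note the estimator does not subtract residual
    autofluorescence inside cells: control acquisitions are assumed bright
    relative to background.
    """
    if not donor_only or not acceptor_only:
        raise ValueError("at least one donor-only and one acceptor-only field required")
    return BleedthroughParams(
        a=_ratio_mean(acceptor_only, "da", "aa", "a = I_DA/I_AA (acceptor-only)"),
        b=_ratio_mean(acceptor_only, "dd", "aa", "b = I_DD/I_AA (acceptor-only)"),
        c=_ratio_mean(donor_only, "aa", "dd", "c = I_AA/I_DD (donor-only)"),
        d=_ratio_mean(donor_only, "da", "dd", "d = I_DA/I_DD (donor-only)"),
    )


def corrected_fret(
    f: ImageField,
    params: BleedthroughParams,
    formula_variant: str = "nested",
) -> np.ndarray:
    """Bleed-through-corrected FRET intensity Fc, pixel by pixel.

    Two algebraic readings of the correction are supported:

    * ``"nested"`` (default): Fc = I_DA - a*(I_AA - c*I_DD) - d*(I_DD - b*I_AA),
      the three-cube correction in which each control channel is itself
      first unmixed before its contribution to DA is subtracted;
    * ``"flat"``:  Fc = I_DA - a*I_AA - c*I_DD - d*I_DD - b*I_AA, the
      plain sum of subtractions.

    The two agree exactly whenever b = c = 0. Removed (invalid) pixels are
    NaN in the returned matrix.
    """
    dd = f.dd.astype(float)
    aa = f.aa.astype(float)
    da = f.da.astype(float)
    if formula_variant == "nested":
        fc = da - params.a * (aa - params.c * dd) - params.d * (dd - params.b * aa)
    elif formula_variant == "flat":
        fc = da - params.a * aa - params.c * dd - params.d * dd - params.b * aa
    else:
        raise ValueError(f"unknown formula variant {formula_variant!r}; use 'nested' or 'flat'")
    fc = fc.copy()
    fc[~f.valid_mask()] = np.nan
    return fc


def pixel_nfret(f: ImageField, fc: np.ndarray, variant: str = "nested") -> PixelNFRETResult:
    """Expression-normalized FRET per pixel: NFRET = Fc / sqrt(I_AA * I_DD).

    A pixel is *defined* when it is valid, both I_AA and I_DD are positive
    and Fc is finite; all other pixels are masked (NaN) and excluded from
    the field mean.
    """
    if fc.shape != f.shape:
        raise ValueError("Fc matrix must match the field shape")
    dd = f.dd.astype(float)
    aa = f.aa.astype(float)
    prod = aa * dd
    defined = f.valid_mask() & (prod > 0) & np.isfinite(fc)
    nfret = np.full(f.shape, np.nan)
    nfret[defined] = fc[defined] / np.sqrt(prod[defined])
    n = int(defined.sum())
    mean = float(nfret[defined].mean()) if n else float("nan")
    return PixelNFRETResult(
        fc=fc,
        nfret=nfret,
        defined=defined,
        field_mean=mean,
        n_defined=n,
        variant=variant,
        metadata={"field_id": f.field_id, "sample_id": f.sample_id},
    )


def sample_nfret(results: Sequence[PixelNFRETResult]) -> dict[str, float]:
    """Sample-level NFRET summaries across fields of view.

    ``pooled_mean`` averages defined pixels pooled across all fields (the
    default sample statistic, equal to the pixel-count-weighted mean of
    field means); ``mean_of_field_means`` is the unweighted alternative.
    """
    counts = np.array([r.n_defined for r in results], dtype=float)
    means = np.array([r.field_mean for r in results], dtype=float)
    total = counts.sum()
    if total == 0:
        warnings.warn("no defined pixels in any field", stacklevel=2)
        return {"pooled_mean": float("nan"), "mean_of_field_means": float("nan"),
                "n_pixels": 0, "n_fields": len(results)}
    ok = counts > 0
    return {
        "pooled_mean": float((means[ok] * counts[ok]).sum() / total),
        "mean_of_field_means": float(means[ok].mean()),
        "n_pixels": int(total),
        "n_fields": len(results),
    }


def render_maps(
    result: PixelNFRETResult,
    fc_path,
    nfret_path,
    fc_range: tuple[float, float] = (0.0, 1000.0),
    nfret_range: tuple[float, float] = (0.0, 1.0),
    cmap: str = "viridis",
    mask_color: tuple[int, int, int] = (128, 128, 128),
) -> dict:
    """Write Fc and NFRET heatmaps as PNG images with a fixed color scale.

    The color scale bounds are fixed (and returned in the metadata) rather
    than data-driven so that images from different samples are directly
    comparable; masked pixels are rendered in a distinct flat gray. Output
    bytes are deterministic for identical inputs.
    """
    import matplotlib

    colormap = matplotlib.colormaps[cmap]
    meta = {
        "fc_range": list(fc_range),
        "nfret_range": list(nfret_range),
        "cmap": cmap,
        "variant": result.variant,
        **result.metadata,
    }
    for matrix, rng, path in ((result.fc, fc_range, fc_path), (result.nfret, nfret_range, nfret_path)):
        lo, hi = rng
        scaled = np.clip((matrix - lo) / (hi - lo), 0.0, 1.0)
        bad = ~np.isfinite(matrix)
        rgba = (colormap(np.where(bad, 0.0, scaled)) * 255).astype(np.uint8)
        rgba[bad] = (*mask_color, 255)
        from PIL import Image

        Image.fromarray(rgba, mode="RGBA").save(path, format="PNG")
    return meta
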