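"""Spectral bleed-through calibration from single-fluorophore controls.

The raw FRET channel contains, besides any sensitized emission, a fixed
fraction of the donor signal (factor ``d``) and of the acceptor signal
(factor ``a``).  Both factors are estimated from control samples carrying
only one fluorophore: in a donor-only sample every rawFRET photon above
background is donor bleed-through, so ``d`` is the proportionality between
rawFRET and DF over the stained pixels (and symmetrically for ``a``).

The default estimator is the least-squares slope through the origin of
rawFRET against the stained channel, restricted to thresholded,
unsaturated foreground pixels — the direct empirical analogue of the
proportional bleed-through model used by the Youvan correction.
Alternatives: the median per-pixel ratio, and the ratio of summed
intensities.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .io_images import TripleStack
from .segmentation import auto_threshold

ESTIMATORS = ("slope", "median_ratio", "sum_ratio")


class CalibrationError(ValueError):
    """Control image unusable for factor estimation."""


@dataclass
class FactorEstimate:
    """One bleed-through factor from one single-stain control."""

    value: float
    n_pixels_used: int
    channel: str  # "donor" or "acceptor"
    method: str
    bit_depth: int


@dataclass
class BleedthroughFactors:
    """Donor (d) and acceptor (a) bleed-through fractions with provenance."""

    d: float
    a: float
    method: str = "slope"
    n_pixels_d: int = 0
    n_pixels_a: int = 0

    def __post_init__(self) -> None:
        if self.d < 0 or self.a < 0:
            raise ValueError("bleed-through factors must be >= 0")
        if self.d >= 1 or self.a >= 1:
            warnings.warn(
                f"bleed-through factor >= 1 (d={self.d}, a={self.a}); "
                "check that the controls are single-stain images"
            )

    def save(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "BleedthroughFactors":
        with open(os.fspath(path), encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _estimate_factor(
    control: TripleStack,
    stained: str,
    mask_method: str,
    estimator: str,
    min_pixels: int,
    subtract_background: bool,
    background_percentile: float,
) -> FactorEstimate:
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    channel = control.channels[stained]
    mask = auto_threshold(channel, method=mask_method).pixels
    # saturated pixels carry no usable intensity information in either channel
    mask &= ~control.saturation_masks[stained]
    mask &= ~control.saturation_masks["rawfret"]
    n = int(mask.sum())
    if n < min_pixels:
        raise CalibrationError(
            f"only {n} foreground pixels in the {stained} control "
            f"(need >= {min_pixels}); is the control stained?"
        )
    x = channel.pixels[mask].astype(np.float64)
    y = control.rawfret.pixels[mask].astype(np.float64)
    if subtract_background:
        x = x - np.percentile(channel.pixels.astype(np.float64), background_percentile)
        y = y - np.percentile(control.rawfret.pixels.astype(np.float64), background_percentile)

    if estimator == "slope":
        denom = float(np.dot(x, x))
        value = float(np.dot(x, y)) / denom if denom > 0 else 0.0
    elif estimator == "median_ratio":
        ok = x > 0
        value = float(np.median(y[ok] / x[ok])) if ok.any() else 0.0
    else:  # sum_ratio
        sx = float(x.sum())
        value = float(y.sum()) / sx if sx > 0 else 0.0

    if value < 0:
        warnings.warn(f"negative fitted bleed-through ({value:.4g}); clipping to 0")
        value = 0.0
    return FactorEstimate(value=value, n_pixels_used=n, channel=stained,
                          method=estimator, bit_depth=control.bit_depth)


def estimate_donor_factor(
    control: TripleStack,
    mask_method: str = "moments",
    estimator: str = "slope",
    min_pixels: int = 50,
    subtract_background: bool = False,
    background_percentile: float = 1.0,
) -> FactorEstimate:
    """Estimate ``d`` from a donor-only control (rawFRET vs DF)."""
    return _estimate_factor(control, "donor", mask_method, estimator,
                            min_pixels, subtract_background, background_percentile)


def estimate_acceptor_factor(
    control: TripleStack,
    mask_method: str = "moments",
    estimator: str = "slope",
    min_pixels: int = 50,
    subtract_background: bool = False,
    background_percentile: float = 1.0,
) -> FactorEstimate:
    """Estimate ``a`` from an acceptor-only control (rawFRET vs AF)."""
    return _estimate_factor(control, "acceptor", mask_method, estimator,
                            min_pixels, subtract_background, background_percentile)


def combine_factors(d_fragment: FactorEstimate, a_fragment: FactorEstimate) -> BleedthroughFactors:
    """Merge the two single-stain estimates into one factors record."""
    if d_fragment.channel != "donor" or a_fragment.channel != "acceptor":
        raise ValueError("fragments must come from a donor-only and an acceptor-only control")
    if d_fragment.bit_depth != a_fragment.bit_depth:
        warnings.warn(
            f"controls have different bit depths "
            f"({d_fragment.bit_depth} vs {a_fragment.bit_depth}); merging anyway"
        )
    method = d_fragment.method if d_fragment.method == a_fragment.method else (
        f"{d_fragment.method}+{a_fragment.method}")
    return BleedthroughFactors(
        d=d_fragment.value,
        a=a_fragment.value,
        method=method,
        n_pixels_d=d_fragment.n_pixels_used,
        n_pixels_a=a_fragment.n_pixels_used,
    )
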