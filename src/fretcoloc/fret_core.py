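"""Corrected and normalized FRET images (three-filter sensitized emission).

The corrected FRET signal removes spectral bleed-through from the raw
FRET channel::

    FRETc = rawFRET - d * DF - a * AF          (Youvan)

where ``d`` and ``a`` are the donor/acceptor bleed-through fractions
measured on single-stain controls.  FRETc scales with the local amounts
of both fluorophores; the normalized value

::

    NFRET = FRETc / sqrt(DF * AF)              (Xia)

is comparable between sites with different staining intensity.  Negative
FRETc values are preserved everywhere except for display: clipping them
in statistics would bias object means toward false-positive FRET.
NFRET is undefined (NaN) wherever DF or AF is zero — a zero would
masquerade as a measured negative result.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .io_images import ShapeError, TripleStack
from .bleedthrough import BleedthroughFactors


@dataclass
class FretImages:
    """FRETc / NFRET grids for one field of view.

    ``nfret`` holds NaN where undefined; ``nfret_defined`` is the
    complementary boolean mask (DF > 0 and AF > 0).
    """

    fretc: np.ndarray
    nfret: np.ndarray
    nfret_defined: np.ndarray
    factors_used: BleedthroughFactors


def compute_fretc(stack: TripleStack, factors: BleedthroughFactors) -> np.ndarray:
    """Pixel-wise ``rawFRET - d*DF - a*AF`` as float64; negatives preserved."""
    df = stack.donor.pixels.astype(np.float64)
    af = stack.acceptor.pixels.astype(np.float64)
    rf = stack.rawfret.pixels.astype(np.float64)
    return rf - factors.d * df - factors.a * af


def compute_nfret(fretc: np.ndarray, stack: TripleStack) -> tuple[np.ndarray, np.ndarray]:
    """``FRETc / sqrt(DF*AF)`` where both channels are positive, else NaN.

    Returns ``(nfret, defined_mask)``.
    """
    if fretc.shape != stack.shape:
        raise ShapeError("FRETc grid does not match the stack dimensions")
    df = stack.donor.pixels.astype(np.float64)
    af = stack.acceptor.pixels.astype(np.float64)
    defined = (df > 0) & (af > 0)
    nfret = np.full(fretc.shape, np.nan)
    nfret[defined] = fretc[defined] / np.sqrt(df[defined] * af[defined])
    return nfret, defined


def compute_fret_images(stack: TripleStack, factors: BleedthroughFactors) -> FretImages:
    """Convenience: FRETc + NFRET in one call."""
    fretc = compute_fretc(stack, factors)
    nfret, defined = compute_nfret(fretc, stack)
    return FretImages(fretc=fretc, nfret=nfret, nfret_defined=defined, factors_used=factors)


def render_fretc(
    fretc: np.ndarray,
    gain: float = 10.0,
    colormap: str = "jet",
    display_max: float | None = None,
    colorbar_width: int = 24,
) -> np.ndarray:
    """Pseudo-color rendering of an amplified FRETc image.

    Values are multiplied by ``gain`` (default 10, the usual amplification
    for weak sensitized-emission signals), clipped to ``[0, display_max]``
    — negatives map to the lowest color, for display only — passed through
    the named colormap, and a vertical gradient color-bar strip is appended
    on the right.  Returns an (H, W + colorbar) x 3 uint8 RGB image.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    if display_max is None:
        display_max = 4095.0
    scaled = np.clip(fretc * gain, 0.0, display_max) / display_max
    cmap = colormaps[colormap]
    rgb = (cmap(scaled)[..., :3] * 255).astype(np.uint8)
    # gradient strip: top = display_max, bottom = 0
    ramp = np.linspace(1.0, 0.0, fretc.shape[0])
    bar = (cmap(ramp)[:, :3] * 255).astype(np.uint8)
    bar = np.repeat(bar[:, None, :], colorbar_width, axis=1)
    gap = np.full((fretc.shape[0], 4, 3), 255, dtype=np.uint8)
    return np.concatenate([rgb, gap, bar], axis=1)


def write_fret_tiff(fret: FretImages, directory: str | os.PathLike, prefix: str = "scene") -> dict[str, str]:
    """Write FRETc and NFRET as 32-bit float TIFFs."""
    import tifffile

    paths = {}
    for name, arr in (("fretc", fret.fretc), ("nfret", fret.nfret)):
        p = os.path.join(os.fspath(directory), f"{prefix}_{name}.tif")
        tifffile.imwrite(p, arr.astype(np.float32))
        paths[name] = p
    return paths
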