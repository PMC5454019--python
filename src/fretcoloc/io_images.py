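"""Reading, validation and saturation auditing of multi-channel TIFF triples.

A measurement consists of three co-registered grayscale images: donor
emission under donor excitation (DF), acceptor emission under acceptor
excitation (AF), and the raw FRET channel (acceptor emission under donor
excitation).  Detectors digitize at a declared bit depth (typically 12-bit
A/D inside a 16-bit TIFF container); a pixel at the maximum code value
``2**bit_depth - 1`` is saturated and must be audited, because clipped
intensities create false-positive colocalization.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

VALID_BIT_DEPTHS = (8, 12, 16)
CHANNEL_ROLES = ("donor", "acceptor", "rawfret")


class ShapeError(ValueError):
    """Channel dimensions disagree."""


class BitDepthError(ValueError):
    """Pixel values exceed the declared bit depth's code range."""


@dataclass
class ChannelImage:
    """One grayscale channel with its declared detector bit depth.

    Parameters
    ----------
    pixels
        2-D non-negative integer intensity grid (row-major, origin top-left).
    bit_depth
        Detector A/D resolution in bits: 8, 12 or 16.  Saturation is judged
        against ``2**bit_depth - 1``, not the container dtype.
    role
        One of ``donor``, ``acceptor``, ``rawfret``.
    """

    pixels: np.ndarray
    bit_depth: int
    role: str = "donor"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ShapeError("channel image must be a non-empty 2-D grid")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise BitDepthError("channel pixels must be integer-valued")
        if self.bit_depth not in VALID_BIT_DEPTHS:
            raise BitDepthError(f"bit_depth must be one of {VALID_BIT_DEPTHS}")
        if self.role not in CHANNEL_ROLES:
            raise ValueError(f"role must be one of {CHANNEL_ROLES}")
        if self.pixels.min() < 0:
            raise BitDepthError("negative pixel values are not valid intensities")
        if self.pixels.max() > self.max_code:
            raise BitDepthError(
                f"pixel value {int(self.pixels.max())} exceeds "
                f"{self.max_code} for {self.bit_depth}-bit data"
            )

    @property
    def max_code(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def saturation_mask(self) -> np.ndarray:
        """Boolean grid, true exactly where the pixel sits at the max code."""
        return self.pixels == self.max_code


@dataclass
class TripleStack:
    """Co-registered donor / acceptor / rawFRET channels of one field of view."""

    donor: ChannelImage
    acceptor: ChannelImage
    rawfret: ChannelImage
    source_id: str = ""
    saturation_masks: dict = field(init=False)

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ShapeError(f"channel dimensions disagree: {sorted(shapes)}")
        self.saturation_masks = {
            name: ch.saturation_mask for name, ch in self.channels.items()
        }

    @property
    def channels(self) -> dict[str, ChannelImage]:
        return {"donor": self.donor, "acceptor": self.acceptor, "rawfret": self.rawfret}

    @property
    def shape(self) -> tuple[int, int]:
        return self.donor.shape

    @property
    def bit_depth(self) -> int:
        return self.donor.bit_depth

    def any_saturated(self) -> np.ndarray:
        """Pixels saturated in at least one channel."""
        m = np.zeros(self.shape, dtype=bool)
        for mask in self.saturation_masks.values():
            m |= mask
        return m


@dataclass
class SaturationReport:
    fractions: dict[str, float]
    tolerance: float
    overexposed: bool


def _read_plane(path: str | os.PathLike, bit_depth: int, role: str) -> ChannelImage:
    arr = tifffile.imread(os.fspath(path))
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise ShapeError(f"{path}: expected a single grayscale plane, got shape {arr.shape}")
    try:
        return ChannelImage(arr, bit_depth=bit_depth, role=role)
    except BitDepthError as exc:
        raise BitDepthError(f"{path}: {exc}") from exc


def load_triple(
    donor_path: str | os.PathLike,
    acceptor_path: str | os.PathLike,
    rawfret_path: str | os.PathLike,
    bit_depth: int = 12,
) -> TripleStack:
    """Load a donor / acceptor / rawFRET triple from three grayscale TIFFs.

    Raises :class:`ShapeError` on dimension mismatch and :class:`BitDepthError`
    (naming the offending file) when a pixel exceeds ``2**bit_depth - 1``.
    """
    donor = _read_plane(donor_path, bit_depth, "donor")
    acceptor = _read_plane(acceptor_path, bit_depth, "acceptor")
    rawfret = _read_plane(rawfret_path, bit_depth, "rawfret")
    source_id = "+".join(
        os.path.splitext(os.path.basename(os.fspath(p)))[0]
        for p in (donor_path, acceptor_path, rawfret_path)
    )
    return TripleStack(donor, acceptor, rawfret, source_id=source_id)


def load_triple_multipage(
    path: str | os.PathLike,
    bit_depth: int = 12,
    page_order: tuple[str, str, str] = ("donor", "acceptor", "rawfret"),
) -> TripleStack:
    """Load a triple from one multi-page TIFF, pages mapped via ``page_order``."""
    if sorted(page_order) != sorted(CHANNEL_ROLES):
        raise ValueError(f"page_order must be a permutation of {CHANNEL_ROLES}")
    arr = tifffile.imread(os.fspath(path))
    if arr.ndim != 3 or arr.shape[0] != 3:
        raise ShapeError(f"{path}: expected 3 pages, got shape {arr.shape}")
    by_role = {role: ChannelImage(arr[i], bit_depth, role) for i, role in enumerate(page_order)}
    source_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return TripleStack(by_role["donor"], by_role["acceptor"], by_role["rawfret"], source_id=source_id)


def write_channel(image: ChannelImage, path: str | os.PathLike) -> None:
    """Write a channel as an unsigned-integer grayscale TIFF (bit-exact round trip)."""
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    tifffile.imwrite(os.fspath(path), image.pixels.astype(dtype))


def write_triple(stack: TripleStack, directory: str | os.PathLike, prefix: str = "scene") -> dict[str, str]:
    """Write the three channels as ``<prefix>_<role>.tif`` files; returns the paths."""
    paths = {}
    for role, ch in stack.channels.items():
        p = os.path.join(os.fspath(directory), f"{prefix}_{role}.tif")
        write_channel(ch, p)
        paths[role] = p
    return paths


def saturation_report(stack: TripleStack, tolerance: float = 0.0) -> SaturationReport:
    """Per-channel saturated-pixel fractions and an overexposure verdict.

    The verdict is true iff any channel's fraction strictly exceeds
    ``tolerance`` (default 0: correct exposure admits no saturated pixel).
    """
    n = stack.donor.pixels.size
    fractions = {
        name: float(mask.sum()) / n for name, mask in stack.saturation_masks.items()
    }
    overexposed = any(f > tolerance for f in fractions.values())
    return SaturationReport(fractions=fractions, tolerance=tolerance, overexposed=overexposed)
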