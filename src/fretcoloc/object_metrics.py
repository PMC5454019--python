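"""Per-object colocalization and FRET statistics.

For every segmented object these routines compute the quantities that
distinguish genuine colocalization from coincidental overlap:

* **object Pearson** — product-moment correlation of the donor/acceptor
  pixel intensities restricted to the object.  Whole-image Pearson is
  also provided because it is the classic, misleading alternative: a
  field dominated by shared background can score ~0.6 even when the two
  stains occupy disjoint structures.
* **color-mix coefficient** — per pixel, ``min(DF, AF) / max(DF, AF)``
  (0 when both are 0), averaged over the object; 1 means complete
  two-channel mix (yellow), 0 a single marker.
* **acceptor:donor ratio** — ``mean_AF / mean_DF`` over the object.
* **object NFRET** — mean of the defined per-pixel NFRET values
  (default), or the ratio-of-means form ``mean_FRETc /
  sqrt(mean_DF * mean_AF)``.
* **colocalization area fraction** — intersection of the two channel
  masks as a percentage of their union, per image and per object.

Undefined values (zero variance, zero denominators, no defined pixels)
are NaN and excluded from aggregates — never silently 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io_images import ChannelImage, TripleStack
from .fret_core import FretImages
from .segmentation import BinaryMask, LabeledObjects

OBJECT_TABLE_COLUMNS = [
    "source_id", "object_id", "provenance", "area_px",
    "centroid_row", "centroid_col",
    "mean_DF", "mean_AF", "mean_rawFRET", "mean_FRETc", "mean_NFRET",
    "pearson", "ad_ratio", "colormix", "coloc_area_fraction_pct",
    "saturated_flag",
]

NFRET_MODES = ("pixel_mean", "ratio_of_means")


def _pixels(channel: ChannelImage | np.ndarray) -> np.ndarray:
    arr = channel.pixels if isinstance(channel, ChannelImage) else np.asarray(channel)
    return arr.astype(np.float64)


def _object_slices(objects: LabeledObjects):
    """Yield (object_id, within-slice boolean mask, slice) for each object."""
    slices = ndi.find_objects(objects.labels, max_label=objects.n_objects)
    for oid, sl in zip(objects.object_ids(), slices):
        if sl is None:
            continue
        yield oid, objects.labels[sl] == oid, sl


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN when either input is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.dot(xc, xc) * np.dot(yc, yc))
    if denom == 0:
        return float("nan")
    return float(np.dot(xc, yc) / denom)


def whole_image_pearson(donor: ChannelImage | np.ndarray, acceptor: ChannelImage | np.ndarray) -> float:
    """Classic full-frame intensity correlation, no object restriction."""
    return pearson(_pixels(donor).ravel(), _pixels(acceptor).ravel())


def pearson_per_object(
    objects: LabeledObjects,
    donor: ChannelImage | np.ndarray,
    acceptor: ChannelImage | np.ndarray,
) -> dict[int, float]:
    """Object-restricted Pearson of (DF, AF); NaN for zero-variance objects."""
    df, af = _pixels(donor), _pixels(acceptor)
    return {oid: pearson(df[sl][m], af[sl][m]) for oid, m, sl in _object_slices(objects)}


def colormix_image(donor: ChannelImage | np.ndarray, acceptor: ChannelImage | np.ndarray) -> np.ndarray:
    """Per-pixel min/max channel ratio in [0, 1]; 0 where both channels are 0."""
    df, af = _pixels(donor), _pixels(acceptor)
    hi = np.maximum(df, af)
    lo = np.minimum(df, af)
    out = np.zeros(df.shape)
    nz = hi > 0
    out[nz] = lo[nz] / hi[nz]
    return out


def colormix_per_object(
    objects: LabeledObjects,
    donor: ChannelImage | np.ndarray,
    acceptor: ChannelImage | np.ndarray,
    mode: str = "pixel_mean",
) -> dict[int, float]:
    """Mean per-pixel color-mix over each object (default), or the
    min/max ratio of the two object-mean intensities (``ratio_of_means``)."""
    df, af = _pixels(donor), _pixels(acceptor)
    if mode == "pixel_mean":
        cm = colormix_image(df, af)
        return {oid: float(cm[sl][m].mean()) for oid, m, sl in _object_slices(objects)}
    if mode == "ratio_of_means":
        out = {}
        for oid, m, sl in _object_slices(objects):
            md, ma = float(df[sl][m].mean()), float(af[sl][m].mean())
            hi = max(md, ma)
            out[oid] = (min(md, ma) / hi) if hi > 0 else 0.0
        return out
    raise ValueError(f"unknown colormix mode {mode!r}")


def ad_ratio_per_object(
    objects: LabeledObjects,
    donor: ChannelImage | np.ndarray,
    acceptor: ChannelImage | np.ndarray,
) -> dict[int, float]:
    """Acceptor:donor ratio ``mean_AF / mean_DF``; NaN when mean_DF is 0."""
    df, af = _pixels(donor), _pixels(acceptor)
    out = {}
    for oid, m, sl in _object_slices(objects):
        md = float(df[sl][m].mean())
        out[oid] = float(af[sl][m].mean()) / md if md > 0 else float("nan")
    return out


def nfret_per_object(
    objects: LabeledObjects,
    fret: FretImages,
    stack: TripleStack | None = None,
    mode: str = "pixel_mean",
) -> dict[int, float]:
    """Object NFRET: mean of defined per-pixel values (default) or the
    ratio-of-means form (requires ``stack``).  NaN when no pixel is defined."""
    if mode not in NFRET_MODES:
        raise ValueError(f"mode must be one of {NFRET_MODES}")
    out = {}
    if mode == "pixel_mean":
        for oid, m, sl in _object_slices(objects):
            vals = fret.nfret[sl][m]
            vals = vals[np.isfinite(vals)]
            out[oid] = float(vals.mean()) if vals.size else float("nan")
    else:
        if stack is None:
            raise ValueError("ratio_of_means mode requires the TripleStack")
        df = stack.donor.pixels.astype(np.float64)
        af = stack.acceptor.pixels.astype(np.float64)
        for oid, m, sl in _object_slices(objects):
            md, ma = float(df[sl][m].mean()), float(af[sl][m].mean())
            if md > 0 and ma > 0:
                out[oid] = float(fret.fretc[sl][m].mean()) / np.sqrt(md * ma)
            else:
                out[oid] = float("nan")
    return out


def coloc_area_fraction(
    union_mask: BinaryMask,
    intersection_mask: BinaryMask,
    objects: LabeledObjects | None = None,
) -> tuple[float, dict[int, float]]:
    """Colocalizing area as a percentage of the combined area.

    Per image: ``100 * |intersection| / |union|`` (0 for an empty union).
    Per object (when ``objects`` is given): percentage of the object's own
    pixels that lie in the intersection mask.
    """
    u = union_mask.area
    image_pct = 100.0 * intersection_mask.area / u if u > 0 else 0.0
    per_object: dict[int, float] = {}
    if objects is not None:
        inter = intersection_mask.pixels
        for oid, m, sl in _object_slices(objects):
            per_object[oid] = 100.0 * float(inter[sl][m].sum()) / float(m.sum())
    return image_pct, per_object


def build_object_table(
    stack: TripleStack,
    fret: FretImages,
    objects: LabeledObjects,
    intersection_mask: BinaryMask | None = None,
    nfret_mode: str = "pixel_mean",
    colormix_mode: str = "pixel_mean",
) -> pd.DataFrame:
    """One row per object with every per-object metric and the saturation flag.

    Objects overlapping any saturated pixel (in any channel) are flagged;
    downstream aggregation excludes flagged objects by default.  Undefined
    metrics are NaN, exported as empty CSV fields.
    """
    sat = stack.any_saturated()
    df = stack.donor.pixels.astype(np.float64)
    af = stack.acceptor.pixels.astype(np.float64)
    rf = stack.rawfret.pixels.astype(np.float64)

    pearsons = pearson_per_object(objects, df, af)
    mixes = colormix_per_object(objects, df, af, mode=colormix_mode)
    ratios = ad_ratio_per_object(objects, df, af)
    nfrets = nfret_per_object(objects, fret, stack=stack, mode=nfret_mode)
    if intersection_mask is not None:
        _, coloc = coloc_area_fraction(
            BinaryMask(objects.labels > 0, "objects", float("nan")),
            intersection_mask, objects)
    else:
        coloc = {}

    rows = []
    for oid, m, sl in _object_slices(objects):
        rr, cc = np.nonzero(m)
        area = int(m.sum())
        rows.append({
            "source_id": stack.source_id,
            "object_id": oid,
            "provenance": objects.provenance,
            "area_px": area,
            "centroid_row": float(rr.mean()) + sl[0].start,
            "centroid_col": float(cc.mean()) + sl[1].start,
            "mean_DF": float(df[sl][m].mean()),
            "mean_AF": float(af[sl][m].mean()),
            "mean_rawFRET": float(rf[sl][m].mean()),
            "mean_FRETc": float(fret.fretc[sl][m].mean()),
            "mean_NFRET": nfrets[oid],
            "pearson": pearsons[oid],
            "ad_ratio": ratios[oid],
            "colormix": mixes[oid],
            "coloc_area_fraction_pct": coloc.get(oid, float("nan")),
            "saturated_flag": bool(sat[sl][m].any()),
        })
    return pd.DataFrame(rows, columns=OBJECT_TABLE_COLUMNS)


def aggregate_table(table: pd.DataFrame, exclude_saturated: bool = True) -> pd.DataFrame:
    """Mean and SEM of each numeric metric over the (optionally unflagged) objects."""
    t = table[~table["saturated_flag"]] if exclude_saturated else table
    metrics = ["mean_DF", "mean_AF", "mean_rawFRET", "mean_FRETc", "mean_NFRET",
               "pearson", "ad_ratio", "colormix", "coloc_area_fraction_pct"]
    rows = []
    for mcol in metrics:
        vals = t[mcol].dropna()
        rows.append({
            "metric": mcol,
            "n": len(vals),
            "mean": vals.mean() if len(vals) else float("nan"),
            "sem": vals.sem() if len(vals) > 1 else float("nan"),
        })
    return pd.DataFrame(rows)
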