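"""Per-image analysis pipeline: segment, correct, measure.

``analyze_triple`` runs the full single-image workflow: threshold both
stain channels with the same automated method, watershed-split and label
the masks, combine them into union ("combined") and intersection
("colocalizing") regions, compute FRETc/NFRET with the supplied
bleed-through factors, and emit per-object tables for the union objects
(the default analysis set) and for each channel's own objects, plus
image-level summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bleedthrough import BleedthroughFactors
from .fret_core import FretImages, compute_fret_images
from .io_images import SaturationReport, TripleStack, saturation_report
from .object_metrics import build_object_table, coloc_area_fraction, whole_image_pearson
from .segmentation import (
    BinaryMask,
    LabeledObjects,
    combine_intersection,
    combine_union,
    label_objects,
    segment_channel,
    watershed_split,
)


@dataclass
class AnalysisResult:
    """Everything measured on one triple."""

    source_id: str
    tables: dict[str, pd.DataFrame]          # provenance -> object table
    masks: dict[str, BinaryMask]             # donor/acceptor/union/intersection
    objects: dict[str, LabeledObjects]
    fret: FretImages
    saturation: SaturationReport
    whole_image_pearson: float
    coloc_area_fraction_pct: float
    threshold_values: dict[str, float] = field(default_factory=dict)

    @property
    def object_table(self) -> pd.DataFrame:
        """The default analysis set: objects of the combined (union) regions."""
        return self.tables["union"]


def analyze_triple(
    stack: TripleStack,
    factors: BleedthroughFactors,
    threshold_method: str = "moments",
    manual_value: float | None = None,
    min_size: int = 10,
    nfret_mode: str = "pixel_mean",
    colormix_mode: str = "pixel_mean",
    saturation_tolerance: float = 0.0,
    watershed_before_combine: bool = True,
) -> AnalysisResult:
    """Run the full object-based FRET/colocalization analysis on one triple.

    The same threshold method is applied to donor and acceptor channels —
    mixing methods between the channels of one analysis would bias the
    mask combination.  ``watershed_before_combine`` controls whether the
    per-channel masks are split before the union/intersection masks are
    formed (default) or only the combined masks are split.
    """
    mask_d, obj_d = segment_channel(stack.donor, method=threshold_method,
                                    manual_value=manual_value, min_size=min_size,
                                    split=watershed_before_combine)
    mask_a, obj_a = segment_channel(stack.acceptor, method=threshold_method,
                                    manual_value=manual_value, min_size=min_size,
                                    split=watershed_before_combine)

    if watershed_before_combine:
        # combine the split masks so separation lines survive into the union
        split_d = BinaryMask(obj_d.labels > 0, mask_d.method, mask_d.threshold_value)
        split_a = BinaryMask(obj_a.labels > 0, mask_a.method, mask_a.threshold_value)
        union = combine_union(split_d, split_a)
        intersection = combine_intersection(split_d, split_a)
        union_objects = label_objects(union, min_size=min_size)
    else:
        union = combine_union(mask_d, mask_a)
        intersection = combine_intersection(mask_d, mask_a)
        union_objects = watershed_split(union)
        union_objects = label_objects(union_objects.labels > 0, min_size=min_size)
    union_objects.provenance = "union"
    intersection_objects = label_objects(intersection, min_size=0)
    intersection_objects.provenance = "intersection"

    fret = compute_fret_images(stack, factors)
    image_pct, _ = coloc_area_fraction(union, intersection)

    tables = {}
    for objects in (union_objects, obj_d, obj_a, intersection_objects):
        tables[objects.provenance] = build_object_table(
            stack, fret, objects,
            intersection_mask=intersection,
            nfret_mode=nfret_mode, colormix_mode=colormix_mode,
        )

    return AnalysisResult(
        source_id=stack.source_id,
        tables=tables,
        masks={"donor": mask_d, "acceptor": mask_a,
               "union": union, "intersection": intersection},
        objects={"donor": obj_d, "acceptor": obj_a,
                 "union": union_objects, "intersection": intersection_objects},
        fret=fret,
        saturation=saturation_report(stack, tolerance=saturation_tolerance),
        whole_image_pearson=whole_image_pearson(stack.donor, stack.acceptor),
        coloc_area_fraction_pct=image_pct,
        threshold_values={"donor": mask_d.threshold_value,
                          "acceptor": mask_a.threshold_value},
    )
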