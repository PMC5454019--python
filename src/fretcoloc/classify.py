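"""Conventional deposition classification and count/percentage summaries.

Each object receives exactly one of three labels, an explicit version of
the traditional visual call on merged-color images:

* ``one_protein`` — the secondary channel's mean intensity does not rise
  above the presence threshold: only one marker is present;
* ``two_colocalizing`` — both markers present and the color-mix
  coefficient exceeds the colormix threshold (a clear yellow mix);
* ``two_combined`` — both markers present but not mixed.

Percentages are **truncated** (not rounded) to one decimal, matching the
convention of the tabulations this module reproduces (25/267 -> 9.3,
5/13 -> 38.4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEPOSITION_LABELS = ("one_protein", "two_combined", "two_colocalizing")


@dataclass
class DepositionLabel:
    object_id: int
    label: str
    group: str = ""

    def __post_init__(self) -> None:
        if self.label not in DEPOSITION_LABELS:
            raise ValueError(f"label must be one of {DEPOSITION_LABELS}")


def truncated_percentage(count: int, total: int, decimals: int = 1) -> float:
    """``100 * count / total`` truncated (floored) to ``decimals`` places."""
    if total == 0:
        return 0.0
    scale = 10**decimals
    return math.floor(100.0 * count / total * scale) / scale


def classify_object(
    record: pd.Series | dict,
    presence_threshold: float,
    colormix_threshold: float = 0.5,
    group: str = "",
) -> DepositionLabel:
    """Label one object-table row.

    The secondary channel is whichever of DF/AF has the lower object mean;
    its mean intensity must exceed ``presence_threshold`` for the object to
    count as double-labeled at all.
    """
    secondary = min(float(record["mean_DF"]), float(record["mean_AF"]))
    if secondary <= presence_threshold:
        label = "one_protein"
    elif float(record["colormix"]) > colormix_threshold:
        label = "two_colocalizing"
    else:
        label = "two_combined"
    return DepositionLabel(object_id=int(record["object_id"]), label=label, group=group)


def classify_table(
    table: pd.DataFrame,
    presence_threshold: float,
    colormix_threshold: float = 0.5,
    group: str = "",
) -> list[DepositionLabel]:
    return [
        classify_object(row, presence_threshold, colormix_threshold, group=group)
        for _, row in table.iterrows()
    ]


def tabulate(labels: list[DepositionLabel]) -> pd.DataFrame:
    """Count table per group: n_total, per-label counts, truncated percentages.

    Empty input yields an empty table.
    """
    cols = ["group", "n_total", "n_one", "n_combined", "n_coloc",
            "pct_one", "pct_combined", "pct_coloc"]
    if not labels:
        return pd.DataFrame(columns=cols)
    rows = []
    groups = sorted({lab.group for lab in labels})
    for g in groups:
        sub = [lab for lab in labels if lab.group == g]
        n = len(sub)
        n_one = sum(1 for lab in sub if lab.label == "one_protein")
        n_comb = sum(1 for lab in sub if lab.label == "two_combined")
        n_col = sum(1 for lab in sub if lab.label == "two_colocalizing")
        rows.append({
            "group": g, "n_total": n,
            "n_one": n_one, "n_combined": n_comb, "n_coloc": n_col,
            "pct_one": truncated_percentage(n_one, n),
            "pct_combined": truncated_percentage(n_comb, n),
            "pct_coloc": truncated_percentage(n_col, n),
        })
    return pd.DataFrame(rows, columns=cols)


def tabulate_counts(n_one: int, n_combined: int, n_coloc: int, group: str = "") -> pd.DataFrame:
    """Count table straight from label counts (e.g. transcribed tallies)."""
    labels = (
        [DepositionLabel(i, "one_protein", group) for i in range(n_one)]
        + [DepositionLabel(i, "two_combined", group) for i in range(n_combined)]
        + [DepositionLabel(i, "two_colocalizing", group) for i in range(n_coloc)]
    )
    return tabulate(labels)


def group_mean_pearson(table: pd.DataFrame, by: str = "source_id") -> pd.DataFrame:
    """Mean and SEM of the object Pearson coefficient per stratum.

    Undefined (NaN) coefficients are excluded; a stratum with fewer than two
    defined values gets ``sem`` NaN and is flagged.
    """
    rows = []
    for g, sub in table.groupby(by):
        vals = sub["pearson"].dropna().to_numpy()
        rows.append({
            by: g,
            "n": vals.size,
            "mean_pearson": float(vals.mean()) if vals.size else float("nan"),
            "sem_pearson": float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan"),
            "flagged": vals.size < 2,
        })
    return pd.DataFrame(rows)
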