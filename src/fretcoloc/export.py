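"""Batch execution over image manifests and CSV / cytometry export.

A batch run applies one fixed parameter set (threshold method, minimum
object size, bleed-through factors, classification thresholds) to every
triple in a manifest, writes one object table per image plus a pooled
table and a per-image summary, and logs one line per item.  A failing
item is logged and skipped; the batch carries on.  Identical config and
seed reproduce byte-identical pooled CSV output.
"""

from __future__ import annotations

import datetime
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

from .bleedthrough import (
    BleedthroughFactors,
    combine_factors,
    estimate_acceptor_factor,
    estimate_donor_factor,
)
from .fcs import write_fcs
from .io_images import load_triple
from .object_metrics import OBJECT_TABLE_COLUMNS
from .pipeline import AnalysisResult, analyze_triple
from .segmentation import ConfigError

DEFAULT_CYTOMETRY_COLUMNS = [
    "area_px", "mean_DF", "mean_AF", "mean_rawFRET", "mean_FRETc",
    "mean_NFRET", "pearson", "ad_ratio", "colormix", "coloc_area_fraction_pct",
]


class BatchError(RuntimeError):
    """The batch cannot start (bad manifest or missing calibration)."""


@dataclass
class RunConfig:
    """Everything a batch needs; loadable from YAML."""

    triples: list[dict]                      # each: donor/acceptor/rawfret paths
    output_dir: str
    bit_depth: int = 12
    threshold_method: str = "moments"
    manual_threshold: float | None = None
    min_size: int = 10
    nfret_mode: str = "pixel_mean"
    saturation_tolerance: float = 0.0
    presence_threshold: float | None = None  # default: secondary channel's threshold
    colormix_threshold: float = 0.5
    factors_file: str | None = None
    donor_control: dict | None = None        # paths of a donor-only triple
    acceptor_control: dict | None = None
    page_order: tuple[str, str, str] = ("donor", "acceptor", "rawfret")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(os.fspath(path), encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class BatchResult:
    per_image: dict[str, pd.DataFrame]
    concatenated: pd.DataFrame
    summary: pd.DataFrame
    factors: BleedthroughFactors
    log_lines: list[str] = dc_field(default_factory=list)


def write_csv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Comma-separated, '.' decimal, one header row, UTF-8, NaN -> empty field."""
    table.to_csv(os.fspath(path), index=False, na_rep="", encoding="utf-8",
                 lineterminator="\n")


def read_csv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(os.fspath(path))


def write_cytometry(
    table: pd.DataFrame,
    path: str | os.PathLike,
    numeric_columns: list[str] | None = None,
) -> str:
    """Export numeric object-table columns as FCS 3.0 plus a numeric-only CSV.

    One event per object, one parameter per column, float storage.  Returns
    the path of the CSV twin.
    """
    if numeric_columns is None:
        numeric_columns = [c for c in DEFAULT_CYTOMETRY_COLUMNS if c in table.columns]
    for col in numeric_columns:
        if col not in table.columns:
            raise ConfigError(f"column {col!r} not in the object table")
        if not pd.api.types.is_numeric_dtype(table[col]):
            raise ConfigError(f"column {col!r} is not numeric; cytometry export takes numeric data only")
    data = table[numeric_columns].to_numpy(dtype=np.float64)
    write_fcs(path, data, numeric_columns)
    csv_path = os.fspath(path)
    csv_path = csv_path[:-4] + ".csv" if csv_path.lower().endswith(".fcs") else csv_path + ".csv"
    write_csv(table[numeric_columns], csv_path)
    return csv_path


def resolve_factors(config: RunConfig) -> BleedthroughFactors:
    """Load factors from file, or estimate them from the manifest's controls."""
    if config.factors_file:
        return BleedthroughFactors.load(config.factors_file)
    if config.donor_control and config.acceptor_control:
        dctl = load_triple(bit_depth=config.bit_depth, **config.donor_control)
        actl = load_triple(bit_depth=config.bit_depth, **config.acceptor_control)
        d_frag = estimate_donor_factor(dctl, mask_method=config.threshold_method)
        a_frag = estimate_acceptor_factor(actl, mask_method=config.threshold_method)
        return combine_factors(d_frag, a_frag)
    raise BatchError(
        "no calibration available: provide factors_file or both "
        "donor_control and acceptor_control in the run config")


def _timestamp() -> str:
    return datetime.datetime.now().strftime("%Y-%m-%d %H:%M:%S")


def run_batch(config: RunConfig, write_outputs: bool = True) -> BatchResult:
    """Process every triple in the manifest with identical parameters.

    Writes ``objects_<source>.csv`` per image, ``objects_all.csv`` (pooled),
    ``summary.csv`` (one row per image) and ``batch.log`` into
    ``config.output_dir``.  Corrupt or unreadable items are logged and
    skipped without aborting the batch.
    """
    factors = resolve_factors(config)
    out_dir = config.output_dir
    if write_outputs:
        os.makedirs(out_dir, exist_ok=True)

    log: list[str] = [f"{_timestamp()} batch start: {len(config.triples)} item(s), "
                      f"seed={config.seed}, method={config.threshold_method}, "
                      f"d={factors.d:.6g}, a={factors.a:.6g}"]
    if not config.triples:
        log.append(f"{_timestamp()} WARNING empty manifest: nothing to do")

    per_image: dict[str, pd.DataFrame] = {}
    summaries = []
    for item in config.triples:
        try:
            stack = load_triple(bit_depth=config.bit_depth, **item)
            result: AnalysisResult = analyze_triple(
                stack, factors,
                threshold_method=config.threshold_method,
                manual_value=config.manual_threshold,
                min_size=config.min_size,
                nfret_mode=config.nfret_mode,
                saturation_tolerance=config.saturation_tolerance,
            )
        except Exception as exc:  # noqa: BLE001 - per-item isolation is the contract
            log.append(f"{_timestamp()} SKIP {item}: {type(exc).__name__}: {exc}")
            continue
        table = result.object_table
        per_image[result.source_id] = table
        summaries.append({
            "source_id": result.source_id,
            "n_objects": len(table),
            "whole_image_pearson": result.whole_image_pearson,
            "coloc_area_fraction_pct": result.coloc_area_fraction_pct,
            "overexposed": result.saturation.overexposed,
            "threshold_donor": result.threshold_values["donor"],
            "threshold_acceptor": result.threshold_values["acceptor"],
        })
        log.append(f"{_timestamp()} OK {result.source_id}: {len(table)} object(s), "
                   f"overexposed={result.saturation.overexposed}")
        if write_outputs:
            write_csv(table, os.path.join(out_dir, f"objects_{result.source_id}.csv"))

    concatenated = (pd.concat(per_image.values(), ignore_index=True)
                    if per_image else pd.DataFrame(columns=OBJECT_TABLE_COLUMNS))
    summary = pd.DataFrame(summaries)
    log.append(f"{_timestamp()} batch done: {len(per_image)}/{len(config.triples)} item(s) processed")

    if write_outputs:
        write_csv(concatenated, os.path.join(out_dir, "objects_all.csv"))
        write_csv(summary, os.path.join(out_dir, "summary.csv"))
        with open(os.path.join(out_dir, "batch.log"), "w", encoding="utf-8") as fh:
            fh.write("\n".join(log) + "\n")

    return BatchResult(per_image=per_image, concatenated=concatenated,
                       summary=summary, factors=factors, log_lines=log)
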