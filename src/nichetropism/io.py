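"""Readers, writers and pipeline configuration.

Formats: multi-page TIFF for stacks (pages channel-major: all Z planes of the
``wolbachia`` channel, then ``hub_marker``, then ``dna``) and label-image TIFF
for masks (0 outside, 1 hub, 2 surrounding); CSV for density tables (long
one-row-per-plane form and a per-hub summary mirroring a ratio-column
spreadsheet), trait tables and reports; newick for trees; YAML for pipeline
configuration; JSON for manifests and summaries.  An importer for multi-sheet
workbooks handles spreadsheet-shaped per-hub density data (one sheet per
host-strain pair).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .image_quant import (
    CHANNEL_DNA,
    CHANNEL_HUB_MARKER,
    CHANNEL_WOLBACHIA,
    HubDensityTable,
    ImageStack,
    MaskSet,
    classify_tropism,
)

__all__ = [
    "CHANNEL_ORDER",
    "SCHEMA_VERSION",
    "write_stack",
    "read_stack",
    "write_masks",
    "read_masks",
    "write_density_table",
    "read_density_table",
    "write_hub_summary",
    "read_hub_summary",
    "read_workbook_density",
    "read_traits",
    "write_traits",
    "write_report",
    "read_report",
    "PipelineConfig",
    "write_manifest",
]

#: Fixed channel order of stack TIFF pages.
CHANNEL_ORDER = (CHANNEL_WOLBACHIA, CHANNEL_HUB_MARKER, CHANNEL_DNA)

#: Version tag written into every report.
SCHEMA_VERSION = "nichetropism-report-1"

_PLANES_COLUMNS = ["line_id", "hub_id", "plane", "hub_density", "surround_density"]


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page TIFF, channel-major page order."""
    pages = np.stack([stack.channel(c) for c in CHANNEL_ORDER if c in stack.channels])
    tifffile.imwrite(str(path), pages.astype(np.float32), imagej=False)


def read_stack(path, channel_order: tuple[str, ...] = CHANNEL_ORDER) -> ImageStack:
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:  # single channel
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"expected (channel, z, y, x) TIFF, got shape {arr.shape}")
    if arr.shape[0] > len(channel_order):
        raise ValueError(
            f"stack has {arr.shape[0]} channels but only {len(channel_order)} names"
        )
    return ImageStack(
        channels={channel_order[i]: arr[i] for i in range(arr.shape[0])}
    )


def write_masks(masks: MaskSet, path) -> None:
    """Write masks as a label-image TIFF: 0 outside, 1 hub, 2 surrounding."""
    tifffile.imwrite(str(path), masks.to_labels())


def read_masks(path) -> MaskSet:
    return MaskSet.from_labels(tifffile.imread(str(path)))


def write_density_table(table: HubDensityTable, path) -> None:
    """Write the long one-row-per-plane form."""
    table.planes_frame().to_csv(path, index=False)


def read_density_table(
    path, threshold: float = 1.5, aggregation: str = "ratio_of_means"
) -> HubDensityTable:
    """Read and validate a long-form density table.

    Ratios and tropism labels are recomputed from the per-plane columns, so a
    stored ratio column can never disagree with the planes.  Malformed rows
    are reported with their line numbers (header = line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _PLANES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    offenses = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header occupies line 1
        for col in ("hub_density", "surround_density"):
            v = row[col]
            if pd.isna(v):
                offenses.append(f"line {lineno}: missing {col}")
            elif v < 0:
                offenses.append(f"line {lineno}: negative {col} ({v})")
    dup_planes = df.duplicated(subset=["line_id", "hub_id", "plane"])
    for idx in df.index[dup_planes]:
        offenses.append(f"line {idx + 2}: duplicate (line_id, hub_id, plane)")
    if offenses:
        raise ValueError(f"{path}: malformed rows:\n" + "\n".join(offenses))
    return HubDensityTable.from_planes_frame(
        df, threshold=threshold, aggregation=aggregation
    )


def write_hub_summary(table: HubDensityTable, path) -> None:
    """Write the per-hub summary (one row per hub with its ratio)."""
    table.hub_frame().to_csv(path, index=False)


def read_hub_summary(path, threshold: float = 1.5) -> pd.DataFrame:
    """Read a per-hub summary and recompute tropism labels from the ratios."""
    df = pd.read_csv(path)
    for col in ("line_id", "hub_id", "ratio"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df.duplicated(subset=["line_id", "hub_id"]).any():
        raise ValueError(f"{path}: duplicate (line_id, hub_id) pairs")
    df = df.copy()
    df["tropism"] = [
        classify_tropism(r, threshold) if np.isfinite(r) else None
        for r in df["ratio"].astype(float)
    ]
    return df


def read_workbook_density(
    path, threshold: float = 1.5, aggregation: str = "ratio_of_means"
) -> HubDensityTable:
    """Import a multi-sheet workbook of per-hub densities.

    One sheet per host-strain pair (the sheet name is the line id); each sheet
    carries the long-form columns ``hub_id, plane, hub_density,
    surround_density``.  Ratios are recomputed per hub.
    """
    sheets = pd.read_excel(path, sheet_name=None)
    frames = []
    for name, sheet in sheets.items():
        needed = {"hub_id", "plane", "hub_density", "surround_density"}
        if not needed <= set(sheet.columns):
            raise ValueError(
                f"sheet {name!r}: missing columns {sorted(needed - set(sheet.columns))}"
            )
        sheet = sheet.copy()
        sheet["line_id"] = name
        frames.append(sheet[_PLANES_COLUMNS])
    if not frames:
        raise ValueError("workbook has no sheets")
    return HubDensityTable.from_planes_frame(
        pd.concat(frames, ignore_index=True),
        threshold=threshold,
        aggregation=aggregation,
    )


def read_traits(path) -> pd.DataFrame:
    """Read a trait table: ``leaf_label`` plus ``frequency_percent`` and/or
    ``state``."""
    df = pd.read_csv(path)
    if "leaf_label" not in df.columns:
        raise ValueError(f"{path}: missing column 'leaf_label'")
    if "frequency_percent" not in df.columns and "state" not in df.columns:
        raise ValueError(f"{path}: need 'frequency_percent' or 'state'")
    return df


def write_traits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _jsonable(value):
    if isinstance(value, pd.DataFrame):
        return {"__frame__": value.to_dict(orient="list")}
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def write_report(results: Mapping, path, format: str = "json") -> None:
    """Write a result bundle with stable ordering and a schema tag.

    JSON keeps nested structure (DataFrames become column dictionaries); CSV
    flattens scalar values to ``key,value`` rows and writes each DataFrame to
    a sibling ``<stem>.<key>.csv`` file.
    """
    path = Path(path)
    if format == "json":
        payload = {"schema": SCHEMA_VERSION}
        payload.update({k: _jsonable(results[k]) for k in sorted(results)})
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "csv":
        rows = [("schema", SCHEMA_VERSION)]
        for key in sorted(results):
            value = results[key]
            if isinstance(value, pd.DataFrame):
                value.to_csv(path.with_suffix(f".{key}.csv"), index=False)
            else:
                rows.append((key, _jsonable(value)))
        pd.DataFrame(rows, columns=["key", "value"]).to_csv(path, index=False)
    else:
        raise ValueError("format must be 'json' or 'csv'")


def read_report(path) -> dict:
    """Read back a JSON report, restoring DataFrames to full precision."""
    payload = json.loads(Path(path).read_text())

    def restore(value):
        if isinstance(value, dict):
            if "__frame__" in value:
                return pd.DataFrame(value["__frame__"])
            return {k: restore(v) for k, v in value.items()}
        return value

    return {k: restore(v) for k, v in payload.items()}


@dataclass
class PipelineConfig:
    """End-to-end run configuration with study defaults.

    ``threshold`` (1.5-fold), ``n_random`` (1000 random characters) and
    ``alpha`` (0.05) default to the study's stated values.  ``simulate``
    describes synthetic cohorts (list of per-line dictionaries accepted by
    :func:`nichetropism.synthetic_data.simulate_density_table`); alternatively
    ``density_table`` points at an existing long-form CSV.
    """

    output_dir: str = "nichetropism_out"
    threshold: float = 1.5
    n_random: int = 1000
    alpha: float = 0.05
    seed: int = 0
    null_model: str = "permutation"
    ci_method: str = "wilson"
    aggregation: str = "ratio_of_means"
    density_table: str | None = None
    tree: str | None = None
    traits: str | None = None
    simulate: list[dict] = field(default_factory=list)
    use_bundled_phylogeny: bool = False

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(config: PipelineConfig, path, extra: Mapping | None = None) -> None:
    """Record everything needed to reproduce a run."""
    manifest = {
        "package": "nichetropism",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(_jsonable(dict(extra)))
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
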