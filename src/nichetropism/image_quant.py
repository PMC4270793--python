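"""Mask-based density quantification of intracellular bacteria in confocal Z-stacks.

The measurement model mirrors standard ROI densitometry: within each Z plane a
*density* is the summed pixel intensity of the bacterial channel inside a mask
divided by the mask area (intensity per pixel, arbitrary grayscale units).  A
hub is scored across at least three planes; its hub/surrounding density ratio
is the quantity of interest, and a ratio of at least 1.5 classifies the hub as
showing niche tropism.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

#: Default fold-increase of hub over surrounding density that counts as tropism.
TROPISM_THRESHOLD = 1.5

#: Minimum number of Z planes expected per hub; fewer triggers a warning.
MIN_PLANES = 3

CHANNEL_WOLBACHIA = "wolbachia"
CHANNEL_HUB_MARKER = "hub_marker"
CHANNEL_DNA = "dna"


class FewPlanesWarning(UserWarning):
    """A hub was measured on fewer Z planes than the recommended minimum."""


@dataclass
class ImageStack:
    """Multi-channel 3-D intensity grid.

    Parameters
    ----------
    channels
        Mapping of channel name (e.g. ``"wolbachia"``, ``"hub_marker"``,
        ``"dna"``) to a ``(z, y, x)`` array of non-negative intensities in
        arbitrary grayscale units.
    voxel_spacing
        Optional physical spacing per axis; carried as metadata only.
    """

    channels: Mapping[str, np.ndarray]
    voxel_spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageStack requires at least one channel")
        channels = {}
        shape = None
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} must be 3-D (z, y, x), got {arr.ndim}-D")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"channel {name!r} shape {arr.shape} differs from {shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            channels[name] = arr
        object.__setattr__(self, "channels", channels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_planes(self) -> int:
        return self.shape[0]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {sorted(self.channels)}"
            ) from None


@dataclass
class MaskSet:
    """Per-Z-plane hub and surrounding-tissue pixel masks.

    Masks are boolean ``(z, y, x)`` volumes; a plane's mask is its 2-D slice.
    Hub and surrounding masks must be disjoint, and the hub mask must be
    non-empty in at least one plane.
    """

    hub: np.ndarray
    surround: np.ndarray

    LABEL_HUB = 1
    LABEL_SURROUND = 2

    def __post_init__(self) -> None:
        hub = np.asarray(self.hub, dtype=bool)
        surround = np.asarray(self.surround, dtype=bool)
        if hub.ndim != 3 or surround.ndim != 3:
            raise ValueError("masks must be 3-D (z, y, x)")
        if hub.shape != surround.shape:
            raise ValueError("hub and surround masks must share one shape")
        if np.any(hub & surround):
            raise ValueError("hub and surrounding masks overlap")
        if not hub.any():
            raise ValueError("hub mask is empty in every plane")
        object.__setattr__(self, "hub", hub)
        object.__setattr__(self, "surround", surround)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hub.shape

    def to_labels(self) -> np.ndarray:
        """Encode as a label image: 0 outside, 1 hub, 2 surrounding."""
        labels = np.zeros(self.shape, dtype=np.uint8)
        labels[self.hub] = self.LABEL_HUB
        labels[self.surround] = self.LABEL_SURROUND
        return labels

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "MaskSet":
        labels = np.asarray(labels)
        return cls(hub=labels == cls.LABEL_HUB, surround=labels == cls.LABEL_SURROUND)


@dataclass
class HubDensityRecord:
    """Per-hub densitometry: per-plane densities and the hub/surrounding ratio.

    ``ratio`` is NaN (and ``tropism`` None) when the mean surrounding density
    is zero; such hubs are excluded from frequency denominators.
    """

    line_id: str
    hub_id: str
    planes: tuple[int, ...]
    hub_densities: tuple[float, ...]
    surround_densities: tuple[float, ...]
    ratio: float
    tropism: bool | None

    @property
    def ratio_defined(self) -> bool:
        return math.isfinite(self.ratio)


class HubDensityTable:
    """Ordered collection of :class:`HubDensityRecord`, grouped by line.

    The long (one-row-per-plane) and per-hub summary views are exposed as
    pandas DataFrames; ``(line_id, hub_id)`` pairs are unique.
    """

    def __init__(self, records: Iterable[HubDensityRecord]):
        self.records = list(records)
        seen = set()
        for rec in self.records:
            key = (rec.line_id, rec.hub_id)
            if key in seen:
                raise ValueError(f"duplicate (line_id, hub_id) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def line_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.line_id not in out:
                out.append(rec.line_id)
        return out

    def for_line(self, line_id: str) -> list[HubDensityRecord]:
        recs = [r for r in self.records if r.line_id == line_id]
        if not recs:
            raise KeyError(f"no records for line {line_id!r}")
        return recs

    def planes_frame(self) -> pd.DataFrame:
        """Long form: one row per (hub, plane)."""
        rows = []
        for rec in self.records:
            for z, h, s in zip(rec.planes, rec.hub_densities, rec.surround_densities):
                rows.append(
                    {
                        "line_id": rec.line_id,
                        "hub_id": rec.hub_id,
                        "plane": z,
                        "hub_density": h,
                        "surround_density": s,
                        "ratio": rec.ratio,
                        "tropism": rec.tropism,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "line_id",
                "hub_id",
                "plane",
                "hub_density",
                "surround_density",
                "ratio",
                "tropism",
            ],
        )

    def hub_frame(self) -> pd.DataFrame:
        """Per-hub summary mirroring a hub-density spreadsheet's ratio column."""
        rows = [
            {
                "line_id": rec.line_id,
                "hub_id": rec.hub_id,
                "n_planes": len(rec.planes),
                "mean_hub_density": float(np.mean(rec.hub_densities)),
                "mean_surround_density": float(np.mean(rec.surround_densities)),
                "ratio": rec.ratio,
                "tropism": rec.tropism,
            }
            for rec in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "line_id",
                "hub_id",
                "n_planes",
                "mean_hub_density",
                "mean_surround_density",
                "ratio",
                "tropism",
            ],
        )

    @classmethod
    def from_planes_frame(
        cls,
        frame: pd.DataFrame,
        threshold: float = TROPISM_THRESHOLD,
        aggregation: str = "ratio_of_means",
    ) -> "HubDensityTable":
        """Rebuild records from the long per-plane form, recomputing ratios."""
        required = {"line_id", "hub_id", "plane", "hub_density", "surround_density"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        records = []
        for (line_id, hub_id), grp in frame.groupby(["line_id", "hub_id"], sort=False):
            records.append(
                _record_from_densities(
                    str(line_id),
                    str(hub_id),
                    grp["plane"].to_numpy(),
                    grp["hub_density"].to_numpy(float),
                    grp["surround_density"].to_numpy(float),
                    threshold=threshold,
                    aggregation=aggregation,
                )
            )
        return cls(records)


@dataclass
class FrequencyEstimate:
    """Tropism frequency for one line: ``100 * k / n`` percent with a 95% CI."""

    k: int
    n: int
    frequency: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.n:
            raise ValueError("require 0 <= k <= n")
        lo, hi = self.ci95
        if not (0.0 <= lo <= self.frequency <= hi <= 100.0):
            raise ValueError("confidence bounds must bracket the frequency in [0, 100]")


def plane_density(
    stack: ImageStack, mask: np.ndarray, channel: str, z: int
) -> float:
    """Mean intensity per pixel of ``channel`` within ``mask`` at plane ``z``.

    This is summed pixel intensity divided by mask area, the per-plane density
    used throughout.
    """
    arr = stack.channel(channel)
    if not 0 <= z < arr.shape[0]:
        raise IndexError(f"plane {z} out of range for stack with {arr.shape[0]} planes")
    mask = np.asarray(mask, dtype=bool)
    plane_mask = mask[z] if mask.ndim == 3 else mask
    if plane_mask.shape != arr.shape[1:]:
        raise ValueError("mask plane shape does not match stack planes")
    area = int(plane_mask.sum())
    if area == 0:
        raise ValueError(f"mask is empty at plane {z}")
    return float(arr[z][plane_mask].sum() / area)


def classify_tropism(ratio: float, threshold: float = TROPISM_THRESHOLD) -> bool:
    """True iff the hub/surrounding density ratio is at least ``threshold``.

    The boundary is inclusive: a 1.5-fold increase counts as tropism.
    """
    if not math.isfinite(ratio):
        raise ValueError("ratio is undefined (non-finite)")
    if ratio < 0:
        raise ValueError("density ratio must be non-negative")
    return ratio >= threshold


def _aggregate_ratio(
    hub: np.ndarray, surround: np.ndarray, aggregation: str
) -> float:
    if aggregation == "ratio_of_means":
        denom = float(np.mean(surround))
        return float(np.mean(hub)) / denom if denom > 0 else float("nan")
    if aggregation == "mean_of_ratios":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.asarray(hub, float) / np.asarray(surround, float)
        if not np.all(np.isfinite(ratios)):
            return float("nan")
        return float(np.mean(ratios))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def _record_from_densities(
    line_id: str,
    hub_id: str,
    planes: Sequence[int],
    hub_densities: np.ndarray,
    surround_densities: np.ndarray,
    threshold: float = TROPISM_THRESHOLD,
    aggregation: str = "ratio_of_means",
) -> HubDensityRecord:
    if len(planes) < 1:
        raise ValueError(f"hub {hub_id!r}: at least one plane required")
    if len(planes) < MIN_PLANES:
        warnings.warn(
            f"hub {hub_id!r} of line {line_id!r} measured on {len(planes)} plane(s); "
            f"at least {MIN_PLANES} are recommended",
            FewPlanesWarning,
            stacklevel=3,
        )
    if np.any(np.asarray(hub_densities) < 0) or np.any(np.asarray(surround_densities) < 0):
        raise ValueError(f"hub {hub_id!r}: negative densities")
    ratio = _aggregate_ratio(hub_densities, surround_densities, aggregation)
    if math.isfinite(ratio):
        tropism: bool | None = classify_tropism(ratio, threshold)
    else:
        tropism = None
        logger.warning(
            "hub %s of line %s: zero surrounding density; ratio undefined, "
            "record excluded from frequency",
            hub_id,
            line_id,
        )
    return HubDensityRecord(
        line_id=line_id,
        hub_id=hub_id,
        planes=tuple(int(z) for z in planes),
        hub_densities=tuple(float(h) for h in hub_densities),
        surround_densities=tuple(float(s) for s in surround_densities),
        ratio=ratio,
        tropism=tropism,
    )


def hub_density_record(
    stack: ImageStack,
    masks: MaskSet,
    line_id: str,
    hub_id: str,
    channel: str = CHANNEL_WOLBACHIA,
    threshold: float = TROPISM_THRESHOLD,
    aggregation: str = "ratio_of_means",
) -> HubDensityRecord:
    """Measure one hub: per-plane densities in both masks and their ratio.

    Planes where either mask is empty are skipped.  The default aggregation
    divides the mean of per-plane hub densities by the mean of per-plane
    surrounding densities (one ratio per hub); ``aggregation="mean_of_ratios"``
    averages per-plane ratios instead.
    """
    if masks.shape != stack.shape:
        raise ValueError("mask volume shape does not match stack shape")
    planes, hubs, surrounds = [], [], []
    for z in range(stack.n_planes):
        if masks.hub[z].any() and masks.surround[z].any():
            planes.append(z)
            hubs.append(plane_density(stack, masks.hub, channel, z))
            surrounds.append(plane_density(stack, masks.surround, channel, z))
    if not planes:
        raise ValueError("no plane has both a non-empty hub and surrounding mask")
    return _record_from_densities(
        line_id,
        hub_id,
        planes,
        np.asarray(hubs),
        np.asarray(surrounds),
        threshold=threshold,
        aggregation=aggregation,
    )


def tropism_frequency(
    table: HubDensityTable, line_id: str, ci_method: str = "wilson"
) -> FrequencyEstimate:
    """Percent of a line's hubs classified tropism-positive, with a 95% CI.

    Hubs whose ratio is undefined (zero surrounding density) are excluded from
    both numerator and denominator.  The default interval is the Wilson score
    interval, which is well behaved at 0% and 100%.
    """
    recs = [r for r in table.for_line(line_id) if r.ratio_defined]
    if not recs:
        raise ValueError(f"line {line_id!r} has no records with a defined ratio")
    n = len(recs)
    k = sum(1 for r in recs if r.tropism)
    lo, hi = proportion_confint(k, n, alpha=0.05, method=ci_method)
    # guard against float roundoff at the 0%/100% boundaries
    lo = min(max(float(lo), 0.0), k / n)
    hi = max(min(float(hi), 1.0), k / n)
    return FrequencyEstimate(
        k=k, n=n, frequency=100.0 * k / n, ci95=(100.0 * lo, 100.0 * hi)
    )


def mean_density_ratio(table: HubDensityTable, line_id: str) -> tuple[float, float]:
    """Arithmetic mean of a line's per-hub density ratios and its SEM."""
    ratios = np.array(
        [r.ratio for r in table.for_line(line_id) if r.ratio_defined], dtype=float
    )
    if ratios.size == 0:
        raise ValueError(f"line {line_id!r} has no defined ratios")
    mean = float(ratios.mean())
    sem = float(ratios.std(ddof=1) / math.sqrt(ratios.size)) if ratios.size > 1 else 0.0
    return mean, sem
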