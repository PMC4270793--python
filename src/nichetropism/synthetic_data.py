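"""Seeded synthetic inputs for every pipeline stage.

Three generators, all deterministic under a fixed seed:

* :func:`simulate_stack` — a confocal-like Z-stack with punctate bacterial
  fluorescence.  Puncta are single-voxel point emitters drawn per voxel from a
  Poisson law (``lambda_hub`` inside an ellipsoidal hub, ``lambda_surround``
  inside a surrounding shell), scaled to a fixed amplitude, convolved with a
  Gaussian point-spread function, offset by a constant background and
  optionally degraded by shot and read noise.  The generating masks and rates
  are returned as exact ground truth.
* :func:`simulate_density_table` — a per-hub density table in the same schema
  the quantification stage emits: per-plane hub and surrounding densities
  whose aggregated ratio scatters around a configurable true-ratio
  distribution.
* :func:`simulate_character` — discrete tropism-like characters on a
  phylogeny, either by uniform permutation of a fixed state multiset (the
  randomization-test null) or under a symmetric k-state Markov (Mk) process
  with tunable rate, which interpolates from perfect phylogenetic signal
  (rate 0) to none (rate → ∞).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import dendropy
import numpy as np
from scipy import ndimage

from .image_quant import (
    CHANNEL_DNA,
    CHANNEL_HUB_MARKER,
    CHANNEL_WOLBACHIA,
    FewPlanesWarning,
    HubDensityTable,
    ImageStack,
    MaskSet,
    MIN_PLANES,
    _record_from_densities,
)

__all__ = [
    "SyntheticStackSpec",
    "GroundTruth",
    "TraitSimSpec",
    "simulate_stack",
    "simulate_density_table",
    "simulate_character",
]


@dataclass(frozen=True)
class SyntheticStackSpec:
    """Parameters of one synthetic Z-stack.

    The hub is an ellipsoid (``hub_center``, ``hub_radii`` in voxels); the
    surrounding tissue is an ellipsoidal shell of thickness
    ``surround_thickness`` separated from the hub by a guard gap of
    ``surround_gap`` voxels so that blur from the bright region does not leak
    into the surround measurement.  Rates are expected puncta per voxel.

    The *measurement* masks returned by :func:`simulate_stack` cover only the
    Z planes whose hub cross-section is at least ``mask_plane_fraction`` of
    the maximal cross-section — the analogue of an experimenter placing masks
    on a few planes well within the niche rather than on the blur-darkened
    ellipsoid caps.  Set ``mask_plane_fraction=0`` to measure every plane; the
    full generating regions are always available in the ground truth.
    """

    shape_zyx: tuple[int, int, int] = (16, 96, 96)
    hub_center: tuple[float, float, float] | None = None
    hub_radii: tuple[float, float, float] = (5.0, 14.0, 14.0)
    surround_gap: float = 6.0
    surround_thickness: float = 10.0
    lambda_hub: float = 0.25
    lambda_surround: float = 0.25
    punctum_amplitude: float = 200.0
    psf_sigma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    psf_truncate: float = 3.0
    background_level: float = 0.0
    noise_model: Literal["none", "poisson", "poisson+gaussian"] = "poisson"
    gaussian_sd: float = 0.0
    mask_plane_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(d) < 1 for d in self.shape_zyx):
            raise ValueError("all stack dimensions must be >= 1")
        if self.lambda_hub < 0 or self.lambda_surround < 0:
            raise ValueError("puncta rates must be non-negative")
        if any(r <= 0 for r in self.hub_radii):
            raise ValueError("hub radii must be positive")
        if self.surround_gap < 0 or self.surround_thickness <= 0:
            raise ValueError("surround gap must be >= 0 and thickness > 0")
        if self.noise_model not in ("none", "poisson", "poisson+gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if not 0.0 <= self.mask_plane_fraction <= 1.0:
            raise ValueError("mask_plane_fraction must lie in [0, 1]")

    @property
    def center(self) -> tuple[float, float, float]:
        if self.hub_center is not None:
            return self.hub_center
        return tuple((d - 1) / 2.0 for d in self.shape_zyx)

    @property
    def true_ratio(self) -> float:
        if self.lambda_surround == 0:
            return float("inf") if self.lambda_hub > 0 else float("nan")
        return self.lambda_hub / self.lambda_surround


@dataclass
class GroundTruth:
    """Exact generative state of a simulated stack."""

    true_ratio: float
    hub_counts: np.ndarray
    surround_counts: np.ndarray
    hub_mask: np.ndarray
    surround_mask: np.ndarray

    @property
    def n_hub_puncta(self) -> int:
        return int(self.hub_counts.sum())

    @property
    def n_surround_puncta(self) -> int:
        return int(self.surround_counts.sum())


def _ellipsoid_mask(
    shape: Sequence[int], center: Sequence[float], radii: Sequence[float]
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in shape)]
    dist2 = sum(
        ((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)
    )
    return dist2 <= 1.0


def region_masks(spec: SyntheticStackSpec) -> tuple[np.ndarray, np.ndarray]:
    """Hub ellipsoid and surrounding shell, guaranteed disjoint."""
    hub = _ellipsoid_mask(spec.shape_zyx, spec.center, spec.hub_radii)
    inner = _ellipsoid_mask(
        spec.shape_zyx,
        spec.center,
        tuple(r + spec.surround_gap for r in spec.hub_radii),
    )
    outer = _ellipsoid_mask(
        spec.shape_zyx,
        spec.center,
        tuple(r + spec.surround_gap + spec.surround_thickness for r in spec.hub_radii),
    )
    surround = outer & ~inner
    if not hub.any():
        raise ValueError("hub region is empty; enlarge the stack or radii")
    if not surround.any():
        raise ValueError("surrounding region is empty; enlarge the stack")
    if np.any(hub & surround):  # geometry guarantees this, but fail loudly
        raise ValueError("hub and surrounding regions overlap")
    return hub, surround


def simulate_stack(
    spec: SyntheticStackSpec,
) -> tuple[ImageStack, MaskSet, GroundTruth]:
    """Render one synthetic stack with exact ground truth.

    Per-voxel punctum counts are Poisson at the region's rate; the emission
    image (counts × amplitude) is blurred by the PSF, the background added and
    the chosen noise applied.  The hub-marker channel is a flat fill of the hub
    region; the DNA channel a dim uniform field.  The returned
    :class:`~nichetropism.image_quant.MaskSet` equals the generating regions
    on the central planes selected by ``mask_plane_fraction``; the full
    regions are in the :class:`GroundTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    hub_mask, surround_mask = region_masks(spec)

    counts = np.zeros(spec.shape_zyx, dtype=np.int64)
    counts[hub_mask] = rng.poisson(spec.lambda_hub, size=int(hub_mask.sum()))
    counts[surround_mask] = rng.poisson(
        spec.lambda_surround, size=int(surround_mask.sum())
    )

    emission = counts.astype(float) * spec.punctum_amplitude
    blurred = ndimage.gaussian_filter(
        emission, sigma=spec.psf_sigma, truncate=spec.psf_truncate, mode="constant"
    )
    signal = blurred + spec.background_level

    if spec.noise_model == "none":
        wolb = signal
    else:
        wolb = rng.poisson(signal).astype(float)
        if spec.noise_model == "poisson+gaussian" and spec.gaussian_sd > 0:
            wolb = wolb + rng.normal(0.0, spec.gaussian_sd, size=wolb.shape)
    wolb = np.clip(wolb, 0.0, None)

    hub_marker = hub_mask.astype(float) * spec.punctum_amplitude
    dna = np.full(spec.shape_zyx, 0.05 * spec.punctum_amplitude)

    stack = ImageStack(
        channels={
            CHANNEL_WOLBACHIA: wolb,
            CHANNEL_HUB_MARKER: hub_marker,
            CHANNEL_DNA: dna,
        }
    )
    # measurement masks: central planes only (see SyntheticStackSpec docs)
    areas = hub_mask.sum(axis=(1, 2))
    keep = areas >= spec.mask_plane_fraction * areas.max()
    meas_hub = hub_mask.copy()
    meas_surround = surround_mask.copy()
    meas_hub[~keep] = False
    meas_surround[~keep] = False
    masks = MaskSet(hub=meas_hub, surround=meas_surround)
    truth = GroundTruth(
        true_ratio=spec.true_ratio,
        hub_counts=counts * hub_mask,
        surround_counts=counts * surround_mask,
        hub_mask=hub_mask,
        surround_mask=surround_mask,
    )
    return stack, masks, truth


def simulate_density_table(
    n_hubs: int,
    ratio_distribution: tuple[float, float, str] = (1.5, 0.5, "lognormal"),
    planes_per_hub: int = 4,
    seed: int = 0,
    line_id: str = "synthetic",
    surround_level: float = 10.0,
    plane_noise: float = 0.05,
    threshold: float = 1.5,
) -> HubDensityTable:
    """Draw a per-hub density table with between-hub ratio variability.

    ``ratio_distribution`` is ``(location, spread, family)`` with family
    ``"normal"`` (mean/sd, truncated at 0) or ``"lognormal"`` (median /
    sd-of-log).  Each hub receives ``planes_per_hub`` planes of surrounding
    density around ``surround_level`` and hub density around
    ``true_ratio × surround_level``, with multiplicative per-plane noise; the
    ratio column is then recomputed from the planes by the same aggregation
    rule the quantification stage uses, so table and planes are always
    self-consistent.
    """
    if n_hubs < 1:
        raise ValueError("n_hubs must be >= 1")
    if planes_per_hub < 1:
        raise ValueError("planes_per_hub must be >= 1")
    if planes_per_hub < MIN_PLANES:
        warnings.warn(
            f"planes_per_hub={planes_per_hub} is below the recommended minimum of "
            f"{MIN_PLANES}",
            FewPlanesWarning,
            stacklevel=2,
        )
    loc, spread, family = ratio_distribution
    rng = np.random.default_rng(seed)
    if family == "normal":
        true_ratios = np.clip(rng.normal(loc, spread, size=n_hubs), 0.0, None)
    elif family == "lognormal":
        true_ratios = loc * np.exp(rng.normal(0.0, spread, size=n_hubs)) if spread > 0 else np.full(n_hubs, float(loc))
    else:
        raise ValueError(f"unknown ratio distribution family {family!r}")

    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FewPlanesWarning)
        for i, r in enumerate(true_ratios):
            if plane_noise > 0:
                s = surround_level * np.exp(
                    rng.normal(0.0, plane_noise, size=planes_per_hub)
                )
                h = r * surround_level * np.exp(
                    rng.normal(0.0, plane_noise, size=planes_per_hub)
                )
            else:
                s = np.full(planes_per_hub, surround_level)
                h = r * s
            records.append(
                _record_from_densities(
                    line_id,
                    f"hub{i + 1:03d}",
                    planes=list(range(planes_per_hub)),
                    hub_densities=h,
                    surround_densities=s,
                    threshold=threshold,
                )
            )
    return HubDensityTable(records)


def normal_tail_mass(loc: float, spread: float, threshold: float = 1.5) -> float:
    """P(ratio >= threshold) for the truncated-normal ratio family.

    Closed form used as the expected tropism frequency of a simulated cohort.
    """
    from scipy.stats import norm

    if spread == 0:
        return float(loc >= threshold)
    return float(norm.sf(threshold, loc=loc, scale=spread))


@dataclass(frozen=True)
class TraitSimSpec:
    """How to simulate a discrete character on a tree.

    ``model="permutation"`` shuffles a fixed multiset of tip states uniformly
    at random (the null of the randomization test); ``model="mk"`` evolves the
    character from a uniformly chosen root state under the symmetric k-state
    Markov model at ``rate`` expected substitutions per unit branch length.
    """

    model: Literal["permutation", "mk"] = "permutation"
    n_states: int = 3
    rate: float = 1.0
    state_multiset: Mapping[str, int] | None = None
    states: tuple[str, ...] = ("low", "moderate", "high")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.model not in ("permutation", "mk"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "permutation" and self.state_multiset is None:
            raise ValueError("permutation model requires a state_multiset")


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    labels = [
        lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None
    ]
    if not labels:
        raise ValueError("tree has no labeled leaves")
    return labels


def _mk_stay_probability(k: int, rate: float, t: float) -> float:
    # Symmetric k-state model: total leaving rate = rate, uniform over targets.
    if not math.isfinite(t):
        return 1.0 / k
    return 1.0 / k + (1.0 - 1.0 / k) * math.exp(-k * rate * t / (k - 1))


def simulate_character(
    tree: dendropy.Tree, spec: TraitSimSpec, rng: np.random.Generator | None = None
) -> dict[str, str]:
    """One simulated tip-state assignment on ``tree`` under ``spec``.

    Permutation draws conserve the state multiset exactly for every draw; Mk
    draws start from a uniform root state and transition independently along
    each branch (branch length defaults to 1 where absent).
    """
    labels = _leaf_labels(tree)
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    if spec.model == "permutation":
        pool: list[str] = []
        for state, count in spec.state_multiset.items():
            if count < 0:
                raise ValueError("state counts must be non-negative")
            pool.extend([state] * int(count))
        if len(pool) != len(labels):
            raise ValueError(
                f"state multiset size {len(pool)} does not match leaf count {len(labels)}"
            )
        perm = rng.permutation(len(pool))
        return {labels[i]: pool[perm[i]] for i in range(len(labels))}

    # Mk model
    states = list(spec.states[: spec.n_states])
    if len(states) < spec.n_states:
        states = [f"s{i}" for i in range(spec.n_states)]
    k = spec.n_states
    assignment: dict[str, str] = {}
    root = tree.seed_node
    node_state: dict[int, int] = {id(root): int(rng.integers(k))}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        parent = node_state[id(edge.tail_node)]
        t = edge.length if edge.length is not None else 1.0
        stay = _mk_stay_probability(k, spec.rate, t)
        if rng.random() < stay:
            child = parent
        else:
            child = int(rng.integers(k - 1))
            if child >= parent:
                child += 1
        node_state[id(edge.head_node)] = child
    for leaf in tree.leaf_node_iter():
        assignment[leaf.taxon.label] = states[node_state[id(leaf)]]
    return assignment
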