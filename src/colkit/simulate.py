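"""Multi-run t-value map simulation with planted tuning, noise and vessels.

The generator plants three voxel classes on a patch geometry:

* **tuned** voxels respond with mean ``amp_pref`` t-units to their true
  preferred condition (taken from a planted preference map) and
  ``amp_nonpref`` to the others;
* **untuned** voxels have mean 0 for every condition;
* **vessel** voxels respond with mean ``vessel_amp`` to every condition —
  the high-sensitivity / low-specificity signature of draining veins.
  They are seeded as contiguous UV discs confined to superficial depths
  (D >= 0.6) to mimic pial-surface contamination.

Each run adds i.i.d. Gaussian noise of standard deviation ``noise_sd`` per
voxel and condition: sub-millimeter acquisitions are thermal-noise
dominated, and no spatial covariance (point-spread) structure is modeled.
t-values are simulated directly; no time series or GLM fitting is
involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PatchGeometry, PreferenceMap

__all__ = [
    "ResponseMap",
    "SimulationConfig",
    "CLASS_TUNED",
    "CLASS_UNTUNED",
    "CLASS_VESSEL",
    "simulate_runs",
    "average_runs",
]

CLASS_TUNED = 1
CLASS_UNTUNED = 2
CLASS_VESSEL = 3


@dataclass
class ResponseMap:
    """Per-voxel K-vector of condition t-values (shape dims + (K,))."""

    values: np.ndarray
    run_id: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be a 4D (x, y, z, condition) array")
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[-1]

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.values.shape[:3])


@dataclass
class SimulationConfig:
    """Effect sizes and nuisance structure of the simulated experiment.

    All amplitudes are in t-units.  Defaults give tuned voxels a
    preferred-vs-nonpreferred contrast of four noise standard deviations
    over four runs — a strong but realistic mesoscopic effect — with a
    small admixture of vessel and untuned voxels.
    """

    amp_pref: float = 5.0
    amp_nonpref: float = 1.0
    noise_sd: float = 1.0
    vessel_fraction: float = 0.05
    vessel_amp: float = 8.0
    untuned_fraction: float = 0.10
    n_runs: int = 4
    seed: int = 0
    vessel_blob_radius: float = 1.0  # mm, UV disc radius of one vessel blob
    vessel_min_depth: float = 0.6  # vessels confined to D >= this

    def validate(self) -> None:
        if not (0.0 <= self.vessel_fraction + self.untuned_fraction <= 1.0):
            raise ValueError("vessel_fraction + untuned_fraction must be in [0, 1]")
        if self.vessel_fraction < 0 or self.untuned_fraction < 0:
            raise ValueError("fractions must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def _assign_classes(
    geom: PatchGeometry, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Class volume: 0 outside GM, else tuned/untuned/vessel codes."""
    classes = np.zeros(geom.dims, dtype=np.int8)
    classes[geom.gm_mask] = CLASS_TUNED
    gm_idx = np.argwhere(geom.gm_mask)
    n = len(gm_idx)

    n_vessel = int(round(config.vessel_fraction * n))
    if n_vessel > 0:
        u = geom.coord_u[geom.gm_mask]
        v = geom.coord_v[geom.gm_mask]
        d = geom.depth_d[geom.gm_mask]
        superficial = d >= config.vessel_min_depth
        vessel = np.zeros(n, dtype=bool)
        cand = np.flatnonzero(superficial)
        attempts = 0
        while vessel.sum() < n_vessel and attempts < 100 and len(cand):
            seed_i = rng.choice(cand)
            blob = (
                superficial
                & ((u - u[seed_i]) ** 2 + (v - v[seed_i]) ** 2
                   <= config.vessel_blob_radius**2)
            )
            vessel |= blob
            attempts += 1
        extra = vessel.sum() - n_vessel
        if extra > 0:  # trim random voxels so the fraction is exact
            drop = rng.choice(np.flatnonzero(vessel), size=extra, replace=False)
            vessel[drop] = False
        classes[tuple(gm_idx[vessel].T)] = CLASS_VESSEL

    n_untuned = int(round(config.untuned_fraction * n))
    if n_untuned > 0:
        free = np.flatnonzero(classes[geom.gm_mask] == CLASS_TUNED)
        pick = rng.choice(free, size=min(n_untuned, len(free)), replace=False)
        classes[tuple(gm_idx[pick].T)] = CLASS_UNTUNED
    return classes


def simulate_runs(
    geom: PatchGeometry,
    truth: PreferenceMap,
    config: SimulationConfig,
) -> tuple[list[ResponseMap], np.ndarray]:
    """Simulate per-run condition t-value maps around a planted truth.

    Returns one :class:`ResponseMap` per run and the ground-truth class
    volume (0 outside GM; tuned=1, untuned=2, vessel=3).  Fully
    reproducible from ``config.seed``.
    """
    config.validate()
    if truth.labels.shape != geom.dims:
        raise ValueError("truth preference map does not match geometry dims")
    if not np.all(truth.labels[geom.gm_mask] > 0):
        raise ValueError("truth must label every GM voxel")
    k = truth.n_conditions
    rng = np.random.default_rng(config.seed)
    classes = _assign_classes(geom, config, rng)

    mean = np.zeros(geom.dims + (k,))
    tuned = classes == CLASS_TUNED
    onehot = (
        truth.labels[tuned, None] == np.arange(1, k + 1)[None, :]
    )
    mean[tuned] = np.where(onehot, config.amp_pref, config.amp_nonpref)
    mean[classes == CLASS_VESSEL] = config.vessel_amp
    # untuned voxels keep mean 0

    runs = []
    for r in range(config.n_runs):
        noise = rng.normal(0.0, config.noise_sd, size=mean.shape)
        values = mean + noise
        values[~geom.gm_mask] = 0.0
        runs.append(ResponseMap(values=values, run_id=r))
    return runs, classes


def average_runs(runs: list[ResponseMap]) -> ResponseMap:
    """Per-voxel, per-condition arithmetic mean across runs."""
    if not runs:
        raise ValueError("need at least one run")
    shapes = {r.values.shape for r in runs}
    if len(shapes) > 1:
        raise ValueError(f"run shape mismatch: {sorted(shapes)}")
    return ResponseMap(
        values=np.mean([r.values for r in runs], axis=0), run_id=None
    )
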