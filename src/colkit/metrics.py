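"""Voxel-wise sensitivity, specificity, preference labels and tuning curves.

Each voxel of a K-condition experiment carries a K-vector of t-values
``v``.  Two scalar summaries characterize its response:

* **sensitivity** — the Euclidean norm ``||v||``: how strongly the voxel
  responds to anything at all.  A vessel-dominated voxel responds strongly
  to every condition and scores high.

* **specificity** — how well the voxel is tuned to a single condition.
  The vector is normalized to unit length, its entries sorted ascending,
  and the angle to the reference winning vector ``w = [0, ..., 0, 1]``
  computed.  Sorting confines that angle to [0, theta_max] where
  ``theta_max = arccos(1/sqrt(K))`` (60 deg for K=4, 45 deg for K=2),
  attained by the fully untuned uniform vector.  Specificity is
  ``1 - angle/theta_max``: 1 for a one-hot response, 0 for a flat one.
  Negative t-values are interpreted as absence of a response and zeroed
  before normalization (optional; response vectors guaranteed all-positive
  skip it).

A voxel whose entries are all <= 0 after zeroing has no direction to be
tuned toward; it is scored 0 and flagged as degenerate rather than
propagating a NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PreferenceMap

__all__ = [
    "SpecificityParams",
    "TuningCurves",
    "theta_max",
    "sensitivity",
    "specificity",
    "preference_map",
    "tuning_curves",
    "sensitivity_specificity_maps",
]


def theta_max(n_conditions: int) -> float:
    """Maximum sorted-vector angle to the winning vector, in degrees.

    Over non-negative unit vectors sorted ascending, the angle to
    ``[0, ..., 0, 1]`` is maximized by the uniform vector, giving
    ``arccos(1/sqrt(K))``.
    """
    if n_conditions < 2:
        raise ValueError("n_conditions must be >= 2")
    return float(np.degrees(np.arccos(1.0 / np.sqrt(n_conditions))))


@dataclass
class SpecificityParams:
    """Parameters of the specificity computation for K conditions."""

    n_conditions: int
    negative_handling: str = "zero"  # "zero" | "reject"

    def __post_init__(self) -> None:
        if self.negative_handling not in ("zero", "reject"):
            raise ValueError("negative_handling must be 'zero' or 'reject'")

    @property
    def theta_max(self) -> float:
        return theta_max(self.n_conditions)

    @property
    def reference_winner(self) -> np.ndarray:
        w = np.zeros(self.n_conditions)
        w[-1] = 1.0
        return w


def sensitivity(v: np.ndarray) -> np.ndarray | float:
    """Euclidean norm of the t-value vector(s); last axis is the condition axis.

    Negative entries contribute through squaring; no zeroing is applied.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[-1] < 2:
        raise ValueError("need at least 2 conditions")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite t-values")
    out = np.linalg.norm(v, axis=-1)
    return float(out) if out.ndim == 0 else out


def specificity(
    v: np.ndarray,
    params: SpecificityParams | None = None,
    *,
    zero_negatives: bool = True,
    return_degenerate: bool = False,
):
    """Tuning specificity in [0, 1]; last axis is the condition axis.

    Steps: (optionally) zero negative entries, normalize to unit length,
    sort ascending, dot with the reference winner ``[0..0, 1]``, take the
    arccos in degrees and scale by ``theta_max``; specificity is one minus
    that ratio.  Invariant to entry permutations and to positive scaling.

    Vectors with no positive entry after zeroing are degenerate: scored 0
    and, with ``return_degenerate=True``, flagged in a boolean array.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[-1] < 2:
        raise ValueError("need at least 2 conditions")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite t-values")
    if params is not None:
        if v.shape[-1] != params.n_conditions:
            raise ValueError("vector length != params.n_conditions")
        zero_negatives = params.negative_handling == "zero"
    k = v.shape[-1]

    scalar = v.ndim == 1
    vv = v.reshape(-1, k).copy()
    if zero_negatives:
        np.clip(vv, 0.0, None, out=vv)
    elif np.any(vv < 0):
        raise ValueError("negative t-values with negative_handling='reject'")
    norms = np.linalg.norm(vv, axis=1)
    degenerate = norms == 0.0

    out = np.zeros(vv.shape[0])
    ok = ~degenerate
    # After zeroing, the sorted-ascending dot with [0..0,1] is max_i v_i / ||v||.
    cos = np.clip(np.max(vv[ok], axis=1) / norms[ok], -1.0, 1.0)
    angle = np.degrees(np.arccos(cos))
    out[ok] = np.clip(1.0 - angle / theta_max(k), 0.0, 1.0)

    shape = v.shape[:-1]
    out = out.reshape(shape)
    degenerate = degenerate.reshape(shape)
    if scalar:
        out = float(out)
        degenerate = bool(degenerate)
    if return_degenerate:
        return out, degenerate
    return out


def preference_map(resp, domain: np.ndarray) -> PreferenceMap:
    """Label each domain voxel with its 1-based strongest condition.

    Ties break toward the lowest condition index (np.argmax), so labels are
    machine-independent.  Voxels outside the domain are labeled 0.
    """
    values = np.asarray(resp.values if hasattr(resp, "values") else resp, dtype=float)
    domain = np.asarray(domain, dtype=bool)
    if values.shape[:-1] != domain.shape:
        raise ValueError("response/domain shape mismatch")
    k = values.shape[-1]
    labels = np.zeros(domain.shape, dtype=np.int32)
    if domain.any():
        labels[domain] = np.argmax(values[domain], axis=-1).astype(np.int32) + 1
    else:
        import warnings

        warnings.warn("empty domain: preference map has no labeled voxels")
    return PreferenceMap(labels=labels, n_conditions=k)


@dataclass
class TuningCurves:
    """Group-mean tuning curves per preferred condition.

    Row r of ``mean_response`` is the mean K-vector over voxels whose
    preferred condition is r+1; ``selectivity_index`` row r is the
    preferred-condition response divided by the mean response to all other
    conditions.  Rows of empty groups are NaN with ``group_counts`` 0.
    """

    mean_response: np.ndarray
    sem: np.ndarray
    group_counts: np.ndarray
    selectivity_index: np.ndarray


def tuning_curves(resp, pref: PreferenceMap, domain: np.ndarray) -> TuningCurves:
    """Average response vectors of voxels grouped by preferred condition."""
    values = np.asarray(resp.values if hasattr(resp, "values") else resp, dtype=float)
    domain = np.asarray(domain, dtype=bool)
    k = values.shape[-1]
    if pref.n_conditions != k:
        raise ValueError("preference map and responses disagree on K")
    mean = np.full((k, k), np.nan)
    sem = np.full((k, k), np.nan)
    counts = np.zeros(k, dtype=int)
    sel = np.full(k, np.nan)
    for r in range(k):
        sel_mask = domain & (pref.labels == r + 1)
        n = int(sel_mask.sum())
        counts[r] = n
        if n == 0:
            continue
        grp = values[sel_mask]  # (n, K)
        mean[r] = grp.mean(axis=0)
        sem[r] = grp.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else 0.0
        others = np.delete(mean[r], r)
        denom = others.mean()
        sel[r] = mean[r, r] / denom if denom != 0 else np.nan
    return TuningCurves(
        mean_response=mean, sem=sem, group_counts=counts, selectivity_index=sel
    )


def sensitivity_specificity_maps(
    resp,
    domain: np.ndarray,
    params: SpecificityParams | None = None,
    *,
    zero_negatives: bool = True,
    pref: PreferenceMap | None = None,
):
    """Voxel-wise sensitivity and specificity maps over a domain.

    Returns ``(sens_map, spec_map, table, n_degenerate)``: two float
    volumes (NaN outside the domain), a tidy per-voxel table for
    scatter plotting, and the count of degenerate voxels (scored 0, never
    dropped).  Sensitivity always uses the raw vector; zeroing applies to
    specificity only.
    """
    import pandas as pd

    values = np.asarray(resp.values if hasattr(resp, "values") else resp, dtype=float)
    domain = np.asarray(domain, dtype=bool)
    if values.shape[:-1] != domain.shape:
        raise ValueError("response/domain shape mismatch")
    vecs = values[domain]
    sens = sensitivity(vecs) if len(vecs) else np.zeros(0)
    spec, degen = (
        specificity(
            vecs, params, zero_negatives=zero_negatives, return_degenerate=True
        )
        if len(vecs)
        else (np.zeros(0), np.zeros(0, dtype=bool))
    )
    sens_map = np.full(domain.shape, np.nan)
    spec_map = np.full(domain.shape, np.nan)
    sens_map[domain] = sens
    spec_map[domain] = spec

    idx = np.argwhere(domain)
    flat = np.ravel_multi_index(idx.T, domain.shape) if len(idx) else np.zeros(0, int)
    table = pd.DataFrame(
        {
            "voxel": flat,
            "i": idx[:, 0] if len(idx) else [],
            "j": idx[:, 1] if len(idx) else [],
            "k": idx[:, 2] if len(idx) else [],
            "sensitivity": sens,
            "specificity": spec,
            "degenerate": degen,
        }
    )
    if pref is not None:
        table["preference"] = pref.labels[domain]
    return sens_map, spec_map, table, int(np.count_nonzero(degen))
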