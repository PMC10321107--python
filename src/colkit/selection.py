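"""Tuned-voxel selection: FDR thresholding, cross-validation, CV+.

Three nested strategies define the voxel sets on which tuning metrics and
the searchlight operate:

* **FDR** — Benjamini–Hochberg step-up control of the false discovery
  rate over the domain's p-values (q < 0.05 by default).
* **CV** — leave-one-run-out label consistency: a voxel survives when the
  preferred condition from the training average (all runs but one) matches
  the left-out run's preference in every fold, and the all-runs-average
  label agrees with that fold label.  A ``min_folds`` relaxation implements
  the majority-agreement reading.
* **CV+** — CV voxels whose run-averaged t-value is strictly positive for
  every condition, excluding voxels whose apparent tuning rests on
  negative responses.

A connected-component cluster-size filter (default threshold 4 voxels,
26-neighborhood) removes isolated speckles from any selection mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .simulate import ResponseMap, average_runs

__all__ = [
    "SelectionResult",
    "fdr_select",
    "cluster_filter",
    "cv_select",
    "cvplus_select",
    "p_from_t",
]


@dataclass
class SelectionResult:
    """A binary selection mask plus the parameters that produced it."""

    mask: np.ndarray
    method: str
    provenance: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.mask))


def p_from_t(t: np.ndarray, dof: int) -> np.ndarray:
    """Two-sided p-values from t statistics with the given degrees of freedom."""
    if dof < 1:
        raise ValueError("dof must be >= 1")
    return 2.0 * stats.t.sf(np.abs(t), dof)


def fdr_select(p_values: np.ndarray, q: float, domain: np.ndarray) -> SelectionResult:
    """Benjamini–Hochberg step-up selection over the domain voxels."""
    p_values = np.asarray(p_values, dtype=float)
    domain = np.asarray(domain, dtype=bool)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    mask = np.zeros(domain.shape, dtype=bool)
    p = p_values[domain]
    if p.size:
        if p.min() < 0 or p.max() > 1:
            raise ValueError("p-values outside [0, 1]")
        reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
        mask[domain] = reject
    return SelectionResult(mask=mask, method="FDR", provenance={"q": q, "m": int(p.size)})


def cluster_filter(
    mask: np.ndarray, min_size: int = 4, connectivity: int = 26
) -> np.ndarray:
    """Drop connected components smaller than ``min_size`` voxels.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (full corner
    connectivity, the default).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    rank = {6: 1, 18: 2, 26: 3}
    if connectivity not in rank:
        raise ValueError("connectivity must be 6, 18 or 26")
    mask = np.asarray(mask, dtype=bool)
    if min_size == 1 or not mask.any():
        return mask.copy()
    structure = ndimage.generate_binary_structure(3, rank[connectivity])
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labeled.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labeled]


def cv_select(
    runs: list[ResponseMap],
    domain: np.ndarray,
    min_folds: int | None = None,
) -> SelectionResult:
    """Leave-one-run-out cross-validated preference consistency.

    For each fold, the training label is the argmax of the mean response of
    all runs but one and the test label is the left-out run's argmax; a
    voxel passes a fold when both agree and the all-runs-average label
    equals that agreed label.  By default a voxel must pass every fold;
    ``min_folds`` keeps voxels passing at least that many folds instead.
    """
    if len(runs) < 2:
        raise ValueError("cross-validation requires at least 2 runs")
    domain = np.asarray(domain, dtype=bool)
    if not domain.any():
        raise ValueError("empty domain")
    n_runs = len(runs)
    if min_folds is None:
        min_folds = n_runs
    if not 1 <= min_folds <= n_runs:
        raise ValueError("min_folds must be in [1, n_runs]")

    stack = np.stack([r.values[domain] for r in runs])  # (R, N, K)
    total = stack.sum(axis=0)
    overall = np.argmax(total / n_runs, axis=-1)
    passes = np.zeros(stack.shape[1], dtype=int)
    for r in range(n_runs):
        train = (total - stack[r]) / (n_runs - 1)
        train_label = np.argmax(train, axis=-1)
        test_label = np.argmax(stack[r], axis=-1)
        passes += (train_label == test_label) & (train_label == overall)
    mask = np.zeros(domain.shape, dtype=bool)
    mask[domain] = passes >= min_folds
    return SelectionResult(
        mask=mask,
        method="CV",
        provenance={"n_runs": n_runs, "min_folds": min_folds},
    )


def cvplus_select(cv: SelectionResult, resp_all_runs: ResponseMap) -> SelectionResult:
    """CV voxels with strictly positive run-averaged t for every condition.

    A t-value of exactly 0 counts as no positive response and removes the
    voxel.
    """
    if resp_all_runs.dims != cv.mask.shape:
        raise ValueError("response map does not match CV mask dims")
    positive = np.all(resp_all_runs.values > 0, axis=-1)
    return SelectionResult(
        mask=cv.mask & positive,
        method="CV+",
        provenance=dict(cv.provenance, parent="CV"),
    )


def select_from_runs(
    runs: list[ResponseMap],
    domain: np.ndarray,
    *,
    min_folds: int | None = None,
    min_cluster: int = 4,
    connectivity: int = 26,
) -> dict[str, SelectionResult]:
    """Convenience: CV and CV+ from runs, each cluster-size filtered last."""
    cv = cv_select(runs, domain, min_folds=min_folds)
    cvp = cvplus_select(cv, average_runs(runs))
    out = {}
    for res in (cv, cvp):
        filtered = cluster_filter(res.mask, min_size=min_cluster, connectivity=connectivity)
        out[res.method] = SelectionResult(
            mask=filtered,
            method=res.method,
            provenance=dict(res.provenance, min_cluster=min_cluster,
                            connectivity=connectivity),
        )
    return out
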