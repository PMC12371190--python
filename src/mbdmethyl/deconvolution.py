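"""Reference-based leukocyte deconvolution by constrained least squares.

Blood methylation signal at cell-type marker regions is modelled as a
non-negative mixture of reference profiles for B cells (CD19), T cells
(CD3D) and monocytes (CD14), with the weights summing to at most one (the
slack absorbs unmodelled cell types):

    w* = argmin || y - P w ||^2   s.t.  w >= 0,  sum(w) <= 1.

For the small number of cell types involved the quadratic program is
solved exactly by enumerating active-constraint patterns and checking the
KKT conditions; an SLSQP fallback covers unusually wide references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_CELL_TYPES = ("B_cell", "T_cell", "monocyte")
CELL_TYPE_MARKERS = {"B_cell": "CD19", "T_cell": "CD3D", "monocyte": "CD14"}


@dataclass
class CellTypeReference:
    """Marker-by-cell-type expected signal matrix (full column rank)."""

    marker_regions: List[str]
    cell_types: List[str]
    profile: np.ndarray

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (len(self.marker_regions), len(self.cell_types)):
            raise ValueError("profile shape does not match markers x cell types")
        if np.linalg.matrix_rank(self.profile) < len(self.cell_types):
            raise ValueError("reference profile is rank-deficient; estimation refused")


@dataclass
class CellProportions:
    sample_id: str
    weights: np.ndarray
    cell_types: List[str]
    residual_norm: float


def _solve_qp(P: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact minimiser of ||y - Pw||^2 over {w >= 0, sum(w) <= 1}."""
    k = P.shape[1]
    Q = P.T @ P
    c = P.T @ y
    if k > 12:  # enumeration too wide; polish with SLSQP
        from scipy.optimize import minimize

        cons = [{"type": "ineq", "fun": lambda w: 1.0 - w.sum()}]
        res = minimize(
            lambda w: 0.5 * w @ Q @ w - c @ w,
            x0=np.full(k, 1.0 / (k + 1)),
            jac=lambda w: Q @ w - c,
            bounds=[(0, None)] * k,
            constraints=cons,
            method="SLSQP",
            options={"ftol": 1e-14, "maxiter": 500},
        )
        return np.maximum(res.x, 0.0)

    best_w = None
    best_obj = np.inf
    # active pattern: for each weight, free or pinned at 0; sum constraint active or not
    for zeros in product((False, True), repeat=k):
        free = [i for i in range(k) if not zeros[i]]
        for sum_active in (False, True):
            nf = len(free)
            w = np.zeros(k)
            if nf == 0:
                if sum_active:
                    continue
            else:
                Qf = Q[np.ix_(free, free)]
                cf = c[free]
                if sum_active:
                    # KKT system with equality sum(w_free) = 1
                    A = np.zeros((nf + 1, nf + 1))
                    A[:nf, :nf] = Qf
                    A[:nf, nf] = 1.0
                    A[nf, :nf] = 1.0
                    b = np.concatenate([cf, [1.0]])
                    try:
                        sol = np.linalg.solve(A, b)
                    except np.linalg.LinAlgError:
                        continue
                    wf, mu = sol[:nf], sol[nf]
                    if mu < -1e-10:  # multiplier must be >= 0
                        continue
                else:
                    try:
                        wf = np.linalg.solve(Qf, cf)
                    except np.linalg.LinAlgError:
                        continue
                if (wf < -1e-10).any():
                    continue
                w[free] = np.maximum(wf, 0.0)
            if w.sum() > 1.0 + 1e-9:
                continue
            grad = Q @ w - c
            # stationarity for pinned weights: gradient must be >= 0 (minus sum multiplier)
            mu_val = 0.0
            if sum_active and nf:
                mu_val = sol[nf]
            ok = all(grad[i] + mu_val >= -1e-8 for i in range(k) if zeros[i])
            if not ok:
                continue
            obj = 0.5 * w @ Q @ w - c @ w
            if obj < best_obj - 1e-15:
                best_obj = obj
                best_w = w
    assert best_w is not None
    return best_w


def estimate_proportions(
    y: np.ndarray, reference: CellTypeReference, sample_id: str = ""
) -> CellProportions:
    """Estimate cell-type weights for one sample's marker signal vector."""
    y = np.asarray(y, dtype=float)
    if y.shape != (len(reference.marker_regions),):
        raise ValueError(
            f"signal length {y.shape} does not match {len(reference.marker_regions)} markers"
        )
    w = _solve_qp(reference.profile, y)
    resid = float(np.linalg.norm(y - reference.profile @ w))
    return CellProportions(
        sample_id=sample_id, weights=w, cell_types=list(reference.cell_types), residual_norm=resid
    )


def estimate_proportions_matrix(
    signals: np.ndarray, reference: CellTypeReference, sample_ids: Sequence[str]
) -> List[CellProportions]:
    """Column-wise estimation for a markers x samples signal matrix."""
    signals = np.asarray(signals, dtype=float)
    return [
        estimate_proportions(signals[:, j], reference, sample_id=sid)
        for j, sid in enumerate(sample_ids)
    ]


def attach_proportions(samples, proportions: Sequence[CellProportions]) -> pd.DataFrame:
    """Build a sample x cell-type covariate table for the differential model.

    Blood samples take their estimated weights; brain samples get the fixed
    all-zero reference level (the correction is a blood-only nuisance, but
    the joint model needs complete rows).
    """
    by_id: Dict[str, CellProportions] = {p.sample_id: p for p in proportions}
    cell_types = (
        list(proportions[0].cell_types) if proportions else list(DEFAULT_CELL_TYPES)
    )
    rows = []
    for s in samples:
        if s.tissue == "blood":
            if s.sample_id not in by_id:
                raise ValueError(f"no cell-proportion estimate for blood sample {s.sample_id}")
            rows.append(list(by_id[s.sample_id].weights))
        else:
            rows.append([0.0] * len(cell_types))
    return pd.DataFrame(rows, index=[s.sample_id for s in samples], columns=cell_types)
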