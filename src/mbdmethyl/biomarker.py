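"""ROC/AUC biomarker selection, panel intersection and combinatorial ranking.

Per-region AUC is the Mann-Whitney pair-count statistic with 0.5 credit
for ties, reported after orientation (max of A and 1-A).  Candidate
biomarkers must be DMRs that also clear strict AUC and CpG-count
thresholds; the subtype panel comes from intersecting the three contrasts
(IIa vs others, IIb vs others, IIb vs IIa); clinical covariates enter as a
single stepwise-AIC logistic score; panels are ranked by exhaustive
combinatorial ROC with a label-permutation bootstrap p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger("mbdmethyl")


@dataclass
class ROCResult:
    region_id: str
    auc: float
    orientation: str  # case_high | case_low
    n_case: int
    n_control: int


@dataclass
class PanelMember:
    region_id: str
    member_class: str  # IIa_defining | IIb_defining | IIb_vs_IIa_top
    auc_per_contrast: Dict[str, float] = field(default_factory=dict)
    cpg_count: Optional[int] = None
    nearest_gene: Optional[str] = None


@dataclass
class BiomarkerPanel:
    members: List[PanelMember]

    @property
    def region_ids(self) -> List[str]:
        return [m.region_id for m in self.members]


@dataclass
class ClinicalModel:
    selected_covariates: List[str]
    coefficients: np.ndarray
    columns: List[str]
    aic: float

    def score(self, covariates: pd.DataFrame) -> np.ndarray:
        """Linear predictor for new rows with the selected covariates."""
        X = np.column_stack(
            [np.ones(len(covariates))]
            + [covariates[c].to_numpy(dtype=float) for c in self.columns[1:]]
        )
        return X @ self.coefficients


@dataclass
class ComboResult:
    combo_id: str
    feature_set: Tuple[str, ...]
    includes_clinical: bool
    auc: float
    accuracy: float
    bootstrap_p: Optional[float] = None


def region_auc(values_case: np.ndarray, values_control: np.ndarray, region_id: str = "") -> ROCResult:
    """Oriented pair-count AUC: A = (#case>control + 0.5 #ties) / (n1*n2)."""
    case = np.asarray(values_case, dtype=float)
    ctrl = np.asarray(values_control, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both arms must be non-empty")
    diff = case[:, None] - ctrl[None, :]
    a = float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (case.size * ctrl.size))
    if a >= 0.5:
        return ROCResult(region_id, a, "case_high", case.size, ctrl.size)
    return ROCResult(region_id, 1 - a, "case_low", case.size, ctrl.size)


def select_dmr_biomarkers(
    dmr_table: pd.DataFrame,
    auc_table: pd.DataFrame,
    cpg_counts: Dict[str, int],
    auc_min: float = 0.65,
    cpg_min: int = 4,
    dmr_p_max: float = 0.01,
) -> pd.DataFrame:
    """Candidate biomarkers for one contrast.

    Keeps regions with DMR p strictly below ``dmr_p_max``, oriented AUC
    strictly above ``auc_min`` and CpG count strictly above ``cpg_min``.
    ``dmr_table`` needs region_id/p_value; ``auc_table`` region_id/auc.
    """
    merged = dmr_table.merge(auc_table[["region_id", "auc"]], on="region_id", how="inner")
    missing = [r for r in merged["region_id"] if r not in cpg_counts]
    if missing:
        raise ValueError(f"regions missing cpg_count (annotate first): {missing[:5]}")
    merged["cpg_count"] = [cpg_counts[r] for r in merged["region_id"]]
    keep = (
        (merged["p_value"] < dmr_p_max)
        & (merged["auc"] > auc_min)
        & (merged["cpg_count"] > cpg_min)
    )
    return merged[keep].reset_index(drop=True)


def intersect_contrasts(
    panel_iia_vs_others: pd.DataFrame,
    panel_iib_vs_others: pd.DataFrame,
    panel_iib_vs_iia: pd.DataFrame,
    cpg_counts: Optional[Dict[str, int]] = None,
    genes: Optional[Dict[str, str]] = None,
) -> BiomarkerPanel:
    """Intersection panel from the three defining contrasts.

    IIa_defining  = (IIa_vs_others  &  IIb_vs_IIa) - IIb_vs_others
    IIb_defining  = (IIb_vs_others  &  IIb_vs_IIa) - IIa_vs_others
    IIb_vs_IIa_top = the single highest-AUC region present in all three
    sets (ties by cpg_count then region_id); absent if the triple
    intersection is empty.
    """
    a: Set[str] = set(panel_iia_vs_others["region_id"])
    b: Set[str] = set(panel_iib_vs_others["region_id"])
    c: Set[str] = set(panel_iib_vs_iia["region_id"])
    auc_a = dict(zip(panel_iia_vs_others["region_id"], panel_iia_vs_others["auc"]))
    auc_b = dict(zip(panel_iib_vs_others["region_id"], panel_iib_vs_others["auc"]))
    auc_c = dict(zip(panel_iib_vs_iia["region_id"], panel_iib_vs_iia["auc"]))
    cpg_counts = cpg_counts or {}
    genes = genes or {}

    def member(rid: str, cls: str) -> PanelMember:
        aucs = {}
        if rid in auc_a:
            aucs["IIa_vs_others"] = float(auc_a[rid])
        if rid in auc_b:
            aucs["IIb_vs_others"] = float(auc_b[rid])
        if rid in auc_c:
            aucs["IIb_vs_IIa"] = float(auc_c[rid])
        return PanelMember(
            region_id=rid,
            member_class=cls,
            auc_per_contrast=aucs,
            cpg_count=cpg_counts.get(rid),
            nearest_gene=genes.get(rid),
        )

    members = [member(r, "IIa_defining") for r in sorted((a & c) - b)]
    members += [member(r, "IIb_defining") for r in sorted((b & c) - a)]
    triple = a & b & c
    if triple:
        top = max(
            triple,
            key=lambda r: (auc_c[r], cpg_counts.get(r, -1), r),
        )
        members.append(member(top, "IIb_vs_IIa_top"))
    return BiomarkerPanel(members=members)


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = 1e-6, maxiter: int = 100) -> np.ndarray:
    """IRLS logistic fit with a tiny ridge penalty; caps coefficients under
    perfect separation while staying deterministic and silent."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = np.maximum(p * (1 - p), 1e-10)
        grad = X.T @ (y - p) - alpha * beta
        H = X.T @ (X * W[:, None]) + alpha * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(step).max() < 1e-10 or np.abs(beta).max() > 50:
            break
    return beta


def _logit_fit(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float, float]:
    """Logistic fit returning (params, deviance, aic); tiny ridge on
    separation."""
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.params)) or not res.mle_retvals.get("converged", False):
                raise ValueError
            params = np.asarray(res.params)
            llf = float(res.llf)
        except Exception:
            params = _ridge_logit(X, y, alpha=1e-6)
            eta = np.clip(X @ params, -30, 30)
            llf = float(np.sum(y * eta - np.log1p(np.exp(eta))))
            log.debug("perfect separation: ridge-stabilised logistic fit")
    deviance = -2 * llf
    aic = deviance + 2 * X.shape[1]
    return params, deviance, aic


def stepwise_aic_logistic(
    outcome: np.ndarray, covariates: pd.DataFrame, scope: Optional[Sequence[str]] = None
) -> ClinicalModel:
    """Bidirectional stepwise logistic regression minimising AIC.

    Starts from the full model over ``scope`` (default: all columns), makes
    the single best add/drop per step, stops at a local AIC minimum.
    Deterministic given input column order.
    """
    y = np.asarray(outcome, dtype=float)
    scope = list(scope) if scope is not None else list(covariates.columns)
    if len(y) <= len(scope):
        raise ValueError("need more observations than candidate covariates")

    def fit(selected: List[str]) -> Tuple[np.ndarray, float, List[str]]:
        columns = ["intercept"] + selected
        X = np.column_stack(
            [np.ones(len(y))] + [covariates[c].to_numpy(dtype=float) for c in selected]
        )
        params, _, aic = _logit_fit(X, y)
        return params, aic, columns

    current = list(scope)
    params, best_aic, columns = fit(current)
    improved = True
    while improved:
        improved = False
        moves = [("drop", c) for c in current] + [("add", c) for c in scope if c not in current]
        best_move = None
        for kind, c in moves:
            trial = [x for x in current if x != c] if kind == "drop" else current + [c]
            try:
                p, aic, cols = fit(trial)
            except Exception:
                continue
            if aic < best_aic - 1e-10:
                best_aic, best_move = aic, (trial, p, cols)
        if best_move is not None:
            current, params, columns = best_move[0], best_move[1], best_move[2]
            improved = True
    return ClinicalModel(
        selected_covariates=list(current), coefficients=params, columns=columns, aic=best_aic
    )


def _score_combo(X: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """In-sample logistic score: oriented AUC and accuracy at the
    Youden-optimal threshold."""
    params, _, _ = _logit_fit(np.column_stack([np.ones(len(y)), X]), y)
    score = np.column_stack([np.ones(len(y)), X]) @ params
    roc = region_auc(score[y == 1], score[y == 0])
    auc = roc.auc
    s = score if roc.orientation == "case_high" else -score
    thresholds = np.unique(s)
    best_acc = 0.0
    best_youden = -np.inf
    for t in thresholds:
        pred = s >= t
        tpr = (pred & (y == 1)).sum() / max((y == 1).sum(), 1)
        fpr = (pred & (y == 0)).sum() / max((y == 0).sum(), 1)
        youden = tpr - fpr
        if youden > best_youden:
            best_youden = youden
            best_acc = float((pred == (y == 1)).mean())
    return auc, best_acc


def combinatorial_roc(
    panel_features: pd.DataFrame,
    outcome: np.ndarray,
    clinical_score: Optional[np.ndarray] = None,
    max_subset_size: int = 3,
    combo_cap: int = 20_000,
) -> List[ComboResult]:
    """Enumerate all non-empty feature subsets up to ``max_subset_size``,
    each with and without the clinical score, score by in-sample logistic
    fit, and rank by AUC (ties by accuracy).

    ``panel_features`` is samples x panel-member columns; output length is
    exactly 2 * sum_k C(m, k).
    """
    y = np.asarray(outcome, dtype=float)
    features = list(panel_features.columns)
    m = len(features)
    if m == 0:
        raise ValueError("panel is empty")
    n_combos = 2 * sum(comb(m, k) for k in range(1, min(max_subset_size, m) + 1))
    if n_combos > combo_cap:
        raise ValueError(
            f"{n_combos} combinations exceed the cap {combo_cap}; lower max_subset_size"
        )
    results: List[ComboResult] = []
    for k in range(1, min(max_subset_size, m) + 1):
        for subset in combinations(features, k):
            base = panel_features[list(subset)].to_numpy(dtype=float)
            for with_cf in (False, True):
                X = base
                if with_cf:
                    if clinical_score is None:
                        X = np.column_stack([base, np.zeros(len(y))])
                    else:
                        X = np.column_stack([base, np.asarray(clinical_score, float)])
                auc, acc = _score_combo(X, y)
                results.append(
                    ComboResult(
                        combo_id="+".join(subset) + ("+Cf" if with_cf else ""),
                        feature_set=subset,
                        includes_clinical=with_cf,
                        auc=auc,
                        accuracy=acc,
                    )
                )
    results.sort(key=lambda r: (-r.auc, -r.accuracy, r.combo_id))
    return results


def bootstrap_auc_pvalue(
    score: np.ndarray, outcome: np.ndarray, n_boot: int = 999, seed: int = 0
) -> float:
    """Label-permutation p-value for an observed AUC with +1 smoothing.

    p = (#{permuted AUC >= observed} + 1) / (n_boot + 1); never 0, never
    above 1.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    y = np.asarray(outcome)
    s = np.asarray(score, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    observed = region_auc(s[y == 1], s[y == 0]).auc
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_boot):
        perm = rng.permutation(y)
        if region_auc(s[perm == 1], s[perm == 0]).auc >= observed - 1e-12:
            k += 1
    return (k + 1) / (n_boot + 1)
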