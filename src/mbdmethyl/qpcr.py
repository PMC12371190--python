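"""Methyl-qPCR analytics: percent methylation from bound/unbound fractions.

MBD capture splits each sample's DNA into a bound (methylated) and unbound
(unmethylated) pool; each is quantified by qPCR against a methylated
spike-in control that cancels between-run technical offsets.  With perfect
doubling per cycle the spike-normalised quantity of fraction f is
Q_f = 2^(Ct_spike_f - Ct_target_f) and

    percent methylation = 100 * Q_bound / (Q_bound + Q_unbound),

which is invariant to adding any constant to all four Ct values and
strictly increasing in (Ct_unbound - Ct_bound).  Replicate wells are
averaged on the Ct scale; group comparisons use Mann-Whitney U.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .biomarker import _score_combo, region_auc
from .core import SampleRecord


@dataclass
class MethylationPercent:
    sample_id: str
    target: str
    percent: Optional[float]  # in [0, 100]; None when both fractions failed
    qc_flags: frozenset = field(default_factory=frozenset)


def _mean_ct(cts: Sequence[Optional[float]]) -> Tuple[Optional[float], bool]:
    """Average replicate Cts; returns (mean or None, replicate-spread flag)."""
    vals = [c for c in cts if c is not None and np.isfinite(c)]
    if not vals:
        return None, False
    spread_flag = (max(vals) - min(vals)) > 1.0
    return float(np.mean(vals)), spread_flag


def percent_methylation(
    ct_bound: Sequence[Optional[float]],
    ct_unbound: Sequence[Optional[float]],
    ct_spike_bound: Sequence[Optional[float]],
    ct_spike_unbound: Sequence[Optional[float]],
    sample_id: str = "",
    target: str = "",
) -> MethylationPercent:
    """Spike-normalised percent methylation for one sample/target.

    Each argument is the list of replicate Cts for that well type
    (``None`` = undetermined).  An undetermined target fraction gets
    quantity 0 with a qc flag; both undetermined yields a missing percent.
    """
    flags = set()
    mb, fb = _mean_ct(ct_bound)
    mu, fu = _mean_ct(ct_unbound)
    sb, fsb = _mean_ct(ct_spike_bound)
    su, fsu = _mean_ct(ct_spike_unbound)
    if fb or fu or fsb or fsu:
        flags.add("replicate_spread")
    if sb is None or su is None:
        flags.add("spike_undetermined")
        sb = sb if sb is not None else 0.0
        su = su if su is not None else 0.0
    if mb is None and mu is None:
        flags.add("both_fractions_undetermined")
        return MethylationPercent(sample_id, target, None, frozenset(flags))
    q_bound = 2.0 ** (sb - mb) if mb is not None else 0.0
    q_unbound = 2.0 ** (su - mu) if mu is not None else 0.0
    if mb is None:
        flags.add("bound_undetermined")
    if mu is None:
        flags.add("unbound_undetermined")
    percent = 100.0 * q_bound / (q_bound + q_unbound)
    return MethylationPercent(sample_id, target, float(percent), frozenset(flags))


def percent_table(wells: pd.DataFrame) -> pd.DataFrame:
    """Percent methylation for every (sample, target) in a long-format well
    table with columns sample_id, target, fraction (bound|unbound|spike),
    replicate, ct (NaN = undetermined).

    Spike wells are shared per sample and fraction (target == 'spike').
    """
    rows = []
    for (sid, target), grp in wells[wells["target"] != "spike"].groupby(["sample_id", "target"]):
        spikes = wells[(wells["sample_id"] == sid) & (wells["target"] == "spike")]

        def cts(frame: pd.DataFrame, fraction: str) -> List[Optional[float]]:
            sel = frame[frame["fraction"] == fraction]["ct"]
            return [None if pd.isna(v) else float(v) for v in sel]

        mp = percent_methylation(
            cts(grp, "bound"),
            cts(grp, "unbound"),
            cts(spikes, "bound"),
            cts(spikes, "unbound"),
            sample_id=sid,
            target=target,
        )
        rows.append((sid, target, mp.percent, ";".join(sorted(mp.qc_flags))))
    return pd.DataFrame(rows, columns=["sample_id", "target", "percent", "qc_flags"])


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> Tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    Exact by full enumeration when the pooled size is <= 20 and there are
    no ties; otherwise the normal approximation with tie and continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.array_equal(np.sort(a), np.sort(b)):
        u = float(stats.mannwhitneyu(a, b, method="asymptotic").statistic)
        return u, 1.0
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def validation_report(
    percents: pd.DataFrame,
    samples: Sequence[SampleRecord],
    panel_targets: Sequence[str],
    group_of: Optional[Dict[str, str]] = None,
) -> Dict[str, pd.DataFrame]:
    """Group summaries, pairwise tests and a combined-panel ROC.

    Groups default to others / IIa / IIb from the sample classifications.
    Returns a dict with keys ``summary`` (mean, SEM, n per target, tissue
    and group), ``tests`` (Mann-Whitney per target/tissue for the three
    pairwise comparisons) and ``roc`` (combined-panel AUC per tissue for
    IIb vs IIa, mean percent across panel targets as the score).
    """
    by_id = {s.sample_id: s for s in samples}

    def group(sid: str) -> str:
        cls = by_id[sid].classification
        if group_of:
            return group_of.get(sid, "others")
        return cls if cls in ("IIa", "IIb") else "others"

    df = percents[percents["target"].isin(panel_targets)].copy()
    df = df[df["percent"].notna()]
    df["group"] = [group(s) for s in df["sample_id"]]
    df["tissue"] = [by_id[s].tissue for s in df["sample_id"]]

    summary_rows = []
    test_rows = []
    for (target, tissue), grp in df.groupby(["target", "tissue"]):
        vals = {g: grp[grp["group"] == g]["percent"].to_numpy() for g in ("others", "IIa", "IIb")}
        for g, v in vals.items():
            sem = float(stats.sem(v)) if v.size >= 2 else None
            mean = float(v.mean()) if v.size else None
            summary_rows.append((target, tissue, g, v.size, mean, sem))
        for g1, g2 in (("others", "IIa"), ("others", "IIb"), ("IIa", "IIb")):
            if vals[g1].size and vals[g2].size:
                u, p = mann_whitney(vals[g1], vals[g2])
                test_rows.append((target, tissue, f"{g1}_vs_{g2}", u, p))

    roc_rows = []
    for tissue, grp in df.groupby("tissue"):
        pivot = grp.pivot_table(index="sample_id", columns="target", values="percent")
        pivot = pivot.dropna()
        groups = pd.Series({sid: group(sid) for sid in pivot.index})
        sel = groups.isin(["IIa", "IIb"])
        if sel.sum() < 4 or groups[sel].nunique() < 2:
            continue
        y = (groups[sel] == "IIb").to_numpy().astype(float)
        auc, _acc = _score_combo(pivot[sel].to_numpy(dtype=float), y)
        roc_rows.append((tissue, auc, int(y.sum()), int(len(y) - y.sum())))

    return {
        "summary": pd.DataFrame(
            summary_rows, columns=["target", "tissue", "group", "n", "mean", "sem"]
        ),
        "tests": pd.DataFrame(test_rows, columns=["target", "tissue", "comparison", "U", "p_value"]),
        "roc": pd.DataFrame(roc_rows, columns=["tissue", "auc", "n_case", "n_control"]),
    }
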