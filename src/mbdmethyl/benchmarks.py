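"""End-to-end verification benchmarks.

Each function regenerates its inputs from a seed, runs the corresponding
pipeline stage(s), and returns the measured quantity: fixture cohort
counts, oracle agreement for the consensus builder and the AUC statistic,
type-I calibration and effect recovery of the differential model,
deconvolution and qPCR recovery error, panel-intersection correctness,
combination enumeration, and stepwise-selection behaviour.  The problem
sizes are chosen to be informative at desk scale.
"""

from __future__ import annotations

from math import comb
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .biomarker import (
    combinatorial_roc,
    intersect_contrasts,
    region_auc,
    select_dmr_biomarkers,
    stepwise_aic_logistic,
)
from .core import GenomicInterval, cohort_summary
from .deconvolution import estimate_proportions_matrix
from .differential import (
    ContrastSpec,
    build_design,
    estimate_dispersions,
    estimate_library_sizes,
    test_all_regions,
)
from .fixtures import load_discovery_cohort, load_replication_cohort
from .normalize import logcpm
from .peaks import build_consensus
from .simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_counts,
    simulate_marker_signals,
    simulate_qpcr,
)
from .qpcr import percent_table


def fixture_cohort_counts() -> Dict[str, int]:
    """Group sizes parsed from the packaged discovery and replication
    cohort fixtures."""
    disc = cohort_summary(load_discovery_cohort())
    repl = cohort_summary(load_replication_cohort())
    return {
        "discovery_n_samples": disc.n_samples,
        "discovery_n_fcd": disc.n_fcd,
        "discovery_n_other": disc.n_other,
        "discovery_n_IIa": disc.per_classification["IIa"],
        "discovery_n_IIb": disc.per_classification["IIb"],
        "discovery_n_IIIa": disc.per_classification["IIIa"],
        "replication_n_paired": repl.n_paired,
    }


def _per_base_consensus(calls_by_sample, min_support, genome_len):
    cov = np.zeros(genome_len, dtype=int)
    for ivs in calls_by_sample.values():
        mask = np.zeros(genome_len, dtype=bool)
        for i in ivs:
            mask[i.start : i.end] = True
        cov += mask
    keep = cov >= min_support
    out = []
    pos = 0
    while pos < genome_len:
        if keep[pos]:
            start = pos
            while pos < genome_len and keep[pos]:
                pos += 1
            out.append(GenomicInterval("chr1", start, pos))
        else:
            pos += 1
    return out


def consensus_oracle_agreement(seed: int, n_trials: int = 200) -> float:
    """Fraction of random multi-sample genomes on which the sweep-line
    consensus equals the per-base counting oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        genome_len = int(rng.integers(1_000, 100_000))
        n_samples = int(rng.integers(1, 9))
        calls = {}
        for s in range(n_samples):
            ivs = []
            for _ in range(int(rng.integers(0, 15))):
                start = int(rng.integers(0, genome_len - 10))
                ivs.append(
                    GenomicInterval("chr1", start, min(start + int(rng.integers(5, 2000)), genome_len))
                )
            calls[f"s{s}"] = ivs
        min_support = int(rng.integers(1, 5))
        got = [p.interval for p in build_consensus(calls, min_support=min_support)]
        want = _per_base_consensus(calls, min_support, genome_len)
        agree += got == want
    return agree / n_trials


def auc_oracle_max_diff(seed: int, n_trials: int = 1000) -> float:
    """Largest deviation between region_auc and exhaustive pair counting
    over random case/control draws including ties."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        n1, n2 = int(rng.integers(2, 12)), int(rng.integers(2, 12))
        case = rng.integers(0, 6, size=n1).astype(float)
        ctrl = rng.integers(0, 6, size=n2).astype(float)
        diff = case[:, None] - ctrl[None, :]
        a = ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (n1 * n2)
        worst = max(worst, abs(region_auc(case, ctrl).auc - max(a, 1 - a)))
    return worst


def _two_arm_cohort(seed, n_per_arm, n_regions, n_dmrs, effect, dispersion):
    cfg = SimulationConfig(
        seed=seed,
        n_regions=n_regions,
        n_dmr_per_contrast=n_dmrs,
        dmr_log2_effect=effect,
        dispersion=dispersion,
        n_marker_regions=0,
        paired_fraction=0.0,
        covariate_effects={"age": 0.1, "gender": 0.1},
        n_subjects_per_group={"IIa": n_per_arm, "IIb": n_per_arm},
        dmr_classes=(("IIb_only", {"IIb": 1.0}),),
    )
    samples = simulate_cohort(cfg)
    cohort = simulate_counts(samples, cfg)
    contrast = ContrastSpec("IIb_vs_IIa", frozenset({"IIb"}), frozenset({"IIa"}))
    lib = estimate_library_sizes(cohort.counts, samples)
    design = build_design(samples, contrast, library_sizes=lib, tissue_mode="brain")
    disp = estimate_dispersions(cohort.counts, design)
    tbl = test_all_regions(cohort.counts, design, disp, "IIb_vs_IIa")
    return cohort, tbl


def null_dmr_fraction(seed: int, n_regions: int = 2000, n_per_arm: int = 8) -> float:
    """Type-I calibration: DMR fraction at p < 0.01 on a null cohort
    (no planted effects, NB dispersion 0.2, 16 samples)."""
    _, tbl = _two_arm_cohort(seed, n_per_arm, n_regions, 0, 0.0, 0.2)
    return float((tbl["p_value"] < 0.01).mean())


def effect_recovery(
    seed: int, n_per_arm: int = 20, n_truth: int = 200, n_regions: int = 600
) -> Tuple[float, float, float]:
    """(bias of log2FC on truth DMRs, direction agreement among detected,
    power at p < 0.01) for an injected +-2.0 log2 effect."""
    cohort, tbl = _two_arm_cohort(seed, n_per_arm, n_regions, n_truth, 2.0, 0.2)
    truth = cohort.truth.set_index("region_id")
    tbl = tbl.set_index("region_id")
    tbl["label"] = truth["label"]
    tbl["true_dir"] = truth["direction"]
    tbl["true_eff"] = truth["log2_effect_IIb"]
    dmrs = tbl[tbl["label"] == "IIb_only"]
    bias = float((dmrs["log2fc"] - dmrs["true_eff"]).mean())
    det = dmrs[dmrs["p_value"] < 0.01]
    agreement = float((det["direction"] == det["true_dir"]).mean()) if len(det) else 0.0
    power = len(det) / len(dmrs)
    return bias, agreement, power


def deconvolution_mae(seed: int, n_markers: int = 50, n_samples: int = 100) -> float:
    """Mean absolute error of recovered cell proportions at noise sd 0.05."""
    ref, W, Y = simulate_marker_signals(n_markers, n_samples, noise_sd=0.05, seed=seed)
    props = estimate_proportions_matrix(Y, ref, [f"s{i}" for i in range(n_samples)])
    return float(np.mean([np.abs(p.weights - W[i]).mean() for i, p in enumerate(props)]))


def panel_logic_agreement(seed: int, n_regions: int = 400, n_per_class: int = 6) -> Dict:
    """End-to-end panel construction on a cohort with planted IIa-only,
    IIb-only and shared (graded) effects.

    Returns the per-class assignment counts and whether every panel member's
    class matches its generative truth label.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_regions=n_regions,
        n_dmr_per_contrast=n_per_class,
        dmr_log2_effect=2.0,
        dispersion=0.1,
        paired_fraction=0.0,
        n_marker_regions=0,
        covariate_effects={"age": 0.1, "gender": 0.1},
        n_subjects_per_group={"IIa": 10, "IIb": 10, "mMCD": 4, "MOGHE": 3, "nonMCD": 3},
    )
    samples = simulate_cohort(cfg)
    cohort = simulate_counts(samples, cfg)
    matrix = cohort.counts
    lib = estimate_library_sizes(matrix, samples)
    norm = logcpm(matrix, samples)
    by_id = {s.sample_id: s for s in samples}
    others = {"mMCD", "MOGHE", "PMG", "nonMCD"}
    panels = {}
    for name, case, ctrl in (
        ("IIa_vs_others", {"IIa"}, others),
        ("IIb_vs_others", {"IIb"}, others),
        ("IIb_vs_IIa", {"IIb"}, {"IIa"}),
    ):
        c = ContrastSpec(name, frozenset(case), frozenset(ctrl))
        design = build_design(samples, c, library_sizes=lib, tissue_mode="brain")
        disp = estimate_dispersions(matrix, design)
        tbl = test_all_regions(matrix, design, disp, name)
        case_cols = [i for i, sid in enumerate(matrix.samples) if by_id[sid].classification in case]
        ctrl_cols = [i for i, sid in enumerate(matrix.samples) if by_id[sid].classification in ctrl]
        aucs = pd.DataFrame(
            [
                (rid, region_auc(norm.values[j, case_cols], norm.values[j, ctrl_cols]).auc)
                for j, rid in enumerate(matrix.region_ids)
            ],
            columns=["region_id", "auc"],
        )
        cpg = {rid: 10 for rid in matrix.region_ids}  # CpG-rich by construction
        panels[name] = select_dmr_biomarkers(tbl, aucs, cpg)
    panel = intersect_contrasts(panels["IIa_vs_others"], panels["IIb_vs_others"], panels["IIb_vs_IIa"])
    truth = cohort.truth.set_index("region_id")
    expected = {"IIa_defining": "IIa_only", "IIb_defining": "IIb_only", "IIb_vs_IIa_top": "shared"}
    matches = [truth.loc[m.region_id, "label"] == expected[m.member_class] for m in panel.members]
    classes = pd.Series([m.member_class for m in panel.members]).value_counts().to_dict()
    return {
        "all_match": bool(matches and all(matches)),
        "match_fraction": float(np.mean(matches)) if matches else 0.0,
        "n_members": len(panel.members),
        "n_iia_defining": classes.get("IIa_defining", 0),
        "n_iib_defining": classes.get("IIb_defining", 0),
        "n_top": classes.get("IIb_vs_IIa_top", 0),
        "n_planted_per_class": n_per_class,
    }


def qpcr_recovery_error(seed: int, n_per_level: int = 4) -> float:
    """Mean absolute percent-methylation recovery error over true levels
    20/50/80% at Ct noise sd 0.1 (duplicate wells)."""
    from .core import SampleRecord

    samples = [
        SampleRecord(f"q{i}_brain", f"q{i}", "brain", "IIa", "M")
        for i in range(3 * n_per_level)
    ]
    truth = pd.DataFrame(
        {t: np.repeat([20.0, 50.0, 80.0], n_per_level) for t in ("T1", "T2", "T3")},
        index=[s.sample_id for s in samples],
    )
    wells = simulate_qpcr(["T1", "T2", "T3"], samples, truth, noise_sd=0.1, seed=seed)
    est = percent_table(wells).pivot(index="sample_id", columns="target", values="percent")
    return float((est.loc[truth.index] - truth).abs().mean().mean())


def combination_count(n_features: int = 13, max_subset_size: int = 3, seed: int = 0) -> int:
    """Number of combinations actually enumerated for a 13-member panel at
    subset size <= 3, with and without the clinical score."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(16, n_features)), columns=[f"f{i}" for i in range(n_features)]
    )
    y = np.repeat([0.0, 1.0], 8)
    res = combinatorial_roc(X, y, clinical_score=rng.normal(size=16), max_subset_size=max_subset_size)
    expected = 2 * sum(comb(n_features, k) for k in range(1, max_subset_size + 1))
    assert len(res) == expected
    return len(res)


def stepwise_exact_selection_rate(seed: int, n_reps: int = 100, n: int = 200) -> float:
    """Fraction of replicates in which bidirectional stepwise AIC selects
    exactly {age, gender} when only those two drive the outcome (5 noise
    covariates in scope)."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_reps):
        age = rng.normal(size=n)
        gender = rng.integers(0, 2, n).astype(float)
        noise = rng.normal(size=(n, 5))
        eta = age + gender
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        cov = pd.DataFrame(
            np.column_stack([age, gender, noise]),
            columns=["age", "gender", "n1", "n2", "n3", "n4", "n5"],
        )
        if set(stepwise_aic_logistic(y, cov).selected_covariates) == {"age", "gender"}:
            exact += 1
    return exact / n_reps
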