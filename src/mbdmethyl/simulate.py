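"""Synthetic cohorts, counts, peak calls and qPCR plates.

The generator is the statistical mirror of the analysis: cohorts follow
the discovery-study design (paired brain/blood across FCD subtypes and
other pathologies), region counts are negative-binomial (variance
mu + phi*mu^2) around a log-linear predictor with covariate effects,
per-sample library-size/spike offsets and planted subtype-specific DMR
effects, blood samples mix marker-region signal over leukocyte reference
profiles with simplex-distributed true proportions, and qPCR plates invert
the percent-methylation formula plus Ct noise.  Every generator is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CountMatrix, GenomicInterval, SampleRecord
from .deconvolution import DEFAULT_CELL_TYPES, CellTypeReference
from .peaks import PeakCall

log = logging.getLogger("mbdmethyl")

#: Discovery-design group sizes (13 FCD + 8 other pathologies).
DEFAULT_GROUPS = {
    "Ia": 1,
    "IIa": 4,
    "IIb": 4,
    "IIIa": 3,
    "IIId": 1,
    "mMCD": 2,
    "MOGHE": 3,
    "PMG": 1,
    "nonMCD": 2,
}

#: Planted DMR classes: label -> classification -> multiplier on
#: dmr_log2_effect.  The graded "shared" class separates IIb from IIa as
#: well as both from others, so it can satisfy all three panel contrasts.
DEFAULT_DMR_CLASSES: Tuple[Tuple[str, Dict[str, float]], ...] = (
    ("IIa_only", {"IIa": 1.0}),
    ("IIb_only", {"IIb": 1.0}),
    ("shared", {"IIa": 1.0, "IIb": 2.0}),
)


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Library sizes are log-normal around 83e6 reads scaled down by
    ``library_scale`` (default 1e4) to desk scale; relative structure is
    preserved.  Covariate effects are per-region coefficients drawn
    N(0, sd) on the log2 scale; defaults are small (<= 0.25) except tissue,
    which dominates genome-wide variance in paired brain/blood designs.
    """

    n_subjects_per_group: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    paired_fraction: float = 1.0
    n_regions: int = 2000
    n_dmr_per_contrast: int = 50
    dmr_log2_effect: float = 1.0
    baseline_log_mean_range: Tuple[float, float] = (np.log(20.0), np.log(500.0))
    dispersion: float = 0.2
    covariate_effects: Dict[str, float] = field(
        default_factory=lambda: {
            "tissue": 1.0,
            "age": 0.1,
            "gender": 0.1,
            "duration": 0.05,
            "combined_risk": 0.1,
        }
    )
    cell_types: Tuple[str, ...] = DEFAULT_CELL_TYPES
    n_marker_regions: int = 30
    spike_ratio_range: Tuple[float, float] = (0.8, 1.25)
    library_mean_reads: float = 83e6
    library_scale: float = 1e4
    library_log_sd: float = 0.3
    dmr_classes: Tuple[Tuple[str, Dict[str, float]], ...] = DEFAULT_DMR_CLASSES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0 and self.dispersion != 0:
            raise ValueError("dispersion must be > 0 (or exactly 0 for the Poisson limit)")
        total_dmrs = self.n_dmr_per_contrast * len(self.dmr_classes)
        if self.n_regions < total_dmrs + self.n_marker_regions:
            raise ValueError("n_regions too small for requested DMRs and marker regions")


@dataclass
class SimulatedCohort:
    samples: List[SampleRecord]
    counts: CountMatrix
    truth: pd.DataFrame  # region_id, label, direction, per-class log2 effects
    cell_proportions_truth: pd.DataFrame  # blood samples x cell types
    reference: Optional[CellTypeReference]  # None when no marker block was simulated


LOCALISATIONS = ("F", "T", "P", "PO", "TPO")


def simulate_cohort(config: SimulationConfig) -> List[SampleRecord]:
    """Draw a cohort of SampleRecords following the configured design.

    Each subject contributes a brain sample, plus a blood sample with
    probability ``paired_fraction``.  Onset ages ~ Uniform(0, 30) years,
    durations ~ Uniform(5, 45), age = onset + duration; spike enrichment
    ratios ~ Uniform(spike_ratio_range).
    """
    rng = np.random.default_rng(config.seed)
    records: List[SampleRecord] = []
    idx = 0
    for cls in sorted(config.n_subjects_per_group):
        for _ in range(config.n_subjects_per_group[cls]):
            idx += 1
            subject = f"S{idx:03d}"
            onset = float(np.round(rng.uniform(0, 30), 1))
            duration = float(np.round(rng.uniform(5, 45), 1))
            gender = "M" if rng.random() < 0.5 else "F"
            risk = frozenset(
                rf
                for rf in ("family_history", "stroke", "tumour", "infection", "TBI")
                if rng.random() < 0.08
            )
            common = dict(
                subject_id=subject,
                classification=cls,
                gender=gender,
                age_years=onset + duration,
                onset_age_years=onset,
                duration_years=duration,
                laterality="L" if rng.random() < 0.5 else "R",
                localisation=str(rng.choice(LOCALISATIONS)),
                mri_positive=bool(rng.random() < 0.75),
                risk_factors=risk,
                prior_surgery=bool(rng.random() < 0.1),
            )
            paired = rng.random() < config.paired_fraction
            tissues = ("brain", "blood") if paired else ("brain",)
            for tissue in tissues:
                records.append(
                    SampleRecord(
                        sample_id=f"{subject}_{tissue}",
                        tissue=tissue,
                        spike_enrichment_ratio=float(rng.uniform(*config.spike_ratio_range)),
                        **common,
                    )
                )
    return records


def _covariate_value(s: SampleRecord, name: str) -> float:
    if name == "tissue":
        return 1.0 if s.tissue == "blood" else 0.0
    if name == "age":
        return (s.age_years or 0.0) / 30.0 - 1.0
    if name == "gender":
        return 1.0 if s.gender == "M" else 0.0
    if name == "duration":
        return (s.duration_years or 0.0) / 25.0 - 1.0
    if name == "combined_risk":
        return 1.0 if s.combined_risk else 0.0
    raise KeyError(name)


def simulate_counts(samples: Sequence[SampleRecord], config: SimulationConfig) -> SimulatedCohort:
    """Simulate the region x sample methyl and input count matrices.

    log mu_ij = beta0_j + sum_c gamma_jc x_ic + ln2 * e_j(class_i)
              + log(lib_i * spike_i / scale), counts ~ NB(mu, phi);
    blood samples add a marker-region mixture term over cell-type
    profiles; input counts drop the group effects.
    """
    if not samples:
        raise ValueError("samples must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    n = len(samples)
    J = config.n_regions

    regions = [
        GenomicInterval("chr1", 1000 + 2000 * j, 1000 + 2000 * j + 500) for j in range(J)
    ]

    beta0 = rng.uniform(*config.baseline_log_mean_range, size=J)
    lib = config.library_mean_reads / config.library_scale * np.exp(
        rng.normal(0, config.library_log_sd, size=n)
    )
    spike = np.array([s.spike_enrichment_ratio for s in samples])
    size_factor = lib * spike
    size_factor = size_factor / np.exp(np.mean(np.log(size_factor)))

    # per-region covariate coefficients (log2 scale in config, ln here)
    cov_names = list(config.covariate_effects)
    gammas = {
        c: rng.normal(0, config.covariate_effects[c] * np.log(2), size=J) for c in cov_names
    }
    xs = {c: np.array([_covariate_value(s, c) for s in samples]) for c in cov_names}

    # planted DMR effects: first regions after the marker block
    labels = np.array(["null"] * J, dtype=object)
    directions = np.array([""] * J, dtype=object)
    class_names = sorted({cls for _, eff in config.dmr_classes for cls in eff})
    effects = {cls: np.zeros(J) for cls in class_names}
    cursor = config.n_marker_regions
    if config.dmr_log2_effect != 0:
        for label, eff_map in config.dmr_classes:
            for _ in range(config.n_dmr_per_contrast):
                j = cursor
                cursor += 1
                sign = 1.0 if rng.random() < 0.5 else -1.0
                labels[j] = label
                directions[j] = "increased" if sign > 0 else "reduced"
                for cls, mult in eff_map.items():
                    effects[cls][j] = sign * mult * config.dmr_log2_effect

    # leukocyte mixture structure on the marker block of blood samples
    k = len(config.cell_types)
    profile = np.exp(rng.normal(0, 1.0, size=(config.n_marker_regions, k)))
    blood_ids = [s.sample_id for s in samples if s.tissue == "blood"]
    props = (
        rng.dirichlet(np.array([3.0, 11.0, 6.0])[:k] if k == 3 else np.ones(k) * 3, size=len(blood_ids))
        if blood_ids
        else np.zeros((0, k))
    )
    props_by_id = dict(zip(blood_ids, props))

    log_mu = np.tile(beta0[:, None], (1, n))
    for c in cov_names:
        log_mu += gammas[c][:, None] * xs[c][None, :]
    ln2 = np.log(2)
    for i, s in enumerate(samples):
        cls = s.classification
        if cls in effects:
            log_mu[:, i] += ln2 * effects[cls]
        if s.tissue == "blood" and config.n_marker_regions > 0:
            mix = profile @ props_by_id[s.sample_id]
            mix = mix / mix.mean()
            log_mu[: config.n_marker_regions, i] += np.log(mix)
    log_mu_input = log_mu.copy()
    for i, s in enumerate(samples):
        cls = s.classification
        if cls in effects:
            log_mu_input[:, i] -= ln2 * effects[cls]
    log_mu += np.log(size_factor)[None, :]
    log_mu_input += np.log(size_factor)[None, :]

    def draw(lmu: np.ndarray) -> np.ndarray:
        mu = np.exp(lmu)
        if config.dispersion <= 1e-8:
            return rng.poisson(mu)
        # NB via gamma-Poisson: shape 1/phi, scale mu*phi
        lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mu)
        return rng.poisson(lam)

    methyl = draw(log_mu)
    inputc = draw(log_mu_input)

    matrix = CountMatrix(regions, [s.sample_id for s in samples], methyl, input_counts=inputc)
    truth = pd.DataFrame(
        {
            "region_id": matrix.region_ids,
            "label": labels,
            "direction": directions,
            **{f"log2_effect_{cls}": effects[cls] for cls in class_names},
            "is_marker": [j < config.n_marker_regions for j in range(J)],
        }
    )
    reference = (
        CellTypeReference(
            marker_regions=matrix.region_ids[: config.n_marker_regions],
            cell_types=list(config.cell_types),
            profile=profile,
        )
        if config.n_marker_regions >= k
        else None
    )
    props_df = pd.DataFrame(props, index=blood_ids, columns=list(config.cell_types))
    return SimulatedCohort(
        samples=list(samples),
        counts=matrix,
        truth=truth,
        cell_proportions_truth=props_df,
        reference=reference,
    )


def simulate_peak_calls(
    samples: Sequence[SampleRecord],
    config: SimulationConfig,
    regions: Optional[Sequence[GenomicInterval]] = None,
    emit_prob: float = 0.9,
    jitter: int = 50,
    n_decoys: int = 20,
) -> Dict[str, List[PeakCall]]:
    """Per-sample peak-call tables over the true region set.

    Each true region is emitted per sample with probability ``emit_prob``,
    boundaries jittered by up to ``jitter`` bp, fold-enrichment above the
    retention threshold; decoy peaks carry sub-threshold enrichment.
    """
    rng = np.random.default_rng(config.seed + 2)
    if regions is None:
        regions = [
            GenomicInterval("chr1", 1000 + 2000 * j, 1000 + 2000 * j + 500)
            for j in range(config.n_regions)
        ]
    calls: Dict[str, List[PeakCall]] = {}
    for s in samples:
        out = []
        for r in regions:
            if rng.random() >= emit_prob:
                continue
            ds = int(rng.integers(-jitter, jitter + 1))
            de = int(rng.integers(-jitter, jitter + 1))
            start = max(0, r.start + ds)
            end = max(start + 50, r.end + de)
            out.append(
                PeakCall(
                    interval=GenomicInterval(r.chrom, start, end),
                    sample_id=s.sample_id,
                    fold_enrichment=float(rng.uniform(4.5, 12.0)),
                    p_value=float(rng.uniform(1e-6, 0.009)),
                )
            )
        for _ in range(n_decoys):
            pos = int(rng.integers(0, 2000 * len(regions)))
            out.append(
                PeakCall(
                    interval=GenomicInterval("chr1", pos, pos + 300),
                    sample_id=s.sample_id,
                    fold_enrichment=float(rng.uniform(0.5, 3.9)),
                    p_value=float(rng.uniform(1e-4, 0.5)),
                )
            )
        calls[s.sample_id] = out
    return calls


def simulate_marker_signals(
    n_markers: int,
    n_samples: int,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> Tuple[CellTypeReference, np.ndarray, np.ndarray]:
    """Direct marker-signal simulation for deconvolution checks.

    Returns (reference, true proportions (samples x k), signal matrix
    (markers x samples)); Y = P w + N(0, noise_sd).
    """
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    P = np.exp(rng.normal(0, 1.0, size=(n_markers, k)))
    W = rng.dirichlet(np.ones(k) * 3.0, size=n_samples)
    Y = P @ W.T + rng.normal(0, noise_sd, size=(n_markers, n_samples))
    ref = CellTypeReference(
        marker_regions=[f"m{i}" for i in range(n_markers)],
        cell_types=list(cell_types),
        profile=P,
    )
    return ref, W, Y


def simulate_qpcr(
    panel_targets: Sequence[str],
    samples: Sequence[SampleRecord],
    true_percent: pd.DataFrame,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Long-format qPCR well table encoding the given true percents.

    ``true_percent`` is indexed by sample_id with one column per target,
    values in (0, 100); values outside are clipped to [1, 99] with a
    warning.  Ct_bound - Ct_unbound = -log2(p/(1-p)) + noise; spike wells
    are constant up to noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in samples:
        spike_base = 22.0
        for frac in ("bound", "unbound"):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (s.sample_id, "spike", frac, rep, spike_base + rng.normal(0, noise_sd))
                )
        for target in panel_targets:
            p = float(true_percent.loc[s.sample_id, target]) / 100.0
            if not (0 < p < 1):
                log.warning("true percent outside (0,100) for %s/%s; clipped", s.sample_id, target)
                p = min(max(p, 0.01), 0.99)
            ct_unbound = rng.uniform(22.0, 26.0)
            delta = -np.log2(p / (1 - p))
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (s.sample_id, target, "unbound", rep, ct_unbound + rng.normal(0, noise_sd))
                )
                rows.append(
                    (
                        s.sample_id,
                        target,
                        "bound",
                        rep,
                        ct_unbound + delta + rng.normal(0, noise_sd),
                    )
                )
    return pd.DataFrame(rows, columns=["sample_id", "target", "fraction", "replicate", "ct"])
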