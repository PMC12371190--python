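"""Core data model shared by every pipeline stage.

Coordinates are 0-based, half-open ``[start, end)`` (BED convention)
throughout the package; every interval emitted by any module follows it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

CLASSIFICATIONS = ("Ia", "IIa", "IIb", "IIIa", "IIId", "mMCD", "MOGHE", "PMG", "nonMCD")
FCD_CLASSIFICATIONS = ("Ia", "IIa", "IIb", "IIIa", "IIId")
OTHER_CLASSIFICATIONS = ("mMCD", "MOGHE", "PMG", "nonMCD")
TISSUES = ("brain", "blood")
RISK_FACTORS = ("family_history", "stroke", "tumour", "infection", "TBI")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic region in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class SampleRecord:
    """One subject/tissue sample with its clinical covariates.

    Paired samples share ``subject_id`` with distinct ``tissue``.  Missing
    clinical values are ``None``, never silently zero.
    """

    sample_id: str
    subject_id: str
    tissue: str
    classification: str
    gender: str
    age_years: Optional[float] = None
    onset_age_years: Optional[float] = None
    duration_years: Optional[float] = None
    laterality: Optional[str] = None
    localisation: Optional[str] = None
    engel: Optional[str] = None
    mri_positive: Optional[bool] = None
    risk_factors: frozenset = field(default_factory=frozenset)
    prior_surgery: bool = False
    spike_enrichment_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r} for sample {self.sample_id}")
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(
                f"unknown classification {self.classification!r} for sample {self.sample_id}"
            )
        if self.gender not in ("M", "F"):
            raise ValueError(f"unknown gender {self.gender!r} for sample {self.sample_id}")
        unknown = set(self.risk_factors) - set(RISK_FACTORS)
        if unknown:
            raise ValueError(f"unknown risk factors {sorted(unknown)} for {self.sample_id}")
        if not self.spike_enrichment_ratio > 0:
            raise ValueError(f"spike_enrichment_ratio must be > 0 for {self.sample_id}")
        self.risk_factors = frozenset(self.risk_factors)

    @property
    def is_fcd(self) -> bool:
        return self.classification in FCD_CLASSIFICATIONS

    @property
    def combined_risk(self) -> bool:
        """Set-valued risk factors collapsed to one binary modelling covariate."""
        return len(self.risk_factors) > 0


@dataclass
class CohortSummary:
    """Counts summarising a cohort; totals equal the sum of their parts."""

    n_samples: int
    per_classification: dict
    per_tissue: dict
    n_paired: int
    n_unpaired_brain: int
    n_unpaired_blood: int
    n_fcd: int
    n_other: int


def cohort_summary(records: Sequence[SampleRecord]) -> CohortSummary:
    """Summarise classification, tissue and brain/blood pairing structure.

    A subject counts as paired when it contributes at least one brain and
    one blood sample (matched on ``subject_id``).
    """
    per_cls = {c: 0 for c in CLASSIFICATIONS}
    per_tissue = {t: 0 for t in TISSUES}
    subjects: dict = {}
    for r in records:
        per_cls[r.classification] += 1
        per_tissue[r.tissue] += 1
        subjects.setdefault(r.subject_id, set()).add(r.tissue)
    n_paired = sum(1 for t in subjects.values() if {"brain", "blood"} <= t)
    n_unp_brain = sum(1 for t in subjects.values() if t == {"brain"})
    n_unp_blood = sum(1 for t in subjects.values() if t == {"blood"})
    n_fcd = sum(per_cls[c] for c in FCD_CLASSIFICATIONS)
    n_other = sum(per_cls[c] for c in OTHER_CLASSIFICATIONS)
    assert n_fcd + n_other == len(records)
    return CohortSummary(
        n_samples=len(records),
        per_classification=per_cls,
        per_tissue=per_tissue,
        n_paired=n_paired,
        n_unpaired_brain=n_unp_brain,
        n_unpaired_blood=n_unp_blood,
        n_fcd=n_fcd,
        n_other=n_other,
    )


class CountMatrix:
    """Regions x samples integer read counts (methyl capture, optional input).

    Row order follows ``regions``; column order follows ``samples`` and is
    the authoritative sample order for all downstream modelling.
    """

    def __init__(
        self,
        regions: Sequence[GenomicInterval],
        samples: Sequence[str],
        methyl_counts: np.ndarray,
        input_counts: Optional[np.ndarray] = None,
        region_ids: Optional[Sequence[str]] = None,
    ) -> None:
        self.regions = list(regions)
        self.samples = list(samples)
        self.methyl_counts = np.asarray(methyl_counts, dtype=np.int64)
        self.input_counts = None if input_counts is None else np.asarray(input_counts, dtype=np.int64)
        if region_ids is None:
            region_ids = [r.region_id for r in self.regions]
        self.region_ids = list(region_ids)
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")
        if self.methyl_counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.methyl_counts.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if (self.methyl_counts < 0).any():
            raise ValueError("negative methyl counts")
        if self.input_counts is not None:
            if self.input_counts.shape != self.methyl_counts.shape:
                raise ValueError("input_counts shape mismatch")
            if (self.input_counts < 0).any():
                raise ValueError("negative input counts")

    @property
    def shape(self) -> tuple:
        return self.methyl_counts.shape

    def library_sizes(self) -> np.ndarray:
        """Per-sample total methyl-capture counts (column sums)."""
        return self.methyl_counts.sum(axis=0).astype(float)

    def subset_regions(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            [self.regions[i] for i in idx],
            self.samples,
            self.methyl_counts[idx],
            None if self.input_counts is None else self.input_counts[idx],
            [self.region_ids[i] for i in idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(
            self.regions,
            list(sample_ids),
            self.methyl_counts[:, idx],
            None if self.input_counts is None else self.input_counts[:, idx],
            self.region_ids,
        )
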