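"""Packaged cohort fixtures.

``load_discovery_cohort`` reads the transcribed clinical summary of the
21-subject discovery cohort (brain samples; each subject also contributed a
matched blood sample).  One published count discrepancy exists between the
study-design and results text for the "no MCD" group (3 vs 2); the fixture
keeps 21 subjects total (13 FCD, 8 other pathologies: mMCD 2, MOGHE 3,
PMG 1, non-MCD 2).  ``age_years`` is derived as onset + duration because
the published table prints no age at surgery; the duration recorded as
"YE" for one FCD IIIa subject is stored as missing, as is the age derived
from it.

``load_replication_cohort`` builds the qPCR replication cohort from its
published group sizes (paired brain+blood n=32: IIa 15, IIb 12, others 5;
unpaired brain n=29: IIa 11, IIb 11, others 7; unpaired blood n=13:
IIa 10, IIb 3).  Per-subject clinical values beyond the group sizes are
synthetic (deterministic placeholder ages), since only the sizes are
published.
"""

from __future__ import annotations

from importlib import resources
from typing import List

from .core import SampleRecord
from .io import parse_sample_sheet


def load_discovery_cohort() -> List[SampleRecord]:
    """The 21 discovery-cohort brain samples with clinical covariates."""
    with resources.as_file(
        resources.files("mbdmethyl.data").joinpath("discovery_cohort.csv")
    ) as path:
        return parse_sample_sheet(path)


def load_replication_cohort() -> List[SampleRecord]:
    """The replication cohort used for Methyl-qPCR validation.

    Group sizes follow the published design; individual ages are synthetic
    placeholders (30 + subject index modulo 40).
    """
    records: List[SampleRecord] = []

    def add(subject: str, tissue: str, cls: str, idx: int) -> None:
        records.append(
            SampleRecord(
                sample_id=f"{subject}_{tissue}",
                subject_id=subject,
                tissue=tissue,
                classification=cls,
                gender="F" if idx % 2 else "M",
                age_years=30.0 + (idx * 7) % 40,
            )
        )

    paired = [("IIa", 15), ("IIb", 12), ("nonMCD", 5)]
    idx = 0
    for cls, n in paired:
        for _ in range(n):
            idx += 1
            subject = f"R{idx:02d}"
            add(subject, "brain", cls, idx)
            add(subject, "blood", cls, idx)

    unpaired_brain = [("IIa", 11), ("IIb", 11), ("nonMCD", 7)]
    for cls, n in unpaired_brain:
        for _ in range(n):
            idx += 1
            add(f"R{idx:02d}", "brain", cls, idx)

    unpaired_blood = [("IIa", 10), ("IIb", 3)]
    for cls, n in unpaired_blood:
        for _ in range(n):
            idx += 1
            add(f"R{idx:02d}", "blood", cls, idx)

    return records
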