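"""Readers and writers for the plain-text formats the pipeline exchanges.

Sample sheets are CSV with a versioned header; intervals are BED3+ with
extra columns carried through as attributes; count matrices are TSV with
``chrom  start  end  region_id`` followed by one column per sample.  Every
reader/writer pair is a bijection on valid files.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CountMatrix, GenomicInterval, SampleRecord

log = logging.getLogger("mbdmethyl")

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "subject_id",
    "tissue",
    "classification",
    "gender",
    "age_years",
    "onset_age_years",
    "duration_years",
    "laterality",
    "localisation",
    "engel",
    "mri_positive",
    "risk_factors",
    "prior_surgery",
    "spike_enrichment_ratio",
]

_MISSING = {"", "NA", "N/A", "nan", "None", "YE"}


def _opt_float(value: str, row: int, column: str) -> Optional[float]:
    value = value.strip()
    if value in _MISSING:
        return None
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"row {row}: non-numeric {column} {value!r}") from None


def _opt_bool(value: str) -> Optional[bool]:
    value = value.strip().lower()
    if value in {s.lower() for s in _MISSING}:
        return None
    return value in {"true", "1", "+", "yes"}


def parse_sample_sheet(path) -> List[SampleRecord]:
    """Parse a cohort sample sheet (CSV) into SampleRecords.

    Unknown classification strings and duplicate sample ids are hard
    errors; missing clinical values become ``None``.  Unknown columns are
    tolerated and ignored (carried through by :func:`write_sample_sheet`
    only for known fields).
    """
    records: List[SampleRecord] = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing_cols = set(SAMPLE_SHEET_COLUMNS[:5]) - set(reader.fieldnames or ())
        if missing_cols:
            raise ValueError(f"sample sheet missing required columns: {sorted(missing_cols)}")
        for i, row in enumerate(reader, start=2):
            sid = row["sample_id"].strip()
            if sid in seen:
                raise ValueError(f"duplicate sample_id {sid!r} at row {i}")
            seen.add(sid)
            risk = frozenset(
                t.strip() for t in row.get("risk_factors", "").split(";") if t.strip()
            )
            spike = row.get("spike_enrichment_ratio", "").strip()
            records.append(
                SampleRecord(
                    sample_id=sid,
                    subject_id=row["subject_id"].strip(),
                    tissue=row["tissue"].strip(),
                    classification=row["classification"].strip(),
                    gender=row["gender"].strip(),
                    age_years=_opt_float(row.get("age_years", ""), i, "age_years"),
                    onset_age_years=_opt_float(row.get("onset_age_years", ""), i, "onset_age_years"),
                    duration_years=_opt_float(row.get("duration_years", ""), i, "duration_years"),
                    laterality=row.get("laterality", "").strip() or None,
                    localisation=row.get("localisation", "").strip() or None,
                    engel=(row.get("engel", "").strip() or None)
                    if row.get("engel", "").strip() not in _MISSING
                    else None,
                    mri_positive=_opt_bool(row.get("mri_positive", "")),
                    risk_factors=risk,
                    prior_surgery=_opt_bool(row.get("prior_surgery", "false")) or False,
                    spike_enrichment_ratio=float(spike) if spike not in _MISSING else 1.0,
                )
            )
    return records


def write_sample_sheet(records: Sequence[SampleRecord], path) -> None:
    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, float) and v == int(v):
            return str(int(v))
        return str(v)

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SAMPLE_SHEET_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.sample_id,
                    r.subject_id,
                    r.tissue,
                    r.classification,
                    r.gender,
                    fmt(r.age_years),
                    fmt(r.onset_age_years),
                    fmt(r.duration_years),
                    fmt(r.laterality),
                    fmt(r.localisation),
                    fmt(r.engel),
                    fmt(r.mri_positive),
                    ";".join(sorted(r.risk_factors)),
                    fmt(r.prior_surgery),
                    repr(r.spike_enrichment_ratio),
                ]
            )


def read_intervals(path) -> Tuple[List[GenomicInterval], List[dict]]:
    """Read a BED3+ file.

    Returns the intervals plus a parallel list of attribute dicts holding
    any extra columns (named ``col4``, ``col5``, ... unless a recognised
    numeric pair, in which case ``score``/``p_value``).
    """
    intervals: List[GenomicInterval] = []
    attrs: List[dict] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path} line {ln}: expected >= 3 tab-separated columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path} line {ln}: non-integer coordinates") from None
            if end <= start:
                raise ValueError(f"{path} line {ln}: end <= start ({start}, {end})")
            intervals.append(GenomicInterval(chrom, start, end))
            extra = {f"col{i + 4}": v for i, v in enumerate(parts[3:])}
            attrs.append(extra)
    return intervals, attrs


def write_intervals(intervals: Sequence[GenomicInterval], path, attrs: Optional[Sequence[dict]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if attrs is not None:
                extra = attrs[i]
                cols += [str(extra[k]) for k in sorted(extra, key=lambda k: int(k[3:]))]
            fh.write("\t".join(cols) + "\n")


def read_counts(path, sample_ids: Optional[Sequence[str]] = None, strict: bool = False) -> CountMatrix:
    """Read a region x sample count matrix TSV.

    First four columns are chrom/start/end/region_id; remaining column
    order defines the sample order.  If ``sample_ids`` is given, unknown
    sample columns warn (or raise when ``strict``).
    """
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "region_id"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"count matrix must start with columns {required}")
    sample_cols = list(df.columns[4:])
    if sample_ids is not None:
        unknown = [s for s in sample_cols if s not in set(sample_ids)]
        if unknown:
            msg = f"count matrix columns not in sample sheet: {unknown}"
            if strict:
                raise ValueError(msg)
            log.warning(msg)
    counts = df[sample_cols].to_numpy()
    if (counts < 0).any():
        raise ValueError("negative count in matrix")
    regions = [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
    return CountMatrix(regions, sample_cols, counts, region_ids=list(df["region_id"].astype(str)))


def write_counts(matrix: CountMatrix, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in matrix.regions],
            "start": [r.start for r in matrix.regions],
            "end": [r.end for r in matrix.regions],
            "region_id": matrix.region_ids,
        }
    )
    for j, s in enumerate(matrix.samples):
        df[s] = matrix.methyl_counts[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_gene_models(path):
    """Read a gene-model TSV into :class:`mbdmethyl.peaks.GeneModel` objects.

    Columns: gene_id, chrom, start, end, strand, exon_starts, exon_ends
    (comma-separated block lists, may be empty).
    """
    from .peaks import GeneModel  # deferred to avoid import cycle

    df = pd.read_csv(path, sep="\t")
    models = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",") if x not in ("", "nan")]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x not in ("", "nan")]
        exons = [GenomicInterval(row.chrom, s, e) for s, e in zip(starts, ends)]
        models.append(
            GeneModel(
                gene_id=str(row.gene_id),
                genebody=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                strand=str(row.strand),
                exons=exons,
            )
        )
    return models


def read_cell_reference(path) -> Tuple[List[str], List[str], np.ndarray]:
    """Read a cell-type reference TSV: marker_region_id then one column per cell type."""
    df = pd.read_csv(path, sep="\t")
    markers = list(df.iloc[:, 0].astype(str))
    cell_types = list(df.columns[1:])
    profile = df.iloc[:, 1:].to_numpy(dtype=float)
    return markers, cell_types, profile


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
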