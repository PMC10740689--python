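"""Typed tabular I/O for every table the pipeline touches.

All tables are UTF-8 TSV with a mandatory header row and "." as the decimal
point.  Readers validate strictly and raise :class:`~pfsskit.errors.FormatError`
/ :class:`~pfsskit.errors.ValidationError` subclasses with row-level context;
writers emit full shortest-roundtrip float precision so that write-then-read
of any valid table yields identical records (report-level tables produced by
the CLI are formatted separately).

Table formats
-------------
sites.tsv        structure_id, sf_model_id, chain, residue_number, anchor_atom, raw_score
calibration.tsv  sf_model_id, mu, sigma, z_threshold
domains.tsv      target_id, domain_id, ranges, category
metrics.tsv      group_name, domain_id, metric_name, value

``ranges`` encodes possibly discontinuous 1-based inclusive residue segments
as comma-separated ``start-end`` pairs, e.g. ``"5-10,40-60"``.  Model-side
structure identifiers follow ``"<target>/<group>/<attempt>"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DuplicateKeyError, FormatError, ValidationError

__all__ = [
    "CATEGORIES",
    "METRICS",
    "ASCENDING_METRICS",
    "SitePrediction",
    "CalibrationEntry",
    "DomainDefinition",
    "MetricRecord",
    "read_site_table",
    "write_site_table",
    "read_calibration_table",
    "write_calibration_table",
    "calibration_index",
    "read_domain_table",
    "write_domain_table",
    "residues_in_domain",
    "read_metric_table",
    "write_metric_table",
    "metrics_frame",
    "make_model_structure_id",
    "split_model_structure_id",
]

#: CASP difficulty categories a domain may carry.
CATEGORIES = ("FM", "TBM-easy", "TBM-hard", "TBM/FM", "Other")

#: Standard per-domain quality metrics consumed (never computed) by the pipeline.
METRICS = ("LDDT", "GDT-TS", "GDT-HA", "GDC-SC", "GDC-ALL", "RMS-CA", "RMS-ALL")

#: Metrics for which smaller is better (root-mean-square deviations, in A).
ASCENDING_METRICS = ("RMS-CA", "RMS-ALL")

SITE_COLUMNS = ["structure_id", "sf_model_id", "chain", "residue_number", "anchor_atom", "raw_score"]
CALIBRATION_COLUMNS = ["sf_model_id", "mu", "sigma", "z_threshold"]
DOMAIN_COLUMNS = ["target_id", "domain_id", "ranges", "category"]
METRIC_COLUMNS = ["group_name", "domain_id", "metric_name", "value"]


@dataclass(frozen=True)
class SitePrediction:
    """One raw functional-site prediction score at an anchor residue.

    ``structure_id`` names either a reference structure (the target id) or a
    submitted model, encoded ``"<target>/<group>/<attempt>"``.  ``raw_score``
    is the dimensionless microenvironment score emitted by the upstream
    functional-site scanner for the SeqFEATURE model ``sf_model_id``.
    Residue numbers use author numbering from the coordinate file: integer,
    but otherwise arbitrary.
    """

    structure_id: str
    sf_model_id: str
    chain: str
    residue_number: int
    anchor_atom: str
    raw_score: float

    @property
    def key(self) -> tuple[str, str, str, int, str]:
        """The uniqueness key within one table."""
        return (self.structure_id, self.sf_model_id, self.chain,
                self.residue_number, self.anchor_atom)


@dataclass(frozen=True)
class CalibrationEntry:
    """Per-SeqFEATURE-model raw-score distribution parameters.

    ``mu``/``sigma`` are the mean and standard deviation of raw scores on a
    large reference corpus, used to Z-score new raw scores. ``z_threshold``
    is the Z cutoff achieving >=90% specificity for this model; only
    reference-side predictions strictly above it enter an analysis.
    """

    sf_model_id: str
    mu: float
    sigma: float
    z_threshold: float


@dataclass(frozen=True)
class DomainDefinition:
    """An evaluation domain: a target, possibly discontinuous residue ranges,
    and a difficulty category."""

    target_id: str
    domain_id: str
    ranges: tuple[tuple[int, int], ...]
    category: str


@dataclass(frozen=True)
class MetricRecord:
    """One precomputed standard-metric value for a (group, domain)."""

    group_name: str
    domain_id: str
    metric_name: str
    value: float


# ---------------------------------------------------------------------------
# low-level helpers


def _read_tsv(path: str | Path, columns: Sequence[str], table: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{table}: file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{table} ({path}): missing column(s): {', '.join(missing)}")
    return df


def _parse_int(text: str, table: str, line: int, column: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise FormatError(f"{table} line {line}: non-integer {column}: {text!r}") from None


def _parse_float(text: str, table: str, line: int, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"{table} line {line}: non-numeric {column}: {text!r}") from None


def _check_unique(keys: Iterable, table: str) -> None:
    seen = set()
    for key in keys:
        if key in seen:
            raise DuplicateKeyError(f"{table}: duplicate key {key!r}")
        seen.add(key)


# ---------------------------------------------------------------------------
# site tables


def read_site_table(path: str | Path) -> list[SitePrediction]:
    """Read a site-prediction score table.

    Raises :class:`FormatError` naming the column or line on malformed input
    and :class:`DuplicateKeyError` if a
    (structure, model, chain, residue, atom) key repeats.
    """
    df = _read_tsv(path, SITE_COLUMNS, "site table")
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        records.append(SitePrediction(
            structure_id=row.structure_id,
            sf_model_id=row.sf_model_id,
            chain=row.chain,
            residue_number=_parse_int(row.residue_number, "site table", line, "residue_number"),
            anchor_atom=row.anchor_atom,
            raw_score=_parse_float(row.raw_score, "site table", line, "raw_score"),
        ))
    _check_unique((r.key for r in records), "site table")
    return records


def write_site_table(records: Iterable[SitePrediction], path: str | Path) -> None:
    records = list(records)
    _check_unique((r.key for r in records), "site table")
    pd.DataFrame(
        [(r.structure_id, r.sf_model_id, r.chain, r.residue_number, r.anchor_atom,
          repr(r.raw_score)) for r in records],
        columns=SITE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# calibration tables


def read_calibration_table(path: str | Path) -> list[CalibrationEntry]:
    """Read per-SeqFEATURE-model (mu, sigma, z_threshold) calibration rows."""
    df = _read_tsv(path, CALIBRATION_COLUMNS, "calibration table")
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        sigma = _parse_float(row.sigma, "calibration table", line, "sigma")
        if not sigma > 0:
            raise ValidationError(
                f"calibration table line {line}: sigma must be > 0 for "
                f"{row.sf_model_id!r}, got {sigma}")
        records.append(CalibrationEntry(
            sf_model_id=row.sf_model_id,
            mu=_parse_float(row.mu, "calibration table", line, "mu"),
            sigma=sigma,
            z_threshold=_parse_float(row.z_threshold, "calibration table", line, "z_threshold"),
        ))
    _check_unique((r.sf_model_id for r in records), "calibration table")
    return records


def write_calibration_table(records: Iterable[CalibrationEntry], path: str | Path) -> None:
    records = list(records)
    _check_unique((r.sf_model_id for r in records), "calibration table")
    pd.DataFrame(
        [(r.sf_model_id, repr(r.mu), repr(r.sigma), repr(r.z_threshold)) for r in records],
        columns=CALIBRATION_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def calibration_index(entries: Iterable[CalibrationEntry]) -> dict[str, CalibrationEntry]:
    """Index calibration entries by SeqFEATURE model id."""
    index: dict[str, CalibrationEntry] = {}
    for entry in entries:
        if entry.sf_model_id in index:
            raise DuplicateKeyError(f"calibration: duplicate sf_model_id {entry.sf_model_id!r}")
        index[entry.sf_model_id] = entry
    return index


# ---------------------------------------------------------------------------
# domain tables

_SEGMENT_RE = re.compile(r"^\s*(-?\d+)\s*-\s*(-?\d+)\s*$")


def _parse_ranges(text: str, context: str) -> tuple[tuple[int, int], ...]:
    segments = []
    for part in text.split(","):
        m = _SEGMENT_RE.match(part)
        if m is None:
            raise FormatError(f"{context}: unparseable residue segment {part!r}")
        start, end = int(m.group(1)), int(m.group(2))
        if start > end:
            raise ValidationError(f"{context}: segment start {start} > end {end}")
        segments.append((start, end))
    ordered = sorted(segments)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if s2 <= e1:
            raise ValidationError(
                f"{context}: overlapping segments {s1}-{e1} and {s2}-{e2}")
    return tuple(segments)


def read_domain_table(path: str | Path) -> list[DomainDefinition]:
    """Read domain definitions; discontinuous residue ranges are preserved
    as multiple segments."""
    df = _read_tsv(path, DOMAIN_COLUMNS, "domain table")
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        context = f"domain table line {line} ({row.domain_id})"
        if row.category not in CATEGORIES:
            raise ValidationError(
                f"{context}: unknown category {row.category!r}; "
                f"expected one of {', '.join(CATEGORIES)}")
        records.append(DomainDefinition(
            target_id=row.target_id,
            domain_id=row.domain_id,
            ranges=_parse_ranges(row.ranges, context),
            category=row.category,
        ))
    _check_unique((r.domain_id for r in records), "domain table")
    return records


def write_domain_table(records: Iterable[DomainDefinition], path: str | Path) -> None:
    pd.DataFrame(
        [(r.target_id, r.domain_id,
          ",".join(f"{s}-{e}" for s, e in r.ranges), r.category) for r in records],
        columns=DOMAIN_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def residues_in_domain(domain: DomainDefinition) -> set[int]:
    """The set of residue numbers covered by a domain: the union of its
    closed integer segments."""
    residues: set[int] = set()
    for start, end in domain.ranges:
        residues.update(range(start, end + 1))
    return residues


# ---------------------------------------------------------------------------
# metric tables


def read_metric_table(path: str | Path) -> list[MetricRecord]:
    """Read precomputed standard-metric values, one per (group, domain, metric)."""
    df = _read_tsv(path, METRIC_COLUMNS, "metric table")
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        if row.metric_name not in METRICS:
            raise ValidationError(
                f"metric table line {line}: unknown metric {row.metric_name!r}")
        records.append(MetricRecord(
            group_name=row.group_name,
            domain_id=row.domain_id,
            metric_name=row.metric_name,
            value=_parse_float(row.value, "metric table", line, "value"),
        ))
    _check_unique(((r.group_name, r.domain_id, r.metric_name) for r in records), "metric table")
    return records


def write_metric_table(records: Iterable[MetricRecord], path: str | Path) -> None:
    records = list(records)
    _check_unique(((r.group_name, r.domain_id, r.metric_name) for r in records), "metric table")
    pd.DataFrame(
        [(r.group_name, r.domain_id, r.metric_name, repr(r.value)) for r in records],
        columns=METRIC_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def metrics_frame(records: Iterable[MetricRecord]) -> pd.DataFrame:
    """Metric records as a tidy DataFrame (group_name, domain_id, metric_name, value)."""
    return pd.DataFrame(
        [(r.group_name, r.domain_id, r.metric_name, r.value) for r in records],
        columns=METRIC_COLUMNS,
    )


# ---------------------------------------------------------------------------
# model structure identifiers


def make_model_structure_id(target_id: str, group_name: str, attempt: int) -> str:
    """Compose the ``"<target>/<group>/<attempt>"`` identifier of a submitted model."""
    if "/" in target_id or "/" in group_name:
        raise ValidationError("target and group names must not contain '/'")
    return f"{target_id}/{group_name}/{attempt}"


def split_model_structure_id(structure_id: str) -> tuple[str, str, int]:
    """Split a model structure id into (target_id, group_name, attempt)."""
    parts = structure_id.split("/")
    if len(parts) != 3:
        raise FormatError(
            f"model structure_id must be '<target>/<group>/<attempt>', got {structure_id!r}")
    target, group, attempt = parts
    try:
        return target, group, int(attempt)
    except ValueError:
        raise FormatError(
            f"model attempt must be an integer in structure_id {structure_id!r}") from None
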