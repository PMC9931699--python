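"""Bibliometric data curation.

Turns a raw multi-source publication table (Scopus / Web of Science /
Google Scholar citation counts, publication year, reproducibility group,
per-year journal impact factors) into per-group analysis vectors.

Curation rules:

* Citation counts missing from Scopus or Web of Science are imputed as the
  Google Scholar count times a fixed factor (default 0.6287, i.e. Scopus/WoS
  run on average 62.87% of Google Scholar). Google Scholar itself is never
  imputed.
* The per-paper citation value is the arithmetic mean of the three sources.
* Optionally, citations are normalized by the journal impact factor (JIF),
  averaged over the years it is available within a fixed window
  (default 2014-2021); papers without any JIF in the window are excluded
  from JIF-normalized analyses.
* Papers are deduplicated by identifier (several models from one paper count
  once) and filtered to an inclusive publication-year period.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "CitationRecord",
    "GroupDataset",
    "CurationConfig",
    "CurationError",
    "impute_missing_sources",
    "average_citations",
    "average_jif",
    "normalize_by_jif",
    "filter_and_deduplicate",
    "build_group_dataset",
    "curate",
    "read_citations_table",
    "write_citations_table",
]

JIF_YEARS = (2014, 2021)


class Group(str, Enum):
    """Reproducibility classification of a published model's paper."""

    REPRODUCIBLE = "REPRODUCIBLE"
    NON_REPRODUCIBLE = "NON_REPRODUCIBLE"
    PETAB = "PETAB"


class CurationError(ValueError):
    """A record violates the curation contract."""


@dataclass(frozen=True)
class CitationRecord:
    """One publication with per-source citation counts and per-year JIFs.

    ``None`` marks a missing citation source. At least one source must be
    present, present counts must be finite and non-negative, and JIFs must
    be positive and keyed by years inside the JIF window.
    """

    paper_id: str
    year: int
    group: Group
    scopus: float | None = None
    wos: float | None = None
    gscholar: float | None = None
    jif_by_year: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sources = (self.scopus, self.wos, self.gscholar)
        if all(s is None for s in sources):
            raise CurationError(f"{self.paper_id}: no citation source present")
        for name, s in zip(("scopus", "wos", "gscholar"), sources):
            if s is not None and (not math.isfinite(s) or s < 0):
                raise CurationError(f"{self.paper_id}: invalid {name} count {s!r}")
        for y, j in self.jif_by_year.items():
            if not (JIF_YEARS[0] <= int(y) <= JIF_YEARS[1]):
                raise CurationError(f"{self.paper_id}: JIF year {y} outside {JIF_YEARS}")
            if not (math.isfinite(j) and j > 0):
                raise CurationError(f"{self.paper_id}: invalid JIF {j!r} for {y}")


@dataclass(frozen=True)
class GroupDataset:
    """A labelled vector of analysis values for one group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise CurationError(f"group {self.label!r}: needs >= 2 values, got {v.size}")
        if not np.all(np.isfinite(v)):
            raise CurationError(f"group {self.label!r}: non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class CurationConfig:
    """Knobs of the curation pipeline.

    ``imputation_factor`` is the Scopus/WoS-to-Google-Scholar ratio used to
    fill missing sources; the default 0.6287 is a corpus-level constant, not
    re-estimated from the input data.
    """

    imputation_factor: float = 0.6287
    period: tuple[int, int] = (1985, 2020)
    jif_years: tuple[int, int] = JIF_YEARS
    normalize_by_jif: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.imputation_factor <= 1):
            raise CurationError(f"imputation_factor must be in (0, 1], got {self.imputation_factor}")
        if self.period[0] > self.period[1]:
            raise CurationError(f"empty period {self.period}")


def impute_missing_sources(record: CitationRecord, cfg: CurationConfig) -> CitationRecord:
    """Fill missing Scopus/WoS counts with gscholar x imputation factor.

    Present values are untouched and Google Scholar is never imputed;
    a record missing Scopus or WoS *and* Google Scholar cannot be imputed.
    """
    if record.scopus is not None and record.wos is not None:
        return record
    if record.gscholar is None:
        raise CurationError(
            f"{record.paper_id}: cannot impute (Scopus/WoS missing and no Google Scholar count)"
        )
    fill = record.gscholar * cfg.imputation_factor
    return replace(
        record,
        scopus=record.scopus if record.scopus is not None else fill,
        wos=record.wos if record.wos is not None else fill,
    )


def average_citations(record: CitationRecord) -> float:
    """Arithmetic mean of the three source counts (record must be imputed)."""
    if record.scopus is None or record.wos is None or record.gscholar is None:
        raise CurationError(f"{record.paper_id}: run imputation first, a source is missing")
    return (record.scopus + record.wos + record.gscholar) / 3.0


def average_jif(record: CitationRecord, cfg: CurationConfig) -> float | None:
    """Mean JIF over the years present within the window; None if none are.

    Partially covered journals are averaged over their available years only.
    """
    lo, hi = cfg.jif_years
    vals = [j for y, j in record.jif_by_year.items() if lo <= int(y) <= hi]
    if not vals:
        return None
    return float(np.mean(vals))


def normalize_by_jif(citations: float, jif: float) -> float:
    """Citations divided by the (positive) journal impact factor."""
    if jif is None or not (math.isfinite(jif) and jif > 0):
        raise CurationError(f"cannot normalize by JIF {jif!r}")
    return citations / jif


def filter_and_deduplicate(
    records: Iterable[CitationRecord], cfg: CurationConfig
) -> list[CitationRecord]:
    """One record per paper_id, restricted to the inclusive year period.

    Exact duplicates collapse to one record; duplicates with conflicting
    fields are a curation error, never silently resolved. Output is sorted
    by paper_id.
    """
    by_id: dict[str, CitationRecord] = {}
    for rec in records:
        prev = by_id.get(rec.paper_id)
        if prev is None:
            by_id[rec.paper_id] = rec
        elif prev != rec:
            raise CurationError(f"{rec.paper_id}: duplicate paper_id with conflicting fields")
    lo, hi = cfg.period
    return [by_id[k] for k in sorted(by_id) if lo <= by_id[k].year <= hi]


def build_group_dataset(
    records: Sequence[CitationRecord],
    group: Group,
    cfg: CurationConfig,
    label: str | None = None,
    log: list[dict] | None = None,
) -> GroupDataset:
    """Assemble the analysis vector for one group from curated records.

    Records lacking a JIF in the window are dropped only when
    ``normalize_by_jif`` is on (and logged if a log list is given).
    """
    values = []
    for rec in records:
        if rec.group is not group:
            continue
        cites = average_citations(rec)
        if cfg.normalize_by_jif:
            jif = average_jif(rec, cfg)
            if jif is None:
                if log is not None:
                    log.append({"paper_id": rec.paper_id, "reason": "no JIF in window"})
                continue
            cites = normalize_by_jif(cites, jif)
        values.append(cites)
    if len(values) < 2:
        raise CurationError(f"group {group.value}: fewer than 2 usable records")
    return GroupDataset(label=label or group.value, values=np.asarray(values, dtype=float))


def curate(
    records: Iterable[CitationRecord],
    groups: Sequence[Group],
    cfg: CurationConfig,
    labels: Sequence[str] | None = None,
) -> tuple[list[GroupDataset], list[dict]]:
    """Full curation: impute, filter/deduplicate, assemble per-group vectors.

    Returns the group datasets and a curation log of excluded records.
    """
    log: list[dict] = []
    kept = filter_and_deduplicate(records, cfg)
    imputed = [impute_missing_sources(r, cfg) for r in kept]
    datasets = [
        build_group_dataset(
            imputed,
            g,
            cfg,
            label=(labels[i] if labels is not None else None),
            log=log,
        )
        for i, g in enumerate(groups)
    ]
    return datasets, log


# ---------------------------------------------------------------------------
# canonical table I/O

_JIF_COLS = [f"jif_{y}" for y in range(JIF_YEARS[0], JIF_YEARS[1] + 1)]
_COLUMNS = ["paper_id", "year", "group", "scopus", "wos", "gscholar", *_JIF_COLS]


def read_citations_table(path) -> list[CitationRecord]:
    """Read the canonical CSV (empty cell = missing) into validated records.

    Malformed rows are reported with their line numbers.
    """
    df = pd.read_csv(path, dtype={"paper_id": str})
    missing_cols = [c for c in ("paper_id", "year", "group", "gscholar") if c not in df.columns]
    if missing_cols:
        raise CurationError(f"{path}: missing required columns {missing_cols}")
    records: list[CitationRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            jifs = {
                int(c.split("_")[1]): float(row[c])
                for c in _JIF_COLS
                if c in df.columns and pd.notna(row.get(c))
            }
            records.append(
                CitationRecord(
                    paper_id=str(row["paper_id"]),
                    year=int(row["year"]),
                    group=Group(str(row["group"])),
                    scopus=None if pd.isna(row.get("scopus")) else float(row["scopus"]),
                    wos=None if pd.isna(row.get("wos")) else float(row["wos"]),
                    gscholar=None if pd.isna(row.get("gscholar")) else float(row["gscholar"]),
                    jif_by_year=jifs,
                )
            )
        except (CurationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise CurationError(f"{path}: malformed rows:\n" + "\n".join(errors))
    return records


def write_citations_table(records: Sequence[CitationRecord], path) -> None:
    """Write records to the canonical CSV schema (empty cell = missing)."""
    rows = []
    for r in records:
        row: dict = {
            "paper_id": r.paper_id,
            "year": r.year,
            "group": r.group.value,
            "scopus": r.scopus,
            "wos": r.wos,
            "gscholar": r.gscholar,
        }
        for y in range(JIF_YEARS[0], JIF_YEARS[1] + 1):
            row[f"jif_{y}"] = r.jif_by_year.get(y)
        rows.append(row)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def write_curation_log(log: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(list(log), fh, indent=2)
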