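"""Domain records, CSV readers/writers, strategy assignment and filtering.

Tagged-colony survey data are flat tables: one row per colony-year transition,
sizes on the raw cm^2 scale (horizontal surface area). Log transformation is
applied downstream, inside the vital-rate fitting, using the natural log.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ColonyObservation",
    "RecruitSurvey",
    "FecundityRecord",
    "StrategyCatalog",
    "STRATEGIES",
    "SurveyFormatError",
    "SurveyValidationError",
    "read_survey",
    "write_survey",
    "read_recruits",
    "write_recruits",
    "read_fecundity",
    "write_fecundity",
    "read_catalog",
    "write_catalog",
    "assign_strategies",
    "filter_assemblage",
    "observations_frame",
]

STRATEGIES = ("competitive", "stress_tolerant", "weedy", "generalist", "mixed")

SURVEY_COLUMNS = [
    "colony_id", "region", "site", "taxon", "strategy", "year_t",
    "size_t", "survived", "size_t1", "fragmented", "remnant_sizes",
]
RECRUIT_COLUMNS = ["region", "site", "year", "n_new", "new_sizes"]
FECUNDITY_COLUMNS = ["strategy", "colony_size", "larval_output"]


class SurveyFormatError(ValueError):
    """Header or file-level format problem."""


class SurveyValidationError(ValueError):
    """Row-level invariant violations; carries offending row numbers."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(f"{message} (rows: {rows})")
        self.rows = rows


@dataclass(frozen=True)
class ColonyObservation:
    """One tagged colony over one annual transition.

    Sizes are horizontal surface area in cm^2 on the raw scale. ``size_t1``
    is present only if the colony survived; for fragmenting survivors it is
    the largest remnant. ``remnant_sizes`` lists all remnants produced.
    """

    colony_id: str
    region: str
    site: str
    taxon: str
    strategy: str
    year_t: int
    size_t: float
    survived: bool
    size_t1: float | None = None
    fragmented: bool = False
    remnant_sizes: tuple[float, ...] = ()

    def validate(self) -> None:
        if not self.size_t > 0:
            raise ValueError(f"size_t must be positive, got {self.size_t}")
        if not self.survived:
            if self.size_t1 is not None:
                raise ValueError("dead colony cannot have size_t1")
            if self.fragmented:
                raise ValueError("dead colony cannot fragment")
        if self.fragmented and len(self.remnant_sizes) < 1:
            raise ValueError("fragmented colony must have >= 1 remnant")
        if any(s <= 0 for s in self.remnant_sizes):
            raise ValueError("remnant sizes must be positive")


@dataclass(frozen=True)
class RecruitSurvey:
    """New colonies (< 5 cm diameter) counted in one plot-year."""

    region: str
    site: str
    year: int
    n_new: int
    new_sizes: tuple[float, ...] = ()

    def validate(self) -> None:
        if self.n_new < 0:
            raise ValueError("n_new must be non-negative")
        if len(self.new_sizes) != self.n_new:
            raise ValueError("length of new_sizes must equal n_new")
        if any(s <= 0 for s in self.new_sizes):
            raise ValueError("recruit sizes must be positive")


@dataclass(frozen=True)
class FecundityRecord:
    """Colony size (cm^2) paired with its larval output."""

    strategy: str
    colony_size: float
    larval_output: float

    def validate(self) -> None:
        if not self.colony_size > 0:
            raise ValueError("colony_size must be positive")
        if self.larval_output < 0:
            raise ValueError("larval_output must be non-negative")


@dataclass
class StrategyCatalog:
    """Genus -> life-history strategy mapping.

    A genus maps either to a single strategy or, where local species span
    several strategies, to ``{strategy: local species count}``.
    """

    mapping: dict[str, str | dict[str, int]] = field(default_factory=dict)

    def strategies_for(self, taxon: str) -> dict[str, int]:
        if taxon not in self.mapping:
            raise KeyError(f"taxon not in catalog: {taxon!r}")
        entry = self.mapping[taxon]
        if isinstance(entry, str):
            return {entry: 1}
        if any(c <= 0 or int(c) != c for c in entry.values()):
            raise ValueError(f"species counts must be positive integers: {entry}")
        return dict(entry)


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_sizes(cell: str) -> tuple[float, ...]:
    cell = (cell or "").strip()
    if not cell:
        return ()
    return tuple(float(tok) for tok in cell.split(";"))


def _fmt_sizes(sizes) -> str:
    return ";".join(repr(float(s)) for s in sizes)


def _check_header(header: list[str], expected: list[str], path) -> None:
    if header != expected:
        raise SurveyFormatError(
            f"{path}: expected columns {expected}, found {header}"
        )


def read_survey(path) -> list[ColonyObservation]:
    """Read a colony-transition table; reject invalid rows by row number."""
    out: list[ColonyObservation] = []
    bad: list[int] = []
    messages: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise SurveyFormatError(f"{path}: empty file")
        _check_header(header, SURVEY_COLUMNS, path)
        for i, row in enumerate(reader, start=2):
            try:
                obs = ColonyObservation(
                    colony_id=row[0],
                    region=row[1],
                    site=row[2],
                    taxon=row[3],
                    strategy=row[4],
                    year_t=int(row[5]),
                    size_t=float(row[6]),
                    survived=row[7].lower() in ("1", "true"),
                    size_t1=float(row[8]) if row[8].strip() else None,
                    fragmented=row[9].lower() in ("1", "true"),
                    remnant_sizes=_parse_sizes(row[10]),
                )
                obs.validate()
            except (ValueError, IndexError) as exc:
                bad.append(i)
                messages.append(str(exc))
                continue
            out.append(obs)
    if bad:
        raise SurveyValidationError(
            "invalid survey rows: " + "; ".join(messages[:5]), bad
        )
    return out


def write_survey(path, observations) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SURVEY_COLUMNS)
        for o in observations:
            writer.writerow([
                o.colony_id, o.region, o.site, o.taxon, o.strategy, o.year_t,
                repr(float(o.size_t)),
                "true" if o.survived else "false",
                "" if o.size_t1 is None else repr(float(o.size_t1)),
                "true" if o.fragmented else "false",
                _fmt_sizes(o.remnant_sizes),
            ])


def read_recruits(path) -> list[RecruitSurvey]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header or [], RECRUIT_COLUMNS, path)
        for i, row in enumerate(reader, start=2):
            rec = RecruitSurvey(
                region=row[0], site=row[1], year=int(row[2]),
                n_new=int(row[3]), new_sizes=_parse_sizes(row[4]),
            )
            rec.validate()
            out.append(rec)
    return out


def write_recruits(path, surveys) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECRUIT_COLUMNS)
        for r in surveys:
            writer.writerow(
                [r.region, r.site, r.year, r.n_new, _fmt_sizes(r.new_sizes)]
            )


def read_fecundity(path) -> list[FecundityRecord]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header or [], FECUNDITY_COLUMNS, path)
        for row in reader:
            rec = FecundityRecord(row[0], float(row[1]), float(row[2]))
            rec.validate()
            out.append(rec)
    return out


def write_fecundity(path, records) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(FECUNDITY_COLUMNS)
        for r in records:
            writer.writerow(
                [r.strategy, repr(float(r.colony_size)), repr(float(r.larval_output))]
            )


def read_catalog(path) -> StrategyCatalog:
    """Two-column mapping file: genus, strategy-or-counts.

    Multi-strategy genera encode counts as ``competitive:3;weedy:1``.
    """
    mapping: dict[str, str | dict[str, int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        _check_header(header or [], ["taxon", "strategy"], path)
        for row in reader:
            cell = row[1].strip()
            if ":" in cell:
                counts = {}
                for tok in cell.split(";"):
                    name, cnt = tok.split(":")
                    counts[name.strip()] = int(cnt)
                mapping[row[0]] = counts
            else:
                mapping[row[0]] = cell
    return StrategyCatalog(mapping)


def write_catalog(path, catalog: StrategyCatalog) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["taxon", "strategy"])
        for taxon, entry in catalog.mapping.items():
            if isinstance(entry, str):
                writer.writerow([taxon, entry])
            else:
                writer.writerow(
                    [taxon, ";".join(f"{k}:{v}" for k, v in entry.items())]
                )


# ---------------------------------------------------------------------------
# Strategy assignment and filtering


def assign_strategies(observations, catalog: StrategyCatalog, seed: int):
    """Resolve colony strategies from a genus catalog.

    Single-strategy genera are assigned deterministically. Where a genus
    spans several strategies, each *colony* (not each row) is assigned
    randomly with probabilities proportional to local species counts, so a
    colony keeps one strategy across all its transitions.
    """
    rng = np.random.default_rng(seed)
    # stable per-colony draw order: first appearance order of colony ids
    colony_taxon: dict[str, str] = {}
    for o in observations:
        colony_taxon.setdefault(o.colony_id, o.taxon)
    assignment: dict[str, str] = {}
    for cid, taxon in colony_taxon.items():
        counts = catalog.strategies_for(taxon)
        names = sorted(counts)
        if len(names) == 1:
            assignment[cid] = names[0]
        else:
            weights = np.array([counts[n] for n in names], dtype=float)
            assignment[cid] = names[rng.choice(len(names), p=weights / weights.sum())]
    return [replace(o, strategy=assignment[o.colony_id]) for o in observations]


def filter_assemblage(observations, strategy: str | None = None,
                      region: str | None = None,
                      drop_generalists: bool = True):
    """Select records for one assemblage; generalists are excluded by default."""
    out = [
        o for o in observations
        if (strategy is None or o.strategy == strategy)
        and (region is None or o.region == region)
        and not (drop_generalists and o.strategy == "generalist")
    ]
    if not out:
        warnings.warn(
            f"filter_assemblage: no records for strategy={strategy!r} "
            f"region={region!r}", stacklevel=2,
        )
    return out


def observations_frame(observations) -> pd.DataFrame:
    """Flatten observations into a DataFrame used by the fitting routines."""
    return pd.DataFrame(
        {
            "colony_id": [o.colony_id for o in observations],
            "region": [o.region for o in observations],
            "site": [o.site for o in observations],
            "strategy": [o.strategy for o in observations],
            "year_t": [o.year_t for o in observations],
            "size_t": [o.size_t for o in observations],
            "survived": [o.survived for o in observations],
            "size_t1": [np.nan if o.size_t1 is None else o.size_t1
                        for o in observations],
            "fragmented": [o.fragmented for o in observations],
            "n_remnants": [len(o.remnant_sizes) for o in observations],
        }
    )
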