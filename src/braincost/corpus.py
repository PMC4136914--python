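"""Data model and I/O for the cost-observation corpus and reference tables.

A *cost observation* is one row of the evidence table: one article reporting
yearly per-patient costs for one disorder (or disorder subtype) in the
article's own currency and costing year, for up to three cost categories.
Amounts are stored exactly as stated in the article; currency conversion and
inflation happen downstream (:mod:`braincost.harmonize`).

A missing cost category is encoded as an absent value (empty cell), never 0;
an explicit 0 is a reported zero cost and participates in pooling.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import (
    ConfigurationError,
    CorpusValidationError,
    CoverageError,
    SchemaError,
    VocabularyError,
)
from .vocab import CATEGORIES, DISORDER_IDS, MENTAL, NEUROLOGICAL

DEFAULT_POPULATION = 46_000_000
YEAR_RANGE = (1995, 2012)

BASES = ("prevalence", "incidence")
INDIRECT_BASES = ("working_age", "all_ages")

CORPUS_COLUMNS = (
    "study_id",
    "disorder_id",
    "subtype_id",
    "costing_year",
    "currency",
    "cost_healthcare",
    "cost_nonmedical",
    "cost_indirect",
    "basis",
    "indirect_basis",
    "quality_high",
    "excluded_outlier",
)


@dataclass(frozen=True)
class CostObservation:
    """One study-level per-patient cost record, in original currency/year."""

    study_id: str
    disorder_id: str
    costing_year: int
    currency: str
    subtype_id: str | None = None
    cost_healthcare: float | None = None
    cost_nonmedical: float | None = None
    cost_indirect: float | None = None
    basis: str = "prevalence"
    indirect_basis: str = "working_age"
    quality_high: bool = False
    excluded_outlier: bool = False

    def amount(self, category: str) -> float | None:
        return getattr(self, f"cost_{category}")

    @property
    def amounts(self) -> dict[str, float | None]:
        return {c: self.amount(c) for c in CATEGORIES}

    def validation_errors(self, year_range: tuple[int, int] = YEAR_RANGE) -> list[str]:
        """Return human-readable invariant violations (empty list = valid)."""
        problems: list[str] = []
        if self.disorder_id not in DISORDER_IDS:
            problems.append(f"unknown disorder_id {self.disorder_id!r}")
        for cat in CATEGORIES:
            v = self.amount(cat)
            if v is not None and (math.isnan(v) or v < 0):
                problems.append(f"cost_{cat} must be >= 0, got {v}")
        if all(self.amount(c) is None for c in CATEGORIES):
            problems.append("at least one cost category must be present")
        lo, hi = year_range
        if not lo <= self.costing_year <= hi:
            problems.append(f"costing_year {self.costing_year} outside {lo}-{hi}")
        if self.basis not in BASES:
            problems.append(f"basis must be one of {BASES}, got {self.basis!r}")
        if self.indirect_basis not in INDIRECT_BASES:
            problems.append(
                f"indirect_basis must be one of {INDIRECT_BASES}, got {self.indirect_basis!r}"
            )
        return problems


@dataclass(frozen=True)
class PrevalenceEntry:
    """Patient numbers for one disorder: a direct count or a proportion of the
    national population, plus the share of patients of working age (used when
    scaling indirect costs estimated on the working-age population)."""

    disorder_id: str
    n_patients: int | None = None
    proportion: float | None = None
    working_age_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_patients is None and self.proportion is None:
            raise ConfigurationError(
                f"{self.disorder_id}: need n_patients or proportion"
            )
        if self.proportion is not None and not 0.0 <= self.proportion <= 1.0:
            raise ConfigurationError(f"{self.disorder_id}: proportion outside [0, 1]")
        if not 0.0 <= self.working_age_fraction <= 1.0:
            raise ConfigurationError(
                f"{self.disorder_id}: working_age_fraction outside [0, 1]"
            )


@dataclass(frozen=True)
class DisorderConfig:
    """Static per-disorder configuration.

    ``indirect_forced_zero`` marks disorders whose patients are assumed to be
    outside the working population (dementia, child/adolescent disorders), so
    indirect costs are set to zero regardless of any evidence or median.

    ``subtype_weights`` (summing to 1) activate subtype-level pooling: category
    means and imputation are computed per subtype and combined as a weighted
    average.  Without weights, subtype rows are pooled as ordinary
    observations of the disorder.
    """

    disorder_id: str
    group: str
    indirect_forced_zero: bool = False
    subtype_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.group not in (MENTAL, NEUROLOGICAL):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.subtype_weights is not None:
            total = sum(self.subtype_weights.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"{self.disorder_id}: subtype weights sum to {total}, expected 1"
                )
            if any(w < 0 for w in self.subtype_weights.values()):
                raise ConfigurationError(f"{self.disorder_id}: negative subtype weight")


@dataclass
class ReferenceSet:
    """All reference tables needed to harmonize and scale a corpus.

    cpi
        all-items consumer price index, ``year -> index value`` (any base).
    fx
        annual nominal exchange rates, ``(currency, year) -> EUR per unit``.
    eu_medians
        European median per-patient costs (pre-adjusted, EUR at the target
        price year), ``(disorder_id, subtype_id | None, category) -> amount``.
        ``subtype_id = None`` is the disorder-level value.
    prevalence
        ``disorder_id -> PrevalenceEntry``.
    """

    cpi: dict[int, float] = field(default_factory=dict)
    fx: dict[tuple[str, int], float] = field(default_factory=dict)
    eu_medians: dict[tuple[str, str | None, str], float] = field(default_factory=dict)
    prevalence: dict[str, PrevalenceEntry] = field(default_factory=dict)
    population: int = DEFAULT_POPULATION

    def __post_init__(self) -> None:
        bad = [y for y, v in self.cpi.items() if v <= 0]
        if bad:
            raise ConfigurationError(f"non-positive CPI values for years {bad}")
        bad = [k for k, v in self.fx.items() if v <= 0]
        if bad:
            raise ConfigurationError(f"non-positive fx rates for {bad}")
        bad = [k for k, v in self.eu_medians.items() if v < 0]
        if bad:
            raise ConfigurationError(f"negative European medians for {bad}")

    def eu_median(
        self, disorder_id: str, subtype_id: str | None, category: str
    ) -> float | None:
        """Median lookup: subtype-level value first, then disorder-level."""
        if subtype_id is not None:
            v = self.eu_medians.get((disorder_id, subtype_id, category))
            if v is not None:
                return v
        return self.eu_medians.get((disorder_id, None, category))


# ---------------------------------------------------------------------------
# corpus I/O


def _parse_amount(cell: str) -> float | None:
    cell = cell.strip()
    if not cell:
        return None
    return float(cell.replace(",", ""))


def _parse_bool(cell: str) -> bool:
    return cell.strip().lower() in ("true", "1", "yes")


def read_corpus(path: str | Path) -> list[CostObservation]:
    """Read a corpus CSV into validated :class:`CostObservation` records.

    Raises :class:`SchemaError` for a bad header and
    :class:`CorpusValidationError` listing offending row numbers when any row
    violates the record invariants.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected a header row")
        missing = set(CORPUS_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        observations: list[CostObservation] = []
        problems: list[tuple[int, str]] = []
        for i, row in enumerate(reader, start=1):
            try:
                obs = CostObservation(
                    study_id=row["study_id"].strip(),
                    disorder_id=row["disorder_id"].strip(),
                    subtype_id=row["subtype_id"].strip() or None,
                    costing_year=int(row["costing_year"]),
                    currency=row["currency"].strip().upper(),
                    cost_healthcare=_parse_amount(row["cost_healthcare"]),
                    cost_nonmedical=_parse_amount(row["cost_nonmedical"]),
                    cost_indirect=_parse_amount(row["cost_indirect"]),
                    basis=row["basis"].strip() or "prevalence",
                    indirect_basis=row["indirect_basis"].strip() or "working_age",
                    quality_high=_parse_bool(row["quality_high"]),
                    excluded_outlier=_parse_bool(row["excluded_outlier"]),
                )
            except (ValueError, KeyError) as exc:
                problems.append((i, f"unparseable row: {exc}"))
                continue
            errs = obs.validation_errors()
            if errs:
                problems.extend((i, e) for e in errs)
            else:
                observations.append(obs)
        if problems:
            raise CorpusValidationError(problems)
    return observations


def write_corpus(observations: Iterable[CostObservation], path: str | Path) -> None:
    """Write observations back to the corpus CSV schema (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CORPUS_COLUMNS)
        for o in observations:
            writer.writerow(
                [
                    o.study_id,
                    o.disorder_id,
                    o.subtype_id or "",
                    o.costing_year,
                    o.currency,
                    "" if o.cost_healthcare is None else repr(o.cost_healthcare),
                    "" if o.cost_nonmedical is None else repr(o.cost_nonmedical),
                    "" if o.cost_indirect is None else repr(o.cost_indirect),
                    o.basis,
                    o.indirect_basis,
                    o.quality_high,
                    o.excluded_outlier,
                ]
            )


# ---------------------------------------------------------------------------
# reference-table I/O


def _read_rows(path: Path, required: tuple[str, ...]) -> list[dict[str, str]]:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(required) - set(reader.fieldnames):
            raise SchemaError(f"{path}: expected columns {required}")
        return list(reader)


def _parse_weights(cell: str) -> dict[str, float] | None:
    cell = cell.strip()
    if not cell:
        return None
    out: dict[str, float] = {}
    for part in cell.split(";"):
        name, w = part.split(":")
        out[name.strip()] = float(w)
    return out


def read_references(
    paths: Mapping[str, str | Path], population: int | None = None
) -> ReferenceSet:
    """Assemble a :class:`ReferenceSet` from delimited tables.

    ``paths`` maps table names (``cpi``, ``fx``, ``eu_medians``,
    ``prevalence``) to file paths.  A missing ``population`` falls back to the
    default national count (46,000,000 inhabitants).
    """
    cpi = {
        int(r["year"]): float(r["index"])
        for r in _read_rows(Path(paths["cpi"]), ("year", "index"))
    }
    fx = {
        (r["currency"].strip().upper(), int(r["year"])): float(r["eur_per_unit"])
        for r in _read_rows(Path(paths["fx"]), ("currency", "year", "eur_per_unit"))
    }
    eu_medians: dict[tuple[str, str | None, str], float] = {}
    for r in _read_rows(
        Path(paths["eu_medians"]),
        ("disorder_id", "subtype_id", "category", "amount_eur2010"),
    ):
        cat = r["category"].strip()
        if cat not in CATEGORIES:
            raise SchemaError(f"eu_medians: unknown category {cat!r}")
        key = (r["disorder_id"].strip(), r["subtype_id"].strip() or None, cat)
        eu_medians[key] = float(r["amount_eur2010"])
    prevalence: dict[str, PrevalenceEntry] = {}
    for r in _read_rows(
        Path(paths["prevalence"]),
        ("disorder_id", "n_patients", "working_age_fraction"),
    ):
        d = r["disorder_id"].strip()
        if d not in DISORDER_IDS:
            raise VocabularyError(f"prevalence: unknown disorder {d!r}")
        n = r["n_patients"].strip()
        prop = r.get("proportion", "").strip() if "proportion" in r else ""
        prevalence[d] = PrevalenceEntry(
            disorder_id=d,
            n_patients=int(n.replace(",", "")) if n else None,
            proportion=float(prop) if prop else None,
            working_age_fraction=float(r["working_age_fraction"] or 1.0),
        )
    return ReferenceSet(
        cpi=cpi,
        fx=fx,
        eu_medians=eu_medians,
        prevalence=prevalence,
        population=population or DEFAULT_POPULATION,
    )


def read_disorder_configs(path: str | Path) -> dict[str, DisorderConfig]:
    configs: dict[str, DisorderConfig] = {}
    for r in _read_rows(
        Path(path), ("disorder_id", "group", "indirect_forced_zero", "subtype_weights")
    ):
        d = r["disorder_id"].strip()
        if d not in DISORDER_IDS:
            raise VocabularyError(f"disorders: unknown disorder {d!r}")
        configs[d] = DisorderConfig(
            disorder_id=d,
            group=r["group"].strip(),
            indirect_forced_zero=_parse_bool(r["indirect_forced_zero"]),
            subtype_weights=_parse_weights(r["subtype_weights"]),
        )
    return configs


# ---------------------------------------------------------------------------
# validation / coverage reporting


def coverage_gaps(
    corpus: Iterable[CostObservation], refs: ReferenceSet, target_year: int = 2010
) -> list[str]:
    """List (currency, year) / CPI gaps the references leave for this corpus."""
    gaps: list[str] = []
    needed_years = {o.costing_year for o in corpus} | {target_year}
    for y in sorted(needed_years - set(refs.cpi)):
        gaps.append(f"CPI index missing for year {y}")
    needed_fx = {
        (o.currency, o.costing_year) for o in corpus if o.currency != "EUR"
    }
    for cur, y in sorted(needed_fx - set(refs.fx)):
        gaps.append(f"exchange rate missing for {cur} {y}")
    return gaps


def check_coverage(
    corpus: Iterable[CostObservation], refs: ReferenceSet, target_year: int = 2010
) -> None:
    gaps = coverage_gaps(corpus, refs, target_year)
    if gaps:
        raise CoverageError("; ".join(gaps))


@dataclass
class ValidationReport:
    """Per-disorder evidence summary (reporting only, never mutates data).

    ``observation_counts`` counts every identified row; ``included_counts``
    counts the rows that enter pooling (outlier-excluded and, by default,
    incidence-based rows removed).  ``fully_imputed`` lists disorders with no
    pooled evidence at all -- these rely entirely on European medians, which
    can include disorders whose only article was excluded.
    """

    observation_counts: dict[str, int]
    included_counts: dict[str, int]
    categories_covered: dict[str, tuple[str, ...]]
    categories_needing_imputation: dict[str, tuple[str, ...]]
    rows_excluded: int
    fully_imputed: tuple[str, ...]

    @property
    def disorders_with_evidence(self) -> tuple[str, ...]:
        return tuple(d for d, n in self.observation_counts.items() if n > 0)


def validate_corpus(
    corpus: Iterable[CostObservation],
    refs: ReferenceSet | None = None,
    configs: Mapping[str, DisorderConfig] | None = None,
    include_incidence: bool = False,
) -> ValidationReport:
    """Summarize evidence per disorder: rows contributing to pooling,
    categories covered, and categories that will need European imputation."""
    corpus = list(corpus)
    included = [
        o
        for o in corpus
        if not o.excluded_outlier and (include_incidence or o.basis == "prevalence")
    ]
    raw_counts = {d: 0 for d in DISORDER_IDS}
    counts = {d: 0 for d in DISORDER_IDS}
    covered: dict[str, set[str]] = {d: set() for d in DISORDER_IDS}
    for o in corpus:
        raw_counts[o.disorder_id] += 1
    for o in included:
        counts[o.disorder_id] += 1
        for cat in CATEGORIES:
            if o.amount(cat) is not None:
                covered[o.disorder_id].add(cat)
    needing = {
        d: tuple(c for c in CATEGORIES if c not in covered[d]) for d in DISORDER_IDS
    }
    return ValidationReport(
        observation_counts=raw_counts,
        included_counts=counts,
        categories_covered={d: tuple(c for c in CATEGORIES if c in covered[d]) for d in DISORDER_IDS},
        categories_needing_imputation=needing,
        rows_excluded=len(corpus) - len(included),
        fully_imputed=tuple(d for d in DISORDER_IDS if counts[d] == 0),
    )


__all__ = [
    "CostObservation",
    "PrevalenceEntry",
    "DisorderConfig",
    "ReferenceSet",
    "ValidationReport",
    "read_corpus",
    "write_corpus",
    "read_references",
    "read_disorder_configs",
    "validate_corpus",
    "coverage_gaps",
    "check_coverage",
    "CORPUS_COLUMNS",
    "DEFAULT_POPULATION",
]
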