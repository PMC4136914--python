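"""Restate cost observations in EUR at a common (target-year) price level.

Two elementary steps, applied in a fixed order:

1. currency conversion at the annual nominal exchange rate of the costing
   year (``EUR amount = amount x eur_per_unit(currency, year)``), then
2. inflation with the national all-items consumer price index
   (``amount x cpi(target) / cpi(source)``).

Converting first keeps all inflation in a single national CPI series.  The
alternative order (source-country CPI, then a current exchange rate) is a
recognised variant and would change non-EUR rows by a few percent; it is not
implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .corpus import CostObservation, ReferenceSet
from .errors import CoverageError
from .vocab import CATEGORIES

TARGET_YEAR = 2010


def convert_currency(
    amount: float,
    currency: str,
    year: int,
    fx: Mapping[tuple[str, int], float],
) -> float:
    """Convert ``amount`` from ``currency`` to EUR at the annual nominal rate
    of ``year``.  EUR input is returned unchanged."""
    if currency == "EUR":
        return amount
    rate = fx.get((currency, year))
    if rate is None:
        raise CoverageError(f"no exchange rate for {currency} {year}")
    return amount * rate


def inflate(
    amount: float, from_year: int, to_year: int, cpi: Mapping[int, float]
) -> float:
    """Restate ``amount`` from ``from_year`` prices to ``to_year`` prices."""
    if from_year == to_year:
        return amount
    try:
        return amount * cpi[to_year] / cpi[from_year]
    except KeyError as exc:
        raise CoverageError(f"CPI index missing for year {exc.args[0]}") from exc


@dataclass(frozen=True)
class HarmonizedObservation(CostObservation):
    """A cost observation restated in EUR at target-year prices.

    Carries the adjustment trail: the exchange rate and CPI factor that were
    applied.  Amount fields keep the corpus semantics (absent stays absent,
    explicit zero stays zero).
    """

    target_year: int = TARGET_YEAR
    fx_rate: float = 1.0
    cpi_factor: float = 1.0
    harmonized: bool = True


def harmonize(
    obs: CostObservation, refs: ReferenceSet, target_year: int = TARGET_YEAR
) -> HarmonizedObservation:
    """Convert then inflate every present cost category of one observation.

    Idempotent: an observation already in EUR at ``target_year`` passes
    through unchanged (factors 1.0).
    """
    fx_rate = 1.0 if obs.currency == "EUR" else refs.fx.get((obs.currency, obs.costing_year))
    if fx_rate is None:
        raise CoverageError(f"no exchange rate for {obs.currency} {obs.costing_year}")
    cpi_factor = (
        1.0
        if obs.costing_year == target_year
        else inflate(1.0, obs.costing_year, target_year, refs.cpi)
    )
    adjusted: dict[str, float | None] = {}
    for cat in CATEGORIES:
        v = obs.amount(cat)
        adjusted[f"cost_{cat}"] = None if v is None else v * fx_rate * cpi_factor
    return HarmonizedObservation(
        study_id=obs.study_id,
        disorder_id=obs.disorder_id,
        subtype_id=obs.subtype_id,
        costing_year=target_year,
        currency="EUR",
        basis=obs.basis,
        indirect_basis=obs.indirect_basis,
        quality_high=obs.quality_high,
        excluded_outlier=obs.excluded_outlier,
        target_year=target_year,
        fx_rate=fx_rate,
        cpi_factor=cpi_factor,
        **adjusted,
    )


def harmonize_corpus(
    corpus: Iterable[CostObservation],
    refs: ReferenceSet,
    target_year: int = TARGET_YEAR,
) -> list[HarmonizedObservation]:
    return [harmonize(o, refs, target_year) for o in corpus]


__all__ = [
    "TARGET_YEAR",
    "HarmonizedObservation",
    "convert_currency",
    "inflate",
    "harmonize",
    "harmonize_corpus",
]
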