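"""End-to-end orchestration shared by the command line and scripts."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .aggregate import (
    PerPatientCost,
    RollupSummary,
    SocietalCost,
    per_patient_costs,
    rollup,
    societal_costs,
)
from .corpus import CostObservation, DisorderConfig, ReferenceSet, check_coverage
from .harmonize import TARGET_YEAR, HarmonizedObservation, harmonize_corpus
from .vocab import CATEGORIES, DISORDER_IDS, display_name, group_of


@dataclass
class EstimateBundle:
    """Deterministic pipeline outputs plus the harmonized corpus they came from."""

    per_patient: dict[str, PerPatientCost]
    societal: dict[str, SocietalCost]
    summary: RollupSummary
    harmonized: list[HarmonizedObservation]

    @property
    def grand_total(self) -> float:
        return self.summary.groups["all"].total

    def per_patient_frame(self) -> pd.DataFrame:
        rows = []
        for d in DISORDER_IDS:
            ppc = self.per_patient[d]
            soc = self.societal[d]
            rows.append(
                {
                    "disorder_id": d,
                    "disorder": display_name(d),
                    "group": group_of(d),
                    "n_patients": soc.n_patients,
                    **{f"pp_{c}": ppc.category(c).amount for c in CATEGORIES},
                    "pp_total": ppc.total,
                    **{f"prov_{c}": ppc.category(c).provenance for c in CATEGORIES},
                }
            )
        return pd.DataFrame(rows)

    def societal_frame(self) -> pd.DataFrame:
        rows = []
        for d in DISORDER_IDS:
            soc = self.societal[d]
            rows.append(
                {
                    "disorder_id": d,
                    "disorder": display_name(d),
                    "group": group_of(d),
                    "n_patients": soc.n_patients,
                    **{f"soc_{c}_millions": soc.category(c) for c in CATEGORIES},
                    "soc_total_millions": soc.total,
                }
            )
        return pd.DataFrame(rows)

    def rollup_frame(self) -> pd.DataFrame:
        rows = []
        for g, s in self.summary.groups.items():
            rows.append(
                {
                    "group": g,
                    "n_patients": s.n_patients,
                    "healthcare_millions": s.healthcare,
                    "nonmedical_millions": s.nonmedical,
                    "indirect_millions": s.indirect,
                    "total_millions": s.total,
                    "mean_per_patient": s.mean_per_patient,
                }
            )
        for c in CATEGORIES:
            rows.append({"group": f"share_{c}_pct", "total_millions": self.summary.shares[c]})
        if self.summary.cost_per_inhabitant is not None:
            rows.append(
                {"group": "cost_per_inhabitant_eur", "total_millions": self.summary.cost_per_inhabitant}
            )
        return pd.DataFrame(rows)


def estimate(
    corpus: Iterable[CostObservation],
    refs: ReferenceSet,
    configs: Mapping[str, DisorderConfig],
    target_year: int = TARGET_YEAR,
    include_incidence: bool = False,
    imputation: bool = True,
) -> EstimateBundle:
    """Harmonize, pool, impute and scale a corpus into the result bundle."""
    corpus = list(corpus)
    check_coverage(corpus, refs, target_year)
    harmonized = harmonize_corpus(corpus, refs, target_year)
    ppc = per_patient_costs(harmonized, refs, configs, include_incidence, imputation)
    soc = societal_costs(ppc, refs, harmonized)
    return EstimateBundle(ppc, soc, rollup(soc, configs, refs.population), harmonized)


def file_checksums(paths: Iterable[str | Path]) -> dict[str, str]:
    out = {}
    for p in paths:
        p = Path(p)
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def write_manifest(path: str | Path, config: Mapping, checksums: Mapping[str, str]) -> None:
    """Run manifest: configuration echo and input checksums.  Timings are
    logged, not stored, so reruns with identical inputs are byte-identical."""
    from . import __version__

    payload = {"version": __version__, "config": dict(config), "inputs": dict(checksums)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


__all__ = ["EstimateBundle", "estimate", "file_checksums", "write_manifest"]
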