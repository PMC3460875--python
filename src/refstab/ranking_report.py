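"""Condition-stratified orchestration and reference-pair recommendation.

The recommendation rule is deliberately simple: the top two genes of the
delta-CT ranking (ascending mean pairwise SD) form the recommended pair for
a condition, and the geNorm trace is attached as concordance context — a
note records whether both recommended genes also sit in geNorm's top five.
geNorm is context rather than arbiter because it can rank co-regulated
genes as jointly "stable"; the delta-CT statistic is the primary criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import CtDataset, subset
from .stability_deltact import DeltaCtResult, deltact_stability
from .stability_genorm import GenormTrace, relative_quantities, stepwise_ranking

__all__ = ["Recommendation", "ConditionReport", "StabilityReport", "recommend_pairs", "run_all"]


@dataclass
class Recommendation:
    """Recommended reference pair for one condition cell."""

    condition: tuple[str, str]  # (treatment or "all", tissue or "both")
    pair: tuple[str, str]  # most stable first
    statistics: tuple[float, float]  # delta-CT mean SD of each (cycles)
    method: str = "deltact"
    concordant: bool | None = None  # both genes in the other method's top 5?

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError("pair members must be distinct")
        if self.statistics[0] > self.statistics[1]:
            raise ValueError("pair must be ordered most stable first")

    @property
    def note(self) -> str:
        if self.concordant is None:
            return "no geNorm trace supplied"
        if self.concordant:
            return "both genes in geNorm top 5"
        return "pair not fully in geNorm top 5"


@dataclass
class ConditionReport:
    condition: tuple[str, str]
    deltact: DeltaCtResult
    genorm: GenormTrace | None
    recommendation: Recommendation


@dataclass
class StabilityReport:
    """Per-condition results plus the overall single-gene recommendation."""

    cells: list[ConditionReport]
    best_single_gene: str | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rec = c.recommendation
            rows.append(
                {
                    "treatment": c.condition[0],
                    "tissue": c.condition[1],
                    "pair": f"{rec.pair[0]}/{rec.pair[1]}",
                    "stat_first": rec.statistics[0],
                    "stat_second": rec.statistics[1],
                    "genorm_note": rec.note,
                }
            )
        return pd.DataFrame(rows)


def recommend_pairs(
    deltact: DeltaCtResult,
    genorm: GenormTrace | None = None,
    condition: tuple[str, str] = ("all", "both"),
) -> Recommendation:
    """Top-two genes of the delta-CT ranking, with geNorm concordance.

    ``deltact`` and ``genorm`` must have been computed on the same
    condition subset.
    """
    if len(deltact.ranking) < 2:
        raise ValueError("need at least 2 ranked genes to recommend a pair")
    g1, g2 = deltact.ranking[0], deltact.ranking[1]
    concordant = None
    if genorm is not None:
        top5 = set(genorm.ranking[:5])
        concordant = g1 in top5 and g2 in top5
    return Recommendation(
        condition=condition,
        pair=(g1, g2),
        statistics=(float(deltact.mean_sd[g1]), float(deltact.mean_sd[g2])),
        concordant=concordant,
    )


def _cell(
    ds: CtDataset,
    treatment: str | None,
    tissue: str | None,
    include_control: bool,
    default_e: float,
    run_genorm: bool,
) -> ConditionReport:
    sub = subset(
        ds,
        tissue=tissue,
        treatments=None if treatment is None else {treatment},
        include_control=include_control,
    )
    dres = deltact_stability(sub)
    trace = None
    if run_genorm and sub.ct.notna().all().all() and sub.n_genes >= 3:
        trace = stepwise_ranking(relative_quantities(sub, default_e=default_e))
    label = (treatment or "all", tissue or "both")
    rec = recommend_pairs(dres, trace, condition=label)
    return ConditionReport(condition=label, deltact=dres, genorm=trace, recommendation=rec)


def run_all(
    ds: CtDataset,
    treatments: list[str] | None = None,
    tissues: list[str] | None = None,
    include_control: bool = True,
    default_e: float = 2.0,
    run_genorm: bool = True,
) -> StabilityReport:
    """Stability analysis for every treatment x tissue cell plus combined cells.

    For each requested treatment (default: every non-control treatment in
    the data) and tissue (default: every tissue, plus the tissues-combined
    stratum) the delta-CT ranking, the geNorm trace and the recommended
    pair are computed; a final all-treatments x tissues-combined cell
    yields the overall single-gene recommendation (the delta-CT winner).
    """
    if treatments is None:
        treatments = [
            t for t in dict.fromkeys(ds.samples["treatment"]) if t != "control"
        ]
    if tissues is None:
        tissues = list(dict.fromkeys(ds.samples["tissue"]))
    tissue_cells: list[str | None] = list(tissues)
    if len(tissues) > 1:
        tissue_cells.append(None)  # tissues combined
    treatment_cells: list[str | None] = list(treatments)
    if len(treatments) > 1:
        treatment_cells.append(None)  # all treatments pooled
    cells = []
    for trt in treatment_cells:
        for tis in tissue_cells:
            cells.append(_cell(ds, trt, tis, include_control, default_e, run_genorm))
    overall = next(
        (c for c in cells if c.condition == ("all", "both")),
        cells[-1],
    )
    return StabilityReport(cells=cells, best_single_gene=overall.deltact.ranking[0])
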