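"""Composition of the stages for one group: differential -> subnetworks ->
enrichment.  Shared by the CLI and by the randomization control."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from activepath.differential import FilterParams, group_differential
from activepath.enrichment import (
    EnrichmentResult,
    PathwayReport,
    aggregate_pathways,
    default_universe,
    enrich_subnetwork,
)
from activepath.io_formats import (
    GeneSetCollection,
    IntensityStudy,
    PPINetwork,
    ProteinGeneMap,
)
from activepath.subnetwork import (
    GeneScoreMap,
    SearchParams,
    Subnetwork,
    calibrate,
    find_subnetworks,
)

logger = logging.getLogger(__name__)


@dataclass
class GroupAnalysis:
    """Everything one group's analysis produced."""

    group: str
    diff_table: pd.DataFrame
    modules: list[Subnetwork] = field(default_factory=list)
    results: list[EnrichmentResult] = field(default_factory=list)
    reports: list[PathwayReport] = field(default_factory=list)

    def pathway_ids(self) -> set[str]:
        return {r.pathway_id for r in self.reports}


def analyze_group(
    study: IntensityStudy,
    pg_map: ProteinGeneMap,
    network: PPINetwork,
    collection: GeneSetCollection,
    group: str,
    control_groups: str | Iterable[str],
    filter_params: FilterParams | None = None,
    search_params: SearchParams | None = None,
    threshold: float = 0.05,
    calibration_k_max: int = 20,
    calibration_samples: int = 150,
    universe: frozenset[str] | None = None,
) -> GroupAnalysis:
    """Run one case group against the control(s) through the full pipeline.

    Every tested gene's p-value feeds the network stage (the module search
    weighs all gene significances, not just the filtered hits, so the score
    background stays non-degenerate); network genes absent from the study are
    scored at the unscored default.  With no testable genes the network stage
    is skipped and the report is empty.
    """
    filter_params = filter_params or FilterParams()
    search_params = search_params or SearchParams()

    diff = group_differential(study, pg_map, group, control_groups, filter_params)
    out = GroupAnalysis(group=group, diff_table=diff)
    if diff.empty:
        logger.info("%s: no testable genes; skipping subnetwork stage", group)
        return out

    p_values = {g: float(p) for g, p in diff["p_value"].items()}
    score_map = GeneScoreMap.from_pvalues(p_values, network)
    k_max = min(calibration_k_max, network.n_nodes)
    calibration = calibrate(
        score_map,
        network,
        k_range=range(1, k_max + 1),
        mc_samples=calibration_samples,
        seed=search_params.seed,
    )
    modules = find_subnetworks(network, score_map, calibration, search_params)
    out.modules = modules
    if not modules:
        return out

    uni = universe if universe is not None else default_universe(network, collection)
    if not uni:
        logger.info("%s: empty enrichment universe", group)
        return out
    results: list[EnrichmentResult] = []
    for i, module in enumerate(modules, start=1):
        results.extend(
            enrich_subnetwork(module, collection, uni, subnetwork_id=f"M{i:03d}")
        )
    out.results = results
    out.reports = aggregate_pathways(results, modules, collection, threshold=threshold)
    return out


def shared_pathways(analyses: Sequence[GroupAnalysis]) -> set[str]:
    """Pathways reported for every analyzed group (the 'common' table)."""
    if not analyses:
        return set()
    shared = analyses[0].pathway_ids()
    for a in analyses[1:]:
        shared &= a.pathway_ids()
    return shared
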