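"""Pathway enrichment of subnetworks and cross-subnetwork aggregation.

Each subnetwork is tested against every pathway with a two-sided
(enrichment/depletion) hypergeometric test using the minimum-likelihood
convention, Bonferroni-corrected over the pathways tested for that
subnetwork.  Per-pathway aggregation keeps the most significant occurrence,
counts how many subnetworks were significant ("times found"), and splits the
pathway's genes into those found in significant subnetworks and the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from activepath.io_formats import GeneSetCollection, PPINetwork
from activepath.subnetwork import Subnetwork

logger = logging.getLogger(__name__)

# relative slack when comparing pmf values for the minimum-likelihood sum;
# ties are exact in rational arithmetic but only near-equal in floats
_PMF_RTOL = 1e-7


def two_sided_hypergeom(x: int, N: int, K: int, n: int) -> float:
    """Two-sided hypergeometric p by minimum-likelihood summation.

    Draw ``n`` from a universe of ``N`` containing ``K`` marked items and
    observe ``x`` marked.  The p-value sums the probabilities of every
    outcome no more likely than ``x`` (the Fisher-exact two-sided
    convention); it covers both enrichment and depletion.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible parameters N={N}, K={K}, n={n}")
    lo, hi = max(0, n + K - N), min(K, n)
    if not lo <= x <= hi:
        raise ValueError(f"x={x} outside the feasible range [{lo}, {hi}]")
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, K, n)
    p_x = pmf[x - lo]
    p = float(pmf[pmf <= p_x * (1.0 + _PMF_RTOL)].sum())
    return min(max(p, float(p_x)), 1.0)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """min(1, m * p) with m = len(p_values); order preserved."""
    m = len(p_values)
    out = []
    for p in p_values:
        if not 0 < p <= 1:
            raise ValueError(f"p-value {p} outside (0, 1]")
        out.append(min(1.0, m * p))
    return out


@dataclass
class EnrichmentResult:
    """One subnetwork x pathway hypergeometric test."""

    pathway_id: str
    subnetwork_id: str
    x: int
    K: int
    n: int
    N: int
    p_raw: float
    p_corr: float
    m: int
    direction: str  # "enrichment", "depletion" or "none"
    genes_overlap: frozenset[str]


def default_universe(network: PPINetwork, collection: GeneSetCollection) -> frozenset[str]:
    """Network genes annotated to at least one pathway (the default N)."""
    return frozenset(network.nodes & collection.all_genes())


def enrich_subnetwork(
    subnetwork: Subnetwork,
    collection: GeneSetCollection,
    universe: Iterable[str],
    subnetwork_id: str = "M001",
) -> list[EnrichmentResult]:
    """Hypergeometric tests of one subnetwork against every pathway.

    Pathways are intersected with the universe; only those with K >= 1
    remain and define the Bonferroni factor m.  Subnetwork genes outside the
    universe are ignored for counting.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    N = len(uni)
    sub_genes = frozenset(subnetwork.genes) & uni
    n = len(sub_genes)
    if n == 0:
        logger.info("subnetwork %s has no genes in the universe", subnetwork_id)
        return []

    tested: list[tuple[str, frozenset[str]]] = []
    for pid in collection.ids():
        genes_in_uni = collection.genes(pid) & uni
        if genes_in_uni:
            tested.append((pid, genes_in_uni))
    m = len(tested)
    if m == 0:
        return []

    results = []
    for pid, pgenes in tested:
        K = len(pgenes)
        overlap = sub_genes & pgenes
        x = len(overlap)
        p_raw = two_sided_hypergeom(x, N, K, n)
        expected = n * K / N
        if x > expected:
            direction = "enrichment"
        elif x < expected:
            direction = "depletion"
        else:
            direction = "none"
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                subnetwork_id=subnetwork_id,
                x=x,
                K=K,
                n=n,
                N=N,
                p_raw=p_raw,
                p_corr=min(1.0, m * p_raw),
                m=m,
                direction=direction,
                genes_overlap=frozenset(overlap),
            )
        )
    return results


@dataclass
class PathwayReport:
    """Per-pathway aggregation across subnetworks (one table row)."""

    pathway_id: str
    description: str
    best_p_corr: float
    times_found: int
    genes_found: frozenset[str]
    genes_not_found: frozenset[str]


def aggregate_pathways(
    all_results: Sequence[EnrichmentResult],
    subnetworks: Sequence[Subnetwork],
    collection: GeneSetCollection,
    threshold: float = 0.05,
    include_depletion: bool = False,
) -> list[PathwayReport]:
    """Aggregate enrichment results into per-pathway report rows.

    A pathway occurrence is *significant* when p_corr < threshold with
    direction "enrichment" (depletion hits are excluded unless
    ``include_depletion``).  Only pathways significant in at least one
    subnetwork are reported; ``best_p_corr`` is the minimum corrected p over
    all subnetworks, and ``genes_found`` collects the pathway's genes present
    in any subnetwork where it was significant.
    """
    if not subnetworks:
        raise ValueError("aggregate_pathways needs at least one subnetwork")
    # subnetwork ids follow the pipeline's positional convention M001, M002, ...
    id_to_genes: dict[str, frozenset[str]] = {
        f"M{i:03d}": frozenset(sub.genes) for i, sub in enumerate(subnetworks, start=1)
    }
    for r in all_results:
        id_to_genes.setdefault(r.subnetwork_id, r.genes_overlap)

    reports = []
    for pid in collection.ids():
        rows = [r for r in all_results if r.pathway_id == pid]
        if not rows:
            continue
        ok_direction = ("enrichment", "depletion") if include_depletion else ("enrichment",)
        significant = [
            r for r in rows if r.p_corr < threshold and r.direction in ok_direction
        ]
        if not significant:
            continue
        pathway_genes = collection.genes(pid)
        found: set[str] = set()
        for r in significant:
            found |= pathway_genes & id_to_genes.get(r.subnetwork_id, frozenset())
        reports.append(
            PathwayReport(
                pathway_id=pid,
                description=collection.description(pid),
                best_p_corr=min(r.p_corr for r in rows),
                times_found=len(significant),
                genes_found=frozenset(found),
                genes_not_found=frozenset(pathway_genes - found),
            )
        )
    return sorted(reports, key=lambda r: (r.best_p_corr, r.pathway_id))


def write_report(reports: Sequence[PathwayReport], path: str | Path) -> None:
    """TSV mirroring the per-pathway table: id, name, best corrected p,
    times found, genes found / not found (comma-joined, sorted)."""
    lines = ["pathway_id\tname\tbest_p_corr\ttimes_found\tgenes_found\tgenes_not_found"]
    for r in reports:
        lines.append(
            "\t".join(
                [
                    r.pathway_id,
                    r.description,
                    repr(r.best_p_corr),
                    str(r.times_found),
                    ",".join(sorted(r.genes_found)),
                    ",".join(sorted(r.genes_not_found)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
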