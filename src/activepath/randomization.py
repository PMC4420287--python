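"""Label-shuffling specificity control.

The full pipeline is re-run on randomly permuted sample->group assignments
and the number of shuffled runs in which each pathway recurs is tabulated.
A pathway that is specific to the true grouping should appear in the
unshuffled analysis but rarely across shuffles; generic pathways recur
regardless of the labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from activepath.differential import FilterParams
from activepath.io_formats import (
    GeneSetCollection,
    IntensityStudy,
    PPINetwork,
    ProteinGeneMap,
)
from activepath.pipeline import analyze_group
from activepath.subnetwork import SearchParams
from dataclasses import replace

logger = logging.getLogger(__name__)


def shuffle_labels(
    groups: Mapping[str, str],
    seed: int,
    scope: str = "all",
    fixed_groups: Iterable[str] = (),
) -> dict[str, str]:
    """Permute the sample->group assignment, preserving group sizes.

    ``scope="all"`` permutes every label; ``scope="ms-only"`` keeps samples
    of the ``fixed_groups`` (typically the controls) in place and permutes
    the remaining labels among themselves.  Deterministic given ``seed``.
    """
    if scope not in {"all", "ms-only"}:
        raise ValueError(f"unknown shuffle scope {scope!r}")
    if len(set(groups.values())) < 2:
        raise ValueError("shuffling needs >= 2 groups")
    fixed = set(fixed_groups) if scope == "ms-only" else set()
    samples = sorted(s for s, g in groups.items() if g not in fixed)
    labels = [groups[s] for s in samples]
    rng = np.random.default_rng(seed)
    permuted = [labels[i] for i in rng.permutation(len(labels))]
    out = dict(groups)
    for s, g in zip(samples, permuted):
        out[s] = g
    return out


@dataclass
class RandomizationSummary:
    """Occurrence counts of pathways per group across R shuffled runs."""

    R: int
    counts: dict[tuple[str, str], int]  # (group, pathway_id) -> count
    seeds: list[int] = field(default_factory=list)

    def count(self, group: str, pathway_id: str) -> int:
        return self.counts.get((group, pathway_id), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "pathway_id": p, "count": c, "R": self.R}
            for (g, p), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["group", "pathway_id", "count", "R"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def derive_run_seeds(master_seed: int, R: int) -> list[int]:
    """Splittable per-run seeds from the master seed (logged for replay)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(R)]


def randomization_analysis(
    study: IntensityStudy,
    pg_map: ProteinGeneMap,
    network: PPINetwork,
    collection: GeneSetCollection,
    groups_to_test: Sequence[str],
    control_groups: Sequence[str],
    filter_params: FilterParams | None = None,
    search_params: SearchParams | None = None,
    threshold: float = 0.05,
    R: int = 10,
    seed: int = 0,
    scope: str = "all",
    **pipeline_kwargs,
) -> RandomizationSummary:
    """R full-pipeline runs on shuffled labels; counts pathway occurrences.

    An occurrence means the pathway is present in that run's report
    (corrected p < threshold in >= 1 subnetwork).  ``scope`` controls
    whether control labels are shuffled too (see :func:`shuffle_labels`).
    Pipeline errors propagate annotated with the run index.
    """
    search_params = search_params or SearchParams()
    run_seeds = derive_run_seeds(seed, R)
    counts: dict[tuple[str, str], int] = {}
    for r, run_seed in enumerate(run_seeds):
        shuffled = shuffle_labels(
            study.groups, seed=run_seed, scope=scope, fixed_groups=control_groups
        )
        shuffled_study = study.with_groups(shuffled)
        run_search = replace(search_params, seed=run_seed % (2**32))
        for group in groups_to_test:
            try:
                analysis = analyze_group(
                    shuffled_study,
                    pg_map,
                    network,
                    collection,
                    group,
                    control_groups,
                    filter_params,
                    run_search,
                    threshold=threshold,
                    **pipeline_kwargs,
                )
            except Exception as exc:  # annotate with run index, then re-raise
                raise RuntimeError(f"randomization run {r} (group {group}) failed") from exc
            for pid in analysis.pathway_ids():
                key = (group, pid)
                counts[key] = counts.get(key, 0) + 1
    return RandomizationSummary(R=R, counts=counts, seeds=run_seeds)
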