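"""Ground-truth synthetic study generator.

Produces an interaction network, a gene-set collection whose designated set
contains a connected core region, and a log-normal intensity study in which
a connected module of planted proteins carries >= 2-fold group effects — the
statistical structure the rest of the pipeline is tested against.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning, so every artefact is bit-identical
under the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from activepath.io_formats import (
    GeneSetCollection,
    IntensityStudy,
    PPINetwork,
    ProteinGeneMap,
)
from activepath.subnetwork import random_connected_set

# Scaled-down group sizes keep the default test-suite run fast; the
# full-scale design (65 / 72 / 42 / 42) is available for larger experiments.
DEFAULT_GROUP_SIZES = {"CIS": 12, "RRMS": 14, "PMS": 8, "CONTROL": 8}
FULL_SCALE_GROUP_SIZES = {"CIS": 65, "RRMS": 72, "PMS": 42, "CONTROL": 42}


@dataclass
class StudyDesign:
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    control_group: str = "CONTROL"

    def __post_init__(self) -> None:
        if self.control_group not in self.group_sizes:
            raise ValueError(f"control group {self.control_group!r} missing from design")
        if any(n < 4 for n in self.group_sizes.values()):
            raise ValueError("every group needs >= 4 samples")

    @property
    def case_groups(self) -> list[str]:
        return sorted(g for g in self.group_sizes if g != self.control_group)


@dataclass
class TruthParams:
    """Planted-effect parameters: module size, fold range, noise level."""

    n_planted: int = 12
    fold_range: tuple[float, float] = (2.0, 4.2)
    target_cv: float = 24.0
    missing_rate: float = 0.02
    mixed_direction: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.fold_range
        if not (hi >= lo >= 2.0):
            raise ValueError("planted fold magnitudes must be >= 2")
        if self.target_cv <= 0:
            raise ValueError("target CV must be positive")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")


@dataclass
class SyntheticTruth:
    """Manifest of what was planted (round-trips through TSV exactly)."""

    planted_genes: frozenset[str]
    designated_pathway: str | None
    planted_folds: dict[str, float]
    group_sizes: dict[str, int]
    target_cv: float
    seed: int

    def write_tsv(self, path: str | Path) -> None:
        lines = [
            f"designated_pathway\t{self.designated_pathway or ''}",
            f"target_cv\t{self.target_cv!r}",
            f"seed\t{self.seed}",
        ]
        for group in sorted(self.group_sizes):
            lines.append(f"group_size\t{group}\t{self.group_sizes[group]}")
        for gene in sorted(self.planted_genes):
            lines.append(f"planted\t{gene}\t{self.planted_folds[gene]!r}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SyntheticTruth":
        designated: str | None = None
        target_cv = 0.0
        seed = 0
        group_sizes: dict[str, int] = {}
        folds: dict[str, float] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            fields = line.split("\t")
            if fields[0] == "designated_pathway":
                designated = fields[1] or None
            elif fields[0] == "target_cv":
                target_cv = float(fields[1])
            elif fields[0] == "seed":
                seed = int(fields[1])
            elif fields[0] == "group_size":
                group_sizes[fields[1]] = int(fields[2])
            elif fields[0] == "planted":
                folds[fields[1]] = float(fields[2])
            else:
                raise ValueError(f"unknown truth record {fields[0]!r}")
        return cls(
            planted_genes=frozenset(folds),
            designated_pathway=designated,
            planted_folds=folds,
            group_sizes=group_sizes,
            target_cv=target_cv,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------


def _connect_components(g: nx.Graph, rng: np.random.Generator) -> None:
    """Attach every small component to the largest one with a single edge."""
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    if len(comps) <= 1:
        return
    giant = sorted(comps[0])
    for comp in comps[1:]:
        nodes = sorted(comp)
        a = nodes[int(rng.integers(len(nodes)))]
        b = giant[int(rng.integers(len(giant)))]
        g.add_edge(a, b)


def generate_network(
    n_genes: int,
    mean_degree: float = 4.0,
    model: str = "configuration-powerlaw",
    seed: int = 0,
) -> PPINetwork:
    """Connected scale-free-ish network with gene labels G0001, G0002, ...

    ``configuration-powerlaw`` draws Pareto expected degrees scaled to the
    requested mean (Chung-Lu construction, heavy-tailed: degree
    variance/mean well above Poisson).  ``duplication-divergence`` uses the
    duplication-divergence growth model; there ``mean_degree`` only sets the
    retention probability heuristically.  Disconnected components are tied
    to the giant component with single edges.
    """
    if n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    rng = np.random.default_rng(seed)
    if model == "configuration-powerlaw":
        alpha = 2.5
        x_min = mean_degree * (alpha - 1) / alpha
        w = x_min * (1.0 + rng.pareto(alpha, size=n_genes))
        w = np.minimum(w, math.sqrt(n_genes * mean_degree))
        g = nx.expected_degree_graph(w.tolist(), seed=int(rng.integers(2**31)), selfloops=False)
    elif model == "duplication-divergence":
        retention = float(np.clip(mean_degree / 10.0, 0.1, 0.7))
        g = nx.duplication_divergence_graph(n_genes, retention, seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown network model {model!r}")
    _connect_components(g, rng)
    width = max(4, len(str(n_genes)))
    mapping = {v: f"G{v + 1:0{width}d}" for v in g.nodes}
    return PPINetwork(nx.relabel_nodes(g, mapping))


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSetPlan:
    """A collection plus which set is designated and its connected core."""

    collection: GeneSetCollection
    designated_id: str
    core_genes: frozenset[str]


def generate_genesets(
    network: PPINetwork,
    n_sets: int = 50,
    size_range: tuple[int, int] = (15, 80),
    overlap_rate: float = 0.1,
    seed: int = 0,
    core_size: int = 12,
) -> GeneSetPlan:
    """Sample ``n_sets`` gene sets from the network's genes.

    One set (chosen at random) is designated: it is built around a random
    connected core of ``core_size`` genes, so a connected planted module can
    live entirely inside it.  ``overlap_rate`` biases a fraction of every
    other set towards a shared pool, inducing realistic overlaps.
    """
    lo, hi = size_range
    nodes = sorted(network.nodes)
    if hi > len(nodes):
        raise ValueError("set sizes exceed the number of network genes")
    if not 1 <= core_size <= lo:
        raise ValueError("core_size must be in [1, min set size]")
    rng = np.random.default_rng(seed)
    adj = {v: list(network.graph[v]) for v in nodes}
    core = frozenset(random_connected_set(adj, nodes, core_size, rng))
    designated_idx = int(rng.integers(n_sets))

    pool_size = max(1, int(round(0.1 * len(nodes))))
    shared_pool = list(rng.choice(nodes, size=pool_size, replace=False))

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    width = max(4, len(str(n_sets)))
    designated_id = ""
    for i in range(n_sets):
        set_id = f"PW{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if i == designated_idx:
            rest = [v for v in nodes if v not in core]
            extra = rng.choice(rest, size=size - len(core), replace=False)
            genes = core | set(str(v) for v in extra)
            designated_id = set_id
        else:
            n_shared = min(int(round(overlap_rate * size)), len(shared_pool))
            chosen: set[str] = set(
                str(v) for v in rng.choice(shared_pool, size=n_shared, replace=False)
            )
            rest = [v for v in nodes if v not in chosen]
            fill = rng.choice(rest, size=size - len(chosen), replace=False)
            genes = chosen | set(str(v) for v in fill)
        sets[set_id] = (f"synthetic pathway {i + 1}", frozenset(genes))
    return GeneSetPlan(
        collection=GeneSetCollection(sets),
        designated_id=designated_id,
        core_genes=core,
    )


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------


def cv_to_sigma(cv_percent: float) -> float:
    """Log-normal sigma for a target coefficient of variation (percent)."""
    cv = cv_percent / 100.0
    return math.sqrt(math.log1p(cv * cv))


def generate_study(
    network: PPINetwork,
    design: StudyDesign,
    truth_params: TruthParams,
    seed: int = 0,
    planted_genes: frozenset[str] | None = None,
    designated_pathway: str | None = None,
) -> tuple[IntensityStudy, ProteinGeneMap, SyntheticTruth]:
    """Log-normal intensity study with planted multiplicative group effects.

    Every network gene gets one protein (``P_<gene>``).  Planted genes carry
    a fold effect in ``truth_params.fold_range`` (direction mixed when
    ``mixed_direction``) applied to all case-group samples; intra-group CV
    is tuned via the log-normal sigma; ~``missing_rate`` of cells are
    missing completely at random.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(network.nodes)
    proteins = [f"P_{g}" for g in genes]
    pg_map = ProteinGeneMap({f"P_{g}": g for g in genes})

    if planted_genes is None and truth_params.n_planted > 0:
        adj = {v: list(network.graph[v]) for v in genes}
        planted_genes = frozenset(
            random_connected_set(adj, genes, truth_params.n_planted, rng)
        )
    planted_genes = planted_genes or frozenset()

    lo, hi = truth_params.fold_range
    folds: dict[str, float] = {}
    for gene in sorted(planted_genes):
        magnitude = float(rng.uniform(lo, hi))
        down = truth_params.mixed_direction and rng.random() < 0.5
        folds[gene] = 1.0 / magnitude if down else magnitude

    groups_order = sorted(design.group_sizes)
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    for g in groups_order:
        for i in range(design.group_sizes[g]):
            sid = f"{g}_{i + 1:02d}"
            sample_ids.append(sid)
            groups[sid] = g

    sigma = cv_to_sigma(truth_params.target_cv)
    n_prot, n_samp = len(proteins), len(sample_ids)
    base = 10.0 ** rng.uniform(2.0, 4.0, size=n_prot)
    noise = rng.normal(-0.5 * sigma * sigma, sigma, size=(n_prot, n_samp))
    intensities = base[:, None] * np.exp(noise)

    case_cols = np.array([groups[s] != design.control_group for s in sample_ids])
    gene_row = {g: i for i, g in enumerate(genes)}
    for gene, fold in folds.items():
        intensities[gene_row[gene], case_cols] *= fold

    if truth_params.missing_rate > 0:
        mask = rng.random(size=(n_prot, n_samp)) < truth_params.missing_rate
        intensities = np.where(mask, np.nan, intensities)

    study = IntensityStudy(
        protein_ids=proteins,
        sample_ids=sample_ids,
        intensities=intensities,
        groups=groups,
    )
    truth = SyntheticTruth(
        planted_genes=planted_genes,
        designated_pathway=designated_pathway,
        planted_folds=folds,
        group_sizes=dict(design.group_sizes),
        target_cv=truth_params.target_cv,
        seed=seed,
    )
    return study, pg_map, truth


# ---------------------------------------------------------------------------
# One-call benchmark
# ---------------------------------------------------------------------------


@dataclass
class Benchmark:
    network: PPINetwork
    collection: GeneSetCollection
    designated_id: str
    study: IntensityStudy
    pg_map: ProteinGeneMap
    truth: SyntheticTruth


def generate_benchmark(
    seed: int,
    n_genes: int = 400,
    mean_degree: float = 4.0,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (15, 80),
    n_planted: int = 12,
    fold_range: tuple[float, float] = (2.5, 4.2),
    design: StudyDesign | None = None,
    target_cv: float = 24.0,
    missing_rate: float = 0.02,
    null: bool = False,
) -> Benchmark:
    """Network + gene sets + study with the planted module inside the
    designated pathway's connected core.  ``null=True`` plants nothing but
    keeps the designated pathway defined (for specificity controls)."""
    design = design or StudyDesign()
    ss = np.random.SeedSequence(seed)
    net_seed, sets_seed, study_seed = (
        int(c.generate_state(1)[0]) % (2**31) for c in ss.spawn(3)
    )
    network = generate_network(n_genes, mean_degree=mean_degree, seed=net_seed)
    plan = generate_genesets(
        network,
        n_sets=n_sets,
        size_range=set_size_range,
        seed=sets_seed,
        core_size=n_planted,
    )
    truth_params = TruthParams(
        n_planted=0 if null else n_planted,
        fold_range=fold_range,
        target_cv=target_cv,
        missing_rate=missing_rate,
    )
    study, pg_map, truth = generate_study(
        network,
        design,
        truth_params,
        seed=study_seed,
        planted_genes=frozenset() if null else plan.core_genes,
        designated_pathway=plan.designated_id,
    )
    return Benchmark(
        network=network,
        collection=plan.collection,
        designated_id=plan.designated_id,
        study=study,
        pg_map=pg_map,
        truth=truth,
    )
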