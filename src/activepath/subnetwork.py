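"""Active-subnetwork identification on a scored interaction network.

Gene p-values become standard-normal upper quantiles z_i = Phi^-1(1 - p_i);
a candidate gene set A of size k is scored z_A = sum(z_i) / sqrt(k) and then
standardized against a Monte-Carlo background of random connected size-k
sets, s_A = (z_A - mu_k) / sigma_k.  High-scoring connected modules are
found by simulated annealing (add a boundary gene / remove a
non-articulation gene, geometric cooling) and reported subject to a maximum
pairwise overlap.

``exhaustive_search`` enumerates every connected induced subgraph and is the
brute-force reference for small networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from activepath.io_formats import PPINetwork

logger = logging.getLogger(__name__)

P_CLAMP = 1e-16
UNSCORED_P = 0.999  # network genes without a score are strongly disfavoured


class DegenerateCalibrationError(ValueError):
    """All gene z-scores identical: background sd is exactly zero."""


class DisconnectedModuleError(ValueError):
    """A gene set does not induce a connected subgraph."""


def p_to_z(p: float | np.ndarray) -> float | np.ndarray:
    """Standard-normal upper quantile of ``p``, clamped to [1e-16, 1 - 1e-16].

    Monotone decreasing in p; p = 0.5 maps to z = 0.  Values at or below 0,
    or above 1, are rejected (p = 1 itself clamps — tied tests produce it).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    z = stats.norm.isf(np.clip(arr, P_CLAMP, 1.0 - P_CLAMP))
    return float(z) if np.isscalar(p) or arr.ndim == 0 else z


def aggregate_z(z_values: Sequence[float]) -> float:
    """z_A = sum(z_i) / sqrt(k); standard normal when z_i are iid N(0,1)."""
    arr = np.asarray(z_values, dtype=float)
    if arr.size == 0:
        raise ValueError("aggregate_z needs a non-empty list")
    return float(arr.sum() / math.sqrt(arr.size))


def overlap_fraction(genes_a: Iterable[str], genes_b: Iterable[str]) -> float:
    """|A n B| / min(|A|, |B|); 1.0 whenever one set contains the other."""
    a, b = set(genes_a), set(genes_b)
    if not a or not b:
        raise ValueError("overlap_fraction needs non-empty sets")
    return len(a & b) / min(len(a), len(b))


@dataclass
class GeneScoreMap:
    """Per-gene p-values and z-scores restricted to the network's nodes."""

    p_values: dict[str, float]
    z_scores: dict[str, float]

    @classmethod
    def from_pvalues(
        cls,
        p_values: Mapping[str, float],
        network: PPINetwork,
        unscored_p: float = UNSCORED_P,
    ) -> "GeneScoreMap":
        """Build scores for every network node.

        Scored genes absent from the network are dropped with a logged count;
        network genes without a score receive ``unscored_p`` (default 0.999)
        so they are strongly disfavoured but finite.
        """
        nodes = network.nodes
        dropped = [g for g in p_values if g not in nodes]
        if dropped:
            logger.info("dropping %d scored gene(s) not in the network", len(dropped))
        p_full = {g: float(p_values.get(g, unscored_p)) for g in nodes}
        z_full = {g: p_to_z(p) for g, p in p_full.items()}
        return cls(p_values=p_full, z_scores=z_full)

    def z(self, gene: str) -> float:
        return self.z_scores[gene]

    def genes(self) -> list[str]:
        return sorted(self.z_scores)


@dataclass
class Subnetwork:
    """Connected gene set with raw aggregate and size-calibrated scores."""

    genes: frozenset[str]
    z_a: float
    s_a: float

    @property
    def k(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class CalibrationTable:
    """Monte-Carlo background (mu_k, sigma_k) of z_A for random connected sets."""

    mu: dict[int, float]
    sigma: dict[int, float]
    mc_samples: int
    seed: int

    def __contains__(self, k: int) -> bool:
        return k in self.mu

    @property
    def k_max(self) -> int:
        return max(self.mu)

    def standardize(self, z_a: float, k: int) -> float:
        return (z_a - self.mu[k]) / self.sigma[k]


def _adjacency(network: PPINetwork) -> dict[str, list[str]]:
    return {v: list(network.graph[v]) for v in network.graph}


def random_connected_set(
    adj: Mapping[str, list[str]],
    nodes: Sequence[str],
    k: int,
    rng: np.random.Generator,
) -> set[str]:
    """Grow a random connected size-k set from a uniform start node.

    Each step adds a uniform choice among the current boundary (distinct
    neighbours outside the set).  Not uniform over all connected sets; it is
    the same sampler used for calibration and search starts, seed-fixed.
    """
    for _ in range(100):
        start = nodes[int(rng.integers(len(nodes)))]
        current = {start}
        boundary = set(adj[start])
        while len(current) < k and boundary:
            pick = sorted(boundary)[int(rng.integers(len(boundary)))]
            current.add(pick)
            boundary.discard(pick)
            boundary.update(u for u in adj[pick] if u not in current)
            boundary -= current
        if len(current) == k:
            return current
    raise ValueError(f"could not grow a connected set of size {k}")


def calibrate(
    score_map: GeneScoreMap,
    network: PPINetwork,
    k_range: Iterable[int],
    mc_samples: int = 200,
    seed: int = 0,
) -> CalibrationTable:
    """Estimate (mu_k, sigma_k) from random connected size-k sets.

    k = 1 is computed exactly by enumerating all nodes.  Raises
    :class:`DegenerateCalibrationError` when every gene shares one z-score.
    sigma estimates of exactly zero (possible when the sampler never touches
    a distinctive gene) are floored at 1e-9 with a warning.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain integers >= 1")
    if mc_samples < 100:
        raise ValueError("mc_samples must be >= 100")
    nodes = sorted(network.nodes)
    if len(nodes) < ks[-1]:
        raise ValueError("network smaller than max(k_range)")
    z_all = np.array([score_map.z(g) for g in nodes])
    if np.ptp(z_all) == 0:
        raise DegenerateCalibrationError("all gene z-scores are identical")

    adj = _adjacency(network)
    rng = np.random.default_rng(seed)
    mu: dict[int, float] = {}
    sigma: dict[int, float] = {}
    for k in ks:
        if k == 1:
            samples = z_all
        else:
            vals = np.empty(mc_samples)
            for i in range(mc_samples):
                genes = random_connected_set(adj, nodes, k, rng)
                vals[i] = sum(score_map.z(g) for g in genes) / math.sqrt(k)
            samples = vals
        mu[k] = float(np.mean(samples))
        sd = float(np.std(samples, ddof=1))
        if sd == 0:
            logger.warning("sigma_%d is 0 in Monte-Carlo calibration; flooring at 1e-9", k)
            sd = 1e-9
        sigma[k] = sd
    return CalibrationTable(mu=mu, sigma=sigma, mc_samples=mc_samples, seed=seed)


def score_subnetwork(
    genes: Iterable[str],
    score_map: GeneScoreMap,
    calibration: CalibrationTable,
    network: PPINetwork,
) -> Subnetwork:
    """Score a connected gene set: s_A = (z_A - mu_k) / sigma_k."""
    gene_set = frozenset(genes)
    if not gene_set:
        raise ValueError("empty gene set")
    sub = network.graph.subgraph(gene_set)
    if sub.number_of_nodes() != len(gene_set):
        missing = sorted(gene_set - network.nodes)
        raise DisconnectedModuleError(f"genes not in network: {missing}")
    if len(gene_set) > 1 and not nx.is_connected(sub):
        raise DisconnectedModuleError("gene set does not induce a connected subgraph")
    k = len(gene_set)
    if k not in calibration:
        raise ValueError(f"no calibration entry for k = {k}")
    z_a = aggregate_z([score_map.z(g) for g in gene_set])
    return Subnetwork(genes=gene_set, z_a=z_a, s_a=calibration.standardize(z_a, k))


@dataclass
class SearchParams:
    """Simulated-annealing and multi-module extraction parameters."""

    n_modules: int = 10
    max_overlap: float = 0.5
    sa_iterations: int = 10_000
    t_start: float = 1.0
    t_end: float = 1e-3
    restarts: int = 5
    seed: int = 0
    attempts_per_module: int = 3

    def __post_init__(self) -> None:
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if not 0 <= self.max_overlap < 1:
            raise ValueError("max_overlap must be in [0, 1)")
        if not self.t_start > self.t_end > 0:
            raise ValueError("need t_start > t_end > 0")


def _anneal_once(
    adj: Mapping[str, list[str]],
    z: Mapping[str, float],
    calibration: CalibrationTable,
    params: SearchParams,
    rng: np.random.Generator,
    start: str,
) -> tuple[float, frozenset[str]]:
    """One annealing run from a given start node; returns (best s_A, genes)."""
    mu, sig = calibration.mu, calibration.sigma
    k_max = calibration.k_max

    def score(z_sum: float, k: int) -> float:
        return (z_sum / math.sqrt(k) - mu[k]) / sig[k]

    current: set[str] = {start}
    z_sum = z[start]
    boundary: dict[str, int] = {}
    for u in adj[start]:
        boundary[u] = boundary.get(u, 0) + 1

    s_cur = score(z_sum, 1)
    best_s, best_set = s_cur, frozenset(current)

    n_iter = params.sa_iterations
    ratio = params.t_end / params.t_start
    for i in range(n_iter):
        temp = params.t_start * ratio ** (i / max(n_iter - 1, 1))
        k = len(current)
        can_add = bool(boundary) and (k + 1) in calibration.mu and k < k_max
        can_remove = k > 1 and (k - 1) in calibration.mu
        if not can_add and not can_remove:
            break
        do_add = can_add and (not can_remove or rng.random() < 0.5)

        if do_add:
            cand = sorted(boundary)
            # bias proposals toward high-z candidates; acceptance still
            # depends on the calibrated score, so this only speeds mixing
            w = np.exp(np.clip([z[u] for u in cand], -8.0, 8.0))
            v = cand[int(rng.choice(len(cand), p=w / w.sum()))]
            new_sum, new_k = z_sum + z[v], k + 1
        else:
            arts = set(nx.articulation_points(nx.Graph(
                (a, b) for a in current for b in adj[a] if b in current and a < b
            ))) if k > 2 else set()
            cand = sorted(current - arts)
            if not cand:
                continue
            v = cand[int(rng.integers(len(cand)))]
            new_sum, new_k = z_sum - z[v], k - 1

        delta = score(new_sum, new_k) - s_cur
        if delta > 0 or rng.random() < math.exp(max(delta / temp, -700.0)):
            if do_add:
                current.add(v)
                boundary.pop(v, None)
                for u in adj[v]:
                    if u not in current:
                        boundary[u] = boundary.get(u, 0) + 1
            else:
                current.discard(v)
                for u in adj[v]:
                    if u not in current:
                        cnt = boundary.get(u, 0) - 1
                        if cnt <= 0:
                            boundary.pop(u, None)
                        else:
                            boundary[u] = cnt
                boundary[v] = sum(1 for u in adj[v] if u in current)
            z_sum, s_cur = new_sum, s_cur + delta
            if s_cur > best_s:
                best_s, best_set = s_cur, frozenset(current)
    return best_s, best_set


def _start_nodes(
    z: Mapping[str, float], n_attempts: int, rng: np.random.Generator
) -> list[str]:
    """Start pool: alternate the top-z genes with uniform random nodes."""
    ranked = sorted(z, key=lambda g: (-z[g], g))
    starts = []
    for j in range(n_attempts):
        if j % 2 == 0:
            starts.append(ranked[(j // 2) % len(ranked)])
        else:
            starts.append(ranked[int(rng.integers(len(ranked)))])
    return starts


def anneal_search(
    network: PPINetwork,
    score_map: GeneScoreMap,
    calibration: CalibrationTable,
    params: SearchParams,
) -> Subnetwork:
    """Best connected subnetwork over ``params.restarts`` annealing runs.

    Deterministic given ``params.seed``.  Never errors on a valid scored
    network: with no improving move the best single start node is returned.
    """
    adj = _adjacency(network)
    if not adj:
        raise ValueError("empty network")
    rng = np.random.default_rng(params.seed)
    z = score_map.z_scores
    starts = _start_nodes(z, params.restarts, rng)
    best: tuple[float, frozenset[str]] | None = None
    for start in starts:
        s, genes = _anneal_once(adj, z, calibration, params, rng, start)
        if best is None or s > best[0] or (s == best[0] and sorted(genes) < sorted(best[1])):
            best = (s, genes)
    assert best is not None
    return score_subnetwork(best[1], score_map, calibration, network)


def find_subnetworks(
    network: PPINetwork,
    score_map: GeneScoreMap,
    calibration: CalibrationTable,
    params: SearchParams,
) -> list[Subnetwork]:
    """Multi-module extraction: repeated annealing restarts, then greedy
    acceptance by descending score subject to pairwise overlap <= max_overlap.
    """
    adj = _adjacency(network)
    rng = np.random.default_rng(params.seed)
    z = score_map.z_scores
    n_attempts = max(params.n_modules * params.attempts_per_module, params.restarts)
    starts = _start_nodes(z, n_attempts, rng)
    candidates: dict[frozenset[str], float] = {}
    for start in starts:
        s, genes = _anneal_once(adj, z, calibration, params, rng, start)
        if genes not in candidates or s > candidates[genes]:
            candidates[genes] = s

    ranked = sorted(candidates.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    kept: list[Subnetwork] = []
    for genes, _ in ranked:
        if len(kept) >= params.n_modules:
            break
        if all(overlap_fraction(genes, m.genes) <= params.max_overlap for m in kept):
            kept.append(score_subnetwork(genes, score_map, calibration, network))
    return sorted(kept, key=lambda m: (-m.s_a, m.sorted_genes()))


# ---------------------------------------------------------------------------
# Brute-force reference
# ---------------------------------------------------------------------------


def connected_subsets(
    network: PPINetwork, k_max: int | None = None
) -> Iterable[frozenset[str]]:
    """Enumerate every connected induced vertex subset exactly once.

    Each subset is generated from its minimum-index node by ordered
    extension with an exclusion set (no duplicates).  Feasible for networks
    of ~20 nodes; intended as an oracle, not a production path.
    """
    nodes = sorted(network.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = {v: sorted(network.graph[v]) for v in nodes}

    def rec(root_i: int, current: set[str], cand: list[str], excluded: set[str]):
        yield frozenset(current)
        if k_max is not None and len(current) >= k_max:
            return
        for pos, w in enumerate(cand):
            ex_w = excluded | set(cand[:pos])
            in_frontier = set(cand[pos + 1:])
            new_cand = cand[pos + 1:] + [
                u
                for u in adj[w]
                if index[u] > root_i
                and u not in current
                and u not in ex_w
                and u not in in_frontier
            ]
            yield from rec(root_i, current | {w}, new_cand, ex_w)

    for root in nodes:
        ri = index[root]
        first = [u for u in adj[root] if index[u] > ri]
        yield from rec(ri, {root}, first, set())


def exhaustive_search(
    network: PPINetwork,
    score_map: GeneScoreMap,
    calibration: CalibrationTable,
    k_max: int | None = None,
) -> Subnetwork:
    """Globally best connected subnetwork by full enumeration."""
    k_cap = calibration.k_max if k_max is None else min(k_max, calibration.k_max)
    best: tuple[float, frozenset[str]] | None = None
    z = score_map.z_scores
    for genes in connected_subsets(network, k_max=k_cap):
        k = len(genes)
        if k not in calibration:
            continue
        z_a = sum(z[g] for g in genes) / math.sqrt(k)
        s_a = calibration.standardize(z_a, k)
        if best is None or s_a > best[0] or (s_a == best[0] and sorted(genes) < sorted(best[1])):
            best = (s_a, genes)
    if best is None:
        raise ValueError("no connected subset within the calibration range")
    return score_subnetwork(best[1], score_map, calibration, network)


# ---------------------------------------------------------------------------
# Module table I/O
# ---------------------------------------------------------------------------


def write_modules(modules: Sequence[Subnetwork], path) -> None:
    """TSV: module_id, k, z_A, s_A, comma-joined sorted gene list."""
    lines = ["module_id\tk\tz_a\ts_a\tgenes"]
    for i, m in enumerate(modules, start=1):
        lines.append(
            f"M{i:03d}\t{m.k}\t{m.z_a!r}\t{m.s_a!r}\t{','.join(m.sorted_genes())}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_modules(path) -> list[tuple[str, frozenset[str], float, float]]:
    """Read the module TSV back as (module_id, genes, z_a, s_a) tuples."""
    from pathlib import Path

    out = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        mid, _k, z_a, s_a, genes = line.split("\t")
        out.append((mid, frozenset(genes.split(",")), float(z_a), float(s_a)))
    return out
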