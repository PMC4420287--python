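"""Readers and writers for the pipeline's external text formats.

Formats covered: intensity TSV (proteins x samples), sample->group TSV,
protein->gene TSV, GMT gene-set collections (Broad dialect), and undirected
interaction networks as two-column edge lists or three-column SIF.

All writers emit UTF-8, Unix line endings, and lexicographically sorted
records so that outputs diff deterministically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class StudyValidationError(ValueError):
    """An in-memory study object violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class IntensityStudy:
    """Protein x sample intensity matrix plus the sample grouping.

    Intensities are non-negative reals on an arbitrary (densitometry) scale;
    missing observations are NaN, never zero.  ``groups`` must cover every
    sample and name at least two distinct group labels.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(set(self.protein_ids)) != len(self.protein_ids):
            dup = _first_duplicate(self.protein_ids)
            raise StudyValidationError(f"duplicate protein ID {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise StudyValidationError(f"duplicate sample ID {dup!r}")
        if self.intensities.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise StudyValidationError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise StudyValidationError(f"sample {missing[0]!r} has no group assignment")
        labels = {self.groups[s] for s in self.sample_ids}
        if len(labels) < 2:
            raise StudyValidationError("study must contain at least two distinct groups")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities < 0):
                raise StudyValidationError("negative intensity encountered")
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_labels(self) -> list[str]:
        return sorted({self.groups[s] for s in self.sample_ids})

    def sample_indices(self, group: str | Iterable[str]) -> np.ndarray:
        """Column indices of the samples belonging to ``group`` (label or labels)."""
        wanted = {group} if isinstance(group, str) else set(group)
        idx = [j for j, s in enumerate(self.sample_ids) if self.groups[s] in wanted]
        if not idx:
            raise KeyError(f"no samples in group(s) {sorted(wanted)}")
        return np.asarray(idx, dtype=int)

    def group_matrix(self, group: str | Iterable[str]) -> np.ndarray:
        """Protein x sample submatrix for one group (or a pooled set of groups)."""
        return self.intensities[:, self.sample_indices(group)]

    def with_groups(self, groups: Mapping[str, str]) -> "IntensityStudy":
        """Same matrix under a different sample->group assignment (for shuffles)."""
        return IntensityStudy(
            protein_ids=list(self.protein_ids),
            sample_ids=list(self.sample_ids),
            intensities=self.intensities,
            groups=dict(groups),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets: ``set_id -> (description, frozenset of gene symbols)``."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, (desc, genes) in list(self.sets.items()):
            if not genes:
                raise StudyValidationError(f"gene set {set_id!r} is empty")
            self.sets[set_id] = (desc, frozenset(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def genes(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def ids(self) -> list[str]:
        return sorted(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass
class PPINetwork:
    """Undirected simple interaction graph over gene symbols."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise StudyValidationError(f"self-loop on node {loops[0][0]!r}")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "PPINetwork":
        g = nx.Graph()
        g.add_edges_from((a, b) for a, b in edges if a != b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        """Canonical sorted edge list (each pair ordered lexicographically)."""
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph[gene])


@dataclass
class ProteinGeneMap:
    """Total protein->gene mapping over the proteins it covers."""

    mapping: dict[str, str]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.mapping

    def __getitem__(self, protein_id: str) -> str:
        return self.mapping[protein_id]

    def get(self, protein_id: str, default: str | None = None) -> str | None:
        return self.mapping.get(protein_id, default)

    def unmapped(self, protein_ids: Iterable[str]) -> list[str]:
        """Proteins without a gene entry — reported, never silently dropped."""
        return [p for p in protein_ids if p not in self.mapping]


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    raise ValueError("no duplicate present")


# ---------------------------------------------------------------------------
# Intensity table + groups
# ---------------------------------------------------------------------------


def read_intensity_table(path: str | Path, groups_path: str | Path) -> IntensityStudy:
    """Read a protein x sample intensity TSV plus a sample->group TSV.

    The intensity file has a header row of sample IDs (first cell is a label
    for the ID column and is ignored) and one row per protein.  Empty cells
    are missing values.  Non-numeric cells and duplicate IDs raise
    :class:`FormatError` naming the offending row/column.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty intensity table")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise FormatError(f"{path}: header row has no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample ID {_first_duplicate(sample_ids)!r}")

    protein_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, got {len(fields)}"
            )
        pid = fields[0]
        if pid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate protein ID {pid!r}")
        seen.add(pid)
        row: list[float] = []
        for sample, cell in zip(sample_ids, fields[1:]):
            cell = cell.strip()
            if cell == "" or cell.upper() in {"NA", "NAN"}:
                row.append(math.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {sample!r}"
                ) from exc
        protein_ids.append(pid)
        rows.append(row)
    if not protein_ids:
        raise FormatError(f"{path}: no protein rows")

    groups = read_groups(groups_path)
    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise FormatError(f"{groups_path}: sample {missing[0]!r} has no group assignment")
    try:
        return IntensityStudy(
            protein_ids=protein_ids,
            sample_ids=sample_ids,
            intensities=np.asarray(rows, dtype=float),
            groups={s: groups[s] for s in sample_ids},
        )
    except StudyValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column sample->group TSV (no header)."""
    path = Path(path)
    groups: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        sample, group = fields
        if sample in groups:
            raise FormatError(f"{path}:{lineno}: duplicate sample ID {sample!r}")
        groups[sample] = group
    if not groups:
        raise FormatError(f"{path}: empty group file")
    return groups


def write_intensity_table(
    study: IntensityStudy, path: str | Path, groups_path: str | Path
) -> None:
    """Write a study back to intensity + groups TSVs (missing cells empty)."""
    lines = ["protein_id\t" + "\t".join(study.sample_ids)]
    for i, pid in enumerate(study.protein_ids):
        cells = [
            "" if math.isnan(v) else repr(float(v)) for v in study.intensities[i]
        ]
        lines.append(pid + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    glines = [f"{s}\t{study.groups[s]}" for s in study.sample_ids]
    Path(groups_path).write_text("\n".join(glines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: ``set_id TAB description TAB gene...``."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}")
        set_id, desc = fields[0], fields[1]
        if set_id in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set ID {set_id!r}")
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise FormatError(f"{path}:{lineno}: set {set_id!r} has no genes")
        sets[set_id] = (desc, genes)
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write canonical GMT: sets sorted by ID, genes sorted within each set."""
    lines = []
    for set_id in collection.ids():
        desc, genes = collection.sets[set_id]
        lines.append("\t".join([set_id, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


def read_network(path: str | Path) -> PPINetwork:
    """Read an undirected network from a 2-column edge list or 3-column SIF.

    Reversed duplicate edges collapse to one; self-loop lines are skipped
    with a logged count; an empty file is an error.
    """
    path = Path(path)
    g = nx.Graph()
    n_loops = 0
    n_edges_seen = 0
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) == 2:
            a, b = fields
        elif len(fields) == 3:
            a, _, b = fields  # SIF: node relation node
        else:
            raise FormatError(f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}")
        n_edges_seen += 1
        if a == b:
            n_loops += 1
            continue
        g.add_edge(a, b)
    if n_loops:
        logger.warning("%s: skipped %d self-loop line(s)", path, n_loops)
    if n_edges_seen == 0:
        raise FormatError(f"{path}: empty network file")
    return PPINetwork(g)


def write_network(network: PPINetwork, path: str | Path) -> None:
    """Write the canonical sorted two-column edge list."""
    lines = [f"{a}\t{b}" for a, b in network.edges()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Protein -> gene map
# ---------------------------------------------------------------------------


def read_protein_gene_map(path: str | Path) -> ProteinGeneMap:
    path = Path(path)
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        protein, gene = fields
        if protein in mapping:
            raise FormatError(f"{path}:{lineno}: duplicate protein ID {protein!r}")
        mapping[protein] = gene
    if not mapping:
        raise FormatError(f"{path}: empty mapping file")
    return ProteinGeneMap(mapping)


def write_protein_gene_map(pg_map: ProteinGeneMap, path: str | Path) -> None:
    lines = [f"{p}\t{g}" for p, g in sorted(pg_map.mapping.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
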