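"""Bait-centric protein-interaction maps: loading, filtering, role assignment.

A guilt-by-association RNAi screen starts from a set of *bait* genes (known or
suspected regulators of the process of interest) and pulls their direct
interaction partners out of a protein-protein interaction (PPI) database
compiled from multiple source datasets (yeast two-hybrid studies, literature
curation, interologs mapped from other species).  Because large interaction
maps contain promiscuous "sticky" hubs whose partner lists are dominated by
false positives, bait partner lists are pruned with a degree cutoff, partly
rescued by multi-study evidence, and a short list of biologically central
baits can be exempted from pruning altogether.  The remaining partners are
the *interactors*; genes in the map touching neither baits nor interactors
form the pool from which random *non-interactor* controls are drawn.

The map is held as an undirected simple :class:`networkx.Graph`; parallel
records of the same pair collapse into one edge carrying the set of source
dataset identifiers (its *evidence*) and an optional confidence score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger("netscreen.network")

__all__ = [
    "InteractionMap",
    "BaitSet",
    "FilterConfig",
    "RoleAssignment",
    "MapFormatError",
    "ConfigurationError",
    "load_interaction_map",
    "read_edge_file",
    "read_gene_list",
    "extract_bait_neighborhood",
    "apply_hub_filter",
    "filter_by_confidence",
    "assign_roles",
    "sample_non_interactors",
    "write_edge_tsv",
]


class MapFormatError(ValueError):
    """Raised when an edge record or edge file cannot be parsed."""


class ConfigurationError(ValueError):
    """Raised for invalid filter or threshold settings."""


def _canon(identifier: str) -> str:
    """Canonicalize a gene identifier: trim whitespace, case-fold.

    Exact string matching only; symbol-alias resolution is an external
    database concern and deliberately out of scope.
    """
    return str(identifier).strip().casefold()


class InteractionMap:
    """Undirected simple graph of protein pairs with per-edge evidence.

    Edge attributes:

    ``datasets``
        ``set`` of source-dataset identifiers supporting the pair; the
        *evidence count* of a pair is ``len(datasets)``.
    ``confidence``
        optional score in [0, 1]; ``None`` when no source supplied one.
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.graph: nx.Graph = graph if graph is not None else nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, gene: str) -> None:
        self.graph.add_node(_canon(gene))

    def add_interaction(
        self,
        protein_a: str,
        protein_b: str,
        dataset_id: str = "unknown",
        confidence: float | None = None,
    ) -> bool:
        """Record one interaction; returns False (and logs) for a self-loop.

        Repeated records of the same unordered pair accumulate dataset
        identifiers; the maximum of the supplied confidence scores is kept.
        """
        a, b = _canon(protein_a), _canon(protein_b)
        if not a or not b:
            raise MapFormatError("empty gene identifier in edge record")
        if a == b:
            logger.warning("self-loop dropped: %s", a)
            return False
        if self.graph.has_edge(a, b):
            data = self.graph.edges[a, b]
            data["datasets"].add(str(dataset_id))
            if confidence is not None:
                prev = data.get("confidence")
                data["confidence"] = confidence if prev is None else max(prev, confidence)
        else:
            self.graph.add_edge(a, b, datasets={str(dataset_id)}, confidence=confidence)
        return True

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(_canon(a), _canon(b))

    def evidence_count(self, a: str, b: str) -> int:
        return len(self.graph.edges[_canon(a), _canon(b)]["datasets"])

    def confidence(self, a: str, b: str) -> float | None:
        return self.graph.edges[_canon(a), _canon(b)].get("confidence")

    def degree(self, gene: str) -> int:
        g = _canon(gene)
        return self.graph.degree(g) if g in self.graph else 0

    def neighbors(self, gene: str) -> set[str]:
        g = _canon(gene)
        return set(self.graph.neighbors(g)) if g in self.graph else set()

    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def copy(self) -> "InteractionMap":
        return InteractionMap(self.graph.copy())

    def subgraph_of_edges(self, edges: Iterable[tuple[str, str]]) -> "InteractionMap":
        """New map containing exactly ``edges`` (with attributes) and their endpoints."""
        sub = nx.Graph()
        for a, b in edges:
            data = self.graph.edges[a, b]
            sub.add_edge(a, b, datasets=set(data["datasets"]), confidence=data.get("confidence"))
        return InteractionMap(sub)

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionMap(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class BaitSet:
    """Bait genes seeding the virtual interaction screen.

    ``rescue_baits`` are exempt from hub pruning: every one of their
    partners is retained regardless of degree (the role Cdk1/Cdk2 played
    as central cell-cycle kinases).
    """

    genes: frozenset[str]
    rescue_baits: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(_canon(g) for g in self.genes))
        object.__setattr__(self, "rescue_baits", frozenset(_canon(g) for g in self.rescue_baits))
        if not self.rescue_baits <= self.genes:
            raise ConfigurationError("rescue_baits must be a subset of the bait genes")

    @classmethod
    def from_lists(cls, genes: Iterable[str], rescue: Iterable[str] = ()) -> "BaitSet":
        return cls(frozenset(genes), frozenset(rescue))


@dataclass(frozen=True)
class FilterConfig:
    """Hub-pruning settings.

    ``max_bait_degree``
        baits with *strictly more* distinct partners than this in the
        extracted neighborhood have their partner edges removed (default 30).
    ``multi_study_min``
        a removed edge is restored when its pair is supported by at least
        this many distinct source datasets (default 2).
    ``min_confidence``
        optional strict lower bound for the separate confidence filter.
    """

    max_bait_degree: int = 30
    multi_study_min: int = 2
    min_confidence: float | None = None

    def __post_init__(self) -> None:
        if self.max_bait_degree < 0:
            raise ConfigurationError("max_bait_degree must be >= 0")
        if self.multi_study_min < 2:
            raise ConfigurationError("multi_study_min must be >= 2")
        if self.min_confidence is not None and not 0.0 <= self.min_confidence <= 1.0:
            raise ConfigurationError("min_confidence must lie in [0, 1]")


ROLE_BAIT = "bait"
ROLE_INTERACTOR = "interactor"
ROLE_NON_INTERACTOR = "non_interactor"
ROLE_UNCLASSIFIED = "unclassified"


@dataclass
class RoleAssignment:
    """Partition of map genes into bait / interactor / non-interactor / unclassified."""

    roles: dict[str, str]

    def genes_with_role(self, role: str) -> set[str]:
        return {g for g, r in self.roles.items() if r == role}

    @property
    def baits(self) -> set[str]:
        return self.genes_with_role(ROLE_BAIT)

    @property
    def interactors(self) -> set[str]:
        return self.genes_with_role(ROLE_INTERACTOR)

    @property
    def non_interactor_candidates(self) -> set[str]:
        return self.genes_with_role(ROLE_NON_INTERACTOR)

    def __getitem__(self, gene: str) -> str:
        return self.roles[_canon(gene)]


# ---------------------------------------------------------------------------
# Loading


def load_interaction_map(edge_records: Iterable[Sequence]) -> InteractionMap:
    """Build an :class:`InteractionMap` from raw edge rows.

    Each row is ``(protein_a, protein_b, dataset_id[, confidence])``.
    Duplicate (pair, dataset) rows collapse; the pair's evidence count is the
    number of distinct datasets naming it.  Self-loops are dropped with a
    logged warning.  Malformed rows raise :class:`MapFormatError` naming the
    row number (1-based).
    """
    imap = InteractionMap()
    for lineno, row in enumerate(edge_records, start=1):
        if len(row) < 3:
            raise MapFormatError(f"row {lineno}: expected >=3 columns, got {len(row)}")
        a, b, dataset = row[0], row[1], row[2]
        if not str(a).strip() or not str(b).strip():
            raise MapFormatError(f"row {lineno}: empty gene identifier")
        confidence = None
        if len(row) >= 4 and row[3] not in (None, ""):
            try:
                confidence = float(row[3])
            except (TypeError, ValueError) as exc:
                raise MapFormatError(f"row {lineno}: bad confidence {row[3]!r}") from exc
        imap.add_interaction(a, b, dataset, confidence)
    return imap


def read_edge_file(path: str | Path) -> InteractionMap:
    """Read a TSV edge list, or 3-column SIF (``A  interacts  B``).

    The TSV dialect has header ``protein_a  protein_b  dataset_id  confidence``
    (confidence column optional, empty cells allowed).  SIF rows get dataset
    ``"unknown"``.
    """
    path = Path(path)
    rows: list[tuple] = []
    sif = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().casefold() == "protein_a":
                continue  # header
            if len(fields) == 3 and fields[1].strip().casefold() == "interacts":
                sif = True
                rows.append((fields[0], fields[2], "unknown"))
                continue
            if len(fields) < 3:
                raise MapFormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            conf = fields[3] if len(fields) > 3 else ""
            for dataset in fields[2].split(";"):  # multi-evidence cells round-trip
                rows.append((fields[0], fields[1], dataset, conf))
    if sif:
        logger.info("read %s as SIF (%d rows)", path, len(rows))
    return load_interaction_map(rows)


def read_gene_list(path: str | Path) -> set[str]:
    """One identifier per line; ``#`` comments and blank lines ignored."""
    genes: set[str] = set()
    with Path(path).open() as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(_canon(line))
    return genes


def write_edge_tsv(imap: InteractionMap, path: str | Path) -> None:
    """Write the map in the 4-column TSV dialect (datasets joined by ``;``)."""
    with Path(path).open("w") as fh:
        fh.write("protein_a\tprotein_b\tdataset_id\tconfidence\n")
        for a, b in sorted(imap.edges()):
            data = imap.graph.edges[a, b]
            conf = data.get("confidence")
            fh.write(
                f"{a}\t{b}\t{';'.join(sorted(data['datasets']))}\t"
                f"{'' if conf is None else conf}\n"
            )


# ---------------------------------------------------------------------------
# Filtering pipeline


def extract_bait_neighborhood(imap: InteractionMap, baits: BaitSet) -> InteractionMap:
    """Edges with at least one bait endpoint; baits absent from the map stay isolated."""
    keep = [
        (a, b)
        for a, b in imap.graph.edges
        if a in baits.genes or b in baits.genes
    ]
    out = imap.subgraph_of_edges(keep)
    for bait in baits.genes:
        out.graph.add_node(bait)
    return out


def apply_hub_filter(
    neighborhood: InteractionMap,
    baits: BaitSet,
    config: FilterConfig = FilterConfig(),
) -> InteractionMap:
    """Prune the partner lists of promiscuous (hub) baits.

    1. Every bait whose degree in ``neighborhood`` strictly exceeds
       ``config.max_bait_degree`` has its incident edges removed.
    2. A removed edge is restored when its evidence count (distinct source
       datasets) is at least ``config.multi_study_min``.
    3. Edges incident to a rescue bait are restored unconditionally.

    The result's edge set is always a subset of the input's; degrees used in
    step 1 are the *pre-filter* degrees, so the operation is a single pass
    and idempotent.
    """
    hub_baits = {
        b for b in baits.genes if neighborhood.degree(b) > config.max_bait_degree
    }
    keep: list[tuple[str, str]] = []
    n_removed = n_rescued = 0
    for a, b in neighborhood.graph.edges:
        touches_hub = a in hub_baits or b in hub_baits
        if not touches_hub:
            keep.append((a, b))
            continue
        if a in baits.rescue_baits or b in baits.rescue_baits:
            keep.append((a, b))
            n_rescued += 1
        elif neighborhood.evidence_count(a, b) >= config.multi_study_min:
            keep.append((a, b))
            n_rescued += 1
        else:
            n_removed += 1
    logger.info(
        "hub filter: %d hub baits (> %d partners); %d edges removed, %d rescued",
        len(hub_baits), config.max_bait_degree, n_removed, n_rescued,
    )
    out = neighborhood.subgraph_of_edges(keep)
    for node in neighborhood.nodes:  # keep baits isolated rather than vanished
        if node in baits.genes:
            out.graph.add_node(node)
    return out


def filter_by_confidence(imap: InteractionMap, min_confidence: float) -> InteractionMap:
    """Keep edges whose confidence is strictly above ``min_confidence``.

    Edges carrying no score are dropped (their count is logged): an unscored
    interaction cannot demonstrate high confidence.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ConfigurationError("min_confidence must lie in [0, 1]")
    keep, n_unscored = [], 0
    for a, b in imap.graph.edges:
        conf = imap.graph.edges[a, b].get("confidence")
        if conf is None:
            n_unscored += 1
        elif conf > min_confidence:
            keep.append((a, b))
    if n_unscored:
        logger.info("confidence filter: %d unscored edges dropped", n_unscored)
    return imap.subgraph_of_edges(keep)


def assign_roles(
    full_map: InteractionMap,
    baits: BaitSet,
    filtered_neighborhood: InteractionMap,
) -> RoleAssignment:
    """Partition every node of ``full_map`` into exactly one role.

    bait > interactor > non-interactor-candidate > unclassified.  An
    interactor is a non-bait with a surviving edge in the filtered
    neighborhood.  A non-interactor candidate is adjacent (in the *full*
    map) to neither a bait nor an interactor — the pool from which random
    comparison genes are drawn.  Everything else (e.g. a gene adjacent to an
    interactor, or a partner pruned by the hub filter) is unclassified.
    """
    interactors = {
        n
        for n in filtered_neighborhood.nodes
        if n not in baits.genes and filtered_neighborhood.degree(n) >= 1
    }
    roles: dict[str, str] = {}
    for node in full_map.nodes | baits.genes:
        if node in baits.genes:
            roles[node] = ROLE_BAIT
        elif node in interactors:
            roles[node] = ROLE_INTERACTOR
        else:
            nbrs = full_map.neighbors(node)
            if nbrs & baits.genes or nbrs & interactors:
                roles[node] = ROLE_UNCLASSIFIED
            else:
                roles[node] = ROLE_NON_INTERACTOR
    return RoleAssignment(roles)


def sample_non_interactors(
    candidates: Iterable[str],
    n: int,
    seed: int | np.random.Generator,
) -> set[str]:
    """Uniform sample of ``n`` candidate genes without replacement (seeded)."""
    pool = sorted({_canon(g) for g in candidates})
    if n > len(pool):
        raise ValueError(f"cannot sample {n} genes from {len(pool)} candidates")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return set(rng.choice(pool, size=n, replace=False)) if n else set()
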