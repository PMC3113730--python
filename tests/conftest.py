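"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid networkx and the package's own graph
helpers: they work on plain edge dictionaries so they can cross-check the
implementation rather than restate it.
"""

from __future__ import annotations

import random

import pandas as pd
import pytest

from netscreen import BaitSet, FilterConfig, InteractionMap, load_interaction_map


# ---------------------------------------------------------------------------
# Brute-force oracles (pure python, no graph library)


def brute_force_hub_filter(
    edges: dict[frozenset, set[str]],
    baits: set[str],
    rescue_baits: set[str],
    max_degree: int,
    multi_study_min: int,
) -> set[frozenset]:
    """Materialize removal and rescue lists explicitly.

    ``edges`` maps unordered pairs to their supporting dataset sets.
    """
    partners: dict[str, set[str]] = {}
    for pair in edges:
        a, b = tuple(pair)
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    hubs = {b for b in baits if len(partners.get(b, set())) > max_degree}
    removed = {pair for pair in edges if pair & hubs}
    rescued = {
        pair
        for pair in removed
        if len(edges[pair]) >= multi_study_min or pair & rescue_baits
    }
    return (set(edges) - removed) | rescued


def brute_force_within_edges(edges: set[frozenset], group: set[str]) -> int:
    members = sorted(group)
    count = 0
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if frozenset((members[i], members[j])) in edges:
                count += 1
    return count


def brute_force_lcc(edges: set[frozenset], nodes: set[str]) -> int:
    """Largest component by hand-rolled breadth-first search."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for pair in edges:
        a, b = tuple(pair)
        if a in nodes and b in nodes:
            adj[a].add(b)
            adj[b].add(a)
    seen: set[str] = set()
    best = 0
    for start in nodes:
        if start in seen:
            continue
        queue, comp = [start], {start}
        while queue:
            for nbr in adj[queue.pop()]:
                if nbr not in comp:
                    comp.add(nbr)
                    queue.append(nbr)
        seen |= comp
        best = max(best, len(comp))
    return best


def random_edge_dict(
    rng: random.Random,
    n_nodes: int,
    p_edge: float = 0.15,
    n_datasets: int = 4,
) -> dict[frozenset, set[str]]:
    names = [f"n{i}" for i in range(n_nodes)]
    edges: dict[frozenset, set[str]] = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                k = 1 + (rng.random() < 0.3)
                edges[frozenset((names[i], names[j]))] = {
                    f"ds{d}" for d in rng.sample(range(n_datasets), k)
                }
    return edges


def map_from_edge_dict(edges: dict[frozenset, set[str]]) -> InteractionMap:
    rows = []
    for pair, datasets in sorted(edges.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(pair)
        for ds in sorted(datasets):
            rows.append((a, b, ds))
    return load_interaction_map(rows)


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture
def toy_map() -> InteractionMap:
    """Bait a with partners b,c; chain to d; separate pair e-f."""
    return load_interaction_map(
        [
            ("a", "b", "y2h1"),
            ("a", "c", "y2h1"),
            ("a", "c", "y2h2"),
            ("c", "d", "lit"),
            ("e", "f", "y2h1"),
        ]
    )


@pytest.fixture
def toy_baits() -> BaitSet:
    return BaitSet.from_lists(["a"])


def star_map(center: str, n_leaves: int, multi_evidence: set[int] = frozenset()):
    """Bait `center` with n_leaves single-dataset partners (some two-dataset)."""
    rows = []
    for i in range(n_leaves):
        rows.append((center, f"leaf{i}", "ds0"))
        if i in multi_evidence:
            rows.append((center, f"leaf{i}", "ds1"))
    return load_interaction_map(rows)


@pytest.fixture
def simple_wells() -> pd.DataFrame:
    """Two single-replicate plates with per-parameter sample means 40 and 60."""
    rows = []
    for plate, base in (("P1", 40.0), ("P2", 60.0)):
        rows.append(
            dict(plate_id=plate, well_id="W0", replicate_id=1, target="GFP",
                 is_control=True, pct_g1=base, pct_g2m=base / 2,
                 pct_gt_g2m=base / 4, pct_subg1=base / 8)
        )
        for i, delta in enumerate((-10.0, 10.0)):
            rows.append(
                dict(plate_id=plate, well_id=f"W{i+1}", replicate_id=1,
                     target=f"gene{plate}{i}", is_control=False,
                     pct_g1=base + delta, pct_g2m=base / 2 + delta / 2,
                     pct_gt_g2m=base / 4 + delta / 4, pct_subg1=base / 8 + delta / 8)
            )
    return pd.DataFrame(rows)
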