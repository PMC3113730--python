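"""Synthetic interaction networks and screen datasets with known ground truth.

Real inputs to a network-guided RNAi screen — a protein-interaction
database and plate-format flow-cytometry tables — are large and external.
These generators emulate their statistical structure so the whole pipeline
is testable, and parameter recovery measurable, without downloads:

* :func:`generate_network` — a degree-heterogeneous (Chung-Lu style,
  Pareto-weight) interaction graph with guaranteed hub nodes (> 30
  partners), a planted densely interconnected module standing in for the
  mutually interacting regulators, and per-edge source-dataset labels with
  a configurable multi-dataset (multi-study) probability.

* :func:`generate_screen` — duplicate 96-well plates with 1–3 GFP-control
  wells each, multiplicative per-plate batch effects, Gaussian well noise,
  true regulators shifting one phase gate upward, off-target false
  positives (a non-regulator dsRNA acting like a regulator) and
  knockdown-failure false negatives (a regulator dsRNA showing no effect).
  Phase percentages come from a five-part baseline composition (G1, S,
  G2/M, >G2/M, subG1) summing to 100; the S fraction is not reported, so
  the four emitted gates sum below 100 in expectation, as gated data do.

* :func:`simulate_validation_screen` — a second, independent dsRNA per
  tested gene: regulator status and affected gate are inherited, while
  off-target and knockdown-failure events are redrawn independently —
  exactly the independence assumption that makes second-reagent validation
  informative.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .network import InteractionMap, RoleAssignment
from .screen import PHASE_COLS, PHASE_LABELS, run_screen

logger = logging.getLogger("netscreen.simulate")

__all__ = [
    "NetworkSimConfig",
    "ScreenSimConfig",
    "NetworkGroundTruth",
    "ScreenGroundTruth",
    "generate_network",
    "generate_screen",
    "simulate_validation_screen",
    "recovery_report",
]


# ---------------------------------------------------------------------------
# Network generator


@dataclass(frozen=True)
class NetworkSimConfig:
    """Settings for the synthetic interaction map.

    Background edges follow a Chung-Lu model with Pareto-distributed node
    weights (shape ``degree_exponent``) rescaled to ``mean_degree``; the
    first ``n_hubs`` nodes additionally get enough extra random partners to
    exceed ``hub_degree_floor``.  A module of ``module_size`` nodes is
    planted with independent within-module edge probability
    ``p_within_module`` on top of the background.  Each edge carries one of
    ``n_datasets`` source labels; with probability ``p_multi_dataset`` it
    carries a second, distinct label (a pair reported by two independent
    studies).
    """

    n_nodes: int = 500
    mean_degree: float = 4.0
    degree_exponent: float = 1.6  # Pareto shape; smaller = heavier tail
    n_hubs: int = 5
    hub_degree_floor: int = 31
    module_size: int = 30
    p_within_module: float = 0.25
    n_datasets: int = 7
    p_multi_dataset: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_within_module", "p_multi_dataset"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.module_size > self.n_nodes:
            raise ValueError("module_size cannot exceed n_nodes")
        if self.n_datasets < 2 and self.p_multi_dataset > 0:
            raise ValueError("multi-dataset edges need n_datasets >= 2")


@dataclass(frozen=True)
class NetworkGroundTruth:
    module_nodes: frozenset[str]
    hub_nodes: frozenset[str]


def _gene(i: int) -> str:
    return f"g{i:05d}"


def generate_network(config: NetworkSimConfig) -> tuple[InteractionMap, NetworkGroundTruth]:
    """Synthetic interaction map with hubs and a planted module (seeded)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    names = [_gene(i) for i in range(n)]

    # Chung-Lu background: P(edge ij) = min(1, w_i w_j / sum(w))
    w = rng.pareto(config.degree_exponent, size=n) + 1.0
    w *= config.mean_degree * n / w.sum()
    total = w.sum()
    imap = InteractionMap()
    for node in names:
        imap.add_node(node)

    def random_dataset_labels() -> list[str]:
        first = int(rng.integers(config.n_datasets))
        labels = [f"ds{first}"]
        if config.n_datasets > 1 and rng.random() < config.p_multi_dataset:
            second = int(rng.integers(config.n_datasets - 1))
            if second >= first:
                second += 1
            labels.append(f"ds{second}")
        return labels

    def add_edge(i: int, j: int) -> None:
        for label in random_dataset_labels():
            imap.add_interaction(names[i], names[j], label)

    iu, ju = np.triu_indices(n, k=1)
    p_bg = np.minimum(1.0, w[iu] * w[ju] / total) if total > 0 else np.zeros(len(iu))
    draws = rng.random(len(iu))
    for i, j in zip(iu[draws < p_bg], ju[draws < p_bg]):
        add_edge(int(i), int(j))

    # Guarantee hubs: top-up the first n_hubs nodes to > hub_degree_floor.
    hubs = list(range(min(config.n_hubs, n)))
    for h in hubs:
        deficit = config.hub_degree_floor + 1 - imap.degree(names[h])
        if deficit > 0:
            others = np.array([k for k in range(n) if k != h], dtype=int)
            current = imap.neighbors(names[h])
            pool = [k for k in others if names[k] not in current]
            for k in rng.choice(pool, size=min(deficit, len(pool)), replace=False):
                add_edge(h, int(k))

    # Planted module: drawn from non-hub nodes so hub pruning cannot erase it.
    module_pool = np.array([k for k in range(n) if k not in set(hubs)], dtype=int)
    module = rng.choice(module_pool, size=config.module_size, replace=False)
    for a_idx in range(len(module)):
        for b_idx in range(a_idx + 1, len(module)):
            i, j = int(module[a_idx]), int(module[b_idx])
            if rng.random() < config.p_within_module and not imap.has_edge(names[i], names[j]):
                add_edge(i, j)

    truth = NetworkGroundTruth(
        module_nodes=frozenset(names[int(k)] for k in module),
        hub_nodes=frozenset(names[h] for h in hubs),
    )
    return imap, truth


# ---------------------------------------------------------------------------
# Screen generator


#: Baseline cell-cycle composition (percent of cells) for an unperturbed
#: asynchronous S2R+-like culture.  Five parts summing to 100; the S-phase
#: fraction is never reported, only the four gated parameters are.
DEFAULT_BASELINE = {
    "pct_g1": 48.0,
    "pct_s": 12.0,
    "pct_g2m": 32.0,
    "pct_gt_g2m": 5.0,
    "pct_subg1": 3.0,
}

#: Per-class probability that a gene truly regulates the cell cycle,
#: mirroring the hit-rate gradient a bait-centric screen is designed to
#: exploit (baits ≫ interactors > random non-interactors).
DEFAULT_CLASS_REGULATOR_PROB = {
    "bait": 0.26,
    "interactor": 0.118,
    "non_interactor": 0.045,
}


@dataclass(frozen=True)
class ScreenSimConfig:
    """Settings for the synthetic plate screen.

    ``roster`` maps gene → role class; each class draws true regulators
    with ``class_regulator_prob[class]``.  A true regulator shifts one
    uniformly chosen reported gate upward by ``effect_size_sd`` well-noise
    SDs.  ``off_target_rate`` is the per-dsRNA probability that a
    non-regulator reagent nevertheless acts like a regulator (random
    gate); ``knockdown_failure_rate`` the per-dsRNA probability that a
    regulator reagent shows no effect.  Plate batch effects are
    multiplicative, log-normal with log-SD ``plate_effect_sd``, drawn per
    physical plate per parameter; well noise is additive Gaussian with SD
    ``well_noise_sd`` percentage points, clipped at zero.
    """

    roster: Mapping[str, str] = field(default_factory=dict)
    class_regulator_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_REGULATOR_PROB)
    )
    effect_size_sd: float = 6.0
    baseline: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    plate_effect_sd: float = 0.08
    well_noise_sd: float = 1.5
    min_controls: int = 1
    max_controls: int = 3
    n_replicates: int = 2
    plate_capacity: int = 96
    off_target_rate: float = 0.0
    knockdown_failure_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("off_target_rate", "knockdown_failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for cls, p in self.class_regulator_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"regulator probability for {cls!r} outside [0, 1]")
        if self.effect_size_sd < 0:
            raise ValueError("effect_size_sd must be >= 0")
        if abs(sum(self.baseline.values()) - 100.0) > 1e-6:
            raise ValueError("baseline composition must sum to 100")
        if not 1 <= self.min_controls <= self.max_controls:
            raise ValueError("need 1 <= min_controls <= max_controls")
        if self.max_controls >= self.plate_capacity:
            raise ValueError("controls cannot fill a whole plate")


@dataclass
class ScreenGroundTruth:
    """Per-gene truth emitted alongside the synthetic wells.

    One row per gene: ``role``, ``is_regulator``, ``affected_param`` (a
    reported gate column, or '' for non-regulators), per-dsRNA
    ``off_target`` and ``knockdown_failed`` flags, and ``effective`` — the
    dsRNA actually produces a phenotype: (regulator AND NOT failed) OR
    off-target.
    """

    genes: pd.DataFrame

    @property
    def true_regulators(self) -> set[str]:
        return set(self.genes.index[self.genes["is_regulator"]])

    @property
    def effective_genes(self) -> set[str]:
        return set(self.genes.index[self.genes["effective"]])


_REPORTED = list(PHASE_COLS)


def _draw_truth(
    roster: Mapping[str, str],
    config: ScreenSimConfig,
    rng: np.random.Generator,
    fixed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regulator/off-target/failure assignment for one dsRNA per gene.

    With ``fixed`` given (columns is_regulator, affected_param), regulator
    status is inherited and only the per-dsRNA event flags are redrawn —
    the independent second reagent of a validation screen.
    """
    genes = list(roster)
    df = pd.DataFrame(index=pd.Index(genes, name="gene"))
    df["role"] = [roster[g] for g in genes]
    if fixed is None:
        p = df["role"].map(lambda r: config.class_regulator_prob.get(r, 0.0)).to_numpy()
        df["is_regulator"] = rng.random(len(df)) < p
        params = rng.choice(_REPORTED, size=len(df))
        df["affected_param"] = np.where(df["is_regulator"], params, "")
    else:
        df["is_regulator"] = fixed.loc[genes, "is_regulator"].to_numpy()
        df["affected_param"] = fixed.loc[genes, "affected_param"].to_numpy()
    df["knockdown_failed"] = df["is_regulator"] & (
        rng.random(len(df)) < config.knockdown_failure_rate
    )
    df["off_target"] = ~df["is_regulator"] & (rng.random(len(df)) < config.off_target_rate)
    # an off-target reagent perturbs a random gate of its own
    ot_params = rng.choice(_REPORTED, size=len(df))
    df.loc[df["off_target"], "affected_param"] = ot_params[df["off_target"].to_numpy()]
    df["effective"] = (df["is_regulator"] & ~df["knockdown_failed"]) | df["off_target"]
    return df


def generate_screen(
    config: ScreenSimConfig,
    fixed_truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ScreenGroundTruth]:
    """Synthetic duplicate-plate well table plus ground truth (seeded).

    Genes are laid out plate by plate; each plate receives a random number
    of control wells (``min_controls``–``max_controls``) and each layout is
    screened on ``n_replicates`` physical plates with independent batch
    effects.  Returns ``(wells, truth)`` where ``wells`` follows the
    well-table dialect of :mod:`netscreen.screen`.
    """
    if not config.roster:
        raise ValueError("empty gene roster")
    rng = np.random.default_rng(config.seed)
    truth_df = _draw_truth(config.roster, config, rng, fixed=fixed_truth)

    baseline = pd.Series({k: float(v) for k, v in config.baseline.items()})
    genes = list(truth_df.index)

    # plate layout: controls drawn per plate, samples fill the rest
    layouts: list[tuple[str, list[str], int]] = []  # (plate_id, genes, n_controls)
    cursor = 0
    plate_no = 0
    while cursor < len(genes):
        n_controls = int(rng.integers(config.min_controls, config.max_controls + 1))
        capacity = config.plate_capacity - n_controls
        plate_genes = genes[cursor : cursor + capacity]
        layouts.append((f"P{plate_no:03d}", plate_genes, n_controls))
        cursor += capacity
        plate_no += 1

    shift = config.effect_size_sd * config.well_noise_sd
    rows = []
    for plate_id, plate_genes, n_controls in layouts:
        targets = [("GFP", True)] * n_controls + [(g, False) for g in plate_genes]
        for rep in range(1, config.n_replicates + 1):
            # multiplicative batch effect per physical plate per gate
            plate_factor = np.exp(rng.normal(0.0, config.plate_effect_sd, size=len(_REPORTED)))
            for well_idx, (target, is_control) in enumerate(targets):
                values = baseline[_REPORTED].to_numpy().copy()
                if not is_control and truth_df.loc[target, "effective"]:
                    k = _REPORTED.index(truth_df.loc[target, "affected_param"])
                    values[k] += shift
                values = values * plate_factor + rng.normal(
                    0.0, config.well_noise_sd, size=len(_REPORTED)
                )
                values = np.clip(values, 0.0, None)
                rows.append(
                    {
                        "plate_id": plate_id,
                        "well_id": f"W{well_idx:02d}",
                        "replicate_id": rep,
                        "target": target,
                        "is_control": is_control,
                        **dict(zip(_REPORTED, values)),
                    }
                )
    wells = pd.DataFrame(rows)
    return wells, ScreenGroundTruth(truth_df)


def simulate_validation_screen(
    config: ScreenSimConfig,
    truth: ScreenGroundTruth,
    tested_genes: set[str] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, ScreenGroundTruth]:
    """Screen a second, independent dsRNA for ``tested_genes``.

    Regulator status and affected gate carry over from ``truth``; the
    off-target and knockdown-failure flags are redrawn independently,
    modeling reagents with non-overlapping target sequences.
    """
    tested = sorted(tested_genes if tested_genes is not None else set(truth.genes.index))
    roster = {g: truth.genes.loc[g, "role"] for g in tested}
    fixed = truth.genes.loc[tested, ["is_regulator", "affected_param"]].copy()
    # off-target-perturbed gates from the primary reagent must not carry over
    fixed.loc[~fixed["is_regulator"], "affected_param"] = ""
    cfg = replace(config, roster=roster, seed=config.seed + 1 if seed is None else seed)
    return generate_screen(cfg, fixed_truth=fixed)


# ---------------------------------------------------------------------------
# Recovery metrics


def recovery_report(
    gene_calls: pd.DataFrame,
    truth: ScreenGroundTruth,
    config: ScreenSimConfig | None = None,
) -> dict:
    """Compare pipeline hit calls against the generator's ground truth.

    Sensitivity and false-discovery proportion are measured against the
    *effective* reagent set (regulators with working knockdown, plus
    off-target reagents): that is what a phenotype screen can see.
    ``true_regulator_fraction_of_hits`` measures contamination of the hit
    list by off-target calls.  When ``config`` is given, analytic expected
    per-class hit rates are included:
    ``P(hit) = p_eff + (1 - p_eff) * p_null`` with
    ``p_eff = p_reg (1 - f_fail) + (1 - p_reg (1 - f_fail)) * f_ot`` and
    ``p_null`` the four-gate false-call probability of replicate-averaged
    Gaussian noise at the k = 3 threshold.
    """
    missing = set(gene_calls.index) - set(truth.genes.index)
    if missing:
        raise ValueError(f"calls for genes absent from truth: {sorted(missing)[:5]}")
    hits = set(gene_calls.index[gene_calls["hit"]])
    tested = set(gene_calls.index)
    effective = truth.effective_genes & tested
    tp = len(hits & effective)
    report: dict = {
        "n_tested": len(tested),
        "n_hits": len(hits),
        "n_effective": len(effective),
        "sensitivity": tp / len(effective) if effective else float("nan"),
        "false_discovery_proportion": (len(hits) - tp) / len(hits) if hits else 0.0,
        "true_regulator_fraction_of_hits": (
            len(hits & truth.true_regulators) / len(hits) if hits else float("nan")
        ),
    }
    rates = {}
    for cls, sub in truth.genes.loc[sorted(tested)].groupby("role"):
        cls_hits = len(hits & set(sub.index))
        rates[cls] = {
            "tested": len(sub),
            "hits": cls_hits,
            "hit_rate": cls_hits / len(sub),
        }
    report["class_hit_rates"] = rates
    if config is not None:
        from scipy import stats as _st

        p_null_gate = float(_st.norm.sf(3.0 * np.sqrt(config.n_replicates)))
        p_null = 1.0 - (1.0 - p_null_gate) ** len(_REPORTED)
        expected = {}
        for cls, p_reg in config.class_regulator_prob.items():
            p_work = p_reg * (1.0 - config.knockdown_failure_rate)
            p_eff = p_work + (1.0 - p_work) * config.off_target_rate
            expected[cls] = p_eff + (1.0 - p_eff) * p_null
        report["expected_class_hit_rates"] = expected
    return report
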