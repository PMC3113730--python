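"""Plate-based flow-cytometry screen analysis: normalization and hit calling.

Each well of a 96-well RNAi screen yields four gated cell-cycle parameters:
the percentage of cells with G1, G2/M, greater-than-G2/M, and sub-G1 DNA
content.  Plates are screened in duplicate and each plate carries one to
three negative-control wells (GFP dsRNA).  Analysis proceeds:

1. **g/p normalization** — per parameter, a global mean *g* over all
   non-control wells and a per-plate mean *p*; every well on a plate
   (controls included) is multiplied by *g/p*, absorbing multiplicative
   plate batch effects exactly.
2. **Replicate averaging** — normalized duplicate values per dsRNA are
   averaged.
3. **Control statistics** — mean and sample SD per parameter over the
   pooled normalized control wells.
4. **Hit calling** — a dsRNA is a hit when a parameter exceeds the control
   mean by strictly more than *k* control SDs (default k = 3, increase
   only); the set of flagged parameters is its phenotype class.
5. **Gene aggregation** — a gene is a hit when any of its dsRNA amplicons
   is; phenotypes union, strongest deviation retained per parameter.

All tables are pandas DataFrames in the well-table dialect
``plate_id, well_id, replicate_id, target, is_control, pct_g1, pct_g2m,
pct_gt_g2m, pct_subg1``.  A *plate* for normalization purposes is one
physical plate, i.e. a (plate_id, replicate_id) pair: duplicates are
normalized independently, then averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import RoleAssignment

__all__ = [
    "PHASE_COLS",
    "WELL_COLS",
    "NormalizationFactors",
    "ControlStats",
    "ScreenError",
    "read_plate_csv",
    "validate_wells",
    "compute_normalization_factors",
    "normalize_wells",
    "average_replicates",
    "control_statistics",
    "score_and_call",
    "aggregate_genes",
    "hit_rate_by_class",
    "run_screen",
]

#: The four gated parameters, in reporting order.
PHASE_COLS = ["pct_g1", "pct_g2m", "pct_gt_g2m", "pct_subg1"]
WELL_COLS = ["plate_id", "well_id", "replicate_id", "target", "is_control"] + PHASE_COLS
_PLATE_KEY = ["plate_id", "replicate_id"]

PHASE_LABELS = {
    "pct_g1": "G1",
    "pct_g2m": "G2/M",
    "pct_gt_g2m": ">G2/M",
    "pct_subg1": "subG1",
}


class ScreenError(ValueError):
    """Raised for malformed well tables or degenerate statistics."""


@dataclass
class NormalizationFactors:
    """Per-plate multiplicative correction factors g/p.

    ``global_mean``: Series indexed by parameter (computed on non-control
    wells across all plates).  ``plate_mean`` and ``factor``: DataFrames
    indexed by (plate_id, replicate_id) with one column per parameter.
    """

    global_mean: pd.Series
    plate_mean: pd.DataFrame
    factor: pd.DataFrame


@dataclass
class ControlStats:
    """Mean and sample SD (ddof=1) per parameter over normalized control wells."""

    mean: pd.Series
    sd: pd.Series
    n_controls: int


def validate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Check the well-table contract; returns the table with normalized dtypes."""
    missing = [c for c in WELL_COLS if c not in wells.columns]
    if missing:
        raise ScreenError(f"well table missing columns: {missing}")
    wells = wells.copy()
    wells["is_control"] = wells["is_control"].astype(bool)
    for col in PHASE_COLS:
        wells[col] = pd.to_numeric(wells[col])
        if (wells[col] < 0).any():
            raise ScreenError(f"negative values in {col}")
    dup = wells.duplicated(subset=["plate_id", "well_id", "replicate_id"])
    if dup.any():
        raise ScreenError("duplicate (plate_id, well_id, replicate_id) rows")
    plates_without_control = (
        wells.groupby(_PLATE_KEY)["is_control"].sum().pipe(lambda s: s[s == 0])
    )
    if len(plates_without_control):
        raise ScreenError(
            f"plates without a control well: {list(plates_without_control.index)[:5]}"
        )
    return wells


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    return validate_wells(pd.read_csv(path))


def compute_normalization_factors(wells: pd.DataFrame) -> NormalizationFactors:
    """Global mean g and per-physical-plate mean p on non-control wells; factors g/p."""
    samples = wells[~wells["is_control"]]
    if samples.empty:
        raise ScreenError("no non-control wells")
    counts = samples.groupby(_PLATE_KEY).size()
    empty = set(map(tuple, wells[_PLATE_KEY].drop_duplicates().to_numpy())) - set(counts.index)
    if empty:
        raise ScreenError(f"plates with zero non-control wells: {sorted(empty)[:5]}")
    g = samples[PHASE_COLS].mean()
    p = samples.groupby(_PLATE_KEY)[PHASE_COLS].mean()
    zero = p[(p == 0).any(axis=1)]
    if len(zero):
        bad = zero.columns[(zero == 0).any()].tolist()
        raise ScreenError(f"zero plate mean for {bad} on plates {list(zero.index)[:5]}")
    return NormalizationFactors(global_mean=g, plate_mean=p, factor=g / p)


def normalize_wells(wells: pd.DataFrame, factors: NormalizationFactors) -> pd.DataFrame:
    """Scale every well (controls included) by its plate's per-parameter factor."""
    plates = set(map(tuple, wells[_PLATE_KEY].drop_duplicates().to_numpy()))
    known = set(factors.factor.index)
    if plates - known:
        raise ScreenError(f"no normalization factor for plates {sorted(plates - known)[:5]}")
    out = wells.copy()
    idx = pd.MultiIndex.from_frame(out[_PLATE_KEY])
    out[PHASE_COLS] = out[PHASE_COLS].to_numpy() * factors.factor.loc[idx, PHASE_COLS].to_numpy()
    return out


def average_replicates(normalized: pd.DataFrame) -> pd.DataFrame:
    """Mean normalized phase vector per dsRNA target across replicate plates.

    Controls are excluded (they are summarized by :func:`control_statistics`).
    A target present on only one replicate keeps its single value and is
    flagged via ``n_replicates``.
    """
    samples = normalized[~normalized["is_control"]]
    if samples.empty:
        raise ScreenError("no non-control wells to average")
    grouped = samples.groupby("target")
    out = grouped[PHASE_COLS].mean()
    out["n_replicates"] = grouped.size()
    return out


def control_statistics(normalized: pd.DataFrame, sigma_source: str = "controls") -> ControlStats:
    """Reference mean/SD per parameter from normalized wells.

    ``sigma_source='controls'`` (default) pools GFP-control wells across
    plates; ``'all'`` uses every non-control well instead, a sensitivity
    switch for screens with too few controls.
    """
    if sigma_source == "controls":
        ref = normalized[normalized["is_control"]]
    elif sigma_source == "all":
        ref = normalized[~normalized["is_control"]]
    else:
        raise ScreenError(f"unknown sigma_source {sigma_source!r}")
    if len(ref) < 2:
        raise ScreenError("need >=2 reference wells for control statistics")
    return ControlStats(
        mean=ref[PHASE_COLS].mean(),
        sd=ref[PHASE_COLS].std(ddof=1),
        n_controls=len(ref),
    )


def score_and_call(
    per_target: pd.DataFrame,
    stats: ControlStats,
    k: float = 3.0,
) -> pd.DataFrame:
    """Deviation scores in control-SD units and one-sided hit calls.

    ``z = (value - mean) / sd`` per parameter; a parameter is flagged when
    ``z > k`` strictly (increases only — a depressed phase percentage is
    never a hit on that parameter).  Returns one row per target with
    ``z_*`` columns, per-parameter flags, the overall ``hit`` flag and the
    ``phenotypes`` string (comma-joined flagged gate labels).
    """
    degenerate = stats.sd[stats.sd <= 0]
    if len(degenerate):
        raise ScreenError(
            f"zero control SD for {degenerate.index.tolist()}: "
            "add control wells or check for constant data"
        )
    out = pd.DataFrame(index=per_target.index)
    flags = {}
    for col in PHASE_COLS:
        z = (per_target[col] - stats.mean[col]) / stats.sd[col]
        out[f"z_{col[4:]}"] = z
        flags[col] = z > k
    flag_df = pd.DataFrame(flags, index=per_target.index)
    out["hit"] = flag_df.any(axis=1)
    out["phenotypes"] = flag_df.apply(
        lambda row: ",".join(PHASE_LABELS[c] for c in PHASE_COLS if row[c]), axis=1
    )
    if "n_replicates" in per_target:
        out["n_replicates"] = per_target["n_replicates"]
    return out


def _phenoset(s: str) -> frozenset[str]:
    return frozenset(x for x in s.split(",") if x)


def aggregate_genes(
    calls: pd.DataFrame,
    amplicon_to_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Collapse per-amplicon calls to genes: any-hit rule, phenotype union.

    With ``amplicon_to_gene`` omitted, each target is its own gene (the
    common one-amplicon-per-gene layout).  Unmapped amplicons are excluded.
    The strongest (maximum) z is retained per parameter.
    """
    if amplicon_to_gene is None:
        out = calls.copy()
        out.index.name = "gene"
        return out
    mapped = calls.loc[[a for a in calls.index if a in amplicon_to_gene]].copy()
    n_dropped = len(calls) - len(mapped)
    if n_dropped:
        import logging

        logging.getLogger("netscreen.screen").warning(
            "%d unmapped amplicons excluded from gene aggregation", n_dropped
        )
    mapped["gene"] = [amplicon_to_gene[a] for a in mapped.index]
    zcols = [c for c in mapped.columns if c.startswith("z_")]
    grouped = mapped.groupby("gene")
    out = grouped[zcols].max()
    out["hit"] = grouped["hit"].any()
    out["phenotypes"] = grouped["phenotypes"].apply(
        lambda s: ",".join(sorted(frozenset().union(*map(_phenoset, s))))
    )
    return out


def hit_rate_by_class(gene_calls: pd.DataFrame, roles: RoleAssignment) -> pd.DataFrame:
    """Percentage of screened genes called hits, per role class.

    Classes with zero tested genes are reported with a missing rate.  Rates
    are kept at full precision; round only for presentation.
    """
    rows = []
    by_class: dict[str, list[str]] = {}
    for gene in gene_calls.index:
        by_class.setdefault(roles[gene], []).append(gene)
    for cls, genes in sorted(by_class.items()):
        tested = len(genes)
        hits = int(gene_calls.loc[genes, "hit"].sum())
        rows.append(
            {
                "class": cls,
                "tested": tested,
                "hits": hits,
                "hit_rate_pct": 100.0 * hits / tested if tested else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def run_screen(
    wells: pd.DataFrame,
    k: float = 3.0,
    sigma_source: str = "controls",
    amplicon_to_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Full pipeline: validate → normalize → average → score → per-gene calls."""
    wells = validate_wells(wells)
    factors = compute_normalization_factors(wells)
    normalized = normalize_wells(wells, factors)
    per_target = average_replicates(normalized)
    stats = control_statistics(normalized, sigma_source=sigma_source)
    calls = score_and_call(per_target, stats, k=k)
    return aggregate_genes(calls, amplicon_to_gene)
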