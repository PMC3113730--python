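"""Cross-screen comparison, second-dsRNA validation, high-confidence sets.

RNAi screens suffer both off-target false positives and knockdown false
negatives, so hit lists from independent screens of the same process
overlap only partially.  Three analytics quantify this:

* **Screen overlap** on the *common screened universe* — only genes tested
  in both screens enter the comparison, never whole genomes.
* **Second-dsRNA validation** — a primary hit is *validated* when an
  independent, minimally overlapping dsRNA against the same gene is itself
  a hit sharing at least one phenotype class (G1, G2/M, >G2/M, subG1) with
  the primary call.  Because off-target effects are independent between
  reagents, the validation rate estimates the primary screen's
  true-positive fraction.
* **High-confidence set** — validated hits, plus genes hit in both the
  current and a previous screen regardless of validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ScreenResultSet",
    "ValidationRecord",
    "HighConfidenceSet",
    "compare_screens",
    "validate_hits",
    "stratified_validation_rate",
    "assemble_high_confidence",
    "classify_novel_regulators",
    "phenotypes_from_calls",
]

Phenotypes = frozenset[str]


@dataclass(frozen=True)
class ScreenResultSet:
    """One screen's tested universe and per-gene hit phenotypes."""

    screen_id: str
    universe: frozenset[str]
    hits: Mapping[str, Phenotypes]  # gene -> phenotype classes (may be empty set)

    def __post_init__(self) -> None:
        extra = set(self.hits) - set(self.universe)
        if extra:
            raise ValueError(f"hits outside screened universe: {sorted(extra)[:5]}")

    @property
    def hit_genes(self) -> frozenset[str]:
        return frozenset(self.hits)


@dataclass(frozen=True)
class ValidationRecord:
    gene: str
    primary_phenotypes: Phenotypes
    validation_phenotypes: Phenotypes
    validation_hit: bool
    validated: bool
    strata: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class HighConfidenceSet:
    """Genes considered reliable regulators, with per-gene provenance.

    Provenance is ``validated``, ``dual_screen`` (hit in both the current
    and a prior screen but not validated), or ``both``.
    """

    provenance: Mapping[str, str]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)


def phenotypes_from_calls(gene_calls: pd.DataFrame) -> dict[str, Phenotypes]:
    """Hit-gene → phenotype-class mapping from a screen_analysis call table."""
    hits = gene_calls[gene_calls["hit"]]
    return {
        gene: frozenset(x for x in str(row["phenotypes"]).split(",") if x)
        for gene, row in hits.iterrows()
    }


def compare_screens(a: ScreenResultSet, b: ScreenResultSet) -> dict:
    """Overlap table on the common screened universe.

    Reports hit counts of each screen restricted to the shared universe,
    the intersection, the counts unique to each, and percentage overlaps
    (intersection as a percentage of each screen's restricted hits).
    """
    common = a.universe & b.universe
    if not common:
        raise ValueError("screens share no tested genes")
    hits_a = a.hit_genes & common
    hits_b = b.hit_genes & common
    both = hits_a & hits_b
    return {
        "screen_a": a.screen_id,
        "screen_b": b.screen_id,
        "common_universe": len(common),
        "hits_a": len(hits_a),
        "hits_b": len(hits_b),
        "intersection": len(both),
        "unique_a": len(hits_a - both),
        "unique_b": len(hits_b - both),
        "pct_of_a": 100.0 * len(both) / len(hits_a) if hits_a else float("nan"),
        "pct_of_b": 100.0 * len(both) / len(hits_b) if hits_b else float("nan"),
    }


def _matches(primary: Phenotypes, validation: Phenotypes, rule: str) -> bool:
    if rule == "shared-class":
        return bool(primary & validation)
    if rule == "exact-set":
        return primary == validation
    if rule == "any-hit":
        return True
    raise ValueError(f"unknown match_rule {rule!r}")


def validate_hits(
    primary: Mapping[str, Phenotypes],
    validation: Mapping[str, Phenotypes],
    tested: Iterable[str] | None = None,
    match_rule: str = "shared-class",
    strata: Mapping[str, Mapping[str, str]] | None = None,
) -> list[ValidationRecord]:
    """Apply the second-dsRNA validation rule to every tested primary hit.

    ``primary`` and ``validation`` map hit genes to phenotype classes (a
    gene absent from ``validation`` was tested but scored no hit).
    ``tested`` lists the genes for which a validation dsRNA exists; default
    is every gene in ``validation``.  Validation records for genes that
    were never primary hits are excluded with a warning.  ``strata``
    optionally attaches per-gene stratum labels (e.g. prior-screen status)
    to each record.
    """
    tested_set = set(tested) if tested is not None else set(validation)
    skipped = sorted(g for g in tested_set if g not in primary)
    if skipped:
        import logging

        logging.getLogger("netscreen.validation").warning(
            "%d validation records for genes never hit in the primary screen "
            "excluded (e.g. %s)", len(skipped), skipped[:3],
        )
    records = []
    for gene in sorted(tested_set & set(primary)):
        prim = primary[gene]
        val = validation.get(gene)
        is_hit = val is not None
        validated = is_hit and _matches(prim, val, match_rule)
        records.append(
            ValidationRecord(
                gene=gene,
                primary_phenotypes=prim,
                validation_phenotypes=val or frozenset(),
                validation_hit=is_hit,
                validated=validated,
                strata={k: v.get(gene, "unknown") for k, v in (strata or {}).items()},
            )
        )
    return records


def stratified_validation_rate(
    records: Iterable[ValidationRecord],
    stratifier: str | None = None,
) -> pd.DataFrame:
    """Validation rate (percent, with counts) overall or per stratum label."""
    records = list(records)
    rows: dict[str, list[ValidationRecord]] = {}
    if stratifier is None:
        rows["all"] = records
    else:
        for rec in records:
            rows.setdefault(rec.strata.get(stratifier, "unknown"), []).append(rec)
    table = []
    for label, recs in sorted(rows.items()):
        n_tested = len(recs)
        n_val = sum(r.validated for r in recs)
        table.append(
            {
                "stratum": label,
                "tested": n_tested,
                "validated": n_val,
                "validation_rate_pct": 100.0 * n_val / n_tested if n_tested else float("nan"),
            }
        )
    return pd.DataFrame(table).set_index("stratum")


def assemble_high_confidence(
    validated: Iterable[str],
    current_hits: Iterable[str],
    prior_hits: Iterable[str],
) -> HighConfidenceSet:
    """Validated hits ∪ (current ∩ prior hits), with provenance per gene."""
    validated = set(validated)
    current = set(current_hits)
    prior = set(prior_hits)
    if not validated <= current:
        raise ValueError("validated genes must be current-screen hits")
    dual = current & prior
    provenance = {}
    for gene in validated | dual:
        if gene in validated and gene in dual:
            provenance[gene] = "both"
        elif gene in validated:
            provenance[gene] = "validated"
        else:
            provenance[gene] = "dual_screen"
    return HighConfidenceSet(provenance)


def classify_novel_regulators(
    candidates: Iterable[str],
    prior_hits: Iterable[str],
    annotated: Iterable[str],
    phenotypes: Mapping[str, Phenotypes] | None = None,
) -> pd.DataFrame:
    """Candidates absent from prior screens and from the annotation list.

    Returns one row per candidate with ``novel`` flag and, when
    ``phenotypes`` is given, its comma-joined phenotype classes, so novel
    regulators can be tallied per phenotype.
    """
    prior = set(prior_hits)
    known = set(annotated)
    rows = []
    for gene in sorted(set(candidates)):
        rows.append(
            {
                "gene": gene,
                "in_prior_screen": gene in prior,
                "annotated": gene in known,
                "novel": gene not in prior and gene not in known,
                "phenotypes": ",".join(sorted((phenotypes or {}).get(gene, ()))),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
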