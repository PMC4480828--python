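"""Severity-ranked consequence profiles and score-threshold summaries.

Consequence terms (Sequence Ontology) and functional-impact scores (GWAVA,
Mutation Assessor, CADD, GERP) arrive as annotation columns produced by
upstream tools; this module only counts and summarises them.  The shipped
severity ranking orders 34 consequence terms from most to least severe; the
"top k severe" fraction (k = 11 by default, transcript_ablation through
missense_variant) summarises how deleterious a variant category is.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .variants import VariantSet

DEFAULT_TOP_K = 11
UNKNOWN_TERM = "__unknown__"


@dataclass(frozen=True)
class SeverityRanking:
    """Ordered consequence terms, most severe first (rank 1 = most severe)."""

    ordered_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ordered_terms)) != len(self.ordered_terms):
            raise ValueError("severity ranking terms must be unique")

    def rank(self, term: str) -> int | None:
        """1-based severity rank, or None for a term outside the ranking."""
        try:
            return self.ordered_terms.index(term) + 1
        except ValueError:
            return None

    def __len__(self) -> int:
        return len(self.ordered_terms)

    @classmethod
    def from_file(cls, path: str | Path) -> "SeverityRanking":
        terms = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    terms.append(line)
        return cls(tuple(terms))

    @classmethod
    def default(cls) -> "SeverityRanking":
        """The shipped 34-term ranking (editable package data file)."""
        ref = resources.files("regvar") / "data" / "consequence_severity.txt"
        with resources.as_file(ref) as path:
            return cls.from_file(path)


@dataclass
class ConsequenceProfile:
    """Per-term fractions and top-k-severe fraction for one variant category."""

    category_label: str
    per_term_fraction: dict[str, float]
    top_k_fraction: float
    k: int
    n_annotated: int
    n_unknown_term: int


def most_severe(terms: Iterable[str], ranking: SeverityRanking) -> str | None:
    """Reduce a multi-consequence annotation to its most severe ranked term."""
    ranked = [(ranking.rank(t), t) for t in terms]
    ranked = [(r, t) for r, t in ranked if r is not None]
    return min(ranked)[1] if ranked else None


def consequence_profile(
    vs: VariantSet,
    ranking: SeverityRanking | None = None,
    k: int = DEFAULT_TOP_K,
) -> ConsequenceProfile:
    """Histogram a category's consequence terms by severity rank.

    Fractions are over variants carrying a term present in the ranking;
    variants with an unranked term are counted in an ``__unknown__`` bucket
    and excluded from the fractions.  Raises if no variant is annotated.
    """
    ranking = ranking or SeverityRanking.default()
    counts: dict[str, int] = {}
    unknown = 0
    for v in vs:
        if v.consequence is None:
            continue
        if ranking.rank(v.consequence) is None:
            unknown += 1
        else:
            counts[v.consequence] = counts.get(v.consequence, 0) + 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError(
            f"variant set {vs.label!r} has no variants with a ranked consequence"
        )
    per_term = {t: c / n for t, c in counts.items()}
    top_k = sum(c for t, c in counts.items() if ranking.rank(t) <= k) / n
    return ConsequenceProfile(
        category_label=vs.label,
        per_term_fraction=per_term,
        top_k_fraction=top_k,
        k=k,
        n_annotated=n,
        n_unknown_term=unknown,
    )


def score_threshold_summary(
    vs: VariantSet,
    score_name: str,
    threshold: float,
    direction: str = "ge",
) -> tuple[float, int, int]:
    """Fraction of scored variants meeting a threshold criterion.

    ``direction='ge'`` counts scores >= threshold (e.g. Mutation Assessor
    medium/high functionality at 1.9); ``'gt'`` counts strictly greater
    (e.g. positive GERP).  Returns ``(fraction, n_scored, n_unscored)``;
    unscored variants are excluded from the denominator.
    """
    if direction not in ("ge", "gt"):
        raise ValueError("direction must be 'ge' or 'gt'")
    scored = [v.scores[score_name] for v in vs if score_name in v.scores]
    n_unscored = len(vs) - len(scored)
    if not scored:
        raise ValueError(f"no variant in {vs.label!r} carries score {score_name!r}")
    if direction == "ge":
        hits = sum(1 for s in scored if s >= threshold)
    else:
        hits = sum(1 for s in scored if s > threshold)
    return (hits / len(scored), len(scored), n_unscored)
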