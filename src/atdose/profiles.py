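"""GO over-representation and categorized cellular-function profiles.

Significant transcripts are tested per GO term with a one-sided
hypergeometric over-representation test against the filtered probe
universe; enriched terms (p < 0.05 by default) are grouped into
(category, subcategory) pairs of higher-level cellular function, and
each subcategory's response intensity is the pooled percentage of
*scored* (significant, annotated) over *filtered* (universe, annotated)
transcripts across its enriched terms.  Intensities are discretized into
five ordered bins for heatmap display:

    very_low  [0, 3)      low  [3, 10)     medium  [10, 30)
    high      [30, 50)    very_high  [50, 100]

plus ``none`` for subcategories without any enriched term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

BIN_LABELS = ["none", "very_low", "low", "medium", "high", "very_high"]
BIN_ORDINAL = {name: i for i, name in enumerate(BIN_LABELS)}


class AnnotationError(ValueError):
    """Raised for unusable annotation or category inputs."""


@dataclass
class AnnotationMap:
    """Transcript -> GO terms plus term -> (name, category, subcategory).

    ``transcript_terms`` maps a transcript/probe id to its set of term
    ids; ``term_category`` maps a term id to a ``(category,
    subcategory)`` pair (terms may be uncategorized); ``term_name`` is
    optional display metadata.
    """

    transcript_terms: dict[str, set[str]]
    term_category: dict[str, tuple[str, str]] = field(default_factory=dict)
    term_name: dict[str, str] = field(default_factory=dict)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.transcript_terms.values():
            out |= ts
        return out

    def annotated(self, term: str, pool: Iterable[str]) -> set[str]:
        return {g for g in pool if term in self.transcript_terms.get(g, ())}

    def subcategories(self) -> list[tuple[str, str]]:
        return sorted(set(self.term_category.values()))


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation result."""

    term: str
    p_value: float
    scored: int    # significant transcripts annotated to the term
    filtered: int  # universe transcripts annotated to the term


@dataclass(frozen=True)
class CategoryProfile:
    """Pooled intensity of one cellular-function subcategory."""

    category: str
    subcategory: str
    intensity: float  # percent, 100 * sum(scored) / sum(filtered)
    bin: str
    n_terms: int = 0


def hypergeom_tail(overlap: int, universe: int, annotated: int, drawn: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, annotated, drawn)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, annotated, drawn))


def enrich(
    significant: set[str],
    universe: set[str],
    annotation: AnnotationMap,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation per GO term.

    ``universe`` is the filtered probe set from the differential
    expression stage and must contain ``significant``.  Terms with
    p < alpha are returned, sorted by p.  No multiplicity correction is
    applied to term p-values (a plain cutoff on the enrichment p).
    """
    if not universe:
        raise AnnotationError("empty universe")
    extra = significant - universe
    if extra:
        raise AnnotationError(
            f"significant set not contained in universe ({len(extra)} ids outside)"
        )
    n_universe, n_sig = len(universe), len(significant)
    results = []
    for term in sorted(annotation.terms()):
        filtered = annotation.annotated(term, universe)
        if not filtered:
            continue
        scored = significant & filtered
        p = hypergeom_tail(len(scored), n_universe, len(filtered), n_sig)
        if p < alpha:
            results.append(
                EnrichmentResult(term=term, p_value=p,
                                 scored=len(scored), filtered=len(filtered))
            )
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def bin_intensity(intensity: float) -> str:
    """Map a percentage to its intensity bin (total, monotone step map)."""
    if not 0.0 <= intensity <= 100.0:
        raise ValueError(f"intensity {intensity} outside [0, 100]")
    if intensity < 3.0:
        return "very_low"
    if intensity < 10.0:
        return "low"
    if intensity < 30.0:
        return "medium"
    if intensity < 50.0:
        return "high"
    return "very_high"


def profile(
    enrichments: list[EnrichmentResult],
    annotation: AnnotationMap,
) -> list[CategoryProfile]:
    """Pool enriched terms into per-subcategory intensity profiles.

    Intensity of a subcategory = 100 * (sum of scored) / (sum of
    filtered) over its enriched terms (count-pooled, not term-averaged).
    Subcategories of the category scheme without any enriched term get
    bin ``none`` and intensity 0.  Enriched terms missing from the
    category scheme are logged and skipped.
    """
    pooled: dict[tuple[str, str], list[EnrichmentResult]] = {
        sub: [] for sub in annotation.subcategories()
    }
    for res in enrichments:
        cat = annotation.term_category.get(res.term)
        if cat is None:
            log.warning("enriched term %s has no category assignment; skipped", res.term)
            continue
        pooled[cat].append(res)
    out = []
    for (category, subcategory), terms in sorted(pooled.items()):
        if not terms:
            out.append(CategoryProfile(category, subcategory, 0.0, "none", 0))
            continue
        scored = sum(t.scored for t in terms)
        filtered = sum(t.filtered for t in terms)
        assert filtered > 0, "enriched terms cannot have zero filtered counts"
        intensity = 100.0 * scored / filtered
        out.append(
            CategoryProfile(category, subcategory, intensity,
                            bin_intensity(intensity), len(terms))
        )
    return out


def profile_heatmap_table(
    profiles_by_condition: Mapping[object, list[CategoryProfile]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long- and matrix-format views of per-condition profiles.

    Returns ``(long, matrix)``: the long table has one row per
    (condition, subcategory) with intensity, bin label and ordinal
    (none=0 .. very_high=5); the matrix is subcategory x condition of
    ordinals with bins recoverable via :data:`BIN_LABELS`.
    """
    if not profiles_by_condition:
        raise AnnotationError("need at least one condition")
    rows = []
    for cond, profs in profiles_by_condition.items():
        for p in profs:
            rows.append(
                {
                    "condition": str(cond),
                    "category": p.category,
                    "subcategory": p.subcategory,
                    "intensity_pct": p.intensity,
                    "bin": p.bin,
                    "ordinal": BIN_ORDINAL[p.bin],
                }
            )
    long = pd.DataFrame(rows)
    matrix = long.pivot_table(
        index=["category", "subcategory"], columns="condition",
        values="ordinal", fill_value=0, aggfunc="first",
    ).astype(int)
    return long, matrix
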