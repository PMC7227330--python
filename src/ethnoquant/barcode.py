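"""Integrative multi-marker BLAST identification.

Each specimen is sequenced at up to four universal markers (ITS, matK,
psbA-trnH, trnL-F) and its hit table per marker drives two calls:

*simple ladder* — all hits within a fixed bit-score window below the best hit
(5 points by default, boundary inclusive) are pooled; if they name one
species the call is species-level, one genus -> genus-level, one family ->
family-level, several families -> ambiguous.

*optimized score* — among the five best-scoring distinct-taxon hits, the hit
maximizing ``max_score * (query_cover / percent_identity)`` (both percentages
on the 0-100 scale, so the ratio is dimensionless) is the optimized winner.
The rationale: between near-equal bit scores, prefer the hit whose alignment
covers more of the query per unit of identity inflation.

The consensus step pools simple and optimized evidence across markers with
the pre-sequencing evidence (local-name dictionary lookup, morphological
determination) and an optional regional occurrence allow-list, resolving to
the most specific rank supported by at least two independent sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import BlastHit, normalize_taxon, taxon_genus

__all__ = [
    "RANKS",
    "MarkerCall",
    "AprioriEvidence",
    "ConsensusCall",
    "score_window",
    "simple_call",
    "optimized_score",
    "optimized_call",
    "marker_summary",
    "integrate_identification",
]

#: rank ladder from most to least specific
RANKS = ("species", "genus", "family", "ambiguous")


@dataclass(frozen=True)
class MarkerCall:
    """One marker's evidence for one specimen."""

    marker: str
    window: tuple[BlastHit, ...]
    rank: str  # species | genus | family | ambiguous | indeterminate
    taxa: frozenset[str]
    best_by_score: BlastHit | None = None
    best_by_identity: BlastHit | None = None
    optimized_best: BlastHit | None = None
    optimized_value: float | None = None
    note: str = ""


@dataclass(frozen=True)
class AprioriEvidence:
    """Pre-sequencing identification evidence for a specimen.

    ``morphology_rank`` qualifies the morphological determination: "species"
    for a firm binomial, "cf." for a tentative one, "genus"/"family" for
    coarser determinations, "none" when the specimen was morphologically
    indeterminable.
    """

    local_name: str = ""
    dictionary_putative: tuple[str, ...] = ()
    morphology_determination: str = ""
    morphology_rank: str = "none"

    def __post_init__(self) -> None:
        if self.morphology_rank not in ("species", "cf.", "genus", "family", "none"):
            raise ValueError(f"bad morphology_rank {self.morphology_rank!r}")


@dataclass(frozen=True)
class ConsensusCall:
    final_taxon: str
    final_rank: str  # species | genus | family | indeterminate
    provenance: tuple[str, ...] = ()
    notes: str = ""


# ---------------------------------------------------------------------------
# Per-marker operations
# ---------------------------------------------------------------------------


def score_window(hits: Sequence[BlastHit], delta: float = 5.0) -> list[BlastHit]:
    """Hits with max_score >= best - delta, boundary inclusive, best first.

    An empty hit list yields an empty window (the unamplified-marker signal),
    not an error.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if not hits:
        return []
    top = max(h.max_score for h in hits)
    kept = [h for h in hits if h.max_score >= top - delta]
    return sorted(kept, key=lambda h: -h.max_score)


def _window_taxonomy(window: Sequence[BlastHit], synonyms=None):
    species = {normalize_taxon(h.subject_species, synonyms) for h in window}
    genera = {h.subject_genus or taxon_genus(h.subject_species) for h in window}
    families = {h.subject_family for h in window if h.subject_family}
    return species, genera, families


def simple_call(
    window: Sequence[BlastHit],
    synonyms: Mapping[str, str] | None = None,
) -> tuple[str, frozenset[str]]:
    """Rank assignment from the taxon composition of a score window.

    One species -> ("species", {binomial}); several species of one genus ->
    ("genus", {genus}); several genera of one family -> ("family", {family});
    several families -> ("ambiguous", family set).  Synonym normalization is
    applied before the species-set test.  An empty window is indeterminate.
    """
    if not window:
        return "indeterminate", frozenset()
    species, genera, families = _window_taxonomy(window, synonyms)
    if len(species) == 1:
        return "species", frozenset(species)
    if len(genera) == 1:
        return "genus", frozenset(genera)
    if families and len(families) == 1:
        return "family", frozenset(families)
    return "ambiguous", frozenset(families or genera)


def optimized_score(hit: BlastHit) -> float:
    """max_score x (query_cover / percent_identity), both on the 0-100 scale."""
    return hit.max_score * (hit.query_cover / hit.percent_identity)


def _dedupe_best_per_taxon(hits: Sequence[BlastHit], synonyms=None) -> list[BlastHit]:
    best: dict[str, BlastHit] = {}
    for h in hits:
        key = normalize_taxon(h.subject_species, synonyms)
        cur = best.get(key)
        if cur is None or (h.max_score, h.percent_identity) > (cur.max_score, cur.percent_identity):
            best[key] = h
    return sorted(best.values(), key=lambda h: -h.max_score)


def optimized_call(
    hits: Sequence[BlastHit],
    mode: str = "top5",
    delta: float = 5.0,
    synonyms: Mapping[str, str] | None = None,
) -> BlastHit:
    """The hit maximizing the optimized score among the leading candidates.

    ``mode="top5"`` considers the five best-scoring distinct-taxon hits
    (duplicate subject taxa collapsed to their best row); ``mode="window"``
    considers all distinct taxa within the score window instead.  Ties go to
    the higher max score, then the higher identity, then input order.
    """
    if not hits:
        raise ValueError("optimized_call needs at least one hit")
    if mode == "top5":
        pool = _dedupe_best_per_taxon(hits, synonyms)[:5]
    elif mode == "window":
        pool = _dedupe_best_per_taxon(score_window(hits, delta), synonyms)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return max(pool, key=lambda h: (optimized_score(h), h.max_score, h.percent_identity))


def marker_summary(
    hits: Sequence[BlastHit],
    marker: str | None = None,
    delta: float = 5.0,
    synonyms: Mapping[str, str] | None = None,
    optimized_mode: str = "top5",
) -> MarkerCall:
    """Full per-marker evidence: window, ladder rank, best hits, optimized winner."""
    marker = marker or (hits[0].marker if hits else "")
    if not hits:
        return MarkerCall(
            marker=marker, window=(), rank="indeterminate", taxa=frozenset(),
            note="NONE: unsuccessfully amplified and/or sequenced",
        )
    window = score_window(hits, delta)
    rank, taxa = simple_call(window, synonyms)
    opt = optimized_call(hits, mode=optimized_mode, delta=delta, synonyms=synonyms)
    return MarkerCall(
        marker=marker,
        window=tuple(window),
        rank=rank,
        taxa=taxa,
        best_by_score=max(window, key=lambda h: h.max_score),
        best_by_identity=max(window, key=lambda h: h.percent_identity),
        optimized_best=opt,
        optimized_value=optimized_score(opt),
    )


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def _candidate_pool(marker_calls, apriori, synonyms):
    """(taxon, rank, source) evidence tuples from markers and a-priori data."""
    evidence: list[tuple[str, str, str]] = []
    for mc in marker_calls:
        if mc.rank == "indeterminate":
            continue
        for taxon in sorted(mc.taxa):
            evidence.append((normalize_taxon(taxon, synonyms) if mc.rank == "species" else taxon,
                             mc.rank if mc.rank != "ambiguous" else "family",
                             f"marker:{mc.marker}"))
        if mc.optimized_best is not None:
            evidence.append((normalize_taxon(mc.optimized_best.subject_species, synonyms),
                             "species", f"marker:{mc.marker}"))
    if apriori:
        for name in apriori.dictionary_putative:
            evidence.append((normalize_taxon(name, synonyms), "species", "dictionary"))
        if apriori.morphology_determination and apriori.morphology_rank != "none":
            rank = "species" if apriori.morphology_rank in ("species", "cf.") else apriori.morphology_rank
            taxon = (normalize_taxon(apriori.morphology_determination, synonyms)
                     if rank == "species" else apriori.morphology_determination)
            evidence.append((taxon, rank, "morphology"))
    return evidence


def integrate_identification(
    marker_calls: Sequence[MarkerCall],
    apriori: AprioriEvidence | None = None,
    allow_list: Iterable[str] | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> ConsensusCall:
    """Deterministic consensus over marker calls, a-priori evidence, occurrence.

    Resolution order: (1) pool candidate taxa from every marker's simple call
    and optimized winner plus the dictionary and morphology names; (2) drop
    species-level candidates absent from the occurrence allow-list when one
    is supplied; (3) drop candidates conflicting with a genus- or
    family-level a-priori determination; (4) accept the most specific rank
    supported by at least two independent sources (two markers, or one marker
    plus morphology/dictionary); failing that, fall back to the lowest common
    rank of the surviving candidates.  Identical inputs always produce the
    identical call and provenance.
    """
    if not marker_calls and (apriori is None or (
            not apriori.dictionary_putative and apriori.morphology_rank == "none")):
        raise ValueError("no evidence: need at least one marker call or a-priori evidence")
    prov: list[str] = []
    evidence = _candidate_pool(marker_calls, apriori, synonyms)
    prov.append(f"pooled {len(evidence)} evidence items from "
                f"{len(marker_calls)} marker(s) and a-priori data")

    if allow_list is not None:
        allowed = {normalize_taxon(a, synonyms).lower() for a in allow_list}
        dropped = sorted({t for t, r, _ in evidence
                          if r == "species" and t.lower() not in allowed})
        if dropped:
            prov.append(
                "allow-list demoted unrecorded species candidates to genus: "
                + ", ".join(dropped)
            )
        # a species absent from the regional occurrence list is not evidence
        # for that species, but its generic affinity still stands
        evidence = [
            (t, r, s) if r != "species" or t.lower() in allowed
            else (taxon_genus(t), "genus", s)
            for t, r, s in evidence
        ]

    # a-priori genus/family constraint
    if apriori and apriori.morphology_rank in ("genus", "family"):
        constraint = apriori.morphology_determination
        if apriori.morphology_rank == "genus":
            keep = lambda t, r: (taxon_genus(t) == taxon_genus(constraint)) if r in ("species", "genus") else True
        else:
            keep = lambda t, r: (t == constraint) if r == "family" else True
        dropped = sorted({t for t, r, s in evidence if s != "morphology" and not keep(t, r)})
        if dropped:
            prov.append(
                f"a-priori {apriori.morphology_rank} {constraint!r} removed: {', '.join(dropped)}")
        evidence = [(t, r, s) for t, r, s in evidence if s == "morphology" or keep(t, r)]

    if not evidence:
        return ConsensusCall("", "indeterminate", tuple(prov), notes="no surviving candidates")

    def support(rank: str) -> dict[str, set[str]]:
        """taxon -> set of independent sources at the given aggregation rank."""
        agg: dict[str, set[str]] = {}
        for t, r, s in evidence:
            if rank == "species" and r == "species":
                agg.setdefault(t, set()).add(s)
            elif rank == "genus" and r in ("species", "genus"):
                agg.setdefault(taxon_genus(t), set()).add(s)
            elif rank == "family" and r == "family":
                agg.setdefault(t, set()).add(s)
        return agg

    for rank in ("species", "genus", "family"):
        sup = support(rank)
        backed = {t: srcs for t, srcs in sup.items() if len(srcs) >= 2}
        if backed:
            # most supported first, then alphabetical for determinism
            winner = sorted(backed.items(), key=lambda kv: (-len(kv[1]), kv[0]))[0]
            prov.append(
                f"{rank}-level consensus on {winner[0]!r} from sources: "
                + ", ".join(sorted(winner[1]))
            )
            return ConsensusCall(winner[0], rank, tuple(prov))

    # no multiply-supported taxon: demote to the lowest common rank
    species = {t for t, r, _ in evidence if r == "species"}
    genera = {taxon_genus(t) for t, r, _ in evidence if r in ("species", "genus")}
    families = {t for t, r, _ in evidence if r == "family"}
    if len(species) == 1:
        taxon, rank = next(iter(species)), "species"
    elif len(genera) == 1 and genera != {""}:
        taxon, rank = next(iter(genera)), "genus"
    elif len(families) == 1 and not genera:
        taxon, rank = next(iter(families)), "family"
    elif len(families) == 1 and len(genera) > 1:
        taxon, rank = next(iter(families)), "family"
    else:
        taxon, rank = "", "indeterminate"
    prov.append(f"single-source fallback: lowest common rank {rank}")
    return ConsensusCall(taxon, rank, tuple(prov),
                         notes="" if taxon else "candidates span multiple families")
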