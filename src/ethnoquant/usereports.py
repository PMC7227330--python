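"""Collapse raw citations into use-reports and build the count tables.

The atomic unit of all downstream indices is the *use-report*: one distinct
(informant, species, category) triple.  An informant naming the same plant
for three digestive complaints contributes one digestive use-report; naming
it for a digestive and a respiratory complaint contributes two.  Multiplicity
("at least two interviewees cited the same plant") is emergent from counting
distinct triples, not a separate filter.

This unit is what makes the published numbers coherent: species use-report
totals exceed the informant total (e.g. UR = 1134 with N = 335), which is
only possible if each informant can contribute one unit per category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from .io import CitationRecord, StudyConfig

__all__ = [
    "UseReport",
    "SpeciesUseMatrix",
    "collapse_citations",
    "species_use_matrix",
    "category_summary",
    "informant_scores",
]


class UseReport(NamedTuple):
    informant_id: str
    species_id: str
    category: int


def collapse_citations(citations: Iterable[CitationRecord]) -> list[UseReport]:
    """Deduplicate citations to one use-report per (informant, species, category).

    Output is sorted, so equal citation multisets give identical lists
    regardless of interview order.
    """
    triples = {UseReport(c.informant_id, c.species_id, c.category) for c in citations}
    return sorted(triples)


@dataclass(frozen=True)
class SpeciesUseMatrix:
    """Per-species use-report counts by category plus derived totals.

    ``counts``          species x category DataFrame of use-report counts
    ``ur_total``        row sums (the Ui of the use-value formula)
    ``uc``              number of categories with a nonzero count
    ``informant_count`` distinct informants citing the species in any
                        category (the denominator of the cultural
                        importance value)
    """

    counts: pd.DataFrame
    ur_total: pd.Series
    uc: pd.Series
    informant_count: pd.Series

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.index)

    def category_counts(self, species_id: str) -> dict[int, int]:
        row = self.counts.loc[species_id]
        return {int(c): int(n) for c, n in row.items() if n > 0}


def species_use_matrix(
    use_reports: Iterable[UseReport],
    config: StudyConfig | None = None,
) -> SpeciesUseMatrix:
    """Tabulate deduplicated use-reports into the species x category matrix.

    Species absent from ``use_reports`` are absent from the matrix; categories
    are the configured ones when a config is given, otherwise those observed.
    """
    reports = list(use_reports)
    cat_cols = sorted(c.code for c in config.categories) if config else None
    if not reports:
        cols = cat_cols or []
        empty = pd.DataFrame(0, index=pd.Index([], name="species_id"), columns=cols, dtype=int)
        s = pd.Series(dtype=int)
        return SpeciesUseMatrix(empty, s, s.copy(), s.copy())
    df = pd.DataFrame(reports, columns=["informant_id", "species_id", "category"])
    counts = (
        df.groupby(["species_id", "category"]).size().unstack(fill_value=0).sort_index()
    )
    if cat_cols:
        counts = counts.reindex(columns=cat_cols, fill_value=0)
    counts.index.name = "species_id"
    ur_total = counts.sum(axis=1).astype(int)
    uc = (counts > 0).sum(axis=1).astype(int)
    informants = df.groupby("species_id")["informant_id"].nunique().reindex(counts.index)
    return SpeciesUseMatrix(counts, ur_total, uc, informants.astype(int))


def category_summary(
    use_reports: Iterable[UseReport],
    config: StudyConfig,
) -> pd.DataFrame:
    """Per-category table of Nur, Nt and their percentage shares.

    Nur is the number of use-reports in the category; Nt the number of
    distinct species used in it.  ``pct_ur`` shares sum to 100 over
    categories.  ``pct_species`` is relative to the *sum of per-category
    species counts* (a species cited in k categories contributes k to the
    denominator), which is how the share column of the source tables is
    normalized.  Categories with no reports are reported as zero with a
    warning rather than dropped.
    """
    reports = list(use_reports)
    df = pd.DataFrame(reports, columns=["informant_id", "species_id", "category"])
    codes = sorted(c.code for c in config.categories)
    nur = df.groupby("category").size().reindex(codes, fill_value=0)
    nt = df.groupby("category")["species_id"].nunique().reindex(codes, fill_value=0)
    total_ur = int(nur.sum())
    total_nt = int(nt.sum())
    empty = [c for c in codes if nur[c] == 0]
    if empty:
        warnings.warn(
            f"categories with no use-reports reported as 0: {empty}",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "category": codes,
            "abbrev": [config.category(c).abbrev for c in codes],
            "n_use_reports": nur.values,
            "n_species": nt.values,
            "pct_ur": [100.0 * n / total_ur if total_ur else 0.0 for n in nur],
            "pct_species": [100.0 * n / total_nt if total_nt else 0.0 for n in nt],
        }
    )
    return out


def informant_scores(use_reports: Iterable[UseReport]) -> dict[str, int]:
    """Knowledge score per informant: use-reports credited to them.

    Scores partition the total — their sum equals the number of use-reports.
    """
    scores: dict[str, int] = {}
    for r in use_reports:
        scores[r.informant_id] = scores.get(r.informant_id, 0) + 1
    return scores
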