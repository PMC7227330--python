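"""The six quantitative ethnopharmacology indices and their tables.

Scalar definitions (UR = use-report count, N = informant total):

* use value              UV  = UR / N
* cultural importance    CIV = (sum over categories of UR_c) / N_p, with N_p
                         the number of informants reporting the plant
* use diversity          UD  = Shannon entropy (nats) of a species'
                         use-reports across categories
* informant consensus    ICF = (Nur - Nt) / (Nur - 1) per category
* fidelity level         FL  = 100 * Ip / Iu per (species, ailment)
* species-list overlap   J   = C / (A + B)        ("paper" variant)
                         J   = C / (A + B - C)    ("standard" Jaccard)

Report rounding is half-up: UV/CIV/UD/ICF to two decimals, FL to a whole
percent.  The CIV flag ``denominator="category_informants"`` implements the
alternative reading of the CIV formula (each category term divided by the
informants citing the plant *in that category*); under the
(informant, species, category) use-report unit each category count is itself
a count of distinct informants, so that variant degenerates to the number of
use categories — it is provided for completeness, not as a headline value.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CitationRecord, StudyConfig, round_half_up
from .usereports import SpeciesUseMatrix, UseReport

__all__ = [
    "use_value",
    "cultural_importance",
    "use_diversity",
    "icf",
    "fidelity_level",
    "jaccard",
    "species_indices",
    "fidelity_table",
    "rank_table",
    "correlation_matrix",
    "category_use_value",
]

BASIC_VALUES = ("UR", "UC", "UV", "CIV", "UD")


def use_value(ur: int, n: int) -> float:
    """UV = UR / N.  Exact quotient; round for report output."""
    if n < 1:
        raise ValueError("N (total informants) must be >= 1")
    if ur < 0:
        raise ValueError("UR must be >= 0")
    return ur / n


def cultural_importance(
    ur_by_category: Mapping[int, int],
    informant_count: int,
) -> float:
    """CIV = sum_c UR_c / N_p with N_p = informants reporting the plant."""
    total = sum(ur_by_category.values())
    if informant_count < 1:
        if total:
            raise ValueError("informant_count must be >= 1 when the plant has use-reports")
        return 0.0
    return total / informant_count


def use_diversity(ur_by_category: Mapping[int, int], base: float = math.e) -> float:
    """Shannon index of uses: H = -sum_c p_c log(p_c), zero counts excluded.

    Natural log by default, so H is in nats and bounded by log(UC).
    """
    counts = [c for c in ur_by_category.values() if c > 0]
    if not counts:
        raise ValueError("use_diversity needs at least one positive count")
    total = sum(counts)
    h = -sum((c / total) * math.log(c / total) for c in counts)
    if base != math.e:
        h /= math.log(base)
    # -0.0 guard for single-category species
    return abs(h) if h == 0 else h


def icf(nur: int, nt: int) -> float:
    """Informant consensus factor (Nur - Nt) / (Nur - 1); needs Nur >= 2."""
    if nur < 2:
        raise ValueError("ICF undefined for Nur < 2")
    if not 1 <= nt <= nur:
        raise ValueError("Nt must satisfy 1 <= Nt <= Nur")
    return (nur - nt) / (nur - 1)


def fidelity_level(ip: int, iu: int) -> float:
    """FL(%) = 100 * Ip / Iu for 1 <= Ip <= Iu."""
    if not 1 <= ip <= iu:
        raise ValueError("need 1 <= Ip <= Iu")
    return 100.0 * ip / iu


def jaccard(set_a: Iterable, set_b: Iterable, variant: str = "paper") -> float:
    """Species-list similarity of two localities.

    ``variant="paper"`` uses C/(A+B) — the form the source study prints, which
    equals 0.5 on identical lists; ``"standard"`` is the classical Jaccard
    C/(A+B-C).  Symmetric in its arguments.
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("both species sets must be nonempty")
    c = len(a & b)
    if variant == "paper":
        return c / (len(a) + len(b))
    if variant == "standard":
        return c / (len(a) + len(b) - c)
    raise ValueError(f"unknown jaccard variant {variant!r}")


# ---------------------------------------------------------------------------
# Table-level operations
# ---------------------------------------------------------------------------


def species_indices(
    matrix: SpeciesUseMatrix,
    config: StudyConfig,
    civ_denominator: str = "plant_informants",
) -> pd.DataFrame:
    """Per-species index table: UR, UC, UV, CIV, UD, informant_count.

    ``civ_denominator`` is ``"plant_informants"`` (the printed formula) or
    ``"category_informants"`` (the alternative reading; see module docstring).
    """
    if civ_denominator not in ("plant_informants", "category_informants"):
        raise ValueError(f"unknown civ_denominator {civ_denominator!r}")
    rows = []
    n = config.n_informants_total
    for sp in matrix.species_ids:
        by_cat = matrix.category_counts(sp)
        ur = int(matrix.ur_total[sp])
        ninf = int(matrix.informant_count[sp])
        if civ_denominator == "plant_informants":
            civ = cultural_importance(by_cat, ninf)
        else:
            civ = sum(c / c for c in by_cat.values() if c > 0)  # degenerates to UC
        rows.append(
            {
                "species_id": sp,
                "UR": ur,
                "UC": int(matrix.uc[sp]),
                "UV": use_value(ur, n),
                "CIV": civ,
                "UD": use_diversity(by_cat),
                "informant_count": ninf,
            }
        )
    return pd.DataFrame(rows)


def fidelity_table(citations: Iterable[CitationRecord], top_k: int | None = None) -> pd.DataFrame:
    """FL rows per (species, ailment): Ip, Iu and the fidelity level.

    Ip counts informants citing the species for that ailment; Iu counts
    informants citing the species for anything.  With ``top_k`` the table is
    reduced to each species' best-supported ailment (highest Ip, ties to the
    alphabetically first ailment) for the ``top_k`` most-cited species.
    """
    df = pd.DataFrame(
        [(c.species_id, c.ailment, c.informant_id) for c in citations],
        columns=["species_id", "ailment", "informant_id"],
    )
    if df.empty:
        return pd.DataFrame(columns=["species_id", "ailment", "Ip", "Iu", "FL"])
    iu = df.groupby("species_id")["informant_id"].nunique()
    ip = df.groupby(["species_id", "ailment"])["informant_id"].nunique()
    out = ip.reset_index().rename(columns={"informant_id": "Ip"})
    out["Iu"] = out["species_id"].map(iu)
    out["FL"] = 100.0 * out["Ip"] / out["Iu"]
    out = out.sort_values(["species_id", "ailment"], ignore_index=True)
    if top_k is not None:
        best = (
            out.sort_values(["species_id", "Ip", "ailment"], ascending=[True, False, True])
            .groupby("species_id", as_index=False)
            .head(1)
        )
        out = best.sort_values(["Iu", "species_id"], ascending=[False, True]).head(top_k)
        out = out.reset_index(drop=True)
    return out


def rank_table(rows: pd.DataFrame, by: str, k: int = 20, name_col: str | None = None) -> pd.DataFrame:
    """Top-k rows by the chosen index, ties broken by species name ascending.

    Input order never matters: a permuted table yields the same ranking.
    """
    if by not in rows.columns:
        raise KeyError(f"no column {by!r} to rank by")
    if k < 0:
        raise ValueError("k must be >= 0")
    name_col = name_col or ("scientific_name" if "scientific_name" in rows.columns else "species_id")
    out = rows.sort_values([by, name_col], ascending=[False, True], kind="mergesort")
    return out.head(k).reset_index(drop=True)


def correlation_matrix(rows: pd.DataFrame, columns: Sequence[str] = BASIC_VALUES) -> pd.DataFrame:
    """Spearman rank correlations among the basic values (midranks for ties).

    UV is a strictly increasing transform of UR, so corr(UR, UV) is exactly 1
    on any table.  A zero-variance column has no rank order; its cells are
    returned as NaN with a warning.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 rows for a rank correlation")
    data = rows.loc[:, list(columns)].astype(float)
    degenerate = [c for c in columns if data[c].nunique() <= 1]
    if degenerate:
        warnings.warn(f"zero-variance columns yield NaN correlations: {degenerate}", stacklevel=2)
    k = len(columns)
    rho = np.full((k, k), np.nan)
    for i, a in enumerate(columns):
        for j, b in enumerate(columns):
            if a in degenerate or b in degenerate:
                continue  # no rank order exists; leave the cell as NaN
            if i == j:
                rho[i, j] = 1.0
            elif j > i:
                rho[i, j] = rho[j, i] = stats.spearmanr(data[a], data[b]).statistic
    return pd.DataFrame(rho, index=list(columns), columns=list(columns))


def category_use_value(nur_by_category: Mapping[int, int], n: int) -> dict[int, float]:
    """Experimental per-category UV: sum of category use-reports over N.

    The per-category "UV" column of the source study's category table is not
    derivable from its printed Nur/Nt/N by any stated formula; this helper
    computes the natural reading (Nur_c / N) and should not be expected to
    reproduce those printed cells.
    """
    warnings.warn(
        "category_use_value is experimental: the printed per-category UV "
        "column is not reproducible from any stated formula",
        stacklevel=2,
    )
    return {c: nur / n for c, nur in nur_by_category.items()}


def report_rounded(df: pd.DataFrame, spec: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Half-up-rounded copy of an index table at printed precision."""
    spec = dict(spec or {"UV": 2, "CIV": 2, "UD": 2, "FL": 0, "pct_ur": 2, "pct_species": 2, "icf": 2})
    out = df.copy()
    for col, nd in spec.items():
        if col in out.columns:
            out[col] = out[col].map(lambda v: round_half_up(v, nd))
            if nd == 0:
                out[col] = out[col].astype(int)
    return out
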