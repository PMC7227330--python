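"""Packaged reference tables from the Agusan Manobo medicinal-plant survey.

These are transcriptions of the published summary tables of the reference
survey (335 Manobo key informants, 122 medicinal plant species, 16 use
categories, Agusan del Sur, Mindanao): the per-category use-report table,
the full per-species index table, the top-20 fidelity-level table, the
top-20 rankings by UV/CIV/UD, the published Spearman matrix, the informant
demographics, the 24 molecularly confirmed species, and the PCR primer
metadata of the four barcode markers.

The printed tables carry a handful of internal inconsistencies, preserved
here exactly as printed (see ``PRINTED_INCONSISTENCIES``): four species
rows whose printed UV disagrees with UR/335 under half-up rounding (three
truncation artifacts, one typo), one category whose printed ICF is one unit
off, and one percentage cell truncated rather than rounded.  Tests pin
these discrepancies rather than silently correcting them.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

from .io import StudyConfig

__all__ = [
    "study_config",
    "load_category_table",
    "load_species_table",
    "load_fidelity_table",
    "load_rank_table",
    "load_spearman_table",
    "load_demographics",
    "load_confirmed_species",
    "load_primers",
    "PRINTED_INCONSISTENCIES",
]

#: printed-table cells that disagree with recomputation from their own inputs
PRINTED_INCONSISTENCIES = {
    # row_id -> (printed UV, half-up UV from UR/335); three truncated, one typo
    "uv_rows": {"15": (0.78, 0.79), "48": (2.41, 2.42), "120": (0.24, 0.25), "118": (0.35, 0.49)},
    # DOS prints ICF 0.99; (2563-40)/2562 = 0.9848 -> 0.98
    "icf_categories": {"DOS": (0.99, 0.98)},
    # DRS prints 9.44; 3896/41247 = 9.4455 -> 9.45
    "pct_ur_categories": {"DRS": (9.44, 9.45)},
}


def _read(name: str) -> pd.DataFrame:
    text = resources.files("ethnoquant.data").joinpath(name).read_text(encoding="utf-8")
    return pd.read_csv(StringIO(text), sep="\t", dtype={"row_id": str})


def study_config() -> StudyConfig:
    """The survey frame: N = 335 informants, the 16 categories, 5-point window."""
    return StudyConfig()


def load_category_table() -> pd.DataFrame:
    """Per-category table: Nur, Nt, printed shares, printed per-category UV, ICF."""
    return _read("category_table.tsv")


def load_species_table() -> pd.DataFrame:
    """The 125-row per-species index table (122 distinct species; three
    species appear twice under paired local-name variants)."""
    return _read("species_index_table.tsv")


def load_fidelity_table() -> pd.DataFrame:
    """Top-20 fidelity-level rows: species, ailment, Ip, Iu, printed FL."""
    return _read("fidelity_table.tsv")


def load_rank_table(by: str) -> pd.DataFrame:
    """Published top-20 ranking by 'uv', 'civ' or 'ud'."""
    if by not in ("uv", "civ", "ud"):
        raise ValueError("by must be 'uv', 'civ' or 'ud'")
    return _read(f"rank_{by}.tsv")


def load_spearman_table() -> pd.DataFrame:
    """Published Spearman correlations among UR, UC, UV, CIV, UD (n = 125)."""
    return _read("spearman_table.tsv")


def load_demographics() -> pd.DataFrame:
    """Informant counts per demographic stratum (seven variables, N = 335)."""
    return _read("informant_demographics.tsv")


def load_confirmed_species() -> pd.DataFrame:
    """The 24 molecularly confirmed specimens with endemicity/conservation flags."""
    return _read("confirmed_species.tsv")


def load_primers() -> pd.DataFrame:
    """PCR primer metadata of the four barcode markers (static reference)."""
    return _read("barcode_primers.tsv")
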