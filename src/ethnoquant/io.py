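"""Shared data model and tabular I/O.

The package moves everything through plain delimited text: citation tables
(one row per informant x plant x reported ailment), informant profiles,
species master tables, and BLAST hit tables exported in tabular form.  All
readers validate against a :class:`StudyConfig`, which fixes the study frame:
the total number of informants ``N`` (the use-value denominator), the closed
list of use categories, and the score window used by the barcode ladder.

Report-style output applies half-up decimal rounding at the precision each
index family is conventionally printed at (two decimals for UV/CIV/UD/ICF and
percentage shares, whole percent for fidelity levels); everything else is
written at full precision so read-write round-trips exactly.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass, field, fields, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SchemaError",
    "ValidationError",
    "Category",
    "StudyConfig",
    "CitationRecord",
    "InformantProfile",
    "SpeciesRecord",
    "BlastHit",
    "MARKERS",
    "DEFAULT_CATEGORIES",
    "round_half_up",
    "normalize_taxon",
    "taxon_genus",
    "read_citations",
    "read_profiles",
    "read_species_table",
    "read_blast_table",
    "read_synonym_map",
    "write_table",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row holds a value outside the study frame (bad category, etc.)."""


# The four universal plant barcode markers consumed by the consensus caller:
# nuclear ribosomal ITS and the plastid loci matK, psbA-trnH and trnL-F.
MARKERS = ("ITS", "matK", "psbA-trnH", "trnL-F")

ROUTES = ("internal", "external", "both")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention of printed index tables.

    Python's builtin ``round`` uses banker's rounding (2.675 -> 2.67); survey
    reports round half up (2.675 -> 2.68).  Goes through ``Decimal(str(...))``
    so binary float artifacts do not leak into the tie-break.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return value
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Taxon name handling
# ---------------------------------------------------------------------------

_RANK_PLACEHOLDERS = {"sp", "sp.", "spp", "spp.", "cf", "cf.", "aff", "aff."}


def normalize_taxon(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Normalize a taxon name for set comparison.

    Strips author strings, markdown emphasis, ``cf.``/``aff.`` qualifiers,
    collapses whitespace and restores Genus-lowercase-epithet capitalization.
    ``synonyms`` (old name -> accepted name, matched case-insensitively on the
    normalized form) is applied last, so synonym keys may be written in either
    spelling convention.
    """
    s = re.sub(r"[*_]", " ", name or "")
    s = re.sub(r"\s+", " ", s).strip()
    if not s:
        return ""
    tokens = s.split(" ")
    genus = tokens[0].capitalize()
    epithet = ""
    for tok in tokens[1:]:
        t = tok.lower()
        if t in _RANK_PLACEHOLDERS:
            continue
        # first all-lowercase token after the genus is the epithet; anything
        # capitalized or parenthesised is an authority and ends the binomial
        if re.fullmatch(r"[a-z][a-z-]+", t):
            epithet = t
        break
    out = f"{genus} {epithet}" if epithet else genus
    if synonyms:
        lut = {normalize_taxon(k).lower(): normalize_taxon(v) for k, v in synonyms.items()}
        out = lut.get(out.lower(), out)
    return out


def taxon_genus(name: str) -> str:
    """Genus of a (possibly normalized) binomial: its first epithet."""
    n = normalize_taxon(name)
    return n.split(" ")[0] if n else ""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Category:
    code: int
    abbrev: str
    name: str


def _default_categories() -> tuple[Category, ...]:
    # 16 disease/purpose groupings of the source survey
    raw = [
        (1, "BVP", "Diseases caused by bacterial, viral, and parasitic infections"),
        (2, "TGP", "Tissue growth problems"),
        (3, "ENM", "Endocrine, nutritional, and metabolic"),
        (4, "DNS", "Diseases of the nervous system"),
        (5, "EYE", "Diseases of the eye"),
        (6, "EAR", "Diseases of the ear"),
        (7, "DCS", "Diseases of the circulatory system"),
        (8, "DRS", "Diseases of the respiratory system"),
        (9, "DDS", "Diseases of the digestive system"),
        (10, "DOS", "Diseases of the skin"),
        (11, "MCP", "Musculoskeletal system and connective tissue problems"),
        (12, "GUP", "Genito-urinary problems"),
        (13, "PMI", "Uses in pregnancy to delivery, maternal and infant care"),
        (14, "ASS", "Abnormal signs and symptoms"),
        (15, "OEC", "Other problems of external causes"),
        (16, "OTU", "Other uses"),
    ]
    return tuple(Category(*r) for r in raw)


DEFAULT_CATEGORIES = _default_categories()

#: decimal places used for "report" output, per column family
REPORT_ROUNDING = {
    "uv": 2, "civ": 2, "ud": 2, "icf": 2,
    "fl": 0, "pct_use_reports": 2, "pct_species": 2,
    "pct_ur": 2, "jaccard": 2, "rho": 2, "p_value": 3,
}


@dataclass(frozen=True)
class StudyConfig:
    """Frame of the survey: informant total, category system, score window.

    ``n_informants_total`` is the N of the use-value formula UV = UR / N.
    ``window_delta`` is the bit-score band ("max score - delta") of the simple
    BLAST identification ladder.  ``jaccard_variant`` selects between the
    C/(A+B) form used in the source tables ("paper") and the classical
    C/(A+B-C) index ("standard").
    """

    n_informants_total: int = 335
    categories: tuple[Category, ...] = DEFAULT_CATEGORIES
    rounding: Mapping[str, int] = field(default_factory=lambda: dict(REPORT_ROUNDING))
    jaccard_variant: str = "paper"
    window_delta: float = 5.0

    def __post_init__(self) -> None:
        if self.n_informants_total < 1:
            raise ValidationError("n_informants_total must be >= 1")
        codes = [c.code for c in self.categories]
        if len(set(codes)) != len(codes):
            raise ValidationError("category codes must be unique")
        if self.window_delta <= 0:
            raise ValidationError("window_delta must be > 0")
        if self.jaccard_variant not in ("paper", "standard"):
            raise ValidationError(f"unknown jaccard_variant {self.jaccard_variant!r}")

    @property
    def category_codes(self) -> frozenset[int]:
        return frozenset(c.code for c in self.categories)

    def category(self, code: int) -> Category:
        for c in self.categories:
            if c.code == code:
                return c
        raise KeyError(code)


@dataclass(frozen=True)
class CitationRecord:
    """One informant's mention of one plant for one ailment (pre-collapse)."""

    informant_id: str
    species_id: str
    ailment: str
    category: int
    locality: str = ""
    route: str = "internal"
    part_used: tuple[str, ...] = ()
    preparation: str = ""

    def __post_init__(self) -> None:
        if not self.informant_id or not self.species_id:
            raise ValidationError("informant_id and species_id must be non-empty")
        if self.route not in ROUTES:
            raise ValidationError(f"route must be one of {ROUTES}, got {self.route!r}")


@dataclass(frozen=True)
class InformantProfile:
    informant_id: str
    locality: str = ""
    education: str = ""
    gender: str = ""
    social_position: str = ""
    occupation: str = ""
    civil_status: str = ""
    age_group: str = ""


@dataclass(frozen=True)
class SpeciesRecord:
    species_id: str
    scientific_name: str
    family: str
    local_name: str = ""
    voucher: str = ""
    endemicity: str = ""
    conservation_status: str = ""

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValidationError("species_id must be non-empty")
        if not self.family:
            raise ValidationError(f"family must be non-empty for {self.species_id}")


@dataclass(frozen=True)
class BlastHit:
    """One subject hit of a tabular BLAST export.

    ``max_score`` is the alignment bit score, ``query_cover`` and
    ``percent_identity`` are on the 0-100 scale as printed by the web
    interface.  ``subject_genus`` defaults to the first epithet of the subject
    binomial when the export carries no explicit genus column.
    """

    query_id: str
    marker: str
    subject_species: str
    max_score: float
    query_cover: float
    percent_identity: float
    evalue: float = 0.0
    subject_genus: str = ""
    subject_family: str = ""

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValidationError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        if not self.max_score > 0:
            raise ValidationError("max_score must be > 0")
        if not 0 <= self.query_cover <= 100:
            raise ValidationError("query_cover must be in [0, 100]")
        if not 0 < self.percent_identity <= 100:
            raise ValidationError("percent_identity must be in (0, 100]")
        if self.evalue < 0:
            raise ValidationError("evalue must be >= 0")
        if not self.subject_genus:
            object.__setattr__(self, "subject_genus", taxon_genus(self.subject_species))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _open_rows(path: str | Path, delimiter: str | None) -> tuple[list[str], list[list[str]]]:
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read()
    if not sample.strip():
        raise SchemaError(f"{path}: empty file, header row is mandatory")
    if delimiter is None:
        first = sample.splitlines()[0]
        delimiter = "," if ("," in first and "\t" not in first) else "\t"
    reader = csv.reader(sample.splitlines(), delimiter=delimiter)
    rows = list(reader)
    return rows[0], rows[1:]


def _require(header: Sequence[str], required: Iterable[str], path) -> dict[str, int]:
    idx = {h.strip(): i for i, h in enumerate(header)}
    for col in required:
        if col not in idx:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return idx


def read_citations(
    path: str | Path,
    config: StudyConfig,
    delimiter: str | None = None,
) -> list[CitationRecord]:
    """Read a long-format citation table.

    Required columns: informant_id, species_id, ailment, category.  Optional:
    locality, route, part_used (slash- or comma-separated codes), preparation.
    Category codes are validated against ``config``; an unknown code raises
    :class:`ValidationError` naming the offending row.
    """
    header, rows = _open_rows(path, delimiter)
    idx = _require(header, ("informant_id", "species_id", "ailment", "category"), path)
    opt = {c: idx.get(c) for c in ("locality", "route", "part_used", "preparation")}
    out: list[CitationRecord] = []
    for rno, row in enumerate(rows, start=2):
        if not any(cell.strip() for cell in row):
            continue
        raw_cat = row[idx["category"]].strip()
        try:
            cat = int(raw_cat)
        except ValueError:
            raise ValidationError(f"{path}: row {rno}: non-integer category {raw_cat!r}")
        if cat not in config.category_codes:
            raise ValidationError(
                f"{path}: row {rno}: unknown category code {cat} "
                f"(configured: {sorted(config.category_codes)})"
            )
        def get(col: str, default: str = "") -> str:
            i = opt[col]
            return row[i].strip() if i is not None and i < len(row) else default
        parts = tuple(p for p in re.split(r"[/,;]\s*", get("part_used")) if p)
        try:
            out.append(
                CitationRecord(
                    informant_id=row[idx["informant_id"]].strip(),
                    species_id=row[idx["species_id"]].strip(),
                    ailment=row[idx["ailment"]].strip(),
                    category=cat,
                    locality=get("locality"),
                    route=get("route", "internal") or "internal",
                    part_used=parts,
                    preparation=get("preparation"),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}: row {rno}: {err}") from None
    return out


def read_profiles(path: str | Path, delimiter: str | None = None) -> list[InformantProfile]:
    header, rows = _open_rows(path, delimiter)
    idx = _require(header, ("informant_id",), path)
    cols = [f.name for f in fields(InformantProfile)]
    out = []
    seen: set[str] = set()
    for rno, row in enumerate(rows, start=2):
        if not any(c.strip() for c in row):
            continue
        kw = {c: row[idx[c]].strip() for c in cols if c in idx and idx[c] < len(row)}
        prof = InformantProfile(**kw)
        if prof.informant_id in seen:
            raise ValidationError(f"{path}: row {rno}: duplicate informant_id {prof.informant_id!r}")
        seen.add(prof.informant_id)
        out.append(prof)
    return out


def read_species_table(path: str | Path, delimiter: str | None = None) -> list[SpeciesRecord]:
    header, rows = _open_rows(path, delimiter)
    idx = _require(header, ("species_id", "scientific_name", "family"), path)
    cols = [f.name for f in fields(SpeciesRecord)]
    out = []
    seen: set[str] = set()
    for rno, row in enumerate(rows, start=2):
        if not any(c.strip() for c in row):
            continue
        kw = {c: row[idx[c]].strip() for c in cols if c in idx and idx[c] < len(row)}
        try:
            rec = SpeciesRecord(**kw)
        except ValidationError as err:
            raise ValidationError(f"{path}: row {rno}: {err}") from None
        if rec.species_id in seen:
            raise ValidationError(f"{path}: row {rno}: duplicate species_id {rec.species_id!r}")
        seen.add(rec.species_id)
        out.append(rec)
    return out


#: accepted aliases for BLAST tabular columns (web export conventions differ)
_BLAST_ALIASES = {
    "query_id": ("qseqid", "query_id", "query"),
    "subject": ("ssciname", "sseqid", "subject", "subject_species"),
    "pident": ("pident", "percent_identity", "identity"),
    "qcovs": ("qcovs", "query_cover", "qcov"),
    "bitscore": ("bitscore", "max_score", "score"),
    "evalue": ("evalue", "e_value"),
}


def read_blast_table(path: str | Path, marker: str, delimiter: str | None = None) -> list[BlastHit]:
    """Read one marker's tabular BLAST hits, sorted by max score descending.

    Column order follows the common export convention qseqid, ssciname/sseqid,
    pident, qcovs, bitscore, evalue; matching is by header name so extra
    columns (and optional ``sgenus``/``sfamily``) are tolerated.  An empty file
    with a header yields an empty list — the "unsuccessfully amplified" case.
    """
    header, rows = _open_rows(path, delimiter)
    idx = {h.strip().lower(): i for i, h in enumerate(header)}

    def col(key: str, required: bool = True) -> int | None:
        for alias in _BLAST_ALIASES[key]:
            if alias in idx:
                return idx[alias]
        if required:
            raise SchemaError(f"{path}: missing required column {_BLAST_ALIASES[key][0]!r}")
        return None

    c_q, c_s = col("query_id"), col("subject")
    c_pi, c_qc, c_bs = col("pident"), col("qcovs"), col("bitscore")
    c_ev = col("evalue", required=False)
    c_genus = idx.get("sgenus", idx.get("subject_genus"))
    c_family = idx.get("sfamily", idx.get("subject_family"))
    out: list[BlastHit] = []
    for rno, row in enumerate(rows, start=2):
        if not any(c.strip() for c in row):
            continue
        def num(i: int | None, label: str, default: float | None = None) -> float:
            if i is None:
                return default
            try:
                return float(row[i])
            except (ValueError, IndexError):
                raise ValidationError(f"{path}: row {rno}: non-numeric {label} {row[i]!r}")
        try:
            out.append(
                BlastHit(
                    query_id=row[c_q].strip(),
                    marker=marker,
                    subject_species=row[c_s].strip(),
                    max_score=num(c_bs, "bitscore"),
                    query_cover=num(c_qc, "query cover"),
                    percent_identity=num(c_pi, "percent identity"),
                    evalue=num(c_ev, "evalue", 0.0),
                    subject_genus=row[c_genus].strip() if c_genus is not None else "",
                    subject_family=row[c_family].strip() if c_family is not None else "",
                )
            )
        except ValidationError as err:
            if "row" in str(err):
                raise
            raise ValidationError(f"{path}: row {rno}: {err}") from None
    out.sort(key=lambda h: -h.max_score)
    return out


def read_synonym_map(path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    """Two-column table (old name -> accepted name) for taxon normalization."""
    header, rows = _open_rows(path, delimiter)
    if len(header) < 2:
        raise SchemaError(f"{path}: synonym map needs two columns")
    return {r[0].strip(): r[1].strip() for r in rows if len(r) >= 2 and r[0].strip()}


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------


def _as_record(row) -> dict:
    if hasattr(row, "__dataclass_fields__"):
        d = asdict(row)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = "/".join(v)
        return d
    return dict(row)


def write_table(
    rows,
    path: str | Path,
    format: str = "tsv",
    report: bool = False,
    rounding: Mapping[str, int] | None = None,
) -> Path:
    """Write records (dataclasses, dicts or a DataFrame) to tsv/csv/json.

    With ``report=True`` numeric columns named in ``rounding`` (default
    :data:`REPORT_ROUNDING`) are half-up rounded to their printed precision;
    otherwise values round-trip at full precision through the matching reader.
    """
    path = Path(path)
    if format not in ("tsv", "csv", "json"):
        raise ValueError(f"unknown format {format!r}")
    if hasattr(rows, "to_dict") and hasattr(rows, "columns"):  # DataFrame
        records = rows.to_dict(orient="records")
        header = list(rows.columns)
    else:
        records = [_as_record(r) for r in rows]
        header = list(records[0]) if records else []
    if report:
        spec = dict(REPORT_ROUNDING)
        spec.update(rounding or {})
        for rec in records:
            for k, nd in spec.items():
                if k in rec and isinstance(rec[k], (int, float)) and not isinstance(rec[k], bool):
                    val = round_half_up(rec[k], nd)
                    rec[k] = int(val) if nd == 0 else val
    try:
        if format == "json":
            path.write_text(json.dumps(records, indent=1, default=str) + "\n", encoding="utf-8")
        else:
            delim = "\t" if format == "tsv" else ","
            with open(path, "w", newline="", encoding="utf-8") as fh:
                w = csv.DictWriter(fh, fieldnames=header, delimiter=delim)
                w.writeheader()
                w.writerows(records)
    except OSError as err:
        raise OSError(f"cannot write {path}: {err}") from err
    return path
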