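"""Substudy corpus: data model, readers/validators and label normalisation.

The analysable unit is the *substudy*: one study x cohort x microRNA
comparison contributing a single 2x2 table of dysregulation-event counts
(cases exhibiting dysregulated expression vs not, against controls).  A
publication may contribute several substudies; ``parent_study_id`` keeps the
link because publication-bias tests need to know when every substudy shares
one parent.

MicroRNA labels in the literature are messy ("hsa-miR-126", "MiR-30c-5p",
"microRNA-21"); :func:`normalize_mirna_name` maps them to a canonical
miRBase-style form ("miR-126", "miR-30c-5p", "miR-21"), consulting an
editable alias table after prefix normalisation.  Historic names such as the
let-7 family are preserved.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

TISSUE_CLASSES = ("blood", "pancreatic", "muscle", "adipose", "vessel", "heart", "kidney")
BLOOD_FRACTIONS = ("serum", "plasma", "pbmc", "whole_blood")
PLATFORMS = ("pcr", "seq", "array", "nanostring")
DIRECTIONS = ("up", "down")

CORPUS_COLUMNS = [
    "substudy_id", "parent_study_id", "mirna", "tissue", "blood_fraction",
    "platform", "n_case", "n_ctrl", "events_case", "events_ctrl",
    "reported_direction",
]

#: Default mapping from raw tissue labels to (tissue_class, blood_fraction).
DEFAULT_TISSUE_MAP: dict[str, tuple[str, str]] = {
    "serum": ("blood", "serum"),
    "plasma": ("blood", "plasma"),
    "pbmc": ("blood", "pbmc"),
    "pbmcs": ("blood", "pbmc"),
    "peripheral blood mononuclear cells": ("blood", "pbmc"),
    "whole blood": ("blood", "whole_blood"),
    "whole_blood": ("blood", "whole_blood"),
    "blood": ("blood", "whole_blood"),
    "pancreas": ("pancreatic", "none"),
    "whole pancreas": ("pancreatic", "none"),
    "pancreatic islets": ("pancreatic", "none"),
    "pancreatic tissue": ("pancreatic", "none"),
    "skeletal muscle": ("muscle", "none"),
    "muscle": ("muscle", "none"),
    "adipose": ("adipose", "none"),
    "adipose tissue": ("adipose", "none"),
    "blood vessel": ("vessel", "none"),
    "blood vessels": ("vessel", "none"),
    "vessel": ("vessel", "none"),
    "heart": ("heart", "none"),
    "kidney": ("kidney", "none"),
    "kidneys": ("kidney", "none"),
}


class CorpusValidationError(ValueError):
    """One or more corpus rows violate the record invariants."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("corpus validation failed:\n" + "\n".join(self.problems))


class SchemaError(ValueError):
    """The input table does not match the documented column schema."""


@dataclass(frozen=True)
class MicroRNAName:
    """A microRNA label with its canonical form and how it was resolved."""

    raw_label: str
    canonical: str
    resolved_via: str  # exact | alias_table | prefix_rule | unresolved

    def __post_init__(self):
        if self.resolved_via != "unresolved" and not self.canonical:
            raise ValueError("canonical must be non-empty when resolved")


_PREFIX_RE = re.compile(r"^(hsa-)?(microrna-?|mir-?)", re.IGNORECASE)
_LET_RE = re.compile(r"^(hsa-)?(let-7)", re.IGNORECASE)


def normalize_mirna_name(raw: str, alias_table: Mapping[str, str] | None = None) -> MicroRNAName:
    """Canonicalise a microRNA label.

    Prefixes ``hsa-``, ``microRNA-`` and any casing of ``miR-`` map to
    ``miR-``; the historic ``let-7`` family keeps its name.  The alias table
    is consulted *after* prefix normalisation (and also on the raw label, so
    verbatim typographic aliases can be shipped).  Unresolvable labels are
    flagged ``unresolved`` rather than dropped.  Idempotent: a canonical
    name normalises to itself with ``resolved_via="exact"``.
    """
    if not raw or not raw.strip():
        raise ValueError("empty microRNA label")
    alias_table = alias_table or {}
    s = raw.strip()

    if s in alias_table:
        return MicroRNAName(raw, alias_table[s], "alias_table")

    m = _LET_RE.match(s)
    if m:
        canonical = "let-7" + s[m.end():]
        via = "exact" if canonical == s else "prefix_rule"
    else:
        m = _PREFIX_RE.match(s)
        if m:
            canonical = "miR-" + s[m.end():]
            via = "exact" if canonical == s else "prefix_rule"
        else:
            canonical = ""
            via = "unresolved"

    if canonical and canonical in alias_table:
        return MicroRNAName(raw, alias_table[canonical], "alias_table")
    if via == "unresolved":
        logger.warning("unresolvable microRNA label: %r", raw)
        return MicroRNAName(raw, "", "unresolved")
    return MicroRNAName(raw, canonical, via)


def classify_tissue(tissue_raw: str, mapping: Mapping[str, tuple[str, str]] | None = None) -> tuple[str, str]:
    """Map a raw tissue/source label to ``(tissue_class, blood_fraction)``.

    Circulating sources (serum, plasma, PBMC, whole blood) classify as
    ``blood`` with their fraction; whole pancreas and pancreatic islets as
    ``pancreatic``.  Unknown labels fall through to ``other:<label>`` with a
    logged warning and never carry a blood fraction.
    """
    mapping = DEFAULT_TISSUE_MAP if mapping is None else mapping
    key = tissue_raw.strip().lower()
    if key in mapping:
        return mapping[key]
    slug = re.sub(r"[^a-z0-9]+", "_", key).strip("_")
    logger.warning("unknown tissue label %r -> other:%s", tissue_raw, slug)
    return (f"other:{slug}", "none")


@dataclass(frozen=True)
class SubStudyRecord:
    """One study x microRNA observation: a 2x2 event table plus strata."""

    substudy_id: str
    parent_study_id: str
    mirna: MicroRNAName
    tissue_raw: str
    tissue_class: str
    blood_fraction: str  # serum | plasma | pbmc | whole_blood | none
    platform: str
    n_case: int
    n_ctrl: int
    events_case: int
    events_ctrl: int
    reported_direction: str

    def validate(self) -> list[str]:
        """Return invariant violations (empty list when valid)."""
        p: list[str] = []
        sid = self.substudy_id
        if self.n_case < 1 or self.n_ctrl < 1:
            p.append(f"{sid}: arm sizes must be >= 1 (n_case={self.n_case}, n_ctrl={self.n_ctrl})")
        if not 0 <= self.events_case <= self.n_case:
            p.append(f"{sid}: events_case={self.events_case} outside [0, n_case={self.n_case}]")
        if not 0 <= self.events_ctrl <= self.n_ctrl:
            p.append(f"{sid}: events_ctrl={self.events_ctrl} outside [0, n_ctrl={self.n_ctrl}]")
        is_blood = self.tissue_class == "blood"
        if is_blood != (self.blood_fraction != "none"):
            p.append(f"{sid}: blood_fraction={self.blood_fraction!r} inconsistent with tissue_class={self.tissue_class!r}")
        if self.platform not in PLATFORMS:
            p.append(f"{sid}: unknown platform {self.platform!r}")
        if self.reported_direction not in DIRECTIONS:
            p.append(f"{sid}: reported_direction must be up/down, got {self.reported_direction!r}")
        return p

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_ctrl


@dataclass
class StudyCorpus:
    """A validated collection of substudy records plus its alias table."""

    records: list[SubStudyRecord]
    alias_table: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    @property
    def total_sample_size(self) -> int:
        return sum(r.n_total for r in self.records)

    def mirnas(self) -> list[str]:
        """Canonical microRNA names present, in first-seen order."""
        seen: dict[str, None] = {}
        for r in self.records:
            if r.mirna.resolved_via != "unresolved":
                seen.setdefault(r.mirna.canonical, None)
        return list(seen)

    def subset(self, predicate) -> "StudyCorpus":
        return StudyCorpus([r for r in self.records if predicate(r)],
                           alias_table=self.alias_table, provenance=self.provenance)


def load_alias_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (raw, canonical) TSV alias table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["raw", "canonical"]:
        raise SchemaError(f"alias table must have columns raw, canonical; got {list(df.columns)}")
    return dict(zip(df["raw"], df["canonical"]))


def default_alias_table() -> dict[str, str]:
    """The packaged alias table (editable TSV shipped with the package)."""
    return load_alias_table(Path(__file__).parent / "data" / "aliases.tsv")


def _records_from_frame(df: pd.DataFrame, alias_table: Mapping[str, str]) -> list[SubStudyRecord]:
    records = []
    for row in df.itertuples(index=False):
        name = normalize_mirna_name(str(row.mirna), alias_table)
        tissue_class, inferred_fraction = classify_tissue(str(row.tissue))
        fraction = str(row.blood_fraction)
        if fraction in ("", "nan", "none", "None"):
            fraction = inferred_fraction
        records.append(SubStudyRecord(
            substudy_id=str(row.substudy_id),
            parent_study_id=str(row.parent_study_id),
            mirna=name,
            tissue_raw=str(row.tissue),
            tissue_class=tissue_class,
            blood_fraction=fraction,
            platform=str(row.platform),
            n_case=int(row.n_case),
            n_ctrl=int(row.n_ctrl),
            events_case=int(row.events_case),
            events_ctrl=int(row.events_ctrl),
            reported_direction=str(row.reported_direction),
        ))
    return records


def read_corpus(path: str | Path, alias_table: Mapping[str, str] | None = None) -> StudyCorpus:
    """Read and validate a substudy corpus TSV.

    The dialect is fixed: UTF-8, tab-separated, ``.`` decimal, header
    required, columns exactly ``CORPUS_COLUMNS``.  All row-level failures
    are collected and raised together in one :class:`CorpusValidationError`.
    """
    alias_table = dict(alias_table or {})
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in CORPUS_COLUMNS]
    if extra:
        raise SchemaError(f"unexpected column(s): {', '.join(extra)}")

    problems: list[str] = []
    for col in ("n_case", "n_ctrl", "events_case", "events_ctrl"):
        bad = df[~df[col].str.fullmatch(r"\d+")]
        for sid, val in zip(bad["substudy_id"], bad[col]):
            problems.append(f"{sid}: non-integer {col}={val!r}")
    if problems:
        raise CorpusValidationError(problems)

    records = _records_from_frame(df, alias_table)
    for rec in records:
        problems.extend(rec.validate())

    counts = df["substudy_id"].value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        problems.append(f"duplicate substudy_id(s): {', '.join(sorted(dups))}")
    if problems:
        raise CorpusValidationError(problems)

    n_unresolved = sum(r.mirna.resolved_via == "unresolved" for r in records)
    if n_unresolved:
        logger.warning("%d record(s) with unresolved microRNA names retained (flagged)", n_unresolved)
    return StudyCorpus(records, alias_table=alias_table, provenance=str(path))


def corpus_to_frame(corpus: StudyCorpus) -> pd.DataFrame:
    """Canonicalised tabular view in the documented column order."""
    rows = []
    for r in corpus.records:
        rows.append({
            "substudy_id": r.substudy_id,
            "parent_study_id": r.parent_study_id,
            "mirna": r.mirna.canonical or r.mirna.raw_label,
            "tissue": r.tissue_raw,
            "blood_fraction": r.blood_fraction,
            "platform": r.platform,
            "n_case": r.n_case,
            "n_ctrl": r.n_ctrl,
            "events_case": r.events_case,
            "events_ctrl": r.events_ctrl,
            "reported_direction": r.reported_direction,
        })
    return pd.DataFrame(rows, columns=CORPUS_COLUMNS)


def write_corpus(corpus: StudyCorpus, path: str | Path) -> None:
    """Write the canonicalised corpus in the documented TSV dialect.

    Round-trips: reading the written file back and writing it again
    reproduces the file byte-identically.
    """
    corpus_to_frame(corpus).to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")
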