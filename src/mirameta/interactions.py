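"""MicroRNA–target interaction ledgers and the robustness filter.

Evidence for a miRNA→gene interaction comes in two kinds: experimentally
validated records carrying the PMIDs of their supporting articles, and
bioinformatic predictions carrying a rank percentile.  A pair is *robust*
when, after retracted articles are struck from the record, it is still
supported by at least two distinct experimental PMIDs **and** also appears
in a prediction ledger (two types of database).  Retractions are applied
before support counting, so a pair citing three articles of which one is
retracted still passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import normalize_mirna_name

logger = logging.getLogger(__name__)

LEDGER_COLUMNS = ["mirna", "gene", "source_type", "database", "pmids", "prediction_rank_pct"]


@dataclass
class InteractionRecord:
    mirna: str
    gene: str
    source_type: str  # experimental | predicted
    database: str
    pmids: frozenset[str] = frozenset()
    prediction_rank_pct: float | None = None

    def __post_init__(self):
        if self.source_type == "experimental" and not self.pmids:
            raise ValueError(f"experimental record {self.mirna}->{self.gene} without PMIDs")
        if self.source_type == "predicted" and self.prediction_rank_pct is None:
            raise ValueError(f"predicted record {self.mirna}->{self.gene} without rank percentile")
        if self.source_type not in ("experimental", "predicted"):
            raise ValueError(f"unknown source_type {self.source_type!r}")


@dataclass
class RobustInteractionSet:
    """miRNA→gene pairs surviving the robustness filter, with provenance."""

    pairs: set[tuple[str, str]]
    provenance: dict[tuple[str, str], tuple[frozenset[str], frozenset[str]]]  # pair -> (pmids, databases)
    filter_stats: dict[str, int] = field(default_factory=dict)

    def targets_of(self, mirna: str) -> set[str]:
        return {g for (m, g) in self.pairs if m == mirna}


def merge_sources(ledgers: Sequence[Sequence[InteractionRecord]],
                  alias_table: Mapping[str, str] | None = None) -> list[InteractionRecord]:
    """Union ledgers, canonicalising names and collapsing duplicates.

    Records sharing (mirna, gene, source_type) are merged: PMIDs unioned,
    database labels concatenated, and the best (smallest) prediction rank
    retained.
    """
    merged: dict[tuple[str, str, str], InteractionRecord] = {}
    n_in = 0
    for ledger in ledgers:
        for rec in ledger:
            n_in += 1
            name = normalize_mirna_name(rec.mirna, alias_table)
            mirna = name.canonical if name.resolved_via != "unresolved" else rec.mirna
            key = (mirna, rec.gene, rec.source_type)
            if key in merged:
                old = merged[key]
                ranks = [r for r in (old.prediction_rank_pct, rec.prediction_rank_pct) if r is not None]
                merged[key] = InteractionRecord(
                    mirna=mirna, gene=rec.gene, source_type=rec.source_type,
                    database=";".join(sorted(set(old.database.split(";")) | set(rec.database.split(";")))),
                    pmids=old.pmids | rec.pmids,
                    prediction_rank_pct=min(ranks) if ranks else None,
                )
            else:
                merged[key] = InteractionRecord(
                    mirna=mirna, gene=rec.gene, source_type=rec.source_type,
                    database=rec.database, pmids=rec.pmids,
                    prediction_rank_pct=rec.prediction_rank_pct,
                )
    logger.info("merged %d records into %d (collapsed %d duplicates)",
                n_in, len(merged), n_in - len(merged))
    return list(merged.values())


def apply_retractions(ledger: Sequence[InteractionRecord],
                      retracted_pmids: Iterable[str]) -> list[InteractionRecord]:
    """Strike retracted PMIDs from every record before support is counted.

    Experimental records left with no surviving PMID are dropped (logged);
    predicted records carry no PMIDs and pass through unchanged.
    """
    retracted = frozenset(str(p) for p in retracted_pmids)
    out = []
    for rec in ledger:
        if rec.source_type != "experimental":
            out.append(rec)
            continue
        kept = rec.pmids - retracted
        removed = rec.pmids & retracted
        if removed:
            logger.info("%s->%s: %d retracted PMID(s) removed", rec.mirna, rec.gene, len(removed))
        if not kept:
            logger.info("%s->%s: dropped, all supporting articles retracted", rec.mirna, rec.gene)
            continue
        out.append(InteractionRecord(rec.mirna, rec.gene, rec.source_type,
                                     rec.database, kept, rec.prediction_rank_pct))
    return out


def prediction_top_filter(ledger: Sequence[InteractionRecord],
                          top_pct: float = 1.4) -> list[InteractionRecord]:
    """Keep predicted records in the top ``top_pct`` percent (inclusive bound)."""
    out = []
    for rec in ledger:
        if rec.source_type == "predicted" and rec.prediction_rank_pct > top_pct:
            continue
        out.append(rec)
    return out


def filter_robust(ledger: Sequence[InteractionRecord], min_pmids: int = 2) -> RobustInteractionSet:
    """Apply the robustness rule to a (post-retraction) merged ledger.

    A pair survives iff its experimental PMIDs (unioned across databases)
    number at least ``min_pmids`` and the pair also appears as a
    prediction.  ``filter_stats`` records the count after each clause.
    """
    exp_pmids: dict[tuple[str, str], set[str]] = {}
    exp_dbs: dict[tuple[str, str], set[str]] = {}
    predicted: set[tuple[str, str]] = set()
    for rec in ledger:
        key = (rec.mirna, rec.gene)
        if rec.source_type == "experimental":
            exp_pmids.setdefault(key, set()).update(rec.pmids)
            exp_dbs.setdefault(key, set()).update(rec.database.split(";"))
        else:
            predicted.add(key)

    stats = {"experimental_pairs": len(exp_pmids)}
    enough = {k for k, p in exp_pmids.items() if len(p) >= min_pmids}
    stats["with_min_pmids"] = len(enough)
    robust = {k for k in enough if k in predicted}
    stats["with_prediction"] = len(robust)

    provenance = {k: (frozenset(exp_pmids[k]), frozenset(exp_dbs[k])) for k in robust}
    logger.info("robustness filter: %s", stats)
    return RobustInteractionSet(pairs=robust, provenance=provenance, filter_stats=stats)


# ---------------------------------------------------------------------------
# TSV I/O

def read_ledger(path: str | Path) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in LEDGER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ledger {path}: missing column(s) {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        pmids = frozenset(p for p in str(row.pmids).split(";") if p)
        rank = float(row.prediction_rank_pct) if row.prediction_rank_pct else None
        records.append(InteractionRecord(row.mirna, row.gene, row.source_type,
                                         row.database, pmids, rank))
    return records


def write_ledger(records: Sequence[InteractionRecord], path: str | Path) -> None:
    rows = [{
        "mirna": r.mirna, "gene": r.gene, "source_type": r.source_type,
        "database": r.database, "pmids": ";".join(sorted(r.pmids)),
        "prediction_rank_pct": "" if r.prediction_rank_pct is None else r.prediction_rank_pct,
    } for r in records]
    pd.DataFrame(rows, columns=LEDGER_COLUMNS).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_retractions(path: str | Path) -> frozenset[str]:
    """One retracted PMID per line."""
    lines = Path(path).read_text().splitlines()
    return frozenset(ln.strip() for ln in lines if ln.strip())


def robust_set_to_frame(robust: RobustInteractionSet) -> pd.DataFrame:
    rows = [{
        "mirna": m, "gene": g,
        "supporting_pmids": ";".join(sorted(robust.provenance[(m, g)][0])),
        "databases": ";".join(sorted(robust.provenance[(m, g)][1])),
    } for (m, g) in sorted(robust.pairs)]
    return pd.DataFrame(rows, columns=["mirna", "gene", "supporting_pmids", "databases"])
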