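"""Readers and merge logic for PPI and DDI source tables.

Interaction pairs are stored under a canonical key (lexicographically
sorted id pair) so that (a, b) and (b, a) are the same record; homotypic
domain pairs and self-interacting proteins are legal.  The DOMINE-style
reader drops low-confidence rows by default; 3did-style tables carry no
confidence class.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .annotation import IdMap
from .errors import IdMappingError, LoadError, ParseError

logger = logging.getLogger(__name__)

PFAM_RE = re.compile(r"^PF\d{5}$")

CONFIDENCE_CLASSES = ("HC", "MC", "LC", "NA")
#: Default DOMINE confidence classes kept on load (low-confidence removed).
DEFAULT_KEEP = frozenset({"HC", "MC"})


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order-independent key for an interaction pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPIRecord:
    gene_a: str
    gene_b: str
    sources: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, str]:
        return canonical_pair(self.gene_a, self.gene_b)


@dataclass(frozen=True)
class DDIRecord:
    pfam_a: str
    pfam_b: str
    sources: frozenset[str] = frozenset()
    confidence: str = "NA"

    def __post_init__(self):
        if self.confidence not in CONFIDENCE_CLASSES:
            raise ParseError(f"unknown confidence class {self.confidence!r}")

    @property
    def key(self) -> tuple[str, str]:
        return canonical_pair(self.pfam_a, self.pfam_b)


def _read_table(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.copy()
    return pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)


def read_ppi(
    table,
    columns: tuple[str, str] = ("gene_a", "gene_b"),
    idmap: IdMap | None = None,
    source: str = "ppi",
    strict: bool = True,
) -> dict[tuple[str, str], PPIRecord]:
    """Read a two-column PPI table into a canonical deduplicated pair set.

    When ``idmap`` is given every id is resolved to its Entrez key first.
    In strict mode unmappable ids abort the load with all offenders listed;
    in lenient mode the offending rows are dropped and counted.
    """
    df = _read_table(table)
    col_a, col_b = columns
    records: dict[tuple[str, str], PPIRecord] = {}
    unmapped: list[str] = []
    n_dupes = 0
    for row in df.to_dict("records"):
        a, b = str(row[col_a]), str(row[col_b])
        if idmap is not None:
            try:
                a, b = idmap.to_entrez(a), idmap.to_entrez(b)
            except IdMappingError as exc:
                unmapped.append(str(exc))
                continue
        key = canonical_pair(a, b)
        if key in records:
            n_dupes += 1
        else:
            records[key] = PPIRecord(key[0], key[1], frozenset({source}))
    if unmapped:
        if strict:
            raise LoadError("unmappable ids in PPI table", unmapped)
        logger.warning("PPI load dropped %d unmappable rows", len(unmapped))
    logger.info("PPI load: %d records, %d duplicate rows dropped", len(records), n_dupes)
    return records


def read_ddi_domine(
    table,
    keep: frozenset[str] | set[str] = DEFAULT_KEEP,
    columns: tuple[str, str, str] = ("pfam_a", "pfam_b", "confidence"),
    source: str = "domine",
) -> dict[tuple[str, str], DDIRecord]:
    """Read a DOMINE-style DDI table, keeping only listed confidence classes.

    The default ``keep`` set {HC, MC} drops low-confidence rows, matching
    the convention of removing LC inferences before network construction.
    """
    df = _read_table(table)
    col_a, col_b, col_c = columns
    records: dict[tuple[str, str], DDIRecord] = {}
    class_counts: dict[str, int] = {}
    for i, row in enumerate(df.to_dict("records")):
        conf = str(row[col_c])
        if conf not in {"HC", "MC", "LC"}:
            raise ParseError(f"row {i}: unknown confidence label {conf!r}")
        class_counts[conf] = class_counts.get(conf, 0) + 1
        if conf not in keep:
            continue
        a, b = _check_pfam(row[col_a], i), _check_pfam(row[col_b], i)
        key = canonical_pair(a, b)
        if key not in records:
            records[key] = DDIRecord(key[0], key[1], frozenset({source}), conf)
    logger.info("DOMINE load: kept %d records; per-class counts %s", len(records), class_counts)
    return records


def _check_pfam(value: str, row: int) -> str:
    value = str(value)
    if not PFAM_RE.match(value):
        raise ParseError(f"row {row}: malformed Pfam id {value!r}")
    return value


def read_ddi_3did(
    table,
    columns: tuple[str, str] = ("pfam_a", "pfam_b"),
    source: str = "threedid",
) -> dict[tuple[str, str], DDIRecord]:
    """Read a 3did-style Pfam pair list (no confidence classes)."""
    df = _read_table(table)
    col_a, col_b = columns
    records: dict[tuple[str, str], DDIRecord] = {}
    n_dupes = 0
    for i, row in enumerate(df.to_dict("records")):
        a, b = _check_pfam(row[col_a], i), _check_pfam(row[col_b], i)
        key = canonical_pair(a, b)
        if key in records:
            n_dupes += 1
        else:
            records[key] = DDIRecord(key[0], key[1], frozenset({source}), "NA")
    logger.info("3did load: %d records, %d duplicate rows dropped", len(records), n_dupes)
    return records


def merge_ddi(*sets: Mapping[tuple[str, str], DDIRecord]) -> dict[tuple[str, str], DDIRecord]:
    """Union DDI sets over canonical pair keys.

    Provenance is cumulative: a pair present in several inputs keeps the
    union of sources.  Once merged, evidence from different sources ranks
    equally; a DOMINE confidence class is retained for reporting only.
    """
    merged: dict[tuple[str, str], DDIRecord] = {}
    for ddi_set in sets:
        for key, rec in ddi_set.items():
            if key in merged:
                old = merged[key]
                conf = old.confidence if old.confidence != "NA" else rec.confidence
                merged[key] = DDIRecord(key[0], key[1], old.sources | rec.sources, conf)
            else:
                merged[key] = rec
    total_in = sum(len(s) for s in sets)
    logger.info("DDI merge: %d inputs totalling %d -> %d records", len(sets), total_in, len(merged))
    return merged
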