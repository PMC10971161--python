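"""Variant knowledge base: multi-source classifications and their merge.

Screening keeps only variants "conclusively described" as pathogenic or
likely pathogenic across the consulted databases.  This module loads the
per-source classification tables (HGMD-style DM calls, ClinVar, the VKGL
national consensus database, and per-centre local databases), normalizes
variant keys, and merges the per-source verdicts under an explicit conflict
policy:

* at least one P/LP/DM source and **no** benign-side source -> ``LP_or_P``;
* both pathogenic- and benign-side entries -> ``conflicting`` (never passed
  by the database branch of the strict filter);
* otherwise the best remaining tier (VUS, then benign), or ``none`` when
  the variant is absent from every source.

Per-workflow knowledge bases (tNGS vs WES/WGS centres with different local
databases) are supported simply by loading different files.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .variant_domain import VariantRecord

__all__ = [
    "SOURCES",
    "CLASSIFICATIONS",
    "Verdict",
    "KnowledgeBaseEntry",
    "AggregatedClass",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "normalize_variant_key",
    "lookup_classification",
    "load_knowledgebase",
]

SOURCES = ("HGMD", "ClinVar", "VKGL", "local")
CLASSIFICATIONS = ("P", "LP", "VUS", "LB", "B", "DM", "conflicting")

PATHOGENIC_SIDE = frozenset({"P", "LP", "DM"})
BENIGN_SIDE = frozenset({"B", "LB"})


class KnowledgeBaseError(ValueError):
    """Malformed knowledge-base input."""


class Verdict(str, enum.Enum):
    LP_or_P = "LP_or_P"
    VUS = "VUS"
    benign_or_likely_benign = "benign_or_likely_benign"
    none = "none"
    conflicting = "conflicting"


def normalize_variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Minimal normalized representation "chrom:pos:ref:alt".

    Uppercases alleles and trims the common suffix then prefix (keeping at
    least one base on each side), adjusting the position for trimmed prefix
    bases.  Symbolic alleles (``<DEL>`` and friends) and the empty-marker
    convention are passed through untouched.
    """
    chrom = chrom.removeprefix("chr")
    ref, alt = ref.upper(), alt.upper()
    if ref.startswith("<") or alt.startswith("<") or not ref or not alt:
        return f"{chrom}:{pos}:{ref}:{alt}"
    # trim common suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass(frozen=True)
class KnowledgeBaseEntry:
    variant_key: str
    source: str
    classification: str
    release: str = ""

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise KnowledgeBaseError(f"unknown source {self.source!r}")
        if self.classification not in CLASSIFICATIONS:
            raise KnowledgeBaseError(f"unknown classification {self.classification!r}")
        if self.classification == "DM" and self.source != "HGMD":
            raise KnowledgeBaseError("classification DM is reserved for source=HGMD")


@dataclass(frozen=True)
class AggregatedClass:
    verdict: Verdict
    supporting_sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.verdict is Verdict.none and self.supporting_sources:
            raise KnowledgeBaseError("verdict=none cannot cite sources")
        if self.verdict is not Verdict.none and not self.supporting_sources:
            raise KnowledgeBaseError(f"verdict={self.verdict} needs >=1 source")


class KnowledgeBase:
    """Set of entries indexed by normalized variant key."""

    def __init__(self, entries: Iterable[KnowledgeBaseEntry] = ()) -> None:
        self._by_key: dict[str, dict[str, KnowledgeBaseEntry]] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: KnowledgeBaseEntry) -> None:
        per_source = self._by_key.setdefault(entry.variant_key, {})
        if entry.source in per_source:
            raise KnowledgeBaseError(
                f"duplicate entry for {entry.variant_key} from {entry.source}"
            )
        per_source[entry.source] = entry

    def entries_for(self, variant_key: str) -> list[KnowledgeBaseEntry]:
        return list(self._by_key.get(variant_key, {}).values())

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_key.values())

    def __iter__(self):
        for per_source in self._by_key.values():
            yield from per_source.values()


def _aggregate(entries: Iterable[KnowledgeBaseEntry]) -> AggregatedClass:
    entries = list(entries)
    if not entries:
        return AggregatedClass(Verdict.none)
    path = sorted({e.source for e in entries if e.classification in PATHOGENIC_SIDE})
    benign = sorted({e.source for e in entries if e.classification in BENIGN_SIDE})
    if path and benign:
        return AggregatedClass(Verdict.conflicting, tuple(path + benign))
    if path:
        return AggregatedClass(Verdict.LP_or_P, tuple(path))
    vus = sorted(
        {e.source for e in entries if e.classification in ("VUS", "conflicting")}
    )
    if vus:
        # a source-level "conflicting" star rating is not conclusive either way
        return AggregatedClass(Verdict.VUS, tuple(vus))
    return AggregatedClass(Verdict.benign_or_likely_benign, tuple(benign))


def lookup_classification(
    variant: VariantRecord | str, kb: KnowledgeBase
) -> AggregatedClass:
    """Merged verdict for one variant across all sources in ``kb``."""
    key = variant if isinstance(variant, str) else variant.key
    return _aggregate(kb.entries_for(key))


def best_pathogenic_class(variant: VariantRecord | str, kb: KnowledgeBase) -> str:
    """"P" when any source reports P/DM, else "LP" (call only on LP_or_P)."""
    key = variant if isinstance(variant, str) else variant.key
    classes = {e.classification for e in kb.entries_for(key)}
    return "P" if classes & {"P", "DM"} else "LP"


KB_COLUMNS = ("chrom", "pos", "ref", "alt", "source", "classification", "release")


def load_knowledgebase(path: str | Path) -> KnowledgeBase:
    """Load a TSV knowledge base (columns: chrom pos ref alt source
    classification release); keys are normalized on the way in."""
    kb = KnowledgeBase()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(KB_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise KnowledgeBaseError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                key = normalize_variant_key(
                    row["chrom"], int(row["pos"]), row["ref"], row["alt"]
                )
                kb.add(
                    KnowledgeBaseEntry(
                        variant_key=key,
                        source=row["source"],
                        classification=row["classification"],
                        release=row.get("release", ""),
                    )
                )
            except (KnowledgeBaseError, ValueError) as exc:
                raise KnowledgeBaseError(f"{path}, line {i}: {exc}") from exc
    return kb


#: ClinVar CLNSIG strings -> closed vocabulary (optional adapter).
CLNSIG_MAP: Mapping[str, str] = {
    "Pathogenic": "P",
    "Likely_pathogenic": "LP",
    "Pathogenic/Likely_pathogenic": "P",
    "Uncertain_significance": "VUS",
    "Likely_benign": "LB",
    "Benign": "B",
    "Benign/Likely_benign": "B",
    "Conflicting_interpretations_of_pathogenicity": "conflicting",
    "Conflicting_classifications_of_pathogenicity": "conflicting",
}
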