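"""Domain types for variants, transcripts and gene panels.

This module defines the in-memory records the screening pipeline operates
on, plus three pieces of annotation logic that the filters depend on:

* :func:`classify_consequence` — place a variant in a transcript model and
  assign a single consequence class (truncating with/without escape from
  nonsense-mediated decay, canonical splice, ±3 splice region, UTR, ...).
* :func:`vaf_in_het_window` — the inclusive 40–60% variant-allele-fraction
  window used to call a het-looking allele.
* :func:`merge_adjacent_calls` — collapse separately called in-cis events
  into a single delins record.

Coordinates are 1-based fully closed genomic intervals (GRCh37 for the
shipped fixtures), matching g.-notation and VCF POS directly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from statistics import mean
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "VariantRecord",
    "PanelGene",
    "ConsequenceClass",
    "VariantDomainError",
    "TranscriptOverlapError",
    "classify_consequence",
    "classify_from_token",
    "vaf_in_het_window",
    "infer_zygosity",
    "merge_adjacent_calls",
    "SMALL_VARIANT_TYPES",
    "CNV_TYPES",
    "ZYGOSITIES",
    "VAR_TYPES",
    "CSQ_TOKENS",
]


class VariantDomainError(ValueError):
    """Invalid variant/transcript input."""


class TranscriptOverlapError(VariantDomainError):
    """Variant does not overlap the transcript it was paired with."""


SMALL_VARIANT_TYPES = frozenset({"SNV", "indel", "delins"})
CNV_TYPES = frozenset({"CNV_del", "CNV_dup"})
VAR_TYPES = SMALL_VARIANT_TYPES | CNV_TYPES
ZYGOSITIES = frozenset({"het", "hom", "hemi", "unknown"})
MOIS = frozenset({"AD", "AR", "XLR"})

#: Input consequence vocabulary (upstream annotation tokens).  Truncating
#: tokens are subject to the NMD-boundary split when transcript geometry is
#: available; without geometry they map to the NMD-sensitive class.
CSQ_TOKENS = frozenset(
    {
        "stop_gained",
        "frameshift",
        "start_lost",
        "stop_lost",
        "splice_acceptor",
        "splice_donor",
        "splice_region",
        "missense",
        "synonymous",
        "inframe_indel",
        "utr5",
        "utr3",
        "intronic",
        "other",
    }
)

#: Tokens describing a premature-termination-type event (NMD rule applies).
PTC_TOKENS = frozenset({"stop_gained", "frameshift"})
#: Truncating tokens exempt from the NMD exception: a start-loss removes the
#: initiator codon and a stop-loss extends the protein; neither produces a
#: premature stop that NMD could act on, so both stay filter-eligible.
NON_PTC_TRUNCATING_TOKENS = frozenset({"start_lost", "stop_lost"})
TRUNCATING_TOKENS = PTC_TOKENS | NON_PTC_TRUNCATING_TOKENS


class ConsequenceClass(str, enum.Enum):
    """Single most severe consequence of a (variant, transcript) pair."""

    truncating_nmd = "truncating_nmd"
    truncating_nmd_escape = "truncating_nmd_escape"
    canonical_splice = "canonical_splice"
    splice_region_pm3 = "splice_region_pm3"
    missense = "missense"
    synonymous = "synonymous"
    utr5 = "utr5"
    utr3 = "utr3"
    deep_intronic = "deep_intronic"
    other = "other"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    assembly: str = "GRCh37"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise VariantDomainError("chrom must be non-empty")
        if self.start > self.end:
            raise VariantDomainError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """Minimal transcript geometry: exons plus CDS bounds.

    Exons are stored in genomic order (ascending coordinates); ``strand``
    decides which end is 5'.  ``cds_start``/``cds_end`` are genomic
    positions of the first/last coding base (cds_start < cds_end
    genomically, regardless of strand).
    """

    transcript_id: str
    gene: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_start: int
    cds_end: int
    is_mane: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise VariantDomainError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise VariantDomainError("transcript needs at least one exon")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        for a, b in zip(exons, exons[1:]):
            if a.chrom != b.chrom:
                raise VariantDomainError("exons must share one chromosome")
            if a.end >= b.start:
                raise VariantDomainError("exons must be ordered and non-overlapping")
        if self.cds_start > self.cds_end:
            raise VariantDomainError("cds_start must be <= cds_end (genomic)")
        for pos in (self.cds_start, self.cds_end):
            if not any(e.contains(pos) for e in exons):
                raise VariantDomainError(f"CDS bound {pos} falls outside all exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    def exon_index_at(self, pos: int) -> Optional[int]:
        """Genomic-order index of the exon containing ``pos``, else None."""
        for i, e in enumerate(self.exons):
            if e.contains(pos):
                return i
        return None

    def coding_exons(self) -> list[GenomicInterval]:
        """Exon pieces intersected with the CDS, in genomic order."""
        out = []
        for e in self.exons:
            s, t = max(e.start, self.cds_start), min(e.end, self.cds_end)
            if s <= t:
                out.append(GenomicInterval(e.chrom, s, t))
        return out

    def cds_offset(self, pos: int) -> Optional[int]:
        """1-based coding-sequence offset of a genomic position (5'->3')."""
        pieces = self.coding_exons()
        if self.strand == "-":
            pieces = pieces[::-1]
        off = 0
        for p in pieces:
            if p.contains(pos):
                return off + (pos - p.start + 1 if self.strand == "+" else p.end - pos + 1)
            off += len(p)
        return None

    def cds_length(self) -> int:
        return sum(len(p) for p in self.coding_exons())

    def last_junction_cds_offset(self) -> Optional[int]:
        """CDS offset of the final exon–exon junction (end of the
        penultimate coding piece), or None for single-coding-exon models."""
        pieces = self.coding_exons()
        if len(pieces) < 2:
            return None
        if self.strand == "-":
            pieces = pieces[::-1]
        return sum(len(p) for p in pieces[:-1])


@dataclass(frozen=True)
class VariantRecord:
    """One observed variant in one individual."""

    locus: GenomicInterval
    ref: str
    alt: str
    gene: str
    var_type: str = "SNV"
    transcript_id: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    csq: Optional[str] = None  # upstream consequence token (CSQ_TOKENS)
    population_af: Optional[float] = None
    vaf: Optional[float] = None
    zygosity: str = "unknown"
    coverage_ok: bool = True
    raw_only: bool = False
    phase_group: Optional[str] = None  # shared id => variants known in cis
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.var_type not in VAR_TYPES:
            raise VariantDomainError(f"unknown var_type {self.var_type!r}")
        if self.zygosity not in ZYGOSITIES:
            raise VariantDomainError(f"unknown zygosity {self.zygosity!r}")
        if self.csq is not None and self.csq not in CSQ_TOKENS:
            raise VariantDomainError(f"unknown consequence token {self.csq!r}")
        for name in ("population_af", "vaf"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise VariantDomainError(f"{name}={v} outside [0, 1]")
        if self.var_type in CNV_TYPES:
            if self.zygosity == "unknown":
                raise VariantDomainError("CNV records need zygosity het/hom/hemi")
        elif self.var_type == "SNV":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise VariantDomainError(
                    f"SNV alleles must be single bases, got {self.ref!r}>{self.alt!r}"
                )

    @property
    def key(self) -> str:
        """Normalized lookup key (delegates to knowledgebase.normalize)."""
        from .knowledgebase import normalize_variant_key

        return normalize_variant_key(self.locus.chrom, self.locus.start, self.ref, self.alt)

    @property
    def is_small(self) -> bool:
        return self.var_type in SMALL_VARIANT_TYPES


@dataclass(frozen=True)
class PanelGene:
    gene: str
    moi: str
    disorder: str
    chrom: str
    mild_phenotype: bool = False

    def __post_init__(self) -> None:
        if self.moi not in MOIS:
            raise VariantDomainError(f"unknown MOI {self.moi!r} for {self.gene}")
        if self.moi == "XLR" and self.chrom not in ("X", "chrX"):
            raise VariantDomainError(f"XLR gene {self.gene} must be on chrX, got {self.chrom}")


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------

def classify_from_token(token: Optional[str], nmd_escape: bool = False) -> ConsequenceClass:
    """Map an upstream consequence token to a class, without geometry.

    Used when no transcript model is available; truncating tokens map to the
    NMD-sensitive class unless ``nmd_escape`` is set by the caller.
    """
    if token is None or token == "other":
        return ConsequenceClass.other
    if token not in CSQ_TOKENS:
        raise VariantDomainError(f"unknown consequence token {token!r}")
    if token in TRUNCATING_TOKENS:
        if token in PTC_TOKENS and nmd_escape:
            return ConsequenceClass.truncating_nmd_escape
        return ConsequenceClass.truncating_nmd
    return {
        "splice_acceptor": ConsequenceClass.canonical_splice,
        "splice_donor": ConsequenceClass.canonical_splice,
        "splice_region": ConsequenceClass.splice_region_pm3,
        "missense": ConsequenceClass.missense,
        "synonymous": ConsequenceClass.synonymous,
        "inframe_indel": ConsequenceClass.other,
        "utr5": ConsequenceClass.utr5,
        "utr3": ConsequenceClass.utr3,
        "intronic": ConsequenceClass.deep_intronic,
    }[token]


def _intron_offset(transcript: TranscriptModel, pos: int) -> Optional[int]:
    """Distance from an intronic position to the nearest exon boundary (>=1),
    or None when ``pos`` is exonic / outside the transcript."""
    if transcript.exon_index_at(pos) is not None:
        return None
    best: Optional[int] = None
    for e in transcript.exons:
        for boundary in (e.start, e.end):
            d = abs(pos - boundary)
            if best is None or d < best:
                best = d
    return best


def _ptc_escapes_nmd(transcript: TranscriptModel, pos: int, nmd_rule_nt: int) -> bool:
    """50-nt rule: a premature stop escapes NMD when it lies in the last
    exon or within ``nmd_rule_nt`` coding bases of the final junction."""
    junction = transcript.last_junction_cds_offset()
    if junction is None:  # single coding exon: no junction, no NMD
        return True
    off = transcript.cds_offset(pos)
    if off is None:
        return False
    return off > junction - nmd_rule_nt


def classify_consequence(
    variant: VariantRecord,
    transcript: TranscriptModel,
    *,
    nmd_rule_nt: int = 50,
    splice_window: int = 3,
) -> ConsequenceClass:
    """Assign the single consequence class of ``variant`` on ``transcript``.

    Intronic positions at offsets 1–2 from an exon boundary are canonical
    splice sites; offset 3 (up to ``splice_window``) is the ±3 splice
    region; deeper positions are deep-intronic.  Exonic positions are split
    into UTR vs coding by the CDS bounds; coding truncations of the
    premature-stop kind (stop-gain, frameshift) are tested against the NMD
    boundary.  Exon-boundary positions on the exon side are classified by
    their coding consequence, not as splice-region.
    """
    if variant.var_type in CNV_TYPES:
        # whole-exon scale events: a deletion is treated as gene-truncating
        return (
            ConsequenceClass.truncating_nmd
            if variant.var_type == "CNV_del"
            else ConsequenceClass.other
        )
    pos = variant.locus.start
    span = transcript.span
    if variant.locus.chrom != span.chrom or not (
        span.start - splice_window <= pos <= span.end + splice_window
    ):
        raise TranscriptOverlapError(
            f"variant at {variant.locus.chrom}:{pos} outside transcript "
            f"{transcript.transcript_id} ({span.chrom}:{span.start}-{span.end})"
        )

    offset = _intron_offset(transcript, pos)
    if offset is not None:  # intronic
        if offset <= 2:
            return ConsequenceClass.canonical_splice
        if offset <= splice_window:
            return ConsequenceClass.splice_region_pm3
        return ConsequenceClass.deep_intronic

    # exonic: UTR vs coding
    if pos < transcript.cds_start:
        return (
            ConsequenceClass.utr5
            if transcript.strand == "+"
            else ConsequenceClass.utr3
        )
    if pos > transcript.cds_end:
        return (
            ConsequenceClass.utr3
            if transcript.strand == "+"
            else ConsequenceClass.utr5
        )

    token = variant.csq
    if token in PTC_TOKENS:
        if _ptc_escapes_nmd(transcript, pos, nmd_rule_nt):
            return ConsequenceClass.truncating_nmd_escape
        return ConsequenceClass.truncating_nmd
    if token in NON_PTC_TRUNCATING_TOKENS:
        return ConsequenceClass.truncating_nmd
    if token in ("splice_acceptor", "splice_donor"):
        # annotated splice token on an exonic base: trust the annotation
        return ConsequenceClass.canonical_splice
    if token is not None and token not in ("intronic", "utr5", "utr3"):
        return classify_from_token(token)
    return ConsequenceClass.other


# ---------------------------------------------------------------------------
# VAF logic
# ---------------------------------------------------------------------------

def vaf_in_het_window(vaf: float, window: tuple[float, float] = (0.40, 0.60)) -> bool:
    """True iff ``vaf`` falls in the inclusive heterozygous window."""
    if not (0.0 <= vaf <= 1.0):
        raise VariantDomainError(f"vaf={vaf} outside [0, 1]")
    low, high = window
    return low <= vaf <= high


def infer_zygosity(
    vaf: float,
    window: tuple[float, float] = (0.40, 0.60),
    hom_vaf_min: float = 0.85,
) -> str:
    """het / hom / unknown from VAF alone (used when no genotype call).

    Unknown is never auto-promoted downstream.
    """
    if vaf_in_het_window(vaf, window):
        return "het"
    if vaf >= hom_vaf_min:
        return "hom"
    return "unknown"


# ---------------------------------------------------------------------------
# in-cis delins merging
# ---------------------------------------------------------------------------

def merge_adjacent_calls(
    variants: Sequence[VariantRecord],
    max_gap: int = 10,
    vaf_tol: float = 0.1,
) -> list[VariantRecord]:
    """Collapse runs of separately called in-cis events into one delins.

    Runs of SNV/indel calls from one gene where consecutive records are at
    most ``max_gap`` bp apart and the run's VAF spread is at most
    ``vaf_tol`` merge into a single delins whose VAF is the mean of the
    merged VAFs.  Existing delins and CNV records pass through untouched
    (which also makes the operation idempotent).  Input must be sorted by
    position.
    """
    variants = list(variants)
    for a, b in zip(variants, variants[1:]):
        if (a.locus.chrom, a.locus.start) > (b.locus.chrom, b.locus.start):
            raise VariantDomainError("merge_adjacent_calls requires position-sorted input")

    def mergeable(v: VariantRecord) -> bool:
        return v.var_type in ("SNV", "indel") and not v.raw_only

    out: list[VariantRecord] = []
    run: list[VariantRecord] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            first, last = run[0], run[-1]
            out.append(
                replace(
                    first,
                    locus=GenomicInterval(
                        first.locus.chrom,
                        first.locus.start,
                        last.locus.end,
                        first.locus.assembly,
                    ),
                    ref="".join(v.ref for v in run),
                    alt="".join(v.alt for v in run),
                    var_type="delins",
                    hgvs_c=None,
                    hgvs_p=None,
                    csq=first.csq,
                    vaf=round(mean(v.vaf for v in run), 6) if all(
                        v.vaf is not None for v in run
                    ) else None,
                )
            )
        run.clear()

    for v in variants:
        if not mergeable(v):
            flush()
            out.append(v)
            continue
        if run:
            prev = run[-1]
            close = (
                v.locus.chrom == prev.locus.chrom
                and v.locus.start - prev.locus.end <= max_gap
            )
            vafs = [x.vaf for x in run + [v]]
            vaf_ok = (
                all(x is not None for x in vafs)
                and max(vafs) - min(vafs) <= vaf_tol + 1e-12
            )
            if not (close and vaf_ok):
                flush()
        run.append(v)
    flush()
    return out
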