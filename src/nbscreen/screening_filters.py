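"""The two variant-selection strategies of the screening protocol.

Strict (L)P filter — a variant from a panel gene is kept iff its population
allele frequency is strictly below the cutoff (1% by default) AND at least
one branch applies:

(a) the knowledge base conclusively calls it P/LP (``db_lp``);
(b) it is truncating (premature stop not escaping NMD, start/stop-loss, or
    canonical ±1/2 splice) and absent from the databases
    (``truncating_novel``);
(c) it sits at an intronic ±3 splice-region position (``splice_pm3``).

Candidates then pass a review table standing in for the clinical laboratory
geneticist's ACMG evaluation (keep / downgrade-to-VUS / exclude).

VUS extension — for every autosomal-recessive or X-linked-recessive gene in
which exactly one P/LP candidate with a heterozygous-window VAF (40–60%)
was found, the sample's remaining rare variants in that gene that are VUS
(or rare, unlisted and non-synonymous) are surfaced as additional VUS
candidates.  The extension only ever adds VUS: the (L)P candidate set is
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .config import PipelineConfig
from .knowledgebase import (
    KnowledgeBase,
    Verdict,
    best_pathogenic_class,
    lookup_classification,
)
from .variant_domain import (
    ConsequenceClass,
    PanelGene,
    TranscriptModel,
    VariantDomainError,
    VariantRecord,
    classify_consequence,
    classify_from_token,
    vaf_in_het_window,
)

__all__ = [
    "SELECTION_REASONS",
    "REVIEW_DECISIONS",
    "CandidateVariant",
    "ReviewDecision",
    "strict_lp_filter",
    "apply_review",
    "vus_extension",
    "load_review_table",
]

logger = logging.getLogger(__name__)

SELECTION_REASONS = ("db_lp", "truncating_novel", "splice_pm3", "vus_extension")
WORKING_CLASSES = ("P", "LP", "VUS")
REVIEW_DECISIONS = (
    "keep_P",
    "keep_LP",
    "downgrade_VUS",
    "exclude_artefact",
    "exclude_cis",
    "exclude_irrelevant",
)

#: consequence classes eligible for the truncating branch of the strict
#: filter: NMD-sensitive truncations and canonical splice sites.
TRUNCATING_BRANCH = frozenset(
    {ConsequenceClass.truncating_nmd, ConsequenceClass.canonical_splice}
)


@dataclass(frozen=True)
class CandidateVariant:
    variant: VariantRecord
    selection_reason: str
    working_class: str
    reviewed: bool = False

    def __post_init__(self) -> None:
        if self.selection_reason not in SELECTION_REASONS:
            raise VariantDomainError(f"unknown selection_reason {self.selection_reason!r}")
        if self.working_class not in WORKING_CLASSES:
            raise VariantDomainError(f"unknown working_class {self.working_class!r}")
        if self.selection_reason == "db_lp" and self.working_class not in ("P", "LP"):
            if not self.reviewed:  # review may downgrade a db hit to VUS
                raise VariantDomainError("db_lp candidates start as P or LP")

    @property
    def key(self) -> str:
        return self.variant.key

    @property
    def is_lp(self) -> bool:
        return self.working_class in ("P", "LP")


@dataclass(frozen=True)
class ReviewDecision:
    variant_key: str
    decision: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.decision not in REVIEW_DECISIONS:
            raise VariantDomainError(f"unknown review decision {self.decision!r}")

    @property
    def is_exclusion(self) -> bool:
        return self.decision.startswith("exclude_")


def _sort_key(c: CandidateVariant):
    v = c.variant
    return (v.locus.chrom, v.locus.start, v.alt)


def _consequence(
    variant: VariantRecord,
    transcripts: Optional[Mapping[str, TranscriptModel]],
    config: PipelineConfig,
) -> ConsequenceClass:
    tx = (transcripts or {}).get(variant.gene)
    if tx is not None:
        return classify_consequence(
            variant,
            tx,
            nmd_rule_nt=config.nmd_rule_nt,
            splice_window=config.splice_window,
        )
    return classify_from_token(variant.csq)


def strict_lp_filter(
    variants: Sequence[VariantRecord],
    kb: KnowledgeBase,
    transcripts: Optional[Mapping[str, TranscriptModel]] = None,
    config: PipelineConfig | None = None,
    af_cutoff: float | None = None,
) -> list[CandidateVariant]:
    """Apply the strict (L)P filter to one sample's panel variants.

    Variants flagged ``raw_only`` were dropped by the upstream pipeline and
    are never seen here.  A missing population AF is an error: the AF gate
    must never silently pass.
    """
    config = config or PipelineConfig()
    cutoff = config.af_cutoff if af_cutoff is None else af_cutoff
    out: list[CandidateVariant] = []
    for v in variants:
        if v.raw_only:
            continue
        if v.population_af is None:
            raise VariantDomainError(
                f"variant {v.gene} {v.locus.chrom}:{v.locus.start} lacks population_af"
            )
        if not v.population_af < cutoff:
            continue
        verdict = lookup_classification(v, kb)
        if verdict.verdict is Verdict.LP_or_P:
            out.append(
                CandidateVariant(v, "db_lp", best_pathogenic_class(v, kb))
            )
            continue
        cls = _consequence(v, transcripts, config)
        if cls in TRUNCATING_BRANCH and verdict.verdict is Verdict.none:
            out.append(CandidateVariant(v, "truncating_novel", "LP"))
            continue
        if cls is ConsequenceClass.splice_region_pm3:
            out.append(CandidateVariant(v, "splice_pm3", "VUS"))
    return sorted(out, key=_sort_key)


def apply_review(
    candidates: Sequence[CandidateVariant],
    review: Sequence[ReviewDecision],
) -> list[CandidateVariant]:
    """Apply clinical-review decisions to filtered candidates.

    Exclusions (artefact / in-cis duplicate / irrelevant) drop the
    candidate; ``keep_P``/``keep_LP`` pin the class; ``downgrade_VUS``
    demotes to VUS.  Review keys with no matching candidate only warn —
    review tables may be cohort-global.
    """
    decisions = {d.variant_key: d for d in review}
    if len(decisions) != len(review):
        raise VariantDomainError("duplicate variant_key in review table")
    seen = set()
    out: list[CandidateVariant] = []
    for c in candidates:
        d = decisions.get(c.key)
        if d is None:
            out.append(c)
            continue
        seen.add(d.variant_key)
        if d.is_exclusion:
            continue
        new_class = {"keep_P": "P", "keep_LP": "LP", "downgrade_VUS": "VUS"}[d.decision]
        out.append(replace(c, working_class=new_class, reviewed=True))
    for key in decisions.keys() - seen:
        logger.warning("review decision for %s matched no candidate", key)
    return sorted(out, key=_sort_key)


def _vus_eligible(
    v: VariantRecord,
    kb: KnowledgeBase,
    transcripts: Optional[Mapping[str, TranscriptModel]],
    config: PipelineConfig,
) -> bool:
    """VUS-extension eligibility: KB VUS, or rare + unlisted + not
    synonymous (novel missense and the like must be reachable)."""
    if v.raw_only:
        return False
    if v.population_af is None or not v.population_af < config.af_cutoff:
        return False
    verdict = lookup_classification(v, kb).verdict
    if verdict is Verdict.VUS:
        return True
    if verdict is Verdict.none:
        cls = _consequence(v, transcripts, config)
        return cls is not ConsequenceClass.synonymous
    return False


def vus_extension(
    candidates: Sequence[CandidateVariant],
    all_variants: Sequence[VariantRecord],
    kb: KnowledgeBase,
    panel: Mapping[str, PanelGene],
    transcripts: Optional[Mapping[str, TranscriptModel]] = None,
    config: PipelineConfig | None = None,
) -> list[CandidateVariant]:
    """Extend the reviewed strict-filter output with same-gene VUS.

    Fires per gene, only for AR/XLR genes holding exactly one P/LP
    candidate whose VAF sits in the heterozygous window (``exactly_one``
    trigger mode; ``at_least_one`` relaxes the count).  Output is always a
    superset of the input candidate list.
    """
    config = config or PipelineConfig()
    by_gene: dict[str, list[CandidateVariant]] = {}
    for c in candidates:
        by_gene.setdefault(c.variant.gene, []).append(c)

    out = list(candidates)
    existing = {(c.variant.gene, c.key) for c in candidates}
    for gene, cands in by_gene.items():
        pg = panel.get(gene)
        if pg is None or pg.moi not in ("AR", "XLR"):
            continue
        lp = [c for c in cands if c.is_lp]
        windowed = [
            c
            for c in lp
            if c.variant.vaf is not None
            and vaf_in_het_window(c.variant.vaf, config.vaf_window)
        ]
        if config.vus_trigger_mode == "exactly_one":
            fired = len(lp) == 1 and len(windowed) == 1
        else:
            fired = len(windowed) >= 1
        if not fired:
            continue
        for v in all_variants:
            if v.gene != gene or (gene, v.key) in existing:
                continue
            if _vus_eligible(v, kb, transcripts, config):
                out.append(CandidateVariant(v, "vus_extension", "VUS"))
                existing.add((gene, v.key))
    return sorted(out, key=_sort_key)


def load_review_table(path) -> list[ReviewDecision]:
    """Read a review TSV (variant_key, decision, note)."""
    import csv

    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            try:
                out.append(
                    ReviewDecision(
                        variant_key=row["variant_key"],
                        decision=row["decision"],
                        note=row.get("note", ""),
                    )
                )
            except (KeyError, VariantDomainError) as exc:
                raise VariantDomainError(f"{path}, line {i}: {exc}") from exc
    return out
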