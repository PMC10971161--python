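"""Background-cohort assessment funnel.

Applies the screening protocol to a large cohort of presumed-healthy
individuals and reports auditable per-stage counts:

1.  individuals with no SNV/indel at all in the panel genes' coding and
    splicing regions;
2.  individuals with variants but no (L)P candidate after the strict filter;
3.  individuals whose (L)P variants fit the gene's mode of inheritance
    (pre-review);
4.  MOI-fit individuals surviving manual review (exclusion of in-cis delins
    called as separate events, sequencing artefacts, irrelevant variants);
5.  among the rest, individuals with exactly one (L)P het (VAF 40–60%) in
    an AR/XLR gene — the VUS-extension candidates;
6.  individuals gaining an MOI fit through the VUS extension (pre-review);
7.  and those surviving review of the extension findings.

Counts, not percentages, are the source of truth; the rendered report
rounds to whole percent.  The audit log records each individual's stage
assignment and reports stage-2 percentages against both the full-cohort
and the with-SNV denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .config import PipelineConfig
from .knowledgebase import KnowledgeBase
from .moi_screening import screen_sample
from .screening_filters import (
    CandidateVariant,
    ReviewDecision,
    apply_review,
    strict_lp_filter,
    vus_extension,
)
from .variant_domain import (
    PanelGene,
    TranscriptModel,
    VariantDomainError,
    VariantRecord,
    vaf_in_het_window,
)

__all__ = ["FunnelCounts", "ReviewQueueItem", "FunnelResult", "run_funnel", "funnel_report"]


@dataclass
class FunnelCounts:
    total: int = 0
    no_snv: int = 0
    no_lp: int = 0
    moi_fit_prereview: int = 0
    moi_fit_postreview: int = 0
    single_lp_het: int = 0
    vus_moi_fit_prereview: int = 0
    vus_moi_fit_postreview: int = 0

    def validate(self) -> None:
        c = self
        checks = [
            c.moi_fit_postreview <= c.moi_fit_prereview,
            c.vus_moi_fit_postreview <= c.vus_moi_fit_prereview,
            c.no_snv + c.no_lp + c.moi_fit_prereview <= c.total,
            c.single_lp_het <= c.total - c.no_snv - c.no_lp - c.moi_fit_prereview,
            c.vus_moi_fit_prereview <= c.single_lp_het,
        ]
        if not all(checks):
            raise VariantDomainError(f"inconsistent funnel counts: {c}")


@dataclass(frozen=True)
class ReviewQueueItem:
    individual_id: str
    gene: str
    variant_keys: tuple[str, ...]
    stage: str  # lp_moi_fit | vus_extension


@dataclass
class FunnelResult:
    counts: FunnelCounts
    review_queue: list[ReviewQueueItem]
    survivors: list[str]  # post-review positive individuals (stages 4 + 7)
    audit: dict[str, dict]


def _has_small_variant(variants: Sequence[VariantRecord]) -> bool:
    return any(v.is_small and not v.raw_only for v in variants)


def run_funnel(
    cohort: Sequence[tuple[str, Sequence[VariantRecord]]],
    panel: Mapping[str, PanelGene],
    kb: KnowledgeBase,
    review: Sequence[ReviewDecision] = (),
    config: PipelineConfig | None = None,
    transcripts: Optional[Mapping[str, TranscriptModel]] = None,
) -> FunnelResult:
    """Run the staged assessment funnel over a cohort.

    ``cohort`` is a sequence of (individual_id, variants); every variant
    must come from a panel gene (the virtual panel is enforced, not
    re-applied).
    """
    config = config or PipelineConfig()
    counts = FunnelCounts(total=len(cohort))
    queue: list[ReviewQueueItem] = []
    survivors: list[str] = []
    audit: dict[str, dict] = {}

    for ind_id, variants in cohort:
        for v in variants:
            if v.gene not in panel:
                raise VariantDomainError(
                    f"{ind_id}: variant in non-panel gene {v.gene}"
                )
        entry: dict = {"stage": None}
        audit[ind_id] = entry

        # stage 1: any SNV/indel at all
        if not _has_small_variant(variants):
            counts.no_snv += 1
            entry["stage"] = "no_snv"
            continue

        # stage 2: strict (L)P filter
        cands = strict_lp_filter(variants, kb, transcripts, config)
        lp = [c for c in cands if c.is_lp]
        if not lp:
            counts.no_lp += 1
            entry["stage"] = "no_lp"
            continue

        # stage 3: MOI fit, pre-review
        strict_res = screen_sample(ind_id, cands, panel, "strict", config)
        prereview_fit = strict_res.overall == "positive"
        if prereview_fit:
            counts.moi_fit_prereview += 1
            entry["stage"] = "moi_fit"
            for f in strict_res.findings:
                if f.call == "positive":
                    queue.append(
                        ReviewQueueItem(
                            ind_id,
                            f.gene,
                            tuple(c.key for c in f.lp_variants),
                            "lp_moi_fit",
                        )
                    )
            # stage 4: review
            reviewed = apply_review(cands, review)
            post = screen_sample(ind_id, reviewed, panel, "strict", config)
            if post.overall == "positive":
                counts.moi_fit_postreview += 1
                entry["post_review_positive"] = True
                survivors.append(ind_id)
            continue

        # stage 5: single (L)P het in the window, AR/XLR gene
        reviewed = apply_review(cands, review)
        lp_reviewed = [c for c in reviewed if c.is_lp]
        single = (
            len(lp_reviewed) == 1
            and lp_reviewed[0].variant.zygosity == "het"
            and lp_reviewed[0].variant.vaf is not None
            and vaf_in_het_window(lp_reviewed[0].variant.vaf, config.vaf_window)
            and panel[lp_reviewed[0].variant.gene].moi in ("AR", "XLR")
        )
        if not single:
            entry["stage"] = "lp_no_moi_fit"
            continue
        counts.single_lp_het += 1
        entry["stage"] = "single_lp_het"

        # stage 6: VUS extension + extended screen (pre-review)
        extended = vus_extension(reviewed, variants, kb, panel, transcripts, config)
        ext_res = screen_sample(ind_id, extended, panel, "extended", config)
        if ext_res.overall != "positive":
            continue
        counts.vus_moi_fit_prereview += 1
        entry["vus_moi_fit"] = True
        for f in ext_res.findings:
            if f.call == "positive":
                queue.append(
                    ReviewQueueItem(
                        ind_id,
                        f.gene,
                        tuple(c.key for c in f.lp_variants + f.vus_variants),
                        "vus_extension",
                    )
                )
        # stage 7: review of the extension findings
        ext_reviewed = apply_review(extended, review)
        post = screen_sample(ind_id, ext_reviewed, panel, "extended", config)
        if post.overall == "positive":
            counts.vus_moi_fit_postreview += 1
            entry["post_review_positive"] = True
            survivors.append(ind_id)

    counts.validate()
    with_snv = counts.total - counts.no_snv
    audit["_denominators"] = {
        "total": counts.total,
        "with_snv": with_snv,
        "no_lp_pct_of_total": _pct(counts.no_lp, counts.total),
        "no_lp_pct_of_with_snv": _pct(counts.no_lp, with_snv),
    }
    return FunnelResult(counts=counts, review_queue=queue, survivors=survivors, audit=audit)


def _pct(part: int, whole: int) -> int:
    return round(100.0 * part / whole) if whole else 0


_REPORT_ROWS = (
    ("total", "individuals assessed"),
    ("no_snv", "no SNV/indel in any panel gene"),
    ("no_lp", "variants present, no (L)P after strict filter"),
    ("moi_fit_prereview", "(L)P number/zygosity fits MOI (pre-review)"),
    ("moi_fit_postreview", "MOI fit surviving review"),
    ("single_lp_het", "single (L)P het (VAF 40-60%) in AR/XLR gene"),
    ("vus_moi_fit_prereview", "MOI fit gained via VUS extension (pre-review)"),
    ("vus_moi_fit_postreview", "VUS-extension fit surviving review"),
)


def funnel_report(counts: FunnelCounts) -> str:
    """Render the funnel as a fixed-order TSV-style table with whole-percent
    rates against the cohort total."""
    if counts.total == 0:
        raise VariantDomainError("cannot report a funnel over zero individuals")
    lines = ["stage\tcount\tpercent"]
    for attr, label in _REPORT_ROWS:
        n = getattr(counts, attr)
        lines.append(f"{label}\t{n}\t{_pct(n, counts.total)}%")
    return "\n".join(lines)
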