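"""Mode-of-inheritance screening calls and carriership detection.

Given a sample's classified candidate variants, each panel gene receives a
call:

* **AD** — one (L)P allele suffices: any P/LP candidate makes the gene
  positive.
* **AR** — two pathogenic alleles are required: homozygous, compound
  heterozygous (assumed in trans unless phased in cis), hemizygous behind a
  deleting CNV, or CNV + small variant.  Exactly one heterozygous (L)P is
  a carrier.  Under the extended strategy, one het (L)P plus at least one
  het VUS in the same gene is positive.
* **XLR** — hemizygous or homozygous (L)P is positive; a heterozygous (L)P
  is a carrier; the extended rule applies as for AR.

Carriership is a single heterozygous (L)P with a 40–60% VAF in an AR gene;
it is computed for every sample but flagged non-reportable by default, as a
carrier state is not itself a screening target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .config import PipelineConfig
from .screening_filters import CandidateVariant
from .variant_domain import PanelGene, VariantDomainError, vaf_in_het_window

__all__ = [
    "GeneFinding",
    "ScreenResult",
    "Carriership",
    "allele_count",
    "screen_gene",
    "screen_sample",
    "detect_carriership",
]

CALLS = ("positive", "carrier", "negative")
STRATEGIES = ("strict", "extended")


@dataclass(frozen=True)
class GeneFinding:
    gene: str
    moi: str
    lp_variants: tuple[CandidateVariant, ...]
    vus_variants: tuple[CandidateVariant, ...]
    call: str

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise VariantDomainError(f"unknown call {self.call!r}")
        lp_keys = {c.key for c in self.lp_variants}
        if lp_keys & {c.key for c in self.vus_variants}:
            raise VariantDomainError(f"{self.gene}: lp/vus candidate lists overlap")


@dataclass(frozen=True)
class ScreenResult:
    sample_id: str
    strategy: str
    overall: str  # positive / negative / inconclusive
    findings: tuple[GeneFinding, ...]

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise VariantDomainError(f"unknown strategy {self.strategy!r}")
        any_pos = any(f.call == "positive" for f in self.findings)
        if (self.overall == "positive") != any_pos and self.overall != "inconclusive":
            raise VariantDomainError(
                f"{self.sample_id}: overall={self.overall} inconsistent with findings"
            )

    @property
    def positive_genes(self) -> tuple[str, ...]:
        return tuple(f.gene for f in self.findings if f.call == "positive")


@dataclass(frozen=True)
class Carriership:
    sample_id: str
    gene: str
    variant_key: str
    vaf: Optional[float]
    reportable: bool = False  # carrier states are outside the screening scope


def allele_count(variants: Sequence[CandidateVariant]) -> int:
    """Pathogenic-allele count for one gene's (L)P candidates.

    hom -> 2; het -> 1; hemizygous -> 2 (no second allele exists to mutate);
    a deleting CNV over the gene -> 1 per copy lost.  Variants sharing a
    phase group (known in cis) count once, as the max of their individual
    contributions.
    """
    genes = {c.variant.gene for c in variants}
    if len(genes) > 1:
        raise VariantDomainError(f"allele_count mixes genes: {sorted(genes)}")

    def one(c: CandidateVariant) -> int:
        v = c.variant
        if v.var_type == "CNV_dup":
            return 0
        if v.zygosity == "hom":
            return 2
        if v.zygosity == "hemi":
            return 2
        if v.zygosity == "het":
            return 1
        return 0  # unknown zygosity is never auto-promoted

    groups: dict[str, list[int]] = {}
    total = 0
    for i, c in enumerate(variants):
        g = c.variant.phase_group
        if g is None:
            total += one(c)
        else:
            groups.setdefault(g, []).append(one(c))
    total += sum(max(v) for v in groups.values())
    return total


def screen_gene(
    gene: str,
    moi: str,
    candidates: Sequence[CandidateVariant],
    strategy: str = "strict",
    config: PipelineConfig | None = None,
) -> GeneFinding:
    """Screening call for one gene of one sample."""
    if strategy not in STRATEGIES:
        raise VariantDomainError(f"unknown strategy {strategy!r}")
    config = config or PipelineConfig()
    lp = tuple(c for c in candidates if c.is_lp)
    vus = tuple(c for c in candidates if not c.is_lp)

    het_lp = [c for c in lp if c.variant.zygosity == "het"]
    het_vus = [c for c in vus if c.variant.zygosity == "het"]
    n_alleles = allele_count(lp)

    call = "negative"
    if moi == "AD":
        if lp:
            call = "positive"
    elif moi == "AR":
        if n_alleles >= 2:
            call = "positive"
        elif len(lp) == 1 and len(het_lp) == 1:
            if strategy == "extended" and het_vus:
                call = "positive"
            else:
                call = "carrier"
    elif moi == "XLR":
        if any(c.variant.zygosity in ("hemi", "hom") for c in lp):
            call = "positive"
        elif len(het_lp) >= 1:
            if strategy == "extended" and len(lp) == 1 and het_vus:
                call = "positive"
            else:
                call = "carrier"
    else:
        raise VariantDomainError(f"unknown MOI {moi!r} for gene {gene}")
    return GeneFinding(gene=gene, moi=moi, lp_variants=lp, vus_variants=vus, call=call)


def screen_sample(
    sample_id: str,
    candidates: Sequence[CandidateVariant],
    panel: Mapping[str, PanelGene],
    strategy: str = "strict",
    config: PipelineConfig | None = None,
) -> ScreenResult:
    """Per-sample screening result across all genes with candidates."""
    by_gene: dict[str, list[CandidateVariant]] = {}
    for c in candidates:
        gene = c.variant.gene
        if gene not in panel:
            raise VariantDomainError(
                f"{sample_id}: gene {gene} is not on the panel (virtual panel violated)"
            )
        by_gene.setdefault(gene, []).append(c)
    findings = tuple(
        screen_gene(gene, panel[gene].moi, cands, strategy, config)
        for gene, cands in sorted(by_gene.items())
    )
    overall = "positive" if any(f.call == "positive" for f in findings) else "negative"
    return ScreenResult(
        sample_id=sample_id, strategy=strategy, overall=overall, findings=findings
    )


def detect_carriership(
    results: Iterable[ScreenResult],
    config: PipelineConfig | None = None,
) -> list[Carriership]:
    """All AR-gene carrier findings whose (L)P variant has a het-window VAF.

    Positivity and carriership are mutually exclusive per gene, so a gene
    called positive never also emits a carriership.
    """
    config = config or PipelineConfig()
    out: list[Carriership] = []
    for r in results:
        for f in r.findings:
            if f.call != "carrier" or f.moi != "AR":
                continue
            for c in f.lp_variants:
                v = c.variant
                if v.vaf is not None and vaf_in_het_window(v.vaf, config.vaf_window):
                    out.append(
                        Carriership(
                            sample_id=r.sample_id,
                            gene=f.gene,
                            variant_key=c.key,
                            vaf=v.vaf,
                        )
                    )
    return out
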