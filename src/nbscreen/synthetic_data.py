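"""Synthetic panels, knowledge bases and cohorts.

No raw sequencing data accompanies the screening study this package
models, so every pipeline stage is exercised on generated data with the
statistical structure the analysis assumes:

* a gene panel with toy transcript models (2–10 exons) and a knowledge
  base seeded with per-gene (L)P, VUS and benign sites;
* patients carrying a planted causal genotype consistent with the gene's
  mode of inheritance (homozygous (L)P, compound het, (L)P + VUS, XLR
  hemizygous, AD het, CNV + small variant, or the known-limitation
  homozygous-VUS case);
* negative controls and a large background cohort with Poisson noise
  variants, population carriers of single (L)P alleles, and a rare
  homozygous (L)P in a mild-phenotype gene.

Default rates are chosen so that a large background cohort funnels like a
general population screened on a ~100-gene metabolic panel: about 7% of
individuals with no variant at all in the panel, ~70% with variants but
nothing (likely) pathogenic, and ~22% carrying exactly one heterozygous
(L)P allele.  The derivation of those defaults is in the methods note;
they are fixed, not fitted per run.

All randomness flows from ``numpy.random.default_rng(seed)``; a fixed seed
reproduces a cohort exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .knowledgebase import KnowledgeBase, KnowledgeBaseEntry, normalize_variant_key
from .outcome_scoring import TruthRecord
from .variant_domain import (
    GenomicInterval,
    PanelGene,
    TranscriptModel,
    VariantDomainError,
    VariantRecord,
)

__all__ = [
    "SimConfig",
    "SiteSpec",
    "PanelBundle",
    "SyntheticCohort",
    "GENOTYPE_TYPES",
    "PLANT_EXPECTATIONS",
    "generate_panel",
    "generate_patient",
    "generate_background_cohort",
    "generate_controls",
    "generate_test_cohort",
]

BASES = ("A", "C", "G", "T")

#: causal genotype kinds a patient can be planted with
GENOTYPE_TYPES = (
    "hom_lp",
    "compound_het",
    "lp_plus_vus",
    "hom_vus",
    "xlr_hemi",
    "ad_het",
    "cnv_plus_snv",
)

#: expected screening outcome per planted genotype, as (strict-positive,
#: extended-positive) — a direct transcription of the MOI rules, usable as
#: an oracle against the pipeline.
PLANT_EXPECTATIONS: Mapping[str, tuple[bool, bool]] = {
    "hom_lp": (True, True),
    "compound_het": (True, True),
    "lp_plus_vus": (False, True),
    "hom_vus": (False, False),
    "xlr_hemi": (True, True),
    "ad_het": (True, True),
    "cnv_plus_snv": (True, True),
}


def _check_mix(name: str, mix: Mapping[str, float]) -> None:
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise VariantDomainError(f"{name} proportions must sum to 1, got {mix}")
    if any(v < 0 for v in mix.values()):
        raise VariantDomainError(f"{name} proportions must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (see module docstring for the calibration)."""

    seed: int = 0
    n_genes: int = 100
    moi_mix: Mapping[str, float] = field(
        default_factory=lambda: {"AD": 0.10, "AR": 0.85, "XLR": 0.05}
    )
    #: mean panel variants per individual per gene (Poisson noise)
    per_gene_variant_rate: float = 0.024
    #: class mix of *rare* noise variants; rare (L)P alleles in the
    #: background are modelled by carrier_rate, not here
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"lp": 0.0, "vus": 0.35, "benign": 0.35, "unlisted": 0.30}
    )
    rare_fraction: float = 0.6
    rare_af_range: tuple[float, float] = (1e-6, 5e-3)  # log-uniform
    common_af_range: tuple[float, float] = (0.01, 0.5)  # uniform
    vaf_noise_sd: float = 0.05
    vaf_clip: tuple[float, float] = (0.35, 0.65)
    carrier_rate: float = 0.23
    hom_lp_rate: float = 3 / 4833
    n_mild_genes: int = 3
    sites_per_class: int = 6
    patient_moi_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "hom_lp": 0.17,
            "compound_het": 0.40,
            "lp_plus_vus": 0.21,
            "hom_vus": 0.09,
            "xlr_hemi": 0.04,
            "ad_het": 0.05,
            "cnv_plus_snv": 0.04,
        }
    )

    def __post_init__(self) -> None:
        _check_mix("moi_mix", self.moi_mix)
        _check_mix("class_mix", self.class_mix)
        _check_mix("patient_moi_fractions", self.patient_moi_fractions)
        if set(self.patient_moi_fractions) - set(GENOTYPE_TYPES):
            raise VariantDomainError("unknown genotype type in patient_moi_fractions")
        if self.n_genes < 1 or self.per_gene_variant_rate < 0:
            raise VariantDomainError("n_genes >= 1 and non-negative rate required")


class SiteSpec(NamedTuple):
    """A known variant site of a synthetic gene."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    csq: str
    population_af: float

    @property
    def key(self) -> str:
        return normalize_variant_key(self.chrom, self.pos, self.ref, self.alt)


class PanelBundle(NamedTuple):
    panel: dict[str, PanelGene]
    transcripts: dict[str, TranscriptModel]
    kb: KnowledgeBase
    sites: dict[str, dict[str, list[SiteSpec]]]  # gene -> class -> sites


@dataclass
class SyntheticCohort:
    individuals: list[tuple[str, str, list[VariantRecord]]]  # (id, role, variants)
    truth: list[TruthRecord]
    panel: dict[str, PanelGene]
    transcripts: dict[str, TranscriptModel]
    kb: KnowledgeBase

    def as_funnel_input(self) -> list[tuple[str, list[VariantRecord]]]:
        return [(sid, variants) for sid, _, variants in self.individuals]


# ---------------------------------------------------------------------------
# panel, transcripts and knowledge base
# ---------------------------------------------------------------------------

def _toy_transcript(gene: str, chrom: str, origin: int, rng: np.random.Generator) -> TranscriptModel:
    n_exons = int(rng.integers(2, 11))
    exons = []
    pos = origin
    for _ in range(n_exons):
        length = int(rng.integers(120, 301))
        exons.append(GenomicInterval(chrom, pos, pos + length - 1))
        pos += length + int(rng.integers(500, 2001))
    # CDS starts/ends comfortably inside the first/last exon so UTR
    # positions exist on both sides
    cds_start = exons[0].start + 30
    cds_end = exons[-1].end - 30
    return TranscriptModel(
        transcript_id=f"TX_{gene}.1",
        gene=gene,
        strand="+",
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
        is_mane=True,
    )


def _coding_positions(tx: TranscriptModel, rng: np.random.Generator, n: int) -> list[int]:
    """Distinct mid-exon coding positions (>= 4 bp from exon boundaries so
    geometry never reads them as splice-region)."""
    pool: list[int] = []
    for e in tx.coding_exons():
        lo, hi = e.start + 4, e.end - 4
        if lo <= hi:
            pool.extend(range(lo, hi + 1))
    if len(pool) < n:
        raise VariantDomainError(f"transcript {tx.transcript_id} too small for {n} sites")
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def generate_panel(config: SimConfig) -> PanelBundle:
    """Generate a toy panel with transcripts and a seeded knowledge base.

    XLR genes are always placed on chromosome X regardless of where the
    round-robin chromosome assignment would have put them.
    """
    rng = np.random.default_rng(config.seed)
    mois = rng.choice(
        list(config.moi_mix), size=config.n_genes, p=list(config.moi_mix.values())
    )
    panel: dict[str, PanelGene] = {}
    transcripts: dict[str, TranscriptModel] = {}
    kb = KnowledgeBase()
    sites: dict[str, dict[str, list[SiteSpec]]] = {}
    n_mild = 0
    for i, moi in enumerate(mois):
        gene = f"G{i + 1:03d}"
        chrom = "X" if moi == "XLR" else str((i % 22) + 1)
        mild = moi == "AR" and n_mild < config.n_mild_genes
        if mild:
            n_mild += 1
        panel[gene] = PanelGene(
            gene=gene,
            moi=str(moi),
            disorder=f"synthetic disorder {i + 1}",
            chrom=chrom,
            mild_phenotype=mild,
        )
        tx = _toy_transcript(gene, chrom, origin=1_000_000 + i * 100_000, rng=rng)
        transcripts[gene] = tx
        per_class: dict[str, list[SiteSpec]] = {"lp": [], "vus": [], "benign": []}
        n_sites = 3 * config.sites_per_class
        positions = _coding_positions(tx, rng, n_sites)
        for j, pos in enumerate(positions):
            ref, alt = rng.choice(BASES, size=2, replace=False)
            cls = ("lp", "vus", "benign")[j % 3]
            af = float(
                10 ** rng.uniform(*np.log10(config.rare_af_range))
                if cls != "benign"
                else rng.uniform(*config.common_af_range) * 0.5
            )
            # benign sites stay rare enough to pass the AF gate sometimes;
            # their benign verdict is what keeps them out of the filter
            if cls == "benign":
                af = float(10 ** rng.uniform(*np.log10(config.rare_af_range)))
            site = SiteSpec(gene, chrom, int(pos), str(ref), str(alt), "missense", af)
            per_class[cls].append(site)
            kb_class = {"lp": ("P" if j % 2 else "LP"), "vus": "VUS", "benign": "B"}[cls]
            source = "ClinVar" if cls != "benign" else "VKGL"
            kb.add(
                KnowledgeBaseEntry(
                    variant_key=site.key,
                    source=source,
                    classification=kb_class,
                    release="sim",
                )
            )
        sites[gene] = per_class
    return PanelBundle(panel=panel, transcripts=transcripts, kb=kb, sites=sites)


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------

def _het_vaf(config: SimConfig, rng: np.random.Generator) -> float:
    lo, hi = config.vaf_clip
    return float(np.clip(rng.normal(0.5, config.vaf_noise_sd), lo, hi))


def _hom_vaf(rng: np.random.Generator) -> float:
    return float(np.clip(rng.normal(0.98, 0.01), 0.9, 1.0))


def _site_variant(
    site: SiteSpec,
    zygosity: str,
    vaf: float,
    sample_id: str,
) -> VariantRecord:
    return VariantRecord(
        locus=GenomicInterval(site.chrom, site.pos, site.pos),
        ref=site.ref,
        alt=site.alt,
        gene=site.gene,
        var_type="SNV",
        csq=site.csq,
        population_af=site.population_af,
        vaf=vaf,
        zygosity=zygosity,
        sample_id=sample_id,
    )


def _noise_variants(
    config: SimConfig,
    bundle: PanelBundle,
    rng: np.random.Generator,
    sample_id: str,
    exclude_gene: Optional[str] = None,
) -> list[VariantRecord]:
    genes = [g for g in bundle.panel if g != exclude_gene]
    if not genes:
        return []
    lam = config.per_gene_variant_rate * len(genes)
    n = int(rng.poisson(lam))
    out: list[VariantRecord] = []
    used: set[str] = set()
    classes = list(config.class_mix)
    weights = list(config.class_mix.values())
    for _ in range(n):
        gene = genes[int(rng.integers(len(genes)))]
        tx = bundle.transcripts[gene]
        rare = bool(rng.random() < config.rare_fraction)
        if rare:
            cls = str(rng.choice(classes, p=weights))
        else:
            cls = "unlisted"
        if cls in ("lp", "vus", "benign"):
            pool = bundle.sites[gene][cls]
            site = pool[int(rng.integers(len(pool)))]
            if site.key in used:
                continue
            used.add(site.key)
            out.append(_site_variant(site, "het", _het_vaf(config, rng), sample_id))
        else:
            pos = _coding_positions(tx, rng, 1)[0]
            ref, alt = rng.choice(BASES, size=2, replace=False)
            key = f"{tx.chrom}:{pos}"
            if key in used:
                continue
            used.add(key)
            af = (
                float(10 ** rng.uniform(*np.log10(config.rare_af_range)))
                if rare
                else float(rng.uniform(*config.common_af_range))
            )
            csq = str(rng.choice(["missense", "synonymous", "intronic"], p=[0.6, 0.25, 0.15]))
            out.append(
                VariantRecord(
                    locus=GenomicInterval(tx.chrom, int(pos), int(pos)),
                    ref=str(ref),
                    alt=str(alt),
                    gene=gene,
                    var_type="SNV",
                    csq=csq,
                    population_af=af,
                    vaf=_het_vaf(config, rng),
                    zygosity="het",
                    sample_id=sample_id,
                )
            )
    return out


def _pick_gene(bundle: PanelBundle, rng: np.random.Generator, mois: tuple[str, ...]) -> str:
    pool = sorted(g for g, pg in bundle.panel.items() if pg.moi in mois)
    if not pool:
        raise VariantDomainError(f"no panel gene with MOI in {mois}")
    return pool[int(rng.integers(len(pool)))]


def generate_patient(
    config: SimConfig,
    bundle: PanelBundle,
    rng: np.random.Generator,
    sample_id: str,
    genotype_type: Optional[str] = None,
) -> tuple[list[VariantRecord], TruthRecord, str]:
    """Plant one causal genotype plus background noise.

    Returns (variants, truth record, genotype type).  Noise is kept out of
    the causal gene so the planted genotype alone determines the expected
    call for that gene.
    """
    if genotype_type is None:
        genotype_type = str(
            rng.choice(
                list(config.patient_moi_fractions),
                p=list(config.patient_moi_fractions.values()),
            )
        )
    g = genotype_type
    planted: list[VariantRecord] = []
    if g in ("hom_lp", "compound_het", "lp_plus_vus", "hom_vus", "cnv_plus_snv"):
        gene = _pick_gene(bundle, rng, ("AR",))
    elif g == "xlr_hemi":
        gene = _pick_gene(bundle, rng, ("XLR",))
    elif g == "ad_het":
        gene = _pick_gene(bundle, rng, ("AD",))
    else:
        raise VariantDomainError(f"unknown genotype type {g!r}")
    lp_sites = bundle.sites[gene]["lp"]
    vus_sites = bundle.sites[gene]["vus"]

    if g == "hom_lp":
        planted.append(_site_variant(lp_sites[0], "hom", _hom_vaf(rng), sample_id))
    elif g == "compound_het":
        planted.append(_site_variant(lp_sites[0], "het", _het_vaf(config, rng), sample_id))
        planted.append(_site_variant(lp_sites[1], "het", _het_vaf(config, rng), sample_id))
    elif g == "lp_plus_vus":
        planted.append(_site_variant(lp_sites[0], "het", _het_vaf(config, rng), sample_id))
        planted.append(_site_variant(vus_sites[0], "het", _het_vaf(config, rng), sample_id))
    elif g == "hom_vus":
        planted.append(_site_variant(vus_sites[0], "hom", _hom_vaf(rng), sample_id))
    elif g == "xlr_hemi":
        planted.append(_site_variant(lp_sites[0], "hemi", _hom_vaf(rng), sample_id))
    elif g == "ad_het":
        planted.append(_site_variant(lp_sites[0], "het", _het_vaf(config, rng), sample_id))
    elif g == "cnv_plus_snv":
        tx = bundle.transcripts[gene]
        planted.append(
            VariantRecord(
                locus=GenomicInterval(tx.chrom, tx.span.start - 100, tx.span.end + 100),
                ref="N",
                alt="<DEL>",
                gene=gene,
                var_type="CNV_del",
                population_af=0.0,
                vaf=_het_vaf(config, rng),
                zygosity="het",
                sample_id=sample_id,
            )
        )
        # the remaining allele carries a small (L)P variant, hemizygous
        # behind the deletion
        planted.append(_site_variant(lp_sites[0], "hemi", _hom_vaf(rng), sample_id))

    variants = planted + _noise_variants(config, bundle, rng, sample_id, exclude_gene=gene)
    truth = TruthRecord(
        sample_id=sample_id,
        cohort_role="patient",
        diagnosis_gene=gene,
        known_variants=tuple((v.key, gene, v.zygosity) for v in planted),
    )
    return variants, truth, g


def _background_individual(
    config: SimConfig,
    bundle: PanelBundle,
    rng: np.random.Generator,
    sample_id: str,
) -> list[VariantRecord]:
    variants = _noise_variants(config, bundle, rng, sample_id)
    if rng.random() < config.carrier_rate:
        gene = _pick_gene(bundle, rng, ("AR", "XLR"))
        pool = bundle.sites[gene]["lp"]
        site = pool[int(rng.integers(len(pool)))]
        variants.append(_site_variant(site, "het", _het_vaf(config, rng), sample_id))
    if rng.random() < config.hom_lp_rate:
        mild = sorted(g for g, pg in bundle.panel.items() if pg.mild_phenotype)
        if mild:
            gene = mild[int(rng.integers(len(mild)))]
            variants.append(
                _site_variant(bundle.sites[gene]["lp"][0], "hom", _hom_vaf(rng), sample_id)
            )
    return variants


def generate_background_cohort(
    config: SimConfig,
    bundle: PanelBundle | None = None,
    n: int = 1000,
) -> SyntheticCohort:
    """Cohort of presumed-healthy individuals (no planted disease genotype
    beyond the rare mild-phenotype homozygote)."""
    if n < 1:
        raise VariantDomainError("n must be >= 1")
    bundle = bundle or generate_panel(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    individuals = []
    truth = []
    for i in range(n):
        sid = f"B{i + 1:06d}"
        individuals.append((sid, "background", _background_individual(config, bundle, rng, sid)))
        truth.append(TruthRecord(sample_id=sid, cohort_role="background"))
    return SyntheticCohort(individuals, truth, bundle.panel, bundle.transcripts, bundle.kb)


def generate_controls(
    config: SimConfig,
    bundle: PanelBundle | None = None,
    n: int = 50,
) -> SyntheticCohort:
    """Negative controls: background-structured individuals labelled as
    controls (carrier alleles allowed; carriers are not positives)."""
    bundle = bundle or generate_panel(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    individuals = []
    truth = []
    for i in range(n):
        sid = f"C{i + 1:04d}"
        individuals.append((sid, "control", _background_individual(config, bundle, rng, sid)))
        truth.append(TruthRecord(sample_id=sid, cohort_role="control"))
    return SyntheticCohort(individuals, truth, bundle.panel, bundle.transcripts, bundle.kb)


def generate_test_cohort(
    config: SimConfig,
    n_patients: int = 50,
    n_controls: int = 50,
    bundle: PanelBundle | None = None,
) -> tuple[SyntheticCohort, dict[str, str]]:
    """Patients with planted genotypes plus negative controls.

    Returns the cohort and a map sample_id -> planted genotype type
    (controls map to "none").
    """
    bundle = bundle or generate_panel(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    individuals = []
    truth = []
    genotype_of: dict[str, str] = {}
    for i in range(n_patients):
        sid = f"P{i + 1:04d}"
        variants, t, g = generate_patient(config, bundle, rng, sid)
        individuals.append((sid, "patient", variants))
        truth.append(t)
        genotype_of[sid] = g
    controls = generate_controls(config, bundle, n_controls)
    for (sid, role, variants), t in zip(controls.individuals, controls.truth):
        individuals.append((sid, role, variants))
        truth.append(t)
        genotype_of[sid] = "none"
    cohort = SyntheticCohort(individuals, truth, bundle.panel, bundle.transcripts, bundle.kb)
    return cohort, genotype_of
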