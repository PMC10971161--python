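import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

from nbscreen import (
    GenomicInterval,
    KnowledgeBase,
    KnowledgeBaseEntry,
    PanelGene,
    PipelineConfig,
    TranscriptModel,
    VariantRecord,
)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def toy_transcript():
    """Three-exon plus-strand transcript with UTRs on both ends.

    Exons 101-200 / 301-400 / 501-600, CDS 131-570.  Coding pieces are
    70 + 100 + 70 nt; the final exon-exon junction sits at coding offset
    170, so premature stops at coding offsets > 120 escape NMD under the
    50-nt rule.
    """
    return TranscriptModel(
        transcript_id="TX_TOY.1",
        gene="TOY1",
        strand="+",
        exons=(
            GenomicInterval("1", 101, 200),
            GenomicInterval("1", 301, 400),
            GenomicInterval("1", 501, 600),
        ),
        cds_start=131,
        cds_end=570,
    )


def make_variant(
    pos=150,
    ref="A",
    alt="T",
    chrom="1",
    gene="TOY1",
    csq=None,
    vaf=0.5,
    zygosity="het",
    population_af=0.0001,
    var_type="SNV",
    end=None,
    **kw,
):
    return VariantRecord(
        locus=GenomicInterval(chrom, pos, end if end is not None else pos),
        ref=ref,
        alt=alt,
        gene=gene,
        var_type=var_type,
        csq=csq,
        population_af=population_af,
        vaf=vaf,
        zygosity=zygosity,
        **kw,
    )


@pytest.fixture(scope="session")
def mini_panel():
    return {
        "TOY1": PanelGene("TOY1", "AR", "toy recessive disorder", "1"),
        "TOY2": PanelGene("TOY2", "AD", "toy dominant disorder", "2"),
        "TOY3": PanelGene("TOY3", "XLR", "toy X-linked disorder", "X"),
    }


def kb_of(*entries):
    kb = KnowledgeBase()
    for key, source, cls in entries:
        kb.add(KnowledgeBaseEntry(variant_key=key, source=source, classification=cls))
    return kb
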