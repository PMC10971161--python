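"""Strict (L)P filter, review application and VUS extension."""

import itertools

import pytest

from nbscreen import (
    PipelineConfig,
    ReviewDecision,
    Verdict,
    apply_review,
    lookup_classification,
    strict_lp_filter,
    vus_extension,
)
from nbscreen.screening_filters import CandidateVariant, load_review_table
from nbscreen.variant_domain import ConsequenceClass, VariantDomainError
from nbscreen.screening_filters import _consequence

from conftest import kb_of, make_variant


def key_of(v):
    return v.key


class TestStrictLpFilter:
    def test_database_lp_hit_retained(self, toy_transcript):
        # a canonical splice-site variant listed LP in ClinVar (like a
        # c.1315+1G>A donor +1 hit)
        v = make_variant(pos=201, population_af=0.0002)
        kb = kb_of((v.key, "ClinVar", "LP"))
        (cand,) = strict_lp_filter([v], kb, {"TOY1": toy_transcript})
        assert cand.selection_reason == "db_lp"
        assert cand.working_class == "LP"

    def test_utr_vus_removed(self, toy_transcript):
        # homozygous 5'UTR variant known only as VUS (like a c.-40G>A)
        v = make_variant(pos=110, zygosity="hom", vaf=0.98)
        kb = kb_of((v.key, "ClinVar", "VUS"))
        assert strict_lp_filter([v], kb, {"TOY1": toy_transcript}) == []

    def test_novel_truncating_retained(self, toy_transcript):
        v = make_variant(pos=320, csq="stop_gained", population_af=0.0)
        (cand,) = strict_lp_filter([v], kb_of(), {"TOY1": toy_transcript})
        assert cand.selection_reason == "truncating_novel"
        assert cand.working_class == "LP"

    def test_af_gate_removes_regardless_of_class(self, toy_transcript):
        v = make_variant(pos=201, population_af=0.02)
        kb = kb_of((v.key, "ClinVar", "P"))
        assert strict_lp_filter([v], kb, {"TOY1": toy_transcript}) == []

    def test_af_cutoff_is_strict(self, toy_transcript):
        v = make_variant(pos=201, population_af=0.01)
        kb = kb_of((v.key, "ClinVar", "P"))
        assert strict_lp_filter([v], kb, {"TOY1": toy_transcript}) == []

    def test_nmd_escaping_stop_not_novel_truncating(self, toy_transcript):
        v = make_variant(pos=510, csq="stop_gained", population_af=0.0)
        assert strict_lp_filter([v], kb_of(), {"TOY1": toy_transcript}) == []

    def test_splice_region_pm3_surfaces_as_vus(self, toy_transcript):
        v = make_variant(pos=203, population_af=0.0)
        (cand,) = strict_lp_filter([v], kb_of(), {"TOY1": toy_transcript})
        assert cand.selection_reason == "splice_pm3"
        assert cand.working_class == "VUS"

    def test_described_truncating_not_novel_branch(self, toy_transcript):
        """A truncating variant with a benign-side database entry passes
        neither the database branch nor the novel-truncating branch."""
        v = make_variant(pos=320, csq="stop_gained")
        kb = kb_of((v.key, "VKGL", "LB"))
        assert strict_lp_filter([v], kb, {"TOY1": toy_transcript}) == []

    def test_raw_only_invisible(self, toy_transcript):
        v = make_variant(pos=201, raw_only=True)
        kb = kb_of((v.key, "ClinVar", "P"))
        assert strict_lp_filter([v], kb, {"TOY1": toy_transcript}) == []

    def test_missing_af_is_an_error(self, toy_transcript):
        v = make_variant(pos=201, population_af=None)
        with pytest.raises(VariantDomainError, match="population_af"):
            strict_lp_filter([v], kb_of(), {"TOY1": toy_transcript})

    def test_output_subset_and_sorted(self, toy_transcript):
        variants = [
            make_variant(pos=p, csq="stop_gained", population_af=0.0)
            for p in (350, 310, 330)
        ]
        out = strict_lp_filter(variants, kb_of(), {"TOY1": toy_transcript})
        positions = [c.variant.locus.start for c in out]
        assert positions == sorted(positions)
        assert {c.key for c in out} <= {v.key for v in variants}

    def test_brute_force_branch_oracle(self, toy_transcript):
        """On instances of up to 6 variants, an exhaustive per-variant
        predicate checker retains exactly the same set as the filter."""
        kbs = {
            "lp": lambda k: kb_of((k, "ClinVar", "P")),
            "vus": lambda k: kb_of((k, "ClinVar", "VUS")),
            "none": lambda k: kb_of(),
        }
        profiles = [
            (201, None),  # canonical splice
            (203, None),  # splice region +-3
            (320, "stop_gained"),  # NMD-sensitive stop
            (510, "stop_gained"),  # NMD-escaping stop
            (150, "missense"),
            (110, None),  # 5' UTR
        ]
        combos = [
            (af, kb_kind)
            for af in (0.0, 0.005, 0.02)
            for kb_kind in ("lp", "vus", "none")
        ]
        config = PipelineConfig()
        tx = {"TOY1": toy_transcript}
        for i in range(len(combos)):
            # one 6-variant instance per rotation of the (af, kb) combos
            chunk = [
                profiles[j] + combos[(i + j) % len(combos)] for j in range(6)
            ]
            variants, kb_entries = [], []
            for pos, csq, af, kb_kind in chunk:
                v = make_variant(pos=pos, csq=csq, population_af=af)
                variants.append(v)
                if kb_kind == "lp":
                    kb_entries.append((v.key, "ClinVar", "P"))
                elif kb_kind == "vus":
                    kb_entries.append((v.key, "ClinVar", "VUS"))
            kb = kb_of(*kb_entries)
            got = {c.key for c in strict_lp_filter(variants, kb, tx, config)}

            expected = set()
            for v in variants:  # independent transcription of the branches
                if not (v.population_af < config.af_cutoff):
                    continue
                verdict = lookup_classification(v, kb).verdict
                cls = _consequence(v, tx, config)
                branch_a = verdict is Verdict.LP_or_P
                branch_b = cls in (
                    ConsequenceClass.truncating_nmd,
                    ConsequenceClass.canonical_splice,
                ) and verdict is Verdict.none
                branch_c = cls is ConsequenceClass.splice_region_pm3
                if branch_a or branch_b or branch_c:
                    expected.add(v.key)
            assert got == expected


class TestApplyReview:
    def _candidate(self, pos=201):
        v = make_variant(pos=pos)
        return CandidateVariant(v, "db_lp", "LP")

    def test_artefact_excluded(self):
        c = self._candidate()
        out = apply_review([c], [ReviewDecision(c.key, "exclude_artefact")])
        assert out == []

    def test_empty_review_is_identity(self):
        c = self._candidate()
        assert apply_review([c], []) == [c]

    def test_downgrade_sets_vus(self):
        c = self._candidate()
        (out,) = apply_review([c], [ReviewDecision(c.key, "downgrade_VUS")])
        assert out.working_class == "VUS" and out.reviewed

    def test_unmatched_key_warns_not_errors(self, caplog):
        c = self._candidate()
        with caplog.at_level("WARNING"):
            out = apply_review([c], [ReviewDecision("9:9:A:T", "exclude_artefact")])
        assert out == [c]
        assert any("matched no candidate" in m for m in caplog.messages)

    def test_review_table_loading(self, tmp_path):
        p = tmp_path / "review.tsv"
        p.write_text(
            "variant_key\tdecision\tnote\n"
            "1:100:A:T\texclude_cis\tcalled as two events\n"
            "1:200:G:C\tkeep_P\t.\n"
        )
        decisions = load_review_table(p)
        assert [d.decision for d in decisions] == ["exclude_cis", "keep_P"]


class TestVusExtension:
    def _setup(self, mini_panel):
        """One AR gene with a het (L)P trigger plus a database VUS (the
        one-(L)P-plus-VUS compound pattern the extension exists for)."""
        lp = make_variant(pos=100, vaf=0.50)
        vus = make_variant(pos=900, ref="G", alt="C", vaf=0.48)
        kb = kb_of((lp.key, "ClinVar", "LP"), (vus.key, "ClinVar", "VUS"))
        cand = CandidateVariant(lp, "db_lp", "LP")
        return lp, vus, kb, cand

    def test_het_lp_triggers_vus_inclusion(self, mini_panel):
        lp, vus, kb, cand = self._setup(mini_panel)
        out = vus_extension([cand], [lp, vus], kb, mini_panel)
        assert {c.key for c in out} == {lp.key, vus.key}
        added = next(c for c in out if c.key == vus.key)
        assert added.working_class == "VUS"
        assert added.selection_reason == "vus_extension"

    def test_hom_vus_without_lp_adds_nothing(self, mini_panel):
        vus = make_variant(pos=900, ref="G", alt="C", vaf=0.98, zygosity="hom")
        kb = kb_of((vus.key, "ClinVar", "VUS"))
        assert vus_extension([], [vus], kb, mini_panel) == []

    def test_ad_gene_excluded(self, mini_panel):
        lp = make_variant(pos=100, gene="TOY2", chrom="2", vaf=0.5)
        vus = make_variant(pos=900, gene="TOY2", chrom="2", ref="G", alt="C")
        kb = kb_of((lp.key, "ClinVar", "LP"), (vus.key, "ClinVar", "VUS"))
        cand = CandidateVariant(lp, "db_lp", "LP")
        out = vus_extension([cand], [lp, vus], kb, mini_panel)
        assert [c.key for c in out] == [lp.key]

    def test_hom_lp_outside_window_no_extension(self, mini_panel):
        lp = make_variant(pos=100, vaf=1.0, zygosity="hom")
        vus = make_variant(pos=900, ref="G", alt="C")
        kb = kb_of((lp.key, "ClinVar", "LP"), (vus.key, "ClinVar", "VUS"))
        cand = CandidateVariant(lp, "db_lp", "LP")
        out = vus_extension([cand], [lp, vus], kb, mini_panel)
        assert [c.key for c in out] == [lp.key]

    def test_two_lp_candidates_do_not_trigger(self, mini_panel):
        lp1 = make_variant(pos=100, vaf=0.5)
        lp2 = make_variant(pos=200, ref="C", alt="G", vaf=0.5)
        vus = make_variant(pos=900, ref="G", alt="C")
        kb = kb_of(
            (lp1.key, "ClinVar", "LP"),
            (lp2.key, "ClinVar", "P"),
            (vus.key, "ClinVar", "VUS"),
        )
        cands = [CandidateVariant(lp1, "db_lp", "LP"), CandidateVariant(lp2, "db_lp", "P")]
        out = vus_extension(cands, [lp1, lp2, vus], kb, mini_panel)
        assert {c.key for c in out} == {lp1.key, lp2.key}

    def test_rare_unlisted_nonsynonymous_is_eligible(self, mini_panel):
        """Novel missense VUS (no database entry) must be reachable."""
        lp = make_variant(pos=100, vaf=0.5)
        novel = make_variant(pos=900, ref="G", alt="C", csq="missense",
                             population_af=0.0)
        syn = make_variant(pos=950, ref="G", alt="A", csq="synonymous",
                           population_af=0.0)
        kb = kb_of((lp.key, "ClinVar", "LP"))
        cand = CandidateVariant(lp, "db_lp", "LP")
        out = vus_extension([cand], [lp, novel, syn], kb, mini_panel)
        assert {c.key for c in out} == {lp.key, novel.key}

    def test_extension_is_monotone_superset(self, mini_panel):
        lp, vus, kb, cand = self._setup(mini_panel)
        out = vus_extension([cand], [lp, vus], kb, mini_panel)
        assert {c.key for c in out} >= {cand.key}
        # (L)P candidate set unchanged
        assert [c.key for c in out if c.is_lp] == [cand.key]
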