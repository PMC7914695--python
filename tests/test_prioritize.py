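"""The PDV selection cascade: hard filters, severity, triage, provenance."""

from __future__ import annotations

import pytest

from bbs_workbench.prioritize import (
    FilterConfig,
    Severity,
    deleterious_triage,
    genotype_qc,
    rarity_pass,
    run_cascade,
    severity_of,
)

from conftest import make_call, make_variant

CFG = FilterConfig()


class TestGenotypeQc:
    @pytest.mark.parametrize(
        "variant_class, indel_length, dp, gq, expected",
        [
            # SNV depth: >= 10 included
            ("SNV", 0, 10, 99.0, True),
            ("SNV", 0, 9, 99.0, False),
            # GQ: < 20 excluded, 20.0 itself retained
            ("SNV", 0, 100, 20.0, True),
            ("SNV", 0, 100, 19.9, False),
            # short indel (<= 5 bp): >= 28X
            ("INDEL", 3, 28, 99.0, True),
            ("INDEL", 3, 27, 99.0, False),
            # 5 bp boundary uses the laxer short-indel rule
            ("INDEL", 5, 28, 99.0, True),
            # long indel (5-200 bp): >= 42X
            ("INDEL", 6, 42, 99.0, True),
            ("INDEL", 6, 41, 99.0, False),
            # 1 bp indels follow the short-indel rule
            ("INDEL", 1, 28, 99.0, True),
            ("INDEL", 1, 27, 99.0, False),
            # indels beyond 200 bp never pass
            ("INDEL", 201, 1000, 99.0, False),
        ],
    )
    def test_thresholds_and_sidedness(self, variant_class, indel_length, dp, gq, expected):
        call = make_call((0, 1), dp=dp, gq=gq)
        assert genotype_qc(call, variant_class, indel_length, CFG) is expected

    def test_absent_dp_or_gq_fails(self):
        assert not genotype_qc(make_call((0, 1), dp=None, gq=99.0), "SNV", 0, CFG)
        assert not genotype_qc(make_call((0, 1), dp=50, gq=None), "SNV", 0, CFG)


class TestRarity:
    @pytest.mark.parametrize(
        "max_af, expected",
        [
            (0.00005, True),
            (0.0001, False),  # strict < 0.01%
            (0.5, False),
            (None, True),  # unobserved in all reference populations counts as rare
        ],
    )
    def test_threshold(self, max_af, expected):
        assert rarity_pass(max_af, CFG) is expected

    def test_out_of_range_af_rejected(self):
        with pytest.raises(ValueError):
            rarity_pass(1.5, CFG)


class TestSeverity:
    @pytest.mark.parametrize(
        "terms, expected",
        [
            ({"missense"}, Severity.MODERATE),
            ({"inframe_insertion"}, Severity.MODERATE),
            ({"inframe_deletion", "intron"}, Severity.MODERATE),
            ({"protein_altering"}, Severity.MODERATE),
            ({"frameshift", "intron"}, Severity.HIGH),
            ({"splice_site"}, Severity.HIGH),
            ({"stop_gained"}, Severity.HIGH),
            ({"stop_lost"}, Severity.HIGH),
            ({"start_lost"}, Severity.HIGH),
            ({"missense", "stop_gained"}, Severity.HIGH),  # highest term wins
            ({"synonymous"}, Severity.NONE),
            (set(), Severity.NONE),
        ],
    )
    def test_classes(self, terms, expected):
        assert severity_of(terms) is expected


class TestTriage:
    def test_boundary_values_pass(self):
        v = make_variant(terms=("missense",), sift=0.04, polyphen=0.70, grantham=100.0)
        assert deleterious_triage(v, CFG)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sift=0.05),  # strict < 0.05
            dict(polyphen=0.699),
            dict(grantham=99.9),
            dict(sift=None),
            dict(polyphen=None),
            dict(grantham=None),
        ],
    )
    def test_failing_or_absent_scores(self, kwargs):
        base = dict(terms=("missense",), sift=0.01, polyphen=0.95, grantham=150.0)
        v = make_variant(**{**base, **kwargs})
        assert not deleterious_triage(v, CFG)

    def test_non_missense_consequences_skip_triage(self):
        v = make_variant(
            ref="A", alt="AG", terms=("frameshift",), sift=None, polyphen=None, grantham=None
        )
        assert deleterious_triage(v, CFG)

    def test_start_lost_snv_is_triaged(self):
        v = make_variant(terms=("start_lost",), sift=0.5, polyphen=0.1, grantham=10.0)
        assert not deleterious_triage(v, CFG)


def _trio_genotypes(child=(0, 1), dp=50, gq=99.0):
    return {
        "CH": make_call(child, dp=dp, gq=gq),
        "MO": make_call((0, 0)),
        "FA": make_call((0, 0)),
    }


class TestRunCascade:
    def test_single_fault_fixture(self, trio_pedigree):
        """One passing missense among five single-fault failures -> 1 PDV."""
        passing = make_variant(pos=1, genotypes=_trio_genotypes())
        low_gq = make_variant(pos=2, genotypes=_trio_genotypes(gq=10.0))
        common = make_variant(pos=3, max_af=0.01, genotypes=_trio_genotypes())
        synonymous = make_variant(pos=4, terms=("synonymous",), genotypes=_trio_genotypes())
        shallow_indel = make_variant(
            pos=5, ref="A", alt="AGGG", terms=("inframe_insertion",),
            genotypes=_trio_genotypes(dp=20),
        )
        benign = make_variant(pos=6, sift=0.9, genotypes=_trio_genotypes())
        records = run_cascade(
            [passing, low_gq, common, synonymous, shallow_indel, benign], [trio_pedigree]
        )
        assert len(records) == 1
        assert records[0].variant.pos == 1
        assert records[0].severity is Severity.MODERATE
        assert records[0].passed_stages == (
            "protein_coding", "child_carrier", "genotype_qc",
            "rarity", "severity", "deleterious_triage",
        )

    def test_child_without_alt_excluded(self, trio_pedigree):
        v = make_variant(genotypes=_trio_genotypes(child=(0, 0)))
        assert run_cascade([v], [trio_pedigree]) == []

    def test_all_synonymous_gives_empty(self, trio_pedigree):
        vs = [
            make_variant(pos=p, terms=("synonymous",), genotypes=_trio_genotypes())
            for p in (1, 2, 3)
        ]
        assert run_cascade(vs, [trio_pedigree]) == []

    def test_parent_failing_qc_demoted_not_dropped(self, trio_pedigree):
        genotypes = _trio_genotypes()
        genotypes["MO"] = make_call((0, 1), gq=5.0)  # deleted parent fails GQ
        v = make_variant(genotypes=genotypes)
        (rec,) = run_cascade([v], [trio_pedigree])
        assert rec.deleted_parent_call.is_missing
        assert not rec.nondeleted_parent_call.is_missing

    def test_idempotent_on_own_output(self, sim_bundle, sim_pdvs):
        _, pedigrees, _ = sim_bundle
        surviving = [p.variant for p in sim_pdvs]
        again = run_cascade(surviving, pedigrees)
        assert {(p.variant.key, p.child_id) for p in again} == {
            (p.variant.key, p.child_id) for p in sim_pdvs
        }

    def test_monotone_subset_of_input(self, sim_bundle, sim_pdvs):
        _, _, variants = sim_bundle
        input_keys = {v.key for v in variants}
        assert {p.variant.key for p in sim_pdvs} <= input_keys


def brute_force_pdv(variant, pedigree) -> bool:
    """Independent single-conjunction oracle for the whole cascade."""
    child = variant.genotypes.get(pedigree.child_id)
    if child is None or child.is_missing:
        return False
    damaging = {
        "splice_site", "stop_gained", "stop_lost", "start_lost", "frameshift",
        "inframe_insertion", "inframe_deletion", "missense", "protein_altering",
    }
    indel_len = abs(len(variant.alt) - len(variant.ref))
    is_snv = len(variant.ref) == 1 and len(variant.alt) == 1
    needs_scores = is_snv and bool(
        variant.consequence_terms & {"missense", "start_lost"}
    )
    return (
        variant.biotype_protein_coding
        and child.n_alt >= 1
        and child.gq is not None
        and child.gq >= 20.0
        and child.dp is not None
        and (
            (is_snv and child.dp >= 10)
            or (not is_snv and indel_len <= 5 and child.dp >= 28)
            or (not is_snv and 5 < indel_len <= 200 and child.dp >= 42)
        )
        and (variant.max_af is None or variant.max_af < 0.0001)
        and bool(variant.consequence_terms & damaging)
        and (
            not needs_scores
            or (
                variant.sift is not None
                and variant.polyphen is not None
                and variant.grantham is not None
                and variant.sift < 0.05
                and variant.polyphen >= 0.70
                and variant.grantham >= 100.0
            )
        )
    )


def test_cascade_matches_brute_force_oracle(sim_bundle, sim_pdvs):
    """Record-for-record equality with the one-conjunction filter."""
    _, pedigrees, variants = sim_bundle
    expected = {
        (v.key, ped.child_id)
        for ped in pedigrees
        for v in variants
        if brute_force_pdv(v, ped)
    }
    assert {(p.variant.key, p.child_id) for p in sim_pdvs} == expected
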