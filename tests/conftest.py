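"""Shared fixtures: small hand-written files and simulated cohorts."""

from __future__ import annotations

import textwrap

import pytest

from bbs_workbench.model import AnnotatedVariant, GenotypeCall, TrioPedigree
from bbs_workbench.prioritize import PdvRecord, Severity, run_cascade
from bbs_workbench.simulate import TrioSimConfig, simulate_trios
from bbs_workbench.variant_io import read_pedigree, read_trio_vcf


def make_call(gt, dp=50, gq=99.0) -> GenotypeCall:
    """Shorthand genotype; gt is a pair, e.g. (0, 1), or None for missing."""
    if gt is None:
        return GenotypeCall(alleles=(None, None))
    return GenotypeCall(alleles=tuple(gt), dp=dp, gq=gq)


def make_variant(
    ref="A",
    alt="G",
    terms=("missense",),
    gene="GENE1",
    max_af=None,
    sift=0.01,
    polyphen=0.95,
    grantham=150.0,
    protein_coding=True,
    genotypes=None,
    chrom="chr1",
    pos=1000,
) -> AnnotatedVariant:
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        biotype_protein_coding=protein_coding,
        consequence_terms=frozenset(terms),
        max_af=max_af,
        sift=sift,
        polyphen=polyphen,
        grantham=grantham,
        genotypes=genotypes or {},
    )


def make_pdv(
    child_id="CH",
    gene="GENE1",
    terms=("missense",),
    category_calls=((0, 1), (0, 0), (0, 0)),
    chrom="chr1",
    pos=1000,
    family_id="F1",
) -> PdvRecord:
    """A minimal PDV with explicit trio genotypes (child, deleted, nondeleted)."""
    child, deleted, nondeleted = category_calls
    variant = make_variant(terms=terms, gene=gene, chrom=chrom, pos=pos)
    return PdvRecord(
        variant=variant,
        child_id=child_id,
        family_id=family_id,
        severity=Severity.MODERATE,
        passed_stages=(),
        child_call=make_call(child),
        deleted_parent_call=make_call(deleted) if deleted is not None else make_call(None),
        nondeleted_parent_call=make_call(nondeleted) if nondeleted is not None else make_call(None),
    )


TRIO_VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1>
    ##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
    ##INFO=<ID=BIOTYPE,Number=1,Type=String,Description="Transcript biotype">
    ##INFO=<ID=CSQCLASS,Number=A,Type=String,Description="Consequence terms">
    ##INFO=<ID=MAX_AF,Number=A,Type=Float,Description="Max reference AF">
    ##INFO=<ID=SIFT,Number=A,Type=Float,Description="SIFT">
    ##INFO=<ID=POLYPHEN,Number=A,Type=Float,Description="PolyPhen">
    ##INFO=<ID=GRANTHAM,Number=A,Type=Float,Description="Grantham">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
    ##FORMAT=<ID=GQ,Number=1,Type=Float,Description="Genotype quality">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tCH\tMO\tFA
    """
)


@pytest.fixture
def write_vcf(tmp_path):
    """Write VCF body lines under the standard 3-sample (CH, MO, FA) header."""

    def _write(*body_lines, name="trio.vcf"):
        path = tmp_path / name
        path.write_text(TRIO_VCF_HEADER + "".join(line + "\n" for line in body_lines))
        return path

    return _write


@pytest.fixture
def trio_pedigree():
    return TrioPedigree(
        family_id="FAM1", child_id="CH", deleted_parent_id="MO", nondeleted_parent_id="FA"
    )


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A moderate simulated trio cohort loaded through the real readers."""
    out = simulate_trios(TrioSimConfig(seed=11), tmp_path_factory.mktemp("sim"))
    pedigrees = read_pedigree(out.ped)
    variants = read_trio_vcf(out.vcf, pedigrees)
    return out, pedigrees, variants


@pytest.fixture(scope="session")
def sim_pdvs(sim_bundle):
    out, pedigrees, variants = sim_bundle
    return run_cascade(variants, pedigrees)
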