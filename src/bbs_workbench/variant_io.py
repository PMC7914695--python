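"""Readers and writers for the constrained VCF dialect and side files.

The VCF dialect is ordinary VCF v4.2 with per-genotype ``GT``/``DP``/``GQ``
FORMAT fields and per-variant INFO annotations (gene symbol, biotype,
consequence terms, maximum reference-population allele frequency and the
SIFT/PolyPhen/Grantham scores). INFO key names are configurable through
:class:`AnnotationKeys` because annotation tools serialize these fields
under different names.

Multi-allelic records are decomposed on read: each (record, alt) pair
becomes one :class:`~bbs_workbench.model.AnnotatedVariant`, with genotype
allele indices remapped so that the retained alt is 1 and every other
allele (including other alts of the same site) is 0. Per-alt (Number=A)
INFO values are split accordingly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
import yaml

from .model import (
    AnnotatedVariant,
    GenePanel,
    GenotypeCall,
    InteractionEdge,
    TrioPedigree,
)


logger = logging.getLogger(__name__)


class VcfParseError(ValueError):
    """A VCF record could not be interpreted; the message names the line."""


class PedigreeError(ValueError):
    """The pedigree file or its correspondence with the VCF is invalid."""


@dataclass(frozen=True)
class AnnotationKeys:
    """Mapping from the package's annotation fields to VCF INFO keys."""

    gene: str = "GENE"
    biotype: str = "BIOTYPE"
    consequence: str = "CSQCLASS"
    max_af: str = "MAX_AF"
    sift: str = "SIFT"
    polyphen: str = "POLYPHEN"
    grantham: str = "GRANTHAM"

    @staticmethod
    def from_yaml(path) -> "AnnotationKeys":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclass_fields(AnnotationKeys)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown annotation-key names: {sorted(unknown)}")
        return AnnotationKeys(**raw)


PROTEIN_CODING = "protein_coding"


def _info_for_alt(value, alt_index: int, n_alts: int):
    """Pick the per-alt element of an INFO value (Number=A), else the scalar."""
    if isinstance(value, (tuple, list)):
        if len(value) == n_alts:
            return value[alt_index]
        return value[0] if len(value) == 1 else value[min(alt_index, len(value) - 1)]
    return value


def _as_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(out) else out


def _remap_allele(allele: Optional[int], alt_number: int) -> Optional[int]:
    if allele is None:
        return None
    return 1 if allele == alt_number else 0


def read_trio_vcf(
    path,
    pedigrees: Sequence[TrioPedigree],
    keys: AnnotationKeys = AnnotationKeys(),
) -> list[AnnotatedVariant]:
    """Load a multi-sample VCF into decomposed :class:`AnnotatedVariant` records.

    Every sample id referenced by ``pedigrees`` must appear in the VCF
    header; a missing id raises :class:`PedigreeError`. Genotype allele
    indices outside the record's allele set raise :class:`VcfParseError`
    naming the offending line.
    """
    path = str(path)
    verbosity = pysam.set_verbosity(0)  # our dialect declares GQ as Float
    try:
        vcf = pysam.VariantFile(path)
    finally:
        pysam.set_verbosity(verbosity)
    header_samples = set(vcf.header.samples)
    needed = {s for ped in pedigrees for s in ped.sample_ids}
    missing = needed - header_samples
    if missing:
        raise PedigreeError(
            f"pedigree sample ids absent from VCF header: {sorted(missing)}"
        )

    with open(path) as fh:  # htslib may synthesize extra header lines; count the file's own
        n_header_lines = sum(1 for line in fh if line.startswith("#"))
    out: list[AnnotatedVariant] = []
    records = iter(vcf)
    record_index = 0
    while True:
        line_no = n_header_lines + 1 + record_index
        try:
            rec = next(records)
        except StopIteration:
            break
        except OSError as exc:  # htslib reports malformed records this way
            raise VcfParseError(f"{path}:{line_no}: malformed record: {exc}") from exc
        record_index += 1
        alts = rec.alts or ()
        n_alts = len(alts)
        if n_alts == 0:
            continue
        info = dict(rec.info)
        for alt_index, alt in enumerate(alts):
            alt_number = alt_index + 1  # VCF allele index of this alt
            genotypes: dict[str, GenotypeCall] = {}
            for sample in needed & set(rec.samples.keys()):
                fmt = rec.samples[sample]
                raw_alleles = fmt.get("GT", (None, None))
                if raw_alleles is None:
                    raw_alleles = (None, None)
                if len(raw_alleles) == 1:
                    # all chromosomes are treated as diploid; a haploid-looking
                    # call is flagged and demoted to missing
                    logger.warning(
                        "%s:%d: sample %s has hemizygous-looking GT; treated as missing",
                        path, line_no, sample,
                    )
                    raw_alleles = (None, None)
                elif len(raw_alleles) != 2:
                    raise VcfParseError(
                        f"{path}:{line_no}: sample {sample!r} has non-diploid GT {raw_alleles!r}"
                    )
                # htslib demotes out-of-range allele indices to missing
                alleles = tuple(_remap_allele(a, alt_number) for a in raw_alleles)
                dp = fmt.get("DP", None)
                gq = fmt.get("GQ", None)
                genotypes[sample] = GenotypeCall(
                    alleles=alleles,  # type: ignore[arg-type]
                    dp=int(dp) if dp is not None else None,
                    gq=float(gq) if gq is not None else None,
                )

            csq_raw = _info_for_alt(info.get(keys.consequence), alt_index, n_alts)
            terms = (
                frozenset(t for t in str(csq_raw).split("&") if t)
                if csq_raw is not None
                else frozenset()
            )
            biotype = _info_for_alt(info.get(keys.biotype), alt_index, n_alts)
            gene = _info_for_alt(info.get(keys.gene), alt_index, n_alts)
            out.append(
                AnnotatedVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    gene=str(gene).upper() if gene is not None else None,
                    biotype_protein_coding=(str(biotype) == PROTEIN_CODING),
                    consequence_terms=terms,
                    max_af=_as_float(_info_for_alt(info.get(keys.max_af), alt_index, n_alts)),
                    sift=_as_float(_info_for_alt(info.get(keys.sift), alt_index, n_alts)),
                    polyphen=_as_float(_info_for_alt(info.get(keys.polyphen), alt_index, n_alts)),
                    grantham=_as_float(_info_for_alt(info.get(keys.grantham), alt_index, n_alts)),
                    genotypes=genotypes,
                )
            )
    return out


def read_pedigree(path) -> list[TrioPedigree]:
    """Read a PED file extended with a deletion-carrier column.

    Columns (whitespace-separated): family, individual, father, mother,
    sex, phenotype, deletion-carrier flag (1 = carries the 15q11.2
    BP1-BP2 deletion). One :class:`TrioPedigree` is produced per child —
    a row not referenced as a parent by any other row of its family.
    Children with ``0`` in both parent columns yield a pedigree with both
    parent ids absent.
    """
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise PedigreeError(
                    f"{path}: expected 7 columns (PED + carrier flag), got {len(parts)}: {line!r}"
                )
            rows.append(parts[:7])

    seen_ids = set()
    for _, iid, *_ in rows:
        if iid in seen_ids:
            raise PedigreeError(f"{path}: duplicate individual id {iid!r}")
        seen_ids.add(iid)

    carriers = {iid for _, iid, _, _, _, _, flag in rows if flag == "1"}
    referenced_parents = {p for _, _, fa, mo, _, _, _ in rows for p in (fa, mo) if p != "0"}

    pedigrees = []
    for fam, iid, father, mother, _sex, _phe, _flag in rows:
        if iid in referenced_parents:
            continue  # parent row, not a child
        parent_ids = [p for p in (father, mother) if p != "0"]
        parent_ids = [p for p in parent_ids if p in seen_ids]
        carrier_parents = [p for p in parent_ids if p in carriers]
        if len(carrier_parents) > 1:
            raise PedigreeError(
                f"{path}: family {fam!r} flags more than one deletion-carrier parent"
            )
        if parent_ids and not carrier_parents:
            raise PedigreeError(
                f"{path}: family {fam!r} has parent rows but no deletion-carrier flag"
            )
        deleted = carrier_parents[0] if carrier_parents else None
        others = [p for p in parent_ids if p != deleted]
        pedigrees.append(
            TrioPedigree(
                family_id=fam,
                child_id=iid,
                deleted_parent_id=deleted,
                nondeleted_parent_id=others[0] if others else None,
            )
        )
    return pedigrees


def read_panels(directory) -> list[GenePanel]:
    """Read every ``*.txt`` gene list in a directory; panel name = file stem."""
    panels = []
    for path in sorted(Path(directory).glob("*.txt")):
        with open(path) as fh:
            symbols = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
        panels.append(GenePanel.from_symbols(path.stem, symbols))
    return panels


def read_edges(path) -> list[InteractionEdge]:
    """Read a three-column TSV of interaction edges (gene_a, gene_b, relation)."""
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, rel = (p.strip() for p in parts)
            try:
                edges.append(InteractionEdge(gene_a=a.upper(), gene_b=b.upper(), relation=rel))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return edges


# ---------------------------------------------------------------------------
# TSV variant-table export / import (round-trip exact)

_FIXED_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "biotype_protein_coding",
    "consequence_terms",
    "max_af",
    "sift",
    "polyphen",
    "grantham",
]

_SAMPLE_PREFIX = "sample:"
_ABSENT = "."


def _fmt_float(x: Optional[float]) -> str:
    return _ABSENT if x is None else repr(float(x))


def _fmt_call(call: GenotypeCall) -> str:
    gt = "/".join(_ABSENT if a is None else str(a) for a in call.alleles)
    dp = _ABSENT if call.dp is None else str(call.dp)
    gq = _ABSENT if call.gq is None else repr(float(call.gq))
    return f"{gt}:{dp}:{gq}"


def _parse_call(text: str) -> GenotypeCall:
    gt, dp, gq = text.split(":")
    alleles = tuple(None if a == _ABSENT else int(a) for a in gt.split("/"))
    return GenotypeCall(
        alleles=alleles,  # type: ignore[arg-type]
        dp=None if dp == _ABSENT else int(dp),
        gq=None if gq == _ABSENT else float(gq),
    )


def write_variant_table(variants: Iterable[AnnotatedVariant], path) -> None:
    """Write variants to TSV; float fields use ``repr`` so re-reading is exact."""
    variants = list(variants)
    samples = sorted({s for v in variants for s in v.genotypes})
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": str(v.pos),
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene if v.gene is not None else _ABSENT,
            "biotype_protein_coding": "1" if v.biotype_protein_coding else "0",
            "consequence_terms": "&".join(sorted(v.consequence_terms)) or _ABSENT,
            "max_af": _fmt_float(v.max_af),
            "sift": _fmt_float(v.sift),
            "polyphen": _fmt_float(v.polyphen),
            "grantham": _fmt_float(v.grantham),
        }
        for s in samples:
            row[_SAMPLE_PREFIX + s] = (
                _fmt_call(v.genotypes[s]) if s in v.genotypes else _ABSENT
            )
        rows.append(row)
    columns = _FIXED_COLUMNS + [_SAMPLE_PREFIX + s for s in samples]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> list[AnnotatedVariant]:
    """Inverse of :func:`write_variant_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sample_cols = [c for c in df.columns if c.startswith(_SAMPLE_PREFIX)]
    out = []
    for _, row in df.iterrows():
        genotypes = {
            c[len(_SAMPLE_PREFIX):]: _parse_call(row[c])
            for c in sample_cols
            if row[c] != _ABSENT
        }
        terms = (
            frozenset(row["consequence_terms"].split("&"))
            if row["consequence_terms"] != _ABSENT
            else frozenset()
        )
        out.append(
            AnnotatedVariant(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                gene=None if row["gene"] == _ABSENT else row["gene"],
                biotype_protein_coding=row["biotype_protein_coding"] == "1",
                consequence_terms=terms,
                max_af=None if row["max_af"] == _ABSENT else float(row["max_af"]),
                sift=None if row["sift"] == _ABSENT else float(row["sift"]),
                polyphen=None if row["polyphen"] == _ABSENT else float(row["polyphen"]),
                grantham=None if row["grantham"] == _ABSENT else float(row["grantham"]),
                genotypes=genotypes,
            )
        )
    return out
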