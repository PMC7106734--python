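"""Genomic-context classification and coding-effect calls for variants.

Classes partition the genome given a gene model: CDS (synonymous /
nonsynonymous for SNPs, ``coding_indel`` for INDELs), UTR, intron,
intergenic. When a variant overlaps several features, the most specific
functional consequence wins (CDS > UTR > intron > intergenic). When a gene
has several transcripts, the one with the longest CDS is used.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .variant_io import Gene, GeneModel, Transcript, VariantRecord

__all__ = [
    "Annotation",
    "classify_variant",
    "classify_all",
    "summarize_classes",
    "annotation_table",
    "CoordinateError",
    "REGION_CLASSES",
]

REGION_CLASSES = (
    "CDS_synonymous",
    "CDS_nonsynonymous",
    "coding_indel",
    "UTR",
    "intron",
    "intergenic",
)

_PRECEDENCE = {c: i for i, c in enumerate(REGION_CLASSES)}


class CoordinateError(ValueError):
    """Variant locus outside the reference sequence."""


@dataclass(frozen=True)
class Annotation:
    region_class: str
    gene_id: str | None = None
    aa_change: tuple[str, int, str] | None = None  # (ref AA, protein pos, alt AA)

    @property
    def aa_string(self) -> str:
        """'I85T'-style string, empty for non-CDS classes."""
        if self.aa_change is None:
            return ""
        r, p, a = self.aa_change
        return f"{r}{p}{a}"

    @property
    def is_nonsynonymous(self) -> bool:
        return self.region_class == "CDS_nonsynonymous"


def _get_seq(reference, chrom: str, start: int, end: int) -> str:
    """Fetch reference bases (1-based inclusive) from pyfaidx.Fasta or a dict."""
    if isinstance(reference, dict):
        seq = reference[chrom]
        if end > len(seq):
            raise CoordinateError(f"{chrom}:{start}-{end} beyond reference ({len(seq)} bp)")
        return seq[start - 1 : end].upper()
    try:
        rec = reference[chrom]
    except KeyError as exc:
        raise CoordinateError(f"chromosome {chrom!r} not in reference") from exc
    if end > len(rec):
        raise CoordinateError(f"{chrom}:{start}-{end} beyond reference ({len(rec)} bp)")
    return rec[start - 1 : end].seq.upper()


def _cds_positions(transcript: Transcript, strand: str) -> list[int]:
    """Genomic positions of CDS bases in transcription (5'->3') order."""
    out: list[int] = []
    intervals = sorted(transcript.cds)
    if strand == "+":
        for s, e in intervals:
            out.extend(range(s, e + 1))
    else:
        for s, e in reversed(intervals):
            out.extend(range(e, s - 1, -1))
    return out


def _locate_in_gene(pos: int, gene: Gene) -> str:
    """Class of a point position relative to one gene (ignoring coding effect)."""
    tr = gene.longest_cds_transcript()
    if any(s <= pos <= e for s, e in tr.cds):
        return "CDS"
    if any(s <= pos <= e for s, e in tr.exons):
        return "UTR"
    lo, hi = gene.span
    if lo <= pos <= hi:
        return "intron"
    return "intergenic"


def _codon_effect(
    record: VariantRecord,
    gene: Gene,
    reference,
) -> tuple[str, tuple[str, int, str]]:
    """Rebuild the affected codon, substitute the alt base, translate both."""
    tr = gene.longest_cds_transcript()
    cds_pos = _cds_positions(tr, gene.strand)
    offset = cds_pos.index(record.pos) + 1  # 1-based CDS offset
    codon_idx = (offset - 1) // 3
    codon_genomic = cds_pos[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon_genomic) < 3:
        raise ValueError(f"transcript {tr.id}: incomplete terminal codon at {record.pos}")

    alt = record.alts[0]
    ref_codon = []
    alt_codon = []
    for g in codon_genomic:
        base = _get_seq(reference, record.chrom, g, g)
        if gene.strand == "-":
            base = str(Seq(base).complement())
        ref_codon.append(base)
        if g == record.pos:
            sub = alt if gene.strand == "+" else str(Seq(alt).complement())
            alt_codon.append(sub)
        else:
            alt_codon.append(base)
    ref_aa = str(Seq("".join(ref_codon)).translate())
    alt_aa = str(Seq("".join(alt_codon)).translate())
    protein_pos = codon_idx + 1
    cls = "CDS_synonymous" if ref_aa == alt_aa else "CDS_nonsynonymous"
    return cls, (ref_aa, protein_pos, alt_aa)


def classify_variant(record: VariantRecord, model: GeneModel, reference) -> Annotation:
    """Classify one variant; compute the amino-acid change for CDS SNPs.

    The reference base at the locus is sanity-checked against the record's
    ref allele (first base) — a mismatch signals a coordinate-system error.
    """
    ref_base = _get_seq(reference, record.chrom, record.pos, record.pos)
    if record.ref[0].upper() != ref_base:
        raise CoordinateError(
            f"{record.chrom}:{record.pos}: VCF ref {record.ref[0]!r} != reference {ref_base!r}"
        )
    best: tuple[int, str, Gene | None] = (_PRECEDENCE["intergenic"], "intergenic", None)
    for gene in model.genes_on(record.chrom):
        cls = _locate_in_gene(record.pos, gene)
        if cls == "intergenic":
            continue
        key = "CDS_synonymous" if cls == "CDS" else cls  # provisional precedence for CDS
        if _PRECEDENCE[key] < best[0]:
            best = (_PRECEDENCE[key], cls, gene)
    _, cls, gene = best
    if cls == "intergenic":
        return Annotation("intergenic")
    if cls == "CDS":
        if record.vclass == "INDEL":
            return Annotation("coding_indel", gene.id)
        region, aa = _codon_effect(record, gene, reference)
        return Annotation(region, gene.id, aa)
    return Annotation(cls, gene.id)


def classify_all(
    records: Iterable[VariantRecord],
    model: GeneModel,
    reference,
) -> list[Annotation]:
    return [classify_variant(r, model, reference) for r in records]


def summarize_classes(annotations: Sequence[Annotation]) -> pd.DataFrame:
    """Counts and proportions per region class; proportions sum to 1."""
    counts = Counter(a.region_class for a in annotations)
    total = len(annotations)
    rows = []
    for cls in REGION_CLASSES:
        n = counts.get(cls, 0)
        rows.append({"class": cls, "count": n, "proportion": (n / total) if total else 0.0})
    return pd.DataFrame(rows)


def annotation_table(
    records: Sequence[VariantRecord],
    annotations: Sequence[Annotation],
) -> pd.DataFrame:
    """TSV-ready table: chrom, pos, ref, alt, class, gene, aa_change."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [",".join(r.alts) for r in records],
            "class": [a.region_class for a in annotations],
            "gene": [a.gene_id or "." for a in annotations],
            "aa_change": [a.aa_string or "." for a in annotations],
        }
    )
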