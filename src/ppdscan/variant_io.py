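"""Variant, genotype, pedigree and gene-model containers plus the standard readers.

Coordinates are 1-based inclusive throughout (VCF/GTF convention); window
arithmetic is half-open internally and converted at the API boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "Pedigree",
    "Gene",
    "Transcript",
    "GeneModel",
    "read_vcf",
    "write_vcf",
    "read_pedigree",
    "read_gene_model",
    "apply_hard_filters",
    "snp_cluster_filter",
    "SNP_HARD_FILTER_CLAUSES",
    "INDEL_HARD_FILTER_CLAUSES",
    "ANNOTATION_KEYS",
    "ParseError",
    "ValidationError",
]

ANNOTATION_KEYS = ("QD", "MQ", "FS", "MQRankSum", "ReadPosRankSum", "MQ0", "DP")


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally valid file violating a semantic invariant."""


@dataclass
class VariantRecord:
    """One variant site (possibly multi-allelic) with QC annotations.

    ``filter_flags`` holds the names of the hard-filter clauses the record
    fails (plus ``SnpCluster`` when set by the cluster filter); an empty set
    means the record passes QC.
    """

    chrom: str
    pos: int  # 1-based
    id: str | None
    ref: str
    alts: list[str]
    qual: float | None = None
    annotations: dict[str, float] = field(default_factory=dict)
    filter_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or any(not a for a in self.alts):
            raise ValidationError(f"empty allele at {self.chrom}:{self.pos}")

    @property
    def vclass(self) -> str:
        """``"SNP"`` iff ref and every alt are single bases, else ``"INDEL"``."""
        if len(self.ref) == 1 and all(len(a) == 1 for a in self.alts):
            return "SNP"
        return "INDEL"

    @property
    def passes_filters(self) -> bool:
        return not self.filter_flags


class GenotypeMatrix:
    """Phased diploid genotypes: sites x samples x 2 allele indices.

    Allele index 0 is the reference, k the k-th alternate, -1 missing.
    The haplotype view is defined only over sites/samples where every
    genotype is phased and non-missing.
    """

    def __init__(
        self,
        samples: Sequence[str],
        alleles: np.ndarray,
        phased: np.ndarray | None = None,
    ) -> None:
        alleles = np.asarray(alleles, dtype=np.int16)
        if alleles.ndim != 3 or alleles.shape[2] != 2:
            raise ValidationError("alleles must have shape (n_sites, n_samples, 2)")
        if alleles.shape[1] != len(samples):
            raise ValidationError("sample count mismatch")
        if phased is None:
            phased = np.ones(alleles.shape[:2], dtype=bool)
        self.samples = list(samples)
        self.alleles = alleles
        self.phased = np.asarray(phased, dtype=bool)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[1]

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"sample {exc} not in genotype matrix") from exc

    def haplotypes(
        self,
        sample_idx: np.ndarray | None = None,
        site_idx: np.ndarray | slice | None = None,
    ) -> np.ndarray:
        """Return a (n_haplotypes, n_sites) view of the phased alleles.

        Raises if any requested genotype is unphased or missing, because a
        haplotype interpretation is meaningless there.
        """
        if sample_idx is None:
            sample_idx = np.arange(self.n_samples)
        if site_idx is None:
            site_idx = slice(None)
        sub = self.alleles[site_idx][:, sample_idx, :]
        ph = self.phased[site_idx][:, sample_idx]
        if (sub < 0).any():
            raise ValidationError("haplotype view requested over missing genotypes")
        # a homozygous genotype is phase-unambiguous even when marked unphased
        if (~ph & (sub[:, :, 0] != sub[:, :, 1])).any():
            raise ValidationError("haplotype view requested over unphased heterozygotes")
        n_sites, n_samp, _ = sub.shape
        return sub.transpose(1, 2, 0).reshape(n_samp * 2, n_sites)


@dataclass
class Pedigree:
    """Family structure with affected/unaffected phenotype labels.

    ``phenotype`` values: 2 = affected, 1 = unaffected, anything else missing.
    """

    samples: list[str]
    family: dict[str, str]
    sire: dict[str, str]
    dam: dict[str, str]
    sex: dict[str, int]
    phenotype: dict[str, int]

    @property
    def cases(self) -> list[str]:
        return [s for s in self.samples if self.phenotype.get(s) == 2]

    @property
    def controls(self) -> list[str]:
        return [s for s in self.samples if self.phenotype.get(s) == 1]

    def parents(self, sample: str) -> tuple[str | None, str | None]:
        s = self.sire.get(sample) or None
        d = self.dam.get(sample) or None
        return (None if s in (None, "0") else s, None if d in (None, "0") else d)

    def founders(self) -> list[str]:
        return [s for s in self.samples if self.parents(s) == (None, None)]


@dataclass
class Transcript:
    id: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted ascending
    cds: list[tuple[int, int]]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for t in self.transcripts for s, _ in t.exons]
        ends = [e for t in self.transcripts for _, e in t.exons]
        return min(starts), max(ends)

    def longest_cds_transcript(self) -> Transcript:
        return max(self.transcripts, key=lambda t: (t.cds_length, t.id))


@dataclass
class GeneModel:
    genes: list[Gene]

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read a VCF 4.x into records plus a genotype matrix.

    Multi-allelic sites are preserved; phase and missingness are carried
    through. Records are required to be coordinate-sorted per chromosome.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    alleles: list[np.ndarray] = []
    phased: list[np.ndarray] = []
    last: dict[str, int] = {}
    for i, rec in enumerate(vcf):
        ann = {}
        for key in ANNOTATION_KEYS:
            val = rec.INFO.get(key)
            if val is not None:
                ann[key] = float(val)
        vr = VariantRecord(
            chrom=rec.CHROM,
            pos=rec.POS,
            id=rec.ID,
            ref=rec.REF,
            alts=list(rec.ALT),
            qual=None if rec.QUAL is None else float(rec.QUAL),
            annotations=ann,
        )
        if rec.CHROM in last and rec.POS < last[rec.CHROM]:
            raise ParseError(f"VCF not coordinate-sorted at record {i + 1} ({rec.CHROM}:{rec.POS})")
        last[rec.CHROM] = rec.POS
        records.append(vr)
        gts = rec.genotypes  # list of [a0, a1, phased]
        site = np.full((len(samples), 2), -1, dtype=np.int16)
        ph = np.zeros(len(samples), dtype=bool)
        for j, g in enumerate(gts):
            site[j, 0] = g[0]
            site[j, 1] = g[1] if len(g) >= 3 else g[0]
            ph[j] = bool(g[-1])
        alleles.append(site)
        phased.append(ph)

    if records:
        matrix = GenotypeMatrix(samples, np.stack(alleles), np.stack(phased))
    else:
        matrix = GenotypeMatrix(samples, np.empty((0, len(samples), 2), dtype=np.int16))
    return records, matrix


def _open_text(path: str, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


_VCF_HEADER_LINES = [
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence by depth">',
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias Fisher phred">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
    '##INFO=<ID=MQ0,Number=1,Type=Integer,Description="Reads with mapping quality zero">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined depth">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def write_vcf(
    records: Sequence[VariantRecord],
    matrix: GenotypeMatrix,
    path: str,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write records + genotypes as an uncompressed VCF 4.2 text file."""
    if len(records) != matrix.n_sites:
        raise ValidationError("record/matrix length mismatch")
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ppdscan\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        for i, rec in enumerate(records):
            info_parts = []
            for key in ANNOTATION_KEYS:
                if key in rec.annotations:
                    v = rec.annotations[key]
                    if key in ("MQ0", "DP"):
                        info_parts.append(f"{key}={int(v)}")
                    else:
                        info_parts.append(f"{key}={v:.6g}")
            info = ";".join(info_parts) if info_parts else "."
            qual = "." if rec.qual is None else f"{rec.qual:.2f}"
            filt = "PASS" if not rec.filter_flags else ";".join(sorted(rec.filter_flags))
            gt_strs = []
            for j in range(matrix.n_samples):
                a0, a1 = matrix.alleles[i, j]
                sep = "|" if matrix.phased[i, j] else "/"
                s0 = "." if a0 < 0 else str(int(a0))
                s1 = "." if a1 < 0 else str(int(a1))
                gt_strs.append(s0 + sep + s1)
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.id or '.'}\t{rec.ref}\t"
                f"{','.join(rec.alts)}\t{qual}\t{filt}\t{info}\tGT\t" + "\t".join(gt_strs) + "\n"
            )


# ---------------------------------------------------------------------------
# Hard filters
# ---------------------------------------------------------------------------

def _mq0_clause(rec: VariantRecord) -> bool | None:
    mq0 = rec.annotations.get("MQ0")
    dp = rec.annotations.get("DP")
    if mq0 is None or dp is None:
        return None
    return mq0 >= 4 and (mq0 / (1.0 * dp)) > 0.1


# Operators exactly as printed in the GATK VariantFiltration expressions
# (mixed inclusive/exclusive boundaries are intentional).
SNP_HARD_FILTER_CLAUSES = {
    "QUAL": lambda r: None if r.qual is None else r.qual <= 40.0,
    "QD": lambda r: None if "QD" not in r.annotations else r.annotations["QD"] <= 2.0,
    "MQ": lambda r: None if "MQ" not in r.annotations else r.annotations["MQ"] <= 40.0,
    "FS": lambda r: None if "FS" not in r.annotations else r.annotations["FS"] >= 60.0,
    "MQRankSum": lambda r: None
    if "MQRankSum" not in r.annotations
    else r.annotations["MQRankSum"] <= -12.5,
    "ReadPosRankSum": lambda r: None
    if "ReadPosRankSum" not in r.annotations
    else r.annotations["ReadPosRankSum"] < -8.0,
    "MQ0": _mq0_clause,
}

INDEL_HARD_FILTER_CLAUSES = {
    "QD": lambda r: None if "QD" not in r.annotations else r.annotations["QD"] < 2.0,
    "FS": lambda r: None if "FS" not in r.annotations else r.annotations["FS"] > 200.0,
    "ReadPosRankSum": lambda r: None
    if "ReadPosRankSum" not in r.annotations
    else r.annotations["ReadPosRankSum"] < -20.0,
}


def apply_hard_filters(
    records: Iterable[VariantRecord],
    mode: str,
    clauses: dict | None = None,
) -> list[VariantRecord]:
    """Flag records failing the per-clause hard filters for ``mode``.

    Only records whose variant class equals ``mode`` are evaluated; others
    are returned untouched. A clause whose annotation is absent is skipped
    (not treated as a failure), matching the behaviour of the genotyping
    toolkit these filter expressions originate from. Each failed clause name
    is added to ``filter_flags``; evaluation is independent per clause.
    """
    if mode not in ("SNP", "INDEL"):
        raise ValueError(f"unknown filter mode {mode!r}; expected 'SNP' or 'INDEL'")
    if clauses is None:
        clauses = SNP_HARD_FILTER_CLAUSES if mode == "SNP" else INDEL_HARD_FILTER_CLAUSES
    out = []
    for rec in records:
        if rec.vclass == mode:
            for name, clause in clauses.items():
                verdict = clause(rec)
                if verdict:
                    rec.filter_flags.add(name)
        out.append(rec)
    return out


def snp_cluster_filter(
    records: Sequence[VariantRecord],
    window_bp: int = 10,
    min_snps: int = 3,
) -> list[VariantRecord]:
    """Flag every SNP lying in any window of ``window_bp`` holding >= ``min_snps`` SNPs.

    The window is a span of ``window_bp`` bases counted inclusively, so SNPs
    at 100/105/109 (span 10) form a cluster while 100/105/111 (span 12) do
    not. Records must be coordinate-sorted. Flag name: ``SnpCluster``.
    """
    per_chrom: dict[str, list[tuple[int, VariantRecord]]] = {}
    for rec in records:
        if rec.vclass == "SNP":
            per_chrom.setdefault(rec.chrom, []).append((rec.pos, rec))
    for chrom, snps in per_chrom.items():
        pos = [p for p, _ in snps]
        if any(pos[i] > pos[i + 1] for i in range(len(pos) - 1)):
            raise ValidationError(f"records on {chrom} not coordinate-sorted")
        n = len(snps)
        for i in range(n - min_snps + 1):
            j = i + min_snps - 1
            if pos[j] - pos[i] + 1 <= window_bp:
                for _, rec in snps[i : j + 1]:
                    rec.filter_flags.add("SnpCluster")
    return list(records)


# ---------------------------------------------------------------------------
# Pedigree / gene model
# ---------------------------------------------------------------------------

def read_pedigree(path: str) -> Pedigree:
    """Read a 6-column PED-like phenotype file.

    Columns: family, individual, sire, dam, sex, phenotype
    (1 = unaffected, 2 = affected, other = missing).
    """
    samples: list[str] = []
    family: dict[str, str] = {}
    sire: dict[str, str] = {}
    dam: dict[str, str] = {}
    sex: dict[str, int] = {}
    phen: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            fam, iid, s, d, sx, ph = parts[:6]
            if iid in phen:
                raise ValidationError(f"{path}:{lineno}: duplicate sample id {iid!r}")
            samples.append(iid)
            family[iid] = fam
            sire[iid] = s
            dam[iid] = d
            try:
                sex[iid] = int(sx)
            except ValueError:
                sex[iid] = 0
            try:
                phen[iid] = int(ph)
            except ValueError:
                phen[iid] = 0
    return Pedigree(samples, family, sire, dam, sex, phen)


def read_gene_model(path: str) -> GeneModel:
    """Read a GTF 2.2 gene model (gene/transcript/exon/CDS features).

    Validates that each transcript's total CDS length is divisible by 3 and
    that CDS intervals are contained in exons.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("gene_id", [g.id])[0]
        transcripts: list[Transcript] = []
        for t in db.children(g, featuretype="transcript"):
            tid = t.attributes.get("transcript_id", [t.id])[0]
            exons = sorted((f.start, f.end) for f in db.children(t, featuretype="exon"))
            cds = sorted((f.start, f.end) for f in db.children(t, featuretype="CDS"))
            tr = Transcript(tid, exons, cds)
            if tr.cds_length % 3 != 0:
                raise ValidationError(
                    f"transcript {tid}: CDS length {tr.cds_length} not divisible by 3"
                )
            for cs, ce in cds:
                if not any(es <= cs and ce <= ee for es, ee in exons):
                    raise ValidationError(f"transcript {tid}: CDS {cs}-{ce} outside exons")
            transcripts.append(tr)
        if transcripts:
            genes.append(Gene(gene_id, g.seqid, g.strand, transcripts))
    return GeneModel(genes)
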