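"""Phased pedigree simulator with a planted recessive causal haplotype.

The generator emulates the post-variant-calling state of a small two-family
case/control resequencing design: 17 phased diploid samples (4 affected, 13
unaffected), a single chromosome segment carrying an implanted recessive
missense variant on a long shared haplotype block, plus background SNPs and
INDELs with GATK-style QC annotations.

Model, in brief:

* Background allele frequencies are drawn per site from a Beta law; founder
  haplotypes sample alleles independently per site (no background LD beyond
  the pedigree itself).
* The causal haplotype is a single fixed "template" over a block of
  configurable length centred on the causal site. Every carrier founder
  carries one identical copy of the template, mimicking a recent shared
  ancestral haplotype. Within the block the background frequency law is
  skewed towards rare alleles (reduced diversity, as in a swept/IBD region)
  and the template carries its own derived alleles at a configurable rate.
* Inheritance is gene dropping with Haldane recombination (Poisson crossover
  counts, no interference). Transmission at the causal site is constrained
  so the configured genotype composition (affected homozygous carriers,
  a fixed number of heterozygous and homozygous-reference unaffected
  relatives) is realized exactly; elsewhere meioses are unconstrained.
* QC annotation fields are drawn from two mixture components per hard-filter
  clause (pass-like / fail-like) so the expected number of records failing
  each clause is known by construction.

All randomness flows from ``SimConfig.seed`` through fixed substreams, so a
given config reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .variant_io import GenotypeMatrix, Pedigree, VariantRecord

__all__ = [
    "FamilySpec",
    "QcNoise",
    "SimConfig",
    "SimTruth",
    "FounderPanel",
    "CohortPanel",
    "SimConfigError",
    "PedigreeError",
    "simulate_founder_haplotypes",
    "gene_drop",
    "emit_dataset",
    "simulate_dataset",
    "load_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


class PedigreeError(ValueError):
    """Pedigree structure error (missing parent, cycle)."""


@dataclass(frozen=True)
class FamilySpec:
    """Sampled individuals of one family.

    ``n_affected`` offspring are forced homozygous for the causal allele;
    ``n_het_normal`` carry exactly one copy; ``n_homref_normal`` carry none.
    Founders (a carrier sire, a carrier dam for the affected litter and a
    non-carrier dam for the unaffected litter) are simulated but not sampled,
    matching a design where parental tissue is unavailable.
    """

    n_affected: int
    n_het_normal: int
    n_homref_normal: int

    @property
    def n_sampled(self) -> int:
        return self.n_affected + self.n_het_normal + self.n_homref_normal


def _default_snp_noise() -> dict[str, float]:
    return {k: 0.006 for k in ("QUAL", "QD", "MQ", "FS", "MQRankSum", "ReadPosRankSum", "MQ0")}


def _default_indel_noise() -> dict[str, float]:
    return {k: 0.01 for k in ("QD", "FS", "ReadPosRankSum")}


@dataclass(frozen=True)
class QcNoise:
    """Per-clause fraction of sites engineered to fail each hard filter."""

    snp: dict[str, float] = field(default_factory=_default_snp_noise)
    indel: dict[str, float] = field(default_factory=_default_indel_noise)

    @classmethod
    def zero(cls) -> "QcNoise":
        return cls(snp={k: 0.0 for k in _default_snp_noise()},
                   indel={k: 0.0 for k in _default_indel_noise()})


@dataclass(frozen=True)
class SimConfig:
    chrom: str = "11"
    chrom_length_bp: int = 5_000_000
    n_background_snps: int = 17_000
    n_background_indels: int = 3_000
    #: Beta(a, b) law for background allele frequencies outside the block.
    founder_allele_freq_beta: tuple[float, float] = (0.5, 0.5)
    #: Rare-skewed Beta law inside the causal block (reduced diversity).
    block_allele_freq_beta: tuple[float, float] = (0.5, 4.0)
    #: Probability the template haplotype carries the derived allele at a
    #: block site, emulating a young haplotype with private variants.
    template_alt_prob: float = 0.4
    recombination_rate_per_bp: float = 1e-8
    causal_position_bp: int = 2_500_000
    causal_haplotype_length_bp: int = 50_000
    penetrance: float = 1.0
    families: tuple[FamilySpec, ...] = (FamilySpec(3, 4, 9), FamilySpec(1, 0, 0))
    missing_rate: float = 0.0
    qc_annotation_noise: QcNoise = field(default_factory=QcNoise)
    seed: int = 0

    def validate(self) -> None:
        if self.chrom_length_bp <= 0:
            raise SimConfigError("chrom_length_bp must be positive")
        if not (1 <= self.causal_position_bp <= self.chrom_length_bp):
            raise SimConfigError("causal_position_bp outside [1, chrom_length_bp]")
        if not (0.0 <= self.penetrance <= 1.0):
            raise SimConfigError("penetrance must lie in [0, 1]")
        if self.n_background_snps < 0 or self.n_background_indels < 0:
            raise SimConfigError("n_background_snps / n_background_indels must be >= 0")
        if self.causal_haplotype_length_bp <= 0:
            raise SimConfigError("causal_haplotype_length_bp must be positive")
        if self.recombination_rate_per_bp < 0:
            raise SimConfigError("recombination_rate_per_bp must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimConfigError("missing_rate must lie in [0, 1)")
        for name, (a, b) in (
            ("founder_allele_freq_beta", self.founder_allele_freq_beta),
            ("block_allele_freq_beta", self.block_allele_freq_beta),
        ):
            if a <= 0 or b <= 0:
                raise SimConfigError(f"{name} parameters must be positive")
        if not (0.0 <= self.template_alt_prob <= 1.0):
            raise SimConfigError("template_alt_prob must lie in [0, 1]")
        if not self.families or all(f.n_sampled == 0 for f in self.families):
            raise SimConfigError("families must define at least one sampled individual")
        for f in self.families:
            if min(f.n_affected, f.n_het_normal, f.n_homref_normal) < 0:
                raise SimConfigError("families counts must be non-negative")
        # causal gene geometry must fit on the chromosome
        if self.causal_position_bp - self._gene_flank < 1 or (
            self.causal_position_bp + self._gene_flank > self.chrom_length_bp
        ):
            raise SimConfigError(
                "causal_position_bp too close to a chromosome edge for the gene model"
            )

    @property
    def _gene_flank(self) -> int:
        # the implanted gene extends this far either side of the causal site
        return max(30_000, self.causal_haplotype_length_bp // 2 + 5_000)

    @property
    def block(self) -> tuple[int, int]:
        half = self.causal_haplotype_length_bp // 2
        return (max(1, self.causal_position_bp - half),
                min(self.chrom_length_bp, self.causal_position_bp + half))


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    causal_variant: tuple[str, int, str, str]
    carrier_haplotypes: set[tuple[str, int]]
    phenotypes: dict[str, int]  # 2 affected / 1 unaffected
    causal_gene_id: str
    block: tuple[int, int]


@dataclass
class _GeneDef:
    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]


@dataclass
class _Scaffold:
    """Reference sequence, gene layout and the variant site table."""

    chrom: str
    seq: np.ndarray  # uint8 base codes, len = chrom_length_bp
    genes: list[_GeneDef]
    causal_gene_id: str
    pos: np.ndarray  # sorted 1-based site positions
    ref: list[str]
    alt: list[str]
    is_indel: np.ndarray
    causal_index: int
    block_mask: np.ndarray


@dataclass
class FounderPanel:
    """Phased founder haplotypes plus the pedigree they head."""

    scaffold: _Scaffold
    founders: list[str]
    haps: dict[str, np.ndarray]  # sample -> (2, n_sites) int8
    pedigree: Pedigree
    #: (child, "sire"|"dam") -> allele the parent must transmit at the causal site
    transmission_constraints: dict[tuple[str, str], int]
    sampled: list[str]


@dataclass
class CohortPanel:
    """Phased haplotypes of the sampled cohort."""

    scaffold: _Scaffold
    samples: list[str]
    haps: np.ndarray  # (n_samples, 2, n_sites) int8
    pedigree: Pedigree

    def matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(self.samples, self.haps.transpose(2, 0, 1).copy())


# ---------------------------------------------------------------------------
# scaffold construction
# ---------------------------------------------------------------------------

def _build_genes(config: SimConfig) -> tuple[list[_GeneDef], str]:
    p = config.causal_position_bp
    flank = config._gene_flank
    # Implanted gene: minus strand, three exons, 900 bp CDS. Codon 85
    # (CDS offsets 253-255) sits at genomic p+1, p, p-1 so the causal A>G at
    # p changes the second codon position (ATC -> ACC, Ile -> Thr).
    causal = _GeneDef(
        gene_id="",
        strand="-",
        exons=[(p - flank + 1, p + 1), (p + 15_000, p + 15_051), (p + flank - 500, p + flank - 1)],
        cds=[(p - 646, p + 1), (p + 15_000, p + 15_051), (p + flank - 500, p + flank - 301)],
    )
    defs: list[tuple[int, _GeneDef]] = [(p - flank + 1, causal)]
    # background genes: 20 kb, two exons, 600 bp CDS, alternating strand
    for k, frac in enumerate((0.1, 0.3, 0.7, 0.9)):
        s = int(config.chrom_length_bp * frac)
        if s + 20_000 >= config.chrom_length_bp or s < 1:
            continue
        if not (s + 20_000 < p - flank or s > p + flank):
            continue  # keep background genes clear of the implanted gene
        strand = "+" if k % 2 == 0 else "-"
        g = _GeneDef(
            gene_id="",
            strand=strand,
            exons=[(s, s + 499), (s + 19_500, s + 19_999)],
            cds=[(s + 100, s + 499), (s + 19_500, s + 19_699)],
        )
        defs.append((s, g))
    defs.sort(key=lambda t: t[0])
    causal_id = ""
    for i, (_, g) in enumerate(defs, start=1):
        g.gene_id = f"gene{i}"
        if g is causal:
            causal_id = g.gene_id
    return [g for _, g in defs], causal_id


def _build_scaffold(config: SimConfig, rng: np.random.Generator) -> _Scaffold:
    L = config.chrom_length_bp
    p = config.causal_position_bp
    seq = rng.integers(0, 4, size=L, dtype=np.uint8)
    genes, causal_gene_id = _build_genes(config)
    # force the causal codon: genomic bases (p-1, p, p+1) = G, A, T, whose
    # minus-strand reading is ATC (Ile); the A>G change yields ACC (Thr)
    seq[p - 2] = _BASE_STR.index("G")
    seq[p - 1] = _BASE_STR.index("A")
    seq[p] = _BASE_STR.index("T")

    n_bg = config.n_background_snps + config.n_background_indels
    if n_bg > 0:
        lo, hi = 10, L - 10
        if hi - lo < n_bg * 2:
            raise SimConfigError("chrom_length_bp too small for the requested variant count")
        cand = rng.choice(np.arange(lo, hi, dtype=np.int64), size=min(hi - lo, n_bg + 200),
                          replace=False)
        cand = cand[np.abs(cand - p) > 10][:n_bg]
        if cand.size < n_bg:
            raise SimConfigError("could not place the requested number of background variants")
        bg_pos = np.sort(cand)
    else:
        bg_pos = np.empty(0, dtype=np.int64)

    is_indel_bg = np.zeros(bg_pos.size, dtype=bool)
    if config.n_background_indels > 0 and bg_pos.size:
        idx = rng.choice(bg_pos.size, size=config.n_background_indels, replace=False)
        is_indel_bg[idx] = True

    pos = np.sort(np.concatenate([bg_pos, [p]]))
    causal_index = int(np.searchsorted(pos, p))
    is_indel = np.zeros(pos.size, dtype=bool)
    is_indel[np.searchsorted(pos, bg_pos[is_indel_bg])] = True

    ref: list[str] = []
    alt: list[str] = []
    for i, q in enumerate(pos):
        base = _BASE_STR[seq[q - 1]]
        if q == p:
            ref.append("A")
            alt.append("G")
        elif is_indel[i]:
            gap = int(pos[i + 1] - q) if i + 1 < pos.size else 10
            max_del = max(1, min(3, gap - 1))
            if rng.random() < 0.5 or q + max_del > L - 1:
                ins = "".join(_BASE_STR[b] for b in rng.integers(0, 4, size=rng.integers(1, 4)))
                ref.append(base)
                alt.append(base + ins)
            else:
                dl = int(rng.integers(1, max_del + 1))
                ref.append("".join(_BASE_STR[b] for b in seq[q - 1 : q + dl]))
                alt.append(base)
        else:
            others = [b for b in _BASE_STR if b != base]
            ref.append(base)
            alt.append(others[rng.integers(0, 3)])

    b0, b1 = config.block
    block_mask = (pos >= b0) & (pos <= b1)
    return _Scaffold(config.chrom, seq, genes, causal_gene_id, pos, ref, alt,
                     is_indel, causal_index, block_mask)


# ---------------------------------------------------------------------------
# founders and pedigree
# ---------------------------------------------------------------------------

def _build_pedigree(config: SimConfig) -> tuple[Pedigree, dict[tuple[str, str], int], list[str]]:
    samples: list[str] = []
    family: dict[str, str] = {}
    sire: dict[str, str] = {}
    dam: dict[str, str] = {}
    sex: dict[str, int] = {}
    phen: dict[str, int] = {}
    constraints: dict[tuple[str, str], int] = {}
    sampled: list[str] = []

    def add(iid: str, fam: str, s: str, d: str, sx: int, ph: int) -> None:
        samples.append(iid)
        family[iid] = fam
        sire[iid] = s
        dam[iid] = d
        sex[iid] = sx
        phen[iid] = ph

    for fi, spec in enumerate(config.families, start=1):
        fam = f"FAM{fi}"
        sire_id = f"F{fi}_SIRE"
        add(sire_id, fam, "0", "0", 1, 1)
        if spec.n_affected > 0:
            damc = f"F{fi}_DAMC"
            add(damc, fam, "0", "0", 2, 1)
        if spec.n_het_normal + spec.n_homref_normal > 0:
            damn = f"F{fi}_DAMN"
            add(damn, fam, "0", "0", 2, 1)
        sx = 0
        for k in range(spec.n_affected):
            iid = f"F{fi}_A{k + 1}"
            add(iid, fam, sire_id, f"F{fi}_DAMC", 1 + sx % 2, 0)
            constraints[(iid, "sire")] = 1
            constraints[(iid, "dam")] = 1
            sampled.append(iid)
            sx += 1
        for k in range(spec.n_het_normal):
            iid = f"F{fi}_N{k + 1}"
            add(iid, fam, sire_id, f"F{fi}_DAMN", 1 + sx % 2, 0)
            constraints[(iid, "sire")] = 1
            sampled.append(iid)
            sx += 1
        for k in range(spec.n_homref_normal):
            iid = f"F{fi}_N{spec.n_het_normal + k + 1}"
            add(iid, fam, sire_id, f"F{fi}_DAMN", 1 + sx % 2, 0)
            constraints[(iid, "sire")] = 0
            sampled.append(iid)
            sx += 1
    ped = Pedigree(samples, family, sire, dam, sex, phen)
    return ped, constraints, sampled


def simulate_founder_haplotypes(config: SimConfig) -> FounderPanel:
    """Draw phased founder haplotypes with the implanted template block.

    Site allele frequencies follow the configured Beta laws; every carrier
    founder carries one identical copy of the template haplotype over the
    causal block (the shared ancestral segment all affected descend from).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_scaffold, rng_freq, rng_founder, *_ = [np.random.default_rng(s) for s in ss.spawn(6)]
    scaffold = _build_scaffold(config, rng_scaffold)
    ped, constraints, sampled = _build_pedigree(config)

    m = scaffold.pos.size
    a0, b0 = config.founder_allele_freq_beta
    freq = rng_freq.beta(a0, b0, size=m)
    ab, bb = config.block_allele_freq_beta
    nblk = int(scaffold.block_mask.sum())
    freq[scaffold.block_mask] = rng_freq.beta(ab, bb, size=nblk)
    freq[scaffold.causal_index] = 0.0  # derived allele exists only on the template

    template = np.zeros(m, dtype=np.int8)
    tmpl_block = (rng_freq.random(nblk) < config.template_alt_prob).astype(np.int8)
    template[scaffold.block_mask] = tmpl_block
    template[scaffold.causal_index] = 1

    haps: dict[str, np.ndarray] = {}
    founders = ped.founders()
    for iid in founders:
        h = (rng_founder.random((2, m)) < freq).astype(np.int8)
        if iid.endswith("_SIRE") or iid.endswith("_DAMC"):
            h[0, scaffold.block_mask] = template[scaffold.block_mask]
            h[0, scaffold.causal_index] = 1
        haps[iid] = h
    return FounderPanel(scaffold, founders, haps, ped, constraints, sampled)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _meiosis(
    parent_haps: np.ndarray,
    positions: np.ndarray,
    chrom_length: int,
    rate: float,
    rng: np.random.Generator,
    forced_allele: int | None,
    causal_index: int,
) -> np.ndarray:
    """One gamete: Haldane crossovers (Poisson count, uniform positions).

    If ``forced_allele`` is given, the two parental haplotype labels are
    swapped when needed so the gamete carries that allele at the causal
    site — a distribution-preserving conditioning, since the crossover
    mosaic is exchangeable in the labels.
    """
    n_x = rng.poisson(rate * chrom_length)
    start = int(rng.integers(0, 2))
    if n_x == 0:
        hap_idx = np.full(positions.size, start, dtype=np.int8)
    else:
        xpos = np.sort(rng.uniform(1, chrom_length, size=n_x))
        hap_idx = ((start + np.searchsorted(xpos, positions, side="left")) % 2).astype(np.int8)
    gamete = parent_haps[hap_idx, np.arange(positions.size)]
    if forced_allele is not None and gamete[causal_index] != forced_allele:
        hap_idx = 1 - hap_idx
        gamete = parent_haps[hap_idx, np.arange(positions.size)]
        if gamete[causal_index] != forced_allele:
            raise PedigreeError(
                "cannot satisfy transmission constraint: parent lacks the required allele"
            )
    return gamete


def gene_drop(
    founders: FounderPanel,
    pedigree: Pedigree | None = None,
    config: SimConfig | None = None,
) -> tuple[CohortPanel, SimTruth]:
    """Transmit founder haplotypes down the pedigree.

    Each offspring haplotype is a recombinant of one parent's two
    haplotypes; crossover counts per meiosis are Poisson with mean
    ``recombination_rate_per_bp * chrom_length_bp`` (Haldane, no
    interference). Phase is recorded exactly (haplotype 0 paternal,
    haplotype 1 maternal). Affected status is assigned to causal
    homozygotes with probability ``penetrance``.
    """
    if config is None:
        raise ValueError("config is required")
    if pedigree is None:
        pedigree = founders.pedigree
    scaffold = founders.scaffold
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(6)
    rng_drop = np.random.default_rng(streams[3])

    haps: dict[str, np.ndarray] = dict(founders.haps)
    pending = [s for s in pedigree.samples if s not in haps]
    m = scaffold.pos.size
    progressed = True
    while pending and progressed:
        progressed = False
        remaining = []
        for child in pending:
            s, d = pedigree.parents(child)
            if s is None or d is None:
                raise PedigreeError(f"non-founder {child!r} has an unknown parent")
            if s in haps and d in haps:
                gam_s = _meiosis(
                    haps[s], scaffold.pos, config.chrom_length_bp,
                    config.recombination_rate_per_bp, rng_drop,
                    founders.transmission_constraints.get((child, "sire")),
                    scaffold.causal_index,
                )
                gam_d = _meiosis(
                    haps[d], scaffold.pos, config.chrom_length_bp,
                    config.recombination_rate_per_bp, rng_drop,
                    founders.transmission_constraints.get((child, "dam")),
                    scaffold.causal_index,
                )
                haps[child] = np.stack([gam_s, gam_d])
                progressed = True
            else:
                remaining.append(child)
        pending = remaining
    if pending:
        raise PedigreeError(f"pedigree cycle or missing parent involving {pending!r}")

    sampled = founders.sampled
    cohort = np.stack([haps[s] for s in sampled])  # (n, 2, m)
    ci = scaffold.causal_index
    phenotypes: dict[str, int] = {}
    carrier_haps: set[tuple[str, int]] = set()
    for i, iid in enumerate(sampled):
        g = cohort[i, :, ci]
        for hx in (0, 1):
            if g[hx] == 1:
                carrier_haps.add((iid, hx))
        hom = g[0] == 1 and g[1] == 1
        affected = hom and (rng_drop.random() < config.penetrance)
        phenotypes[iid] = 2 if affected else 1
        pedigree.phenotype[iid] = phenotypes[iid]

    sub_ped = Pedigree(
        samples=list(sampled),
        family={s: pedigree.family[s] for s in sampled},
        sire={s: "0" for s in sampled},  # parents are unsampled
        dam={s: "0" for s in sampled},
        sex={s: pedigree.sex[s] for s in sampled},
        phenotype={s: phenotypes[s] for s in sampled},
    )
    truth = SimTruth(
        causal_variant=(scaffold.chrom, int(scaffold.pos[ci]), scaffold.ref[ci], scaffold.alt[ci]),
        carrier_haplotypes=carrier_haps,
        phenotypes=phenotypes,
        causal_gene_id=scaffold.causal_gene_id,
        block=(int(config.block[0]), int(config.block[1])),
    )
    return CohortPanel(scaffold, list(sampled), cohort, sub_ped), truth


# ---------------------------------------------------------------------------
# QC annotations
# ---------------------------------------------------------------------------

def _qc_values(
    is_indel: np.ndarray,
    causal_index: int,
    noise: QcNoise,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict[str, float]]]:
    """QUAL plus INFO annotations per site; two mixture components per clause."""
    m = is_indel.size
    qual = rng.uniform(60.0, 1500.0, size=m)
    qd = rng.uniform(5.0, 35.0, size=m)
    mq = rng.uniform(45.0, 60.0, size=m)
    fs = rng.uniform(0.0, 30.0, size=m)
    mqrs = rng.uniform(-5.0, 5.0, size=m)
    rprs = rng.uniform(-5.0, 5.0, size=m)
    dp = rng.integers(300, 900, size=m).astype(float)
    mq0 = rng.integers(0, 4, size=m).astype(float)

    snp = ~is_indel
    for clause, frac in noise.snp.items():
        if frac <= 0:
            continue
        fail = snp & (rng.random(m) < frac)
        k = int(fail.sum())
        if k == 0:
            continue
        if clause == "QUAL":
            qual[fail] = rng.uniform(1.0, 40.0, size=k)
        elif clause == "QD":
            qd[fail] = rng.uniform(0.05, 2.0, size=k)
        elif clause == "MQ":
            mq[fail] = rng.uniform(10.0, 40.0, size=k)
        elif clause == "FS":
            fs[fail] = rng.uniform(60.0, 250.0, size=k)
        elif clause == "MQRankSum":
            mqrs[fail] = rng.uniform(-25.0, -12.6, size=k)
        elif clause == "ReadPosRankSum":
            rprs[fail] = rng.uniform(-15.0, -8.05, size=k)
        elif clause == "MQ0":
            dpf = rng.integers(20, 60, size=k).astype(float)
            dp[fail] = dpf
            mq0[fail] = np.maximum(4.0, np.ceil(0.12 * dpf))
    for clause, frac in noise.indel.items():
        if frac <= 0:
            continue
        fail = is_indel & (rng.random(m) < frac)
        k = int(fail.sum())
        if k == 0:
            continue
        if clause == "QD":
            qd[fail] = rng.uniform(0.05, 1.95, size=k)
        elif clause == "FS":
            fs[fail] = rng.uniform(200.5, 400.0, size=k)
        elif clause == "ReadPosRankSum":
            rprs[fail] = rng.uniform(-40.0, -20.5, size=k)

    # the implanted causal variant always passes QC
    qual[causal_index] = 900.0
    qd[causal_index] = 25.0
    mq[causal_index] = 59.0
    fs[causal_index] = 1.0
    mqrs[causal_index] = 0.5
    rprs[causal_index] = 0.5
    dp[causal_index] = 600.0
    mq0[causal_index] = 0.0

    ann = [
        {
            "QD": round(float(qd[i]), 2),
            "MQ": round(float(mq[i]), 2),
            "FS": round(float(fs[i]), 3),
            "MQRankSum": round(float(mqrs[i]), 3),
            "ReadPosRankSum": round(float(rprs[i]), 3),
            "MQ0": float(int(mq0[i])),
            "DP": float(int(dp[i])),
        }
        for i in range(m)
    ]
    return np.round(qual, 2), ann


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def _write_fasta(scaffold: _Scaffold, path: Path, width: int = 60) -> None:
    s = _BASES[scaffold.seq].tobytes().decode()
    with open(path, "w") as fh:
        fh.write(f">{scaffold.chrom}\n")
        for i in range(0, len(s), width):
            fh.write(s[i : i + width] + "\n")


def _gtf_frame(cds: list[tuple[int, int]], strand: str) -> list[int]:
    order = cds if strand == "+" else list(reversed(cds))
    frames = []
    cum = 0
    for s, e in order:
        frames.append((3 - cum % 3) % 3)
        cum += e - s + 1
    return frames if strand == "+" else list(reversed(frames))


def _write_gtf(scaffold: _Scaffold, path: Path) -> None:
    with open(path, "w") as fh:
        for g in scaffold.genes:
            tid = f"{g.gene_id}.t1"
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
            start = min(s for s, _ in g.exons)
            end = max(e for _, e in g.exons)
            fh.write(f"{scaffold.chrom}\tsim\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                     f'gene_id "{g.gene_id}";\n')
            fh.write(f"{scaffold.chrom}\tsim\ttranscript\t{start}\t{end}\t.\t{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{scaffold.chrom}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            for (s, e), fr in zip(g.cds, _gtf_frame(g.cds, g.strand)):
                fh.write(f"{scaffold.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t{fr}\t{attrs}\n")


def _write_truth(truth: SimTruth, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("record\tkey\tvalue\n")
        c, p, r, a = truth.causal_variant
        fh.write(f"causal_variant\tchrom\t{c}\n")
        fh.write(f"causal_variant\tpos\t{p}\n")
        fh.write(f"causal_variant\tref\t{r}\n")
        fh.write(f"causal_variant\talt\t{a}\n")
        fh.write(f"causal_gene\tid\t{truth.causal_gene_id}\n")
        fh.write(f"block\tstart\t{truth.block[0]}\n")
        fh.write(f"block\tend\t{truth.block[1]}\n")
        for s in sorted(truth.phenotypes):
            fh.write(f"phenotype\t{s}\t{truth.phenotypes[s]}\n")
        for s, hx in sorted(truth.carrier_haplotypes):
            fh.write(f"carrier_haplotype\t{s}\t{hx}\n")


def load_truth(path: str) -> SimTruth:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("record")
        for line in fh:
            rows.append(line.rstrip("\n").split("\t"))
    kv = {(r[0], r[1]): r[2] for r in rows}
    phen = {r[1]: int(r[2]) for r in rows if r[0] == "phenotype"}
    carriers = {(r[1], int(r[2])) for r in rows if r[0] == "carrier_haplotype"}
    return SimTruth(
        causal_variant=(kv[("causal_variant", "chrom")], int(kv[("causal_variant", "pos")]),
                        kv[("causal_variant", "ref")], kv[("causal_variant", "alt")]),
        carrier_haplotypes=carriers,
        phenotypes=phen,
        causal_gene_id=kv[("causal_gene", "id")],
        block=(int(kv[("block", "start")]), int(kv[("block", "end")])),
    )


def emit_dataset(
    panel: CohortPanel,
    truth: SimTruth,
    config: SimConfig,
    outdir: str,
) -> dict[str, Path]:
    """Write VCF + PED + FASTA + GTF + truth file for a simulated cohort.

    Identical config (including seed) reproduces byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    scaffold = panel.scaffold
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(6)
    rng_qc = np.random.default_rng(streams[4])
    rng_miss = np.random.default_rng(streams[5])

    qual, ann = _qc_values(scaffold.is_indel, scaffold.causal_index,
                           config.qc_annotation_noise, rng_qc)
    records = [
        VariantRecord(
            chrom=scaffold.chrom,
            pos=int(scaffold.pos[i]),
            id=None,
            ref=scaffold.ref[i],
            alts=[scaffold.alt[i]],
            qual=float(qual[i]),
            annotations=ann[i],
        )
        for i in range(scaffold.pos.size)
    ]
    alleles = panel.haps.transpose(2, 0, 1).astype(np.int16).copy()
    if config.missing_rate > 0:
        miss = rng_miss.random(alleles.shape[:2]) < config.missing_rate
        miss[scaffold.causal_index, :] = False
        alleles[miss] = -1
    matrix = GenotypeMatrix(panel.samples, alleles)

    paths = {
        "vcf": out / "cohort.vcf",
        "ped": out / "cohort.ped",
        "fasta": out / "reference.fa",
        "gtf": out / "genes.gtf",
        "truth": out / "truth.tsv",
    }
    from .variant_io import write_vcf

    write_vcf(records, matrix, str(paths["vcf"]),
              contigs={scaffold.chrom: config.chrom_length_bp})
    with open(paths["ped"], "w") as fh:
        ped = panel.pedigree
        for s in ped.samples:
            fh.write(f"{ped.family[s]}\t{s}\t{ped.sire[s]}\t{ped.dam[s]}\t"
                     f"{ped.sex[s]}\t{ped.phenotype[s]}\n")
    _write_fasta(scaffold, paths["fasta"])
    _write_gtf(scaffold, paths["gtf"])
    _write_truth(truth, paths["truth"])
    return paths


def simulate_dataset(config: SimConfig, outdir: str) -> tuple[dict[str, Path], SimTruth]:
    """Full generator: founders -> gene drop -> files on disk."""
    founders = simulate_founder_haplotypes(config)
    panel, truth = gene_drop(founders, config=config)
    paths = emit_dataset(panel, truth, config, outdir)
    return paths, truth
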