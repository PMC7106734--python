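"""Generator contracts: Mendelian consistency, recombination model,
frequency law, QC-noise engineering and byte-level determinism."""

from __future__ import annotations

import numpy as np
import pytest

from ppdscan.synthetic_data import (
    FamilySpec,
    PedigreeError,
    QcNoise,
    SimConfig,
    SimConfigError,
    _meiosis,
    gene_drop,
    simulate_dataset,
    simulate_founder_haplotypes,
)
from ppdscan.variant_io import apply_hard_filters, read_vcf


def _replace(cfg: SimConfig, **kw) -> SimConfig:
    from dataclasses import replace

    return replace(cfg, **kw)


BASE = SimConfig(
    chrom_length_bp=400_000,
    n_background_snps=800,
    n_background_indels=100,
    causal_position_bp=200_000,
    seed=3,
)


@pytest.mark.parametrize(
    "field, value",
    [
        ("penetrance", 1.5),
        ("causal_position_bp", 0),
        ("n_background_snps", -1),
        ("chrom_length_bp", 0),
        ("recombination_rate_per_bp", -1e-8),
        ("founder_allele_freq_beta", (0.0, 1.0)),
    ],
)
def test_invalid_config_names_field(field, value):
    cfg = _replace(BASE, **{field: value})
    with pytest.raises(SimConfigError, match=field.split("_")[0]):
        cfg.validate()


def test_empty_background_panel_contains_only_causal_site():
    cfg = _replace(BASE, n_background_snps=0, n_background_indels=0)
    founders = simulate_founder_haplotypes(cfg)
    assert founders.scaffold.pos.tolist() == [cfg.causal_position_bp]
    assert founders.scaffold.ref[0] == "A" and founders.scaffold.alt[0] == "G"


def test_template_block_identical_across_carrier_founders():
    founders = simulate_founder_haplotypes(BASE)
    blk = founders.scaffold.block_mask
    carriers = [s for s in founders.founders if s.endswith(("_SIRE", "_DAMC"))]
    assert len(carriers) >= 2
    first = founders.haps[carriers[0]][0, blk]
    for c in carriers[1:]:
        assert np.array_equal(founders.haps[c][0, blk], first)
    # the causal derived allele rides only on the template
    ci = founders.scaffold.causal_index
    for s in founders.founders:
        for hx in (0, 1):
            is_template = s in carriers and hx == 0
            assert founders.haps[s][hx, ci] == (1 if is_template else 0)


def test_penetrance_one_affected_equals_causal_homozygotes():
    founders = simulate_founder_haplotypes(BASE)
    panel, truth = gene_drop(founders, config=BASE)
    ci = panel.scaffold.causal_index
    for i, s in enumerate(panel.samples):
        hom = panel.haps[i, 0, ci] == 1 and panel.haps[i, 1, ci] == 1
        assert (truth.phenotypes[s] == 2) == hom
    assert sum(1 for v in truth.phenotypes.values() if v == 2) == 4
    assert len(panel.samples) == 17


def test_allele_conservation_every_offspring_allele_from_a_parent():
    founders = simulate_founder_haplotypes(BASE)
    panel, _ = gene_drop(founders, config=BASE)
    ped = founders.pedigree
    for i, child in enumerate(panel.samples):
        sire, dam = ped.parents(child)
        for hx, parent in ((0, sire), (1, dam)):
            ph = founders.haps[parent]
            gamete = panel.haps[i, hx]
            ok = (gamete == ph[0]) | (gamete == ph[1])
            assert ok.all()


def test_no_recombination_copies_a_parental_haplotype_exactly():
    cfg = _replace(BASE, recombination_rate_per_bp=0.0)
    founders = simulate_founder_haplotypes(cfg)
    panel, _ = gene_drop(founders, config=cfg)
    ped = founders.pedigree
    for i, child in enumerate(panel.samples):
        sire, dam = ped.parents(child)
        for hx, parent in ((0, sire), (1, dam)):
            ph = founders.haps[parent]
            gamete = panel.haps[i, hx]
            assert np.array_equal(gamete, ph[0]) or np.array_equal(gamete, ph[1])


def test_crossover_count_matches_haldane_poisson_mean():
    # 10,000 meioses at 1e-8/bp over 10 Mb: mean crossovers/meiosis ~ 0.1.
    # Parent haplotypes are all-0 vs all-1, so each switch in the gamete
    # marks a crossover between adjacent markers (double crossovers within
    # one 10 kb inter-marker gap are negligible at this rate).
    rng = np.random.default_rng(42)
    L = 10_000_000
    positions = np.linspace(1, L, 1000).astype(np.int64)
    parent = np.vstack([np.zeros(1000, np.int8), np.ones(1000, np.int8)])
    n_meioses = 10_000
    switches = 0
    for _ in range(n_meioses):
        g = _meiosis(parent, positions, L, 1e-8, rng, None, 0)
        switches += int((np.diff(g) != 0).sum())
    mean = switches / n_meioses
    se = np.sqrt(0.1 / n_meioses)
    assert abs(mean - 0.1) < 3 * se


def test_founder_frequencies_match_beta_law_moments():
    # Empirical mean and variance of per-site haplotype allele frequencies
    # against the analytic Beta-binomial moments, within 3 standard errors.
    cfg = _replace(
        BASE,
        n_background_snps=1000,
        n_background_indels=0,
        families=(FamilySpec(0, 0, 2),),
        founder_allele_freq_beta=(0.5, 0.5),
        seed=7,
    )
    founders = simulate_founder_haplotypes(cfg)
    out = ~founders.scaffold.block_mask  # block sites follow a different law
    haps = np.vstack([founders.haps[s] for s in founders.founders])
    # drop the template haplotype (carrier sire hap 0 is constrained in-block only,
    # so outside the block every haplotype is an iid Bernoulli(q) draw)
    x = haps[:, out].mean(axis=0)  # per-site frequency over H haplotypes
    H = haps.shape[0]
    a, b = 0.5, 0.5
    mean_q = a / (a + b)
    var_q = a * b / ((a + b) ** 2 * (a + b + 1))
    var_x = var_q + (mean_q * (1 - mean_q) - var_q) / H  # Beta-binomial/H^2 moment
    S = x.size
    se_mean = np.sqrt(var_x / S)
    assert abs(x.mean() - mean_q) < 3 * se_mean
    # variance of the site-frequency distribution, generous 4-se band
    se_var = np.sqrt(2.0 / S) * var_x  # rough normal-theory se for a variance
    assert abs(x.var() - var_x) < 4 * se_var


def test_same_seed_reproduces_byte_identical_files(tmp_path):
    cfg = _replace(BASE, n_background_snps=300, n_background_indels=50)
    p1, _ = simulate_dataset(cfg, tmp_path / "a")
    p2, _ = simulate_dataset(cfg, tmp_path / "b")
    for key in ("vcf", "ped", "fasta", "gtf", "truth"):
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_zero_qc_noise_means_no_hard_filter_failures(tmp_path):
    cfg = _replace(BASE, qc_annotation_noise=QcNoise.zero())
    paths, _ = simulate_dataset(cfg, tmp_path)
    records, _ = read_vcf(str(paths["vcf"]))
    apply_hard_filters(records, "SNP")
    apply_hard_filters(records, "INDEL")
    assert all(r.passes_filters for r in records)


def test_qc_noise_fractions_engineer_expected_failure_counts(tmp_path):
    frac = 0.2
    noise = QcNoise(
        snp={**{k: 0.0 for k in QcNoise().snp}, "QD": frac},
        indel={k: 0.0 for k in QcNoise().indel},
    )
    cfg = _replace(BASE, n_background_snps=2000, n_background_indels=0,
                   qc_annotation_noise=noise, seed=5)
    paths, _ = simulate_dataset(cfg, tmp_path)
    records, _ = read_vcf(str(paths["vcf"]))
    apply_hard_filters(records, "SNP")
    flagged = sum(1 for r in records if "QD" in r.filter_flags)
    others = sum(1 for r in records if r.filter_flags - {"QD"})
    n = 2000
    tol = 4 * np.sqrt(n * frac * (1 - frac))
    assert abs(flagged - n * frac) < tol
    assert others == 0


def test_missing_parent_raises_pedigree_error():
    founders = simulate_founder_haplotypes(BASE)
    ped = founders.pedigree
    ped.sire["F1_A1"] = "GHOST"
    with pytest.raises(PedigreeError):
        gene_drop(founders, ped, BASE)


def test_causal_codon_is_isoleucine_to_threonine(tmp_path):
    # the implanted missense change must read ATC->ACC (I->T) at protein
    # position 85 once the emitted GTF/FASTA are parsed back
    from ppdscan.annotate import classify_variant
    from ppdscan.variant_io import read_gene_model
    import pyfaidx

    paths, truth = simulate_dataset(BASE, tmp_path)
    records, _ = read_vcf(str(paths["vcf"]))
    model = read_gene_model(str(paths["gtf"]))
    fa = pyfaidx.Fasta(str(paths["fasta"]))
    reference = {name: str(fa[name][:]) for name in fa.keys()}
    causal = next(r for r in records if r.pos == truth.causal_variant[1])
    ann = classify_variant(causal, model, reference)
    assert ann.region_class == "CDS_nonsynonymous"
    assert ann.gene_id == truth.causal_gene_id
    assert ann.aa_string == "I85T"
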