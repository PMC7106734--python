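"""Weir-Cockerham F_ST against an exact rational-arithmetic oracle, plus
window arithmetic, thresholds and permutation-null sanity."""

from __future__ import annotations

from fractions import Fraction as F

import numpy as np
import pandas as pd
import pytest

from ppdscan.fst import (
    WindowStat,
    filter_windows,
    fst_windows,
    merge_regions,
    site_fst_table,
    wc_fst_site,
)
from tests.conftest import TOP_SNP_GENOTYPES, cohort_from_genotypes


def wc84_oracle(case_gts, ctrl_gts):
    """Independent implementation of the 1984 two-population diploid
    variance components, in exact rational arithmetic, straight from the
    textbook definitions (r=2, observed-heterozygosity correction)."""

    def stats(gts):
        n = len(gts)
        alt = sum(a + b for a, b in gts)
        het = sum(1 for a, b in gts if a != b)
        return n, F(alt, 2 * n), F(het, n)

    n1, p1, h1 = stats(case_gts)
    n2, p2, h2 = stats(ctrl_gts)
    r = 2
    nbar = F(n1 + n2, 2)
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - F(r - 1, r) * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - F(r - 1, r) * s2 - F(2 * nbar - 1, 4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def _random_config(rng):
    n1 = int(rng.integers(2, 10))
    n2 = int(rng.integers(2, 16))
    case = [tuple(int(x) for x in rng.integers(0, 2, 2)) for _ in range(n1)]
    ctrl = [tuple(int(x) for x in rng.integers(0, 2, 2)) for _ in range(n2)]
    return case, ctrl


def test_components_match_rational_oracle_on_random_configurations():
    rng = np.random.default_rng(20)
    checked = 0
    while checked < 100:
        case, ctrl = _random_config(rng)
        rec, m, ped = cohort_from_genotypes(case, ctrl)
        site = wc_fst_site(rec, m, ped)
        a, b, c = wc84_oracle(case, ctrl)
        assert abs(site.a - float(a)) < 1e-12
        assert abs(site.b - float(b)) < 1e-12
        assert abs(site.c - float(c)) < 1e-12
        checked += 1


@pytest.mark.parametrize("n1, n2", [(2, 2), (4, 13), (3, 7), (2, 9), (6, 11)])
def test_fixed_difference_gives_exactly_one(n1, n2):
    rec, m, ped = cohort_from_genotypes([(1, 1)] * n1, [(0, 0)] * n2)
    assert wc_fst_site(rec, m, ped).fst == 1.0


def test_identical_group_compositions_give_nonpositive_fst():
    gts = [(0, 0), (0, 1), (1, 1), (0, 1)]
    rec, m, ped = cohort_from_genotypes(gts, gts)
    site = wc_fst_site(rec, m, ped)
    assert site.fst <= 0  # negative estimates are reported as computed


def test_published_exonic_genotype_row_matches_oracle():
    row = TOP_SNP_GENOTYPES["exonic_70439379"]
    rec, m, ped = cohort_from_genotypes(row["cases"], row["controls"])
    site = wc_fst_site(rec, m, ped)
    a, b, c = wc84_oracle(row["cases"], row["controls"])
    assert site.fst == pytest.approx(float(a / (a + b + c)), abs=1e-12)


def test_group_swap_leaves_estimate_unchanged():
    rng = np.random.default_rng(21)
    for _ in range(20):
        case, ctrl = _random_config(rng)
        rec, m1, p1 = cohort_from_genotypes(case, ctrl)
        _, m2, p2 = cohort_from_genotypes(ctrl, case)
        s1, s2 = wc_fst_site(rec, m1, p1), wc_fst_site(rec, m2, p2)
        assert s1.fst == pytest.approx(s2.fst, abs=1e-12, nan_ok=True)


def test_group_missing_at_site_is_skipped_with_reason():
    rec, m, ped = cohort_from_genotypes([(-1, -1), (-1, -1)], [(0, 1), (0, 0)])
    with pytest.raises(ValueError, match="skipped"):
        wc_fst_site(rec, m, ped)


def test_window_weighted_ratio_of_sums():
    sites = pd.DataFrame(
        {"chrom": ["1", "1"], "pos": [100, 200], "a": [1.0, 0.0], "d": [2.0, 2.0],
         "fst": [0.5, 0.0]}
    )
    w = fst_windows(sites, span_bp=10_000, step_bp=10_000, chrom_length=10_000)
    assert len(w) == 1
    assert w[0].weighted_fst == pytest.approx(0.25)  # (1+0)/(2+2)
    assert w[0].n_variants == 2
    single = pd.DataFrame({"chrom": ["1"], "pos": [100], "a": [3.0], "d": [3.0],
                           "fst": [1.0]})
    w2 = fst_windows(single, 10_000, 10_000, 10_000)
    assert w2[0].weighted_fst == 1.0


def test_windows_tile_with_span_and_step_and_match_bruteforce(small_dataset):
    from ppdscan.variant_io import read_pedigree, read_vcf

    paths, _, cfg = small_dataset
    records, matrix = read_vcf(str(paths["vcf"]))
    ped = read_pedigree(str(paths["ped"]))
    snps = [r for r in records if r.vclass == "SNP"]
    mask = np.array([r.vclass == "SNP" for r in records])
    from ppdscan.variant_io import GenotypeMatrix

    m = GenotypeMatrix(matrix.samples, matrix.alleles[mask], matrix.phased[mask])
    sites = site_fst_table(snps, m, ped)
    wins = fst_windows(sites, 10_000, 2_000, cfg.chrom_length_bp)
    starts = sorted({w.start for w in wins})
    assert starts[:3] == [1, 2001, 4001]
    assert all(w.end - w.start + 1 == 10_000 for w in wins)
    # brute-force recomputation of every 25th window
    pos = sites["pos"].to_numpy()
    for w in wins[::25]:
        in_w = (pos >= w.start) & (pos <= w.end)
        assert w.n_variants == int(in_w.sum())
        if w.n_variants:
            num = sites["a"].to_numpy()[in_w].sum()
            den = sites["d"].to_numpy()[in_w].sum()
            expect = num / den if den != 0 else float("nan")
            assert w.weighted_fst == pytest.approx(expect, nan_ok=True)
        else:
            assert np.isnan(w.weighted_fst)


@pytest.mark.parametrize(
    "weighted, n, kept",
    [(0.61, 10, True), (0.60, 50, False), (0.9, 9, False), (0.601, 10, True)],
)
def test_window_thresholds_strict_on_statistic_inclusive_on_count(weighted, n, kept):
    w = WindowStat("1", 1, 10_000, n, weighted, weighted)
    assert (len(filter_windows([w])) == 1) == kept


def test_merge_regions_joins_overlapping_windows():
    wins = [WindowStat("1", 1, 10_000, 10, 0.7, 0.7),
            WindowStat("1", 8_001, 18_000, 10, 0.7, 0.7),
            WindowStat("1", 50_001, 60_000, 10, 0.7, 0.7),
            WindowStat("2", 1, 10_000, 10, 0.7, 0.7)]
    assert merge_regions(wins) == [("1", 1, 18_000), ("1", 50_001, 60_000),
                                   ("2", 1, 10_000)]


def test_permutation_null_rarely_exceeds_threshold():
    # groups drawn from a single population: windows above 0.6 must be rare
    rng = np.random.default_rng(33)
    m_sites, n_ind = 2_000, 17
    freq = rng.beta(0.5, 0.5, size=m_sites)
    alleles = (rng.random((m_sites, n_ind, 2)) < freq[:, None, None]).astype(np.int16)
    pos = np.sort(rng.choice(np.arange(1, 1_000_000), size=m_sites, replace=False))
    from ppdscan.variant_io import GenotypeMatrix, Pedigree, VariantRecord

    samples = [f"s{i}" for i in range(n_ind)]
    exceed = total = 0
    for _ in range(5):
        labels = rng.permutation([2] * 4 + [1] * 13)
        ped = Pedigree(samples, {s: "F" for s in samples}, {s: "0" for s in samples},
                       {s: "0" for s in samples}, {s: 1 for s in samples},
                       dict(zip(samples, (int(x) for x in labels))))
        recs = [VariantRecord("1", int(p), None, "A", ["G"]) for p in pos]
        sites = site_fst_table(recs, GenotypeMatrix(samples, alleles), ped)
        wins = [w for w in fst_windows(sites, 10_000, 2_000, 1_000_000)
                if w.n_variants >= 10]
        exceed += sum(1 for w in wins if w.weighted_fst > 0.6)
        total += len(wins)
    assert total > 100
    assert exceed / total < 0.05  # mass far below the significance threshold


def test_span_smaller_than_step_rejected():
    with pytest.raises(ValueError):
        fst_windows(pd.DataFrame({"chrom": [], "pos": [], "a": [], "d": [], "fst": []}),
                    span_bp=1_000, step_bp=2_000)
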