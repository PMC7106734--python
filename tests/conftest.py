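"""Shared fixtures: tiny cohorts built from genotype counts, and the
published top-SNP genotype configurations used as worked examples."""

from __future__ import annotations

import numpy as np
import pytest

from ppdscan.variant_io import GenotypeMatrix, Pedigree, VariantRecord


def cohort_from_genotypes(
    case_gts: list[tuple[int, int]],
    control_gts: list[tuple[int, int]],
    chrom: str = "11",
    pos: int = 100,
    ref: str = "A",
    alt: str = "G",
) -> tuple[VariantRecord, GenotypeMatrix, Pedigree]:
    """One-site cohort: cases first, then controls."""
    gts = case_gts + control_gts
    samples = [f"s{i}" for i in range(len(gts))]
    alleles = np.array(gts, dtype=np.int16).reshape(1, len(gts), 2)
    ped = Pedigree(
        samples=samples,
        family={s: "FAM1" for s in samples},
        sire={s: "0" for s in samples},
        dam={s: "0" for s in samples},
        sex={s: 1 for s in samples},
        phenotype={s: (2 if i < len(case_gts) else 1) for i, s in enumerate(samples)},
    )
    rec = VariantRecord(chrom, pos, None, ref, [alt])
    return rec, GenotypeMatrix(samples, alleles), ped


# Published genotype compositions of the four worked-example SNPs
# (4 affected vs 13 unaffected pigs), with their printed allelic chi-squares.
TOP_SNP_GENOTYPES = {
    "rs791053563": {
        "cases": [(0, 0)] * 4,
        "controls": [(1, 1)] * 11 + [(0, 1)] * 2,
        "chisq": 25.11,
        "p": 5.422e-7,
    },
    "rs709805150": {
        "cases": [(1, 1)] * 3 + [(0, 0)],
        "controls": [(0, 0)] * 13,
        "chisq": 23.68,
        "p": 1.138e-6,
    },
    "rs711914258": {
        "cases": [(1, 1)] * 4,
        "controls": [(0, 0)] * 11 + [(0, 1)] + [(1, 1)],
        "chisq": 21.87,
        "p": 2.911e-6,
    },
    "exonic_70439379": {
        "cases": [(1, 1)] * 4,
        "controls": [(0, 0)] * 9 + [(0, 1)] * 4,
        "chisq": 19.18,
        "p": 1.19e-5,
    },
}


@pytest.fixture(scope="session")
def small_sim_config():
    """A quick-to-generate dataset exercising every pipeline stage."""
    from ppdscan.synthetic_data import SimConfig

    return SimConfig(
        chrom_length_bp=500_000,
        n_background_snps=1_700,
        n_background_indels=300,
        causal_position_bp=250_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_sim_config, tmp_path_factory):
    """Simulated files + truth for the small config (generated once)."""
    from ppdscan.synthetic_data import simulate_dataset

    outdir = tmp_path_factory.mktemp("smallsim")
    paths, truth = simulate_dataset(small_sim_config, str(outdir))
    return paths, truth, small_sim_config
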