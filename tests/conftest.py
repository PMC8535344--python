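"""Shared fixtures: small synthetic cohorts and genotype matrices.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pandas as pd
import pytest

import sibscan as sb


@pytest.fixture(scope="session")
def marker_map9():
    return sb.default_marker_map(9)


@pytest.fixture(scope="session")
def pool9(marker_map9):
    """3-block founder pool over 9 markers, moderately high MAF."""
    return sb.build_founder_pool(marker_map9, n_blocks=3, haplos_per_block=3,
                                 seed=42, maf_range=(0.3, 0.5))


@pytest.fixture(scope="session")
def cohort114(pool9):
    """Study-sized cohort: 114 sib pairs, causal marker in the middle block."""
    cfg = sb.SimulationConfig(n_pairs=114, causal_marker="snp005",
                              effect_size=1.0, seed=7)
    cohort = sb.simulate_families(pool9, cfg)
    phenotypes = sb.attach_phenotypes(cohort, cfg)
    return cohort, phenotypes, cfg


def genotypes_from_dosage(dosage, marker_ids=None, alleles=None):
    """Construct a GenotypeMatrix straight from a dosage array (test helper)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    marker_ids = marker_ids or [f"m{j + 1}" for j in range(m)]
    alleles = alleles or [("A", "G")] * m
    mm = sb.marker_map_from_arrays(
        marker_ids, [1000 * (j + 1) for j in range(m)],
        [a for a, _ in alleles], [b for _, b in alleles])
    return sb.GenotypeMatrix([f"s{i + 1}" for i in range(n)], mm, dosage)


@pytest.fixture
def toy_genotypes():
    return genotypes_from_dosage


def make_phenotypes(values):
    """PhenotypeTable from (sample_id, family_id, weight, fev1[, birth_year])."""
    rows = []
    for v in values:
        rows.append({
            "sample_id": v[0], "family_id": v[1],
            "weight_pct_pred": v[2], "fev1_centile": v[3],
            "birth_year": v[4] if len(v) > 4 else 1980,
        })
    return sb.PhenotypeTable(data=pd.DataFrame(rows))


@pytest.fixture
def phenotype_builder():
    return make_phenotypes
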