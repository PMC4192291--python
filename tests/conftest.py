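"""Shared fixtures: one default simulated study, QC'd once per session."""

import numpy as np
import pandas as pd
import pytest

from imputeval import (
    design_chip,
    impute_nn_window,
    mask_to_chip,
    regress_accuracy_on_relatedness,
    relatedness_summary,
    run_qc,
    score_scenario,
    vanraden_grm,
)
from imputeval.io_formats import GenotypeMatrix, MarkerMap
from imputeval.synthetic_data import SimConfig, make_study_fixture


@pytest.fixture(scope="session")
def study():
    """Default desk-scale study dataset (seed 1)."""
    return make_study_fixture(SimConfig(seed=1))


@pytest.fixture(scope="session")
def post_qc(study):
    """(report, filtered genotypes, filtered map) for the study panel."""
    geno = study.genotypes.subset_individuals(study.genotyped_ids())
    return run_qc(geno, study.marker_map, reference_ids=study.reference_ids)


@pytest.fixture(scope="session")
def study_grm(post_qc):
    _, filt, _ = post_qc
    return vanraden_grm(filt)


@pytest.fixture(scope="session")
def density_ladder(study, post_qc, study_grm):
    """Accuracy and CORR~Mean10 regressions across nested chip densities.

    even_last selection at window sizes 32/16/8/4 yields nested panels; the
    nearest-neighbour baseline is run with its window scaled to chip spacing
    (8 map markers per chip marker) so donor haplotypes always span a
    comparable number of chip SNPs.
    """
    _, filt, fmap = post_qc
    rel = relatedness_summary(study_grm, study.reference_ids, study.young_sire_ids)
    out = {}
    for k in (32, 16, 8, 4):
        chip = design_chip(filt, fmap, k, "even_last")
        scn = mask_to_chip(filt, fmap, chip, study.reference_ids,
                           study.young_sire_ids)
        result = score_scenario(scn, impute_nn_window(scn, 8 * k))
        fit = regress_accuracy_on_relatedness(result, rel, degree=1)
        out[k] = (chip, result, fit)
    return out


def small_matrix(seed=0, n=12, m=30, missing=False):
    """A small random genotype matrix + map for unit tests."""
    rng = np.random.default_rng(seed)
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing:
        mask = rng.random((n, m)) < 0.1
        dosage[mask] = -1
    table = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chromosome": [1 + j // ((m + 1) // 2) for j in range(m)],
            "position_bp": [(j % ((m + 1) // 2) + 1) * 1000 for j in range(m)],
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    ids = [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(ids, dosage), MarkerMap(table)
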