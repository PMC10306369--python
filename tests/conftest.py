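"""Shared fixtures: small demographic models and the session-scoped
reference tables used by the validation experiments."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from selfkit.selfing_model import DemographicModel, Epoch
from selfkit.coalsim import RngState
from selfkit.abc import (
    ParamPrior,
    PriorSpec,
    SimDims,
    build_reference_table,
    fit_pls,
    pilot_class_edges,
)

# ---------------------------------------------------------------------------
# test-scale ABC conditions: as close to n=8 haplotypes / two 500-kb loci /
# several-thousand-row tables as a single-CPU run affords; priors span the
# regime the pseudo-observed datasets are drawn from
# ---------------------------------------------------------------------------

TEST_DIMS = SimDims(n=8, L=500_000, n_loci=2, mu=1e-8, r=1e-8)
TEST_TABLE_SIZE = 5000
TEST_PILOT = 300
TEST_TOLERANCE = 0.02  # ~100 accepted rows
TEST_PLS = 20

TEST_PRIOR_M1 = PriorSpec(1, {
    "N": ParamPrior("loguniform", 5e3, 5e4),
    "sigma_anc": ParamPrior("uniform", 0.0, 0.2),
    "sigma_pres": ParamPrior("uniform", 0.8, 0.999),
    "t_sigma": ParamPrior("loguniform", 1e2, 1e5),
})
TEST_PRIOR_M2 = PriorSpec(2, {
    "N_pres": ParamPrior("loguniform", 5e3, 5e4),
    "N_anc": ParamPrior("loguniform", 5e3, 5e4),
    "sigma": ParamPrior("uniform", 0.0, 0.999),
    "t_N": ParamPrior("loguniform", 1e2, 1e5),
})


def constant_model(N, sigma, r=1e-8):
    return DemographicModel([Epoch(0.0, N, sigma, r)])


@pytest.fixture(scope="session")
def class_edges():
    return pilot_class_edges(TEST_PRIOR_M1, TEST_DIMS, RngState(100),
                             n_pilot=TEST_PILOT)


@pytest.fixture(scope="session")
def table_m1(class_edges):
    table = build_reference_table(1, TEST_PRIOR_M1, TEST_DIMS, TEST_TABLE_SIZE,
                                  RngState(101), class_edges=class_edges)
    return fit_pls(table, TEST_PLS)


@pytest.fixture(scope="session")
def table_m2(class_edges):
    table = build_reference_table(2, TEST_PRIOR_M2, TEST_DIMS, TEST_TABLE_SIZE,
                                  RngState(102), class_edges=class_edges)
    return fit_pls(table, TEST_PLS)
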