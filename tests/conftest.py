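import dataclasses

import numpy as np
import pytest

from xlmsbench.denoise_search import Spectrum
from xlmsbench.pipeline import RunConfig, grade_against_truth, run_pipeline
from xlmsbench.synthetic_data import AcquisitionMethod, SimConfig
from xlmsbench.xl_core import CrosslinkerSpec, MassConfig

# round-number synthetic linkers so no test depends on vendor constants
SIMPLE_LINKER = CrosslinkerSpec(name="X", spacer_mass=100.0,
                                max_distance=20.0)
CLEAVABLE_LINKER = CrosslinkerSpec(name="XC", spacer_mass=100.0,
                                   cleavable=True, arm_masses=(30.0, 70.0),
                                   max_distance=20.0)


@pytest.fixture(scope="session")
def mass_cfg():
    return MassConfig()


def random_spectrum(rng, n_peaks=80, mz_range=(150.0, 1800.0)):
    mz = np.sort(rng.uniform(*mz_range, n_peaks))
    inten = rng.exponential(1000.0, n_peaks)
    return Spectrum(scan_id=1, precursor_mz=500.0, precursor_charge=2,
                    rt=10.0, cv=-48.0, mz=mz, intensity=inten)


@pytest.fixture(scope="session")
def default_bundle():
    """One full default-scale pipeline run (500 true links, fixed seed),
    shared by the end-to-end and acceptance tests."""
    return run_pipeline(RunConfig().with_seed(1))


@pytest.fixture(scope="session")
def default_grade(default_bundle):
    return grade_against_truth(default_bundle)


@pytest.fixture()
def small_config():
    """A scaled-down run for tests that exercise plumbing, not power."""
    cfg = RunConfig().with_seed(11)
    return dataclasses.replace(
        cfg,
        sim=dataclasses.replace(cfg.sim, n_links=60, n_residues=300,
                                n_linear_peptides=40, seed=11),
        method=dataclasses.replace(cfg.method, gradient_minutes=8.0))
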