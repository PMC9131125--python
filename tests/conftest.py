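import numpy as np
import pytest

from endokin.dynamics import KineticParams
from endokin.measurement import estimate_quench_efficiency
from endokin.synthetic_data import (
    StudyDesign,
    default_measurement,
    default_population,
    generate_dataset,
)

#: homogeneous-model calibration of the real assay (rates in 1/min)
REF_CALIBRATION = {"lam": 0.106, "beta": 0.047, "p": 0.068, "alpha1": 7840.0}


@pytest.fixture(scope="session")
def reference_kinetics() -> KineticParams:
    return KineticParams(REF_CALIBRATION["lam"], REF_CALIBRATION["beta"], REF_CALIBRATION["p"])


@pytest.fixture(scope="session")
def study_dataset():
    """Default-condition synthetic dataset (7 times x 2 conditions x 1000)."""
    return generate_dataset(
        default_population(), default_measurement(), StudyDesign(seed=42)
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Quick dataset for structural tests (3 times x 2 conditions x 200)."""
    return generate_dataset(
        default_population(),
        default_measurement(),
        StudyDesign(times=(0.0, 10.0, 60.0), n_per_sample=200,
                    n_autofluorescence=500, seed=9),
    )


@pytest.fixture(scope="session")
def study_eta(study_dataset):
    return estimate_quench_efficiency(
        study_dataset.quench_control[0],
        study_dataset.quench_control[1],
        study_dataset.autofluorescence.gmfi_Q(),
    )


def reduced_problem(dataset, eta, n_sim=1000):
    """ABC problem with only (mu_lam, mu_beta, p, alpha1) free, everything
    else pinned at the generating truth."""
    from endokin.abc import ABCProblem, DiscrepancyConfig, default_prior_box
    from endokin.gmfi_fit import GmfiSeries

    truth = {**dataset.truth["population"], **dataset.truth["measurement"]}
    truth.pop("eta", None)
    free = ("mu_lam", "mu_beta", "p", "alpha1")
    fixed = {k: v for k, v in truth.items() if k not in free}
    gs = GmfiSeries.from_dataset(dataset)
    gmax = float(max(gs.unquenched.max(), gs.quenched.max()))
    problem = ABCProblem(
        obs=dataset,
        prior=default_prior_box(gmax),
        fixed=fixed,
        eta=eta,
        cfg=DiscrepancyConfig(n_sim=n_sim),
    )
    theta_truth = np.array([truth[n] for n in problem.free])
    return problem, theta_truth
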