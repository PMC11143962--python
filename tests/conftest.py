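import numpy as np
import pandas as pd
import pytest

from clonedisperse import simdata, workflow


def make_patient(mode: str, seed: int, noise: str = "none", **overrides):
    """One synthetic patient with sensible per-mode defaults."""
    kw = dict(
        mode=mode,
        n_disseminated=1 if mode == simdata.MONOCLONAL else 2,
        n_clones=5,
        seed=seed,
        noise=noise,
    )
    kw.update(overrides)
    return simdata.simulate_patient(simdata.SimulationConfig(**kw))


@pytest.fixture(scope="session")
def patient_factory():
    return make_patient


@pytest.fixture(scope="session")
def default_params():
    return workflow.PipelineParams()


@pytest.fixture(scope="session")
def noise_free_patients(patient_factory):
    """A small panel of noise-free patients covering the three modes."""
    return [
        patient_factory(simdata.MONOCLONAL, seed=11),
        patient_factory(simdata.MONOPHYLETIC, seed=12),
        patient_factory(simdata.POLYPHYLETIC, seed=13, n_sites=3),
    ]


def random_prevalence_matrix(rng: np.random.Generator, n_clusters: int,
                             n_samples: int = 3,
                             structured: bool = False) -> pd.DataFrame:
    """Random cluster-by-sample prevalences with a guaranteed root row.

    With ``structured=True`` the matrix is built from a hidden random tree
    by stick-breaking, so at least one sum-rule-consistent tree exists.
    """
    if structured:
        P = np.zeros((n_clusters, n_samples))
        P[0, :] = 1.0
        remaining = P.copy()
        for i in range(1, n_clusters):
            p = int(rng.integers(0, i))
            frac = rng.uniform(0.1, 0.9, size=n_samples)
            P[i] = remaining[p] * frac
            remaining[p] -= P[i]
            remaining[i] = P[i].copy()
    else:
        P = rng.uniform(0.0, 0.9, size=(n_clusters, n_samples))
        P[0, :] = 1.0
    return pd.DataFrame(P, index=[f"c{i}" for i in range(n_clusters)],
                        columns=[f"s{j}" for j in range(n_samples)])
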