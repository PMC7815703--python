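import numpy as np
import pytest

from seegwm.features import ShankRecord
from seegwm.synthetic import GeneratorConfig, simulate_cohort


def brute_force_marginals(beta, log_node):
    """Enumerate all labelings of a chain; independent oracle for the
    transfer-matrix / forward-backward routines."""
    from scipy.special import logsumexp

    from seegwm.chain import enumerate_labelings

    log_node = np.asarray(log_node, dtype=float)
    n = log_node.shape[0]
    labs = enumerate_labelings(n)
    energy = beta * np.sum(labs[:, :-1] * labs[:, 1:], axis=1)
    loglik = ((labs > 0) @ log_node[:, 1] + (labs < 0) @ log_node[:, 0])
    joint = energy + loglik
    log_z = logsumexp(joint)
    w = np.exp(joint - log_z)
    return w @ (labs > 0), log_z


def make_record(s, depth=None, labels=None, patient="P", shank="S"):
    s = np.asarray(s, dtype=float)
    if depth is None:
        depth = np.arange(s.size - 1, -1, -1, dtype=float)
    return ShankRecord(patient=patient, shank=shank,
                       contacts=[f"{shank}{i + 1}" for i in range(s.size)],
                       s=s, depth=depth,
                       labels=None if labels is None else np.asarray(labels,
                                                                     float))


@pytest.fixture(scope="session")
def default_cohort():
    """The package's default synthetic study: 8 patients x 6 shanks x 12."""
    cohort = simulate_cohort(GeneratorConfig())
    return [r for pat in sorted(cohort) for r in cohort[pat]]


@pytest.fixture(scope="session")
def small_cohort():
    """Faster cohort for harness-level tests."""
    cfg = GeneratorConfig(n_patients=4, shanks_per_patient=3,
                          contacts_per_shank=10, seed=3)
    cohort = simulate_cohort(cfg)
    return [r for pat in sorted(cohort) for r in cohort[pat]]
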