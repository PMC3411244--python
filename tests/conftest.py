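import numpy as np
import pytest

from shudiv import SubjectIndex, load_pool


def brute_force_shustrings(query: str, subject: str):
    """Quadratic reference: shortest substring at each query start that is
    absent from the subject, capped at the distance to the query end."""
    lengths, capped = [], []
    for i in range(len(query)):
        remaining = len(query) - i
        x = 1
        while x <= remaining and query[i : i + x] in subject:
            x += 1
        if x > remaining:
            lengths.append(remaining)
            capped.append(True)
        else:
            lengths.append(x)
            capped.append(False)
    return np.array(lengths), np.array(capped)


def profile_strings(query: str, subject: str):
    """Single-strand shustring profile of two raw sequences."""
    qp = load_pool([query], strand_double=False)
    sp = load_pool([subject], strand_double=False)
    return SubjectIndex(sp).profile(qp.codes)


@pytest.fixture(scope="session")
def worked_example_profile():
    """The five-position query CCGTT against subject TCGT."""
    return profile_strings("CCGTT", "TCGT")


@pytest.fixture(scope="session")
def small_sim_pair():
    """A modest simulated pair reused by several estimator tests."""
    from shudiv import simulate_pair

    return simulate_pair(50_000, pi=0.01, rho=0.01, seed=4242)
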