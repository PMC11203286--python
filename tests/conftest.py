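import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from floranmr import SpectrumParams, default_design, default_library

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def design(library):
    return default_design(library)


@pytest.fixture()
def clean_params():
    """Noiseless acquisition with no solvent or reference residuals."""
    return SpectrumParams(noise_sigma=0.0, solvent_peaks=())


def ward_oracle(points: np.ndarray):
    """Exhaustive Ward agglomeration from coordinates.

    Evaluates every candidate pair's exact within-cluster variance
    increase (from centroids, independent of the Lance-Williams
    recursion) and merges the minimum; heights are sqrt(2 * delta ESS)
    so two singletons merge at their Euclidean distance.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    clusters = {i: [i] for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        ids = sorted(clusters)
        for ai, i in enumerate(ids):
            for j in ids[ai + 1 :]:
                a, b = points[clusters[i]], points[clusters[j]]
                na, nb = len(a), len(b)
                d_ess = na * nb / (na + nb) * float(
                    np.sum((a.mean(axis=0) - b.mean(axis=0)) ** 2)
                )
                if best is None or d_ess < best[0]:
                    best = (d_ess, i, j)
        d_ess, i, j = best
        merges.append((i, j, float(np.sqrt(2.0 * d_ess)), len(clusters[i]) + len(clusters[j])))
        clusters[n + step] = clusters.pop(i) + clusters.pop(j)
    return merges
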