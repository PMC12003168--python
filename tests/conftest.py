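import numpy as np
import pytest

from gliaquant import SimulationParams, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic scene shared by read-only tests."""
    return generate_scene(SimulationParams(rng_seed=11))


@pytest.fixture(scope="session")
def noiseless_params():
    return SimulationParams(rng_seed=5, noise_sd=0.0, background_amplitude=0.0)


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_params):
    return generate_scene(noiseless_params)


def brute_force_otsu(values, nbins=256):
    """Independent exhaustive Otsu: enumerate every histogram split and
    maximize the between-class variance directly."""
    v = np.asarray(values, float).ravel()
    hist, edges = np.histogram(v, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_idx = None, None
    for i in range(nbins - 1):
        n0, n1 = hist[: i + 1].sum(), hist[i + 1:].sum()
        if n0 == 0 or n1 == 0:
            continue
        m0 = (hist[: i + 1] * centers[: i + 1]).sum() / n0
        m1 = (hist[i + 1:] * centers[i + 1:]).sum() / n1
        var = n0 * n1 * (m0 - m1) ** 2
        if best is None or var > best * (1 + 1e-12):
            best, best_idx = var, i
    return edges[best_idx + 1]


def brute_force_kruskal_h(groups):
    """Kruskal-Wallis H from first principles: midranks, the rank-sum
    formula, and the tie correction factor."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    order = np.argsort(all_vals, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = all_vals[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # midrank (1-based)
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(sorted_vals, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    return h / tie


def brute_force_holm(pvals):
    """Holm step-down from its definition: sort ascending, multiply the i-th
    smallest by (m - i), enforce monotonicity by a running max, cap at 1."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
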