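import numpy as np
import pytest

from hiddenpair.tables import PairTable


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def random_table_factory():
    """Factory for non-degenerate random 3x3x2 tables (every cell >= 1)."""

    def make(rng, low=1, high=20):
        c = rng.integers(low, high, size=(3, 3, 2))
        return PairTable(c, int(c.sum()))

    return make


def ipf_on_margins(counts, margin_axes, tol=1e-12, max_iter=5000):
    """Reference IPF fitting an arbitrary set of margins of a 3x3x2 table.

    ``margin_axes`` lists, per margin, the axes summed OVER (the dot
    positions).  Independent of the package's IPF implementation: plain
    loops over margins with explicit broadcasting.
    """
    counts = np.asarray(counts, dtype=float)
    targets = [counts.sum(axis=ax) for ax in margin_axes]
    mu = np.ones_like(counts)
    for _ in range(max_iter):
        old = mu.copy()
        for ax, target in zip(margin_axes, targets):
            cur = mu.sum(axis=ax)
            ratio = np.ones_like(target)
            np.divide(target, cur, out=ratio, where=cur > 0)
            ratio[target == 0] = 0.0
            mu = mu * np.expand_dims(ratio, ax)
        if np.abs(mu - old).max() < tol:
            break
    return mu
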