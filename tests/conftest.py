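import numpy as np
import pytest

import buttseq as b


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic study shared across read-level tests."""
    cfg = b.SimConfig(n_genes=30, seed=101)
    ann, genome, truth = b.simulate_genome(cfg)
    return cfg, ann, genome, truth


@pytest.fixture(scope="session")
def read_sim(small_sim):
    cfg, ann, genome, truth = small_sim
    pairs, rst = b.simulate_reads(truth, ann, 5000, seed=202)
    return pairs, rst


def multinomial_max_tail_exact(c: int, total: int, width: int) -> float:
    """Exact P(max cell count >= c) for `total` balls uniform over `width`
    cells, by full enumeration of compositions (independent oracle)."""
    from itertools import combinations_with_replacement
    from math import factorial

    def compositions(t, w):
        # ordered tuples of w nonnegative ints summing to t
        if w == 1:
            yield (t,)
            return
        for first in range(t + 1):
            for rest in compositions(t - first, w - 1):
                yield (first,) + rest

    p_cell = 1.0 / width
    tail = 0.0
    for comp in compositions(total, width):
        if max(comp) >= c:
            coef = factorial(total)
            for k in comp:
                coef //= factorial(k)
            tail += coef * p_cell**total
    return tail


def ks_d_bruteforce(x, y, n_grid: int = 20001) -> float:
    """Sup |Fx - Fy| evaluated on a fine grid plus all sample points."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo = min(x.min(), y.min()) - 1.0
    hi = max(x.max(), y.max()) + 1.0
    grid = np.concatenate([np.linspace(lo, hi, n_grid), x, y])
    fx = np.searchsorted(np.sort(x), grid, side="right") / x.size
    fy = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.max(np.abs(fx - fy)))
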