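"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spacc.pipeline import run_pipeline
from spacc.simulate import SimConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# oracles (kept independent of the package implementations they check)

def binom_tail_oracle(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct summation of the binomial pmf."""
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def binom_tail_enumeration(k: int, n: int, p: float) -> float:
    """P(X >= k) by exhaustive enumeration of all 2**n outcomes."""
    total = 0.0
    for outcome in range(2**n):
        ones = bin(outcome).count("1")
        if ones >= k:
            total += p**ones * (1 - p) ** (n - ones)
    return total


def bh_stepup_oracle(pvalues) -> np.ndarray:
    """Textbook BH step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def union_bitmap_oracle(intervals, span: int) -> list[tuple[int, int]]:
    """Interval union via an explicit coverage bitmap."""
    mask = np.zeros(span, dtype=bool)
    for s, e in intervals:
        mask[max(0, s) : min(span, e)] = True
    out = []
    i = 0
    while i < span:
        if mask[i]:
            j = i
            while j < span and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def percentile_oracle(values, q: float) -> float:
    """Linear-interpolation percentile computed from first principles."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 1:
        return float(v[0])
    rank = q / 100 * (len(v) - 1)
    lo = int(math.floor(rank))
    hi = int(math.ceil(rank))
    frac = rank - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


# ---------------------------------------------------------------------------
# fixtures

SMALL_CONFIG = SimConfig(
    seed=7,
    chrom_sizes={"chr1": 700_000, "chr2": 300_000, "chrM": 20_000},
    n_reads=2_500,
)


@pytest.fixture(scope="session")
def small_result():
    """One mid-size pipeline run shared across test modules."""
    return run_pipeline(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_sim(small_result):
    return small_result.sim
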