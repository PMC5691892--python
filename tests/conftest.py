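"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive every statistic from first
principles with plain Python loops so that they share no code path with
the package implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from xsig.datamodel import ExpressionMatrix, GeneSet
from xsig.ranking import RankedList


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_running_sum(
    metric: list[float], hit_positions: set[int], weight_p: float
) -> list[float]:
    """Plain-loop weighted KS running sum; positions are 0-based."""
    n = len(metric)
    n_h = len(hit_positions)
    nr = sum(abs(metric[i]) ** weight_p for i in hit_positions)
    run, s = [], 0.0
    for i in range(n):
        if i in hit_positions:
            s += abs(metric[i]) ** weight_p / nr
        else:
            s -= 1.0 / (n - n_h)
        run.append(s)
    return run


def brute_force_es(
    metric: list[float], hit_positions: set[int], weight_p: float
) -> tuple[float, int]:
    """ES and 1-based peak from the brute-force running sum.

    The peak is the first position attaining the maximal |running sum|.
    """
    run = brute_force_running_sum(metric, hit_positions, weight_p)
    max_abs = max(abs(v) for v in run)
    best = next(
        i for i, v in enumerate(run) if abs(v) >= max_abs - 1e-12
    )
    return run[best], best + 1


def exhaustive_null_es(
    metric: list[float], k: int, weight_p: float
) -> list[float]:
    """ES of every size-k subset of positions (exhaustive enumeration)."""
    n = len(metric)
    return [
        brute_force_es(metric, set(combo), weight_p)[0]
        for combo in itertools.combinations(range(n), k)
    ]


def exhaustive_sign_matched_p(es: float, null: list[float]) -> float:
    """Sign-matched tail probability over an exhaustive null."""
    if es >= 0:
        tail = [v for v in null if v > 0]
        extreme = sum(1 for v in tail if v >= es)
    else:
        tail = [v for v in null if v < 0]
        extreme = sum(1 for v in tail if v <= es)
    return extreme / len(tail)


def brute_force_ssgsea(
    set_positions: set[int], n: int, alpha: float
) -> float:
    """Single-sample score from 0-based within-sample positions alone."""
    weights = {
        i: (n - i) ** alpha for i in set_positions  # r = N - rank + 1
    }
    total = sum(weights.values())
    k = len(set_positions)
    es, p_in, p_out = 0.0, 0.0, 0.0
    for i in range(n):
        if i in set_positions:
            p_in += weights[i] / total
        else:
            p_out += 1.0 / (n - k)
        es += p_in - p_out
    return es


# ---------------------------------------------------------------------------
# fixtures

def make_ranked(metric: list[float]) -> RankedList:
    genes = tuple(f"g{i:03d}" for i in range(len(metric)))
    return RankedList(genes=genes, metric=tuple(float(m) for m in metric))


def gene_set_at(ranked: RankedList, positions: set[int],
                name: str = "S") -> GeneSet:
    """Gene set occupying the given 0-based ranked positions."""
    return GeneSet(name, frozenset(ranked.genes[i] for i in positions))


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples, two annotated groups, deterministic."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(8, 1, size=(4, 6)),
        index=["Ga", "Gb", "Gc", "Gd"],
        columns=[f"s{i}" for i in range(6)],
    )
    ann = {f"s{i}": ("wt" if i < 3 else "ko") for i in range(6)}
    return ExpressionMatrix(values, ann)


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic bundle shared across tests (seed 7)."""
    from xsig.simulate import SimConfig, simulate_study

    return simulate_study(SimConfig(seed=7))
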