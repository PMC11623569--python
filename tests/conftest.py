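"""Shared fixtures and independent statistical oracles.

The oracles (hypergeometric tail enumeration, rank-split enumeration,
step-up FDR by hand) are deliberately written from first principles with
``math.comb`` so they share no code path with the package implementations
they check.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import List, Sequence, Tuple

import pytest

from psiscan.pileup_model import PileupSite, PileupTable


# ---------------------------------------------------------------------------
# oracles


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p for [[a, b], [c, d]] by direct enumeration.

    Conditions on fixed margins: first-column total k is hypergeometric;
    p = P(K >= a).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    num = sum(
        math.comb(r1, k) * math.comb(r2, c1 - k)
        for k in range(max(a, k_min), k_max + 1)
    )
    return num / denom


def ranksum_two_sided_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided rank-sum p by enumerating every rank split.

    Requires tie-free pooled values.  Uses the Mann-Whitney U of the first
    group; under the null U is symmetric about n1*n2/2, so the two-sided p
    is the probability of a split at least as far from the centre.
    """
    pooled = sorted(x) + sorted(y)
    assert len(set(list(x) + list(y))) == len(x) + len(y), "oracle needs no ties"
    values = sorted(list(x) + list(y))
    rank = {v: i + 1 for i, v in enumerate(values)}
    n1, n2 = len(x), len(y)
    u_obs = sum(rank[v] for v in x) - n1 * (n1 + 1) / 2
    centre = n1 * n2 / 2
    dist = abs(u_obs - centre)
    total = 0
    extreme = 0
    all_ranks = range(1, n1 + n2 + 1)
    for subset in combinations(all_ranks, n1):
        u = sum(subset) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - centre) >= dist - 1e-12:
            extreme += 1
    return extreme / total


def bh_oracle(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, written out by hand."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = p_values[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def spearman_no_ties_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """rho = 1 - 6 sum d^2 / (n (n^2 - 1)); valid only without ties."""
    n = len(x)
    rx = {v: i + 1 for i, v in enumerate(sorted(x))}
    ry = {v: i + 1 for i, v in enumerate(sorted(y))}
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    return 1 - 6 * d2 / (n * (n**2 - 1))


# ---------------------------------------------------------------------------
# fixtures


def make_table(
    sample_id: str,
    rows: Sequence[Tuple[str, int, str, int, int]],
) -> PileupTable:
    """Build a PileupTable from (ref, pos, base, depth, del_count) rows."""
    table = PileupTable(sample_id=sample_id)
    for ref, pos, base, depth, del_count in rows:
        table.add(PileupSite(ref, pos, base, depth, del_count))
    return table


@pytest.fixture
def small_reference():
    #           123456789012345678901234567890
    return {"chr1": "AGGTATCCGATTTGACGTACGCATGCAAAC"}


@pytest.fixture
def tiny_pair(small_reference):
    """One clear Psi site at chr1:4 (T) plus background positions."""
    seq = small_reference["chr1"]
    treated = PileupTable(sample_id="t1_BS")
    untreated = PileupTable(sample_id="t1_untreated")
    for pos in range(1, len(seq) + 1):
        base = seq[pos - 1]
        del_t = 20 if pos == 4 else 0
        treated.add(PileupSite("chr1", pos, base, 100, del_t))
        untreated.add(PileupSite("chr1", pos, base, 100, 0))
    return treated, untreated
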