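"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import bisect
import math

import numpy as np
import pandas as pd
import pytest

from clonmet.simulate import SampleTruth, SimulationConfig, simulate_clone_tree


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact-integer enumeration oracle for the two-sided Fisher test.

    Enumerates every table with the observed margins, computing each
    table's conditional probability as an exact integer weight
    C(r1, x) * C(r2, c1 - x); the two-sided p sums weights no larger
    than the observed one (relative ties within 1e-7 included, matching
    the test's definition).  Independent of the package implementation.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    ws = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    tot = sum(ws)
    w_obs = ws[a - lo]
    num = sum(w for w in ws if w * 10**7 <= w_obs * (10**7 + 1))
    return min(num / tot, 1.0)


def bh_oracle(pvals) -> np.ndarray:
    """Literal step-up BH: q_(i) = min_{j>=i} p_(j) * m / j, plain loops."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return np.array(q)


def jt_oracle(groups) -> float:
    """Brute-force pairwise-count Jonckheere-Terpstra statistic."""
    j = 0.0
    for gi in range(len(groups)):
        for gj in range(gi + 1, len(groups)):
            for x in groups[gi]:
                for y in groups[gj]:
                    if y > x:
                        j += 1.0
                    elif y == x:
                        j += 0.5
    return j


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_patients=2,
        n_primary_foci=3,
        n_lnm=2,
        fraction_independent_foci=0.0,
        n_clones=3,
        n_truncal_mutations=30,
        n_private_mean=8.0,
    )


@pytest.fixture
def two_clone_tree():
    return simulate_clone_tree(2, n_truncal=10, n_private_mean=5.0, seed=5)


def make_sample(
    sample_id: str,
    site: str,
    purity: float,
    fractions: dict,
    patient: str = "P1",
    truth: str = "metastatic-clone",
) -> SampleTruth:
    if site in ("BLN", "NP"):
        truth = "benign"
    return SampleTruth(sample_id, site, purity, fractions, patient, truth)


def variant_frame(rows) -> pd.DataFrame:
    """Build a MAF-lite variant table from (sample, chrom, pos, ref, alt, rc, ac)."""
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"],
    ).assign(patient_id="P1", gene="G0001")
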