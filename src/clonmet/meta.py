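"""Cohort-level metastasis-vs-primary mutation-enrichment testing.

Given a binary gene x sample mutation table and an arm label per sample
(primary or metastasis), each gene is tested with a two-sided Fisher
exact test on its 2x2 mutated/wild-type by arm table; q-values are BH
across all tested genes and a direction is assigned by the odds-ratio
side when q falls below the significance threshold.  This mirrors the
cBioPortal-style comparison used to validate metastasis-enriched
mutations in large public cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from clonmet.stats import benjamini_hochberg, fisher_exact_many

__all__ = ["EnrichmentResult", "test_met_vs_primary_enrichment"]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Per-gene 2x2 counts and test results (a/b mutated/wild-type metastases,
    c/d mutated/wild-type primaries)."""

    gene: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float
    direction: str


def _display_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Odds ratio (a*d)/(b*c) with the Haldane-Anscombe 0.5 correction when
    any cell is zero; display only, the test uses uncorrected counts."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def test_met_vs_primary_enrichment(
    mutation_table: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Fisher tests of mutation enrichment in metastases vs primaries.

    Parameters
    ----------
    mutation_table
        Binary genes x samples table (entries 0, 1 or NaN; NaN samples
        are excluded per gene).  A samples x genes table is transposed
        automatically when its columns match the label index.
    labels
        sample -> {"primary", "metastasis"}.
    alpha
        q threshold below which a direction call is made.

    Returns a DataFrame sorted by q with columns gene, a, b, c, d,
    odds_ratio, p, q, direction.  Genes with zero mutations in both
    arms are skipped (logged), not tested.
    """
    labels = pd.Series(labels)
    bad = labels[~labels.isin(("primary", "metastasis"))]
    if len(bad):
        raise ValueError(f"unknown arm labels: {sorted(bad.unique())}")
    table = mutation_table
    if not table.columns.isin(labels.index).all() and table.index.isin(labels.index).all():
        table = table.T  # accept samples x genes orientation
    samples = [s for s in table.columns if s in labels.index]
    if not samples:
        raise ValueError("no overlap between mutation table samples and labels")
    table = table[samples]
    vals = table.to_numpy(dtype=float)
    if not np.all(np.isnan(vals) | (vals == 0) | (vals == 1)):
        raise ValueError("mutation table entries must be 0, 1 or missing")
    is_met = labels.reindex(samples).eq("metastasis").to_numpy()
    if is_met.all() or not is_met.any():
        raise ValueError("need at least one sample in each arm")

    observed = ~np.isnan(vals)
    mut = np.nan_to_num(vals) == 1
    a = (mut & observed & is_met).sum(axis=1)
    b = (~mut & observed & is_met).sum(axis=1)
    c = (mut & observed & ~is_met).sum(axis=1)
    d = (~mut & observed & ~is_met).sum(axis=1)

    testable = (a + c) > 0
    skipped = int((~testable).sum())
    if skipped:
        logger.info("skipping %d genes with zero mutations in both arms", skipped)
    genes = table.index.to_numpy()[testable]
    a, b, c, d = a[testable], b[testable], c[testable], d[testable]
    p = fisher_exact_many(np.stack([a, b, c, d], axis=1))
    q = benjamini_hochberg(p)
    orat = np.array([_display_odds_ratio(*t) for t in zip(a, b, c, d)])
    direction = np.where(
        (q < alpha) & (orat > 1),
        "metastasis-enriched",
        np.where((q < alpha) & (orat < 1), "primary-enriched", "none"),
    )
    out = pd.DataFrame(
        {
            "gene": genes,
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "odds_ratio": orat,
            "p": p,
            "q": q,
            "direction": direction,
        }
    )
    return out.sort_values(["q", "p", "gene"], ignore_index=True)
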