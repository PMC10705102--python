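"""Expression scores: log-CPM, two-group DE, stage trends, signature z-score.

The differential-expression engine here is a deliberately simple one
(Welch t-test on log2-CPM with BH adjustment); the trend and signature
operations consume any per-gene table with (lfc, q) columns, so output
from a negative-binomial GLM engine can be substituted unchanged.

The signature score follows the composite-z construction: per gene,
expression is z-scored across samples; a sample's score is the mean z
over the gene-set members (e.g. the leading-edge OXPHOS genes), so
scores always average to zero across the cohort and rise when the set
is coordinately up-regulated.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from clonmet.stats import benjamini_hochberg, jonckheere_terpstra

__all__ = [
    "GeneSet",
    "compare_score_by_stage",
    "normalize_log_cpm",
    "select_trend_genes",
    "signature_zscore",
    "simple_de_test",
]

logger = logging.getLogger(__name__)

STAGE_ORDER = ("NP", "PTF", "LNM")


class GeneSet:
    """Named, non-empty set of unique gene identifiers."""

    def __init__(self, name: str, genes: Iterable[str]):
        members = list(dict.fromkeys(genes))
        if not members:
            raise ValueError("gene set must be non-empty")
        self.name = name
        self.genes = members

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __repr__(self) -> str:
        return f"GeneSet({self.name!r}, n={len(self)})"


def normalize_log_cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2(CPM + pseudocount) normalization of a genes x samples count matrix.

    Dividing by the library size before adding the pseudocount makes the
    transform exactly invariant to per-sample scaling of the counts.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = counts.div(lib, axis=1) * 1e6
    return np.log2(cpm + pseudocount)


def simple_de_test(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Two-group differential expression: Welch t on log2-CPM, BH across genes.

    Returns per-gene ``lfc`` (mean log2-CPM of B minus A), ``p`` and
    ``q``.  Genes with zero variance in both groups get p = 1 by
    convention (no evidence either way from a constant gene).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)[:5]}")
    logcpm = normalize_log_cpm(counts)
    xa = logcpm[group_a].to_numpy()
    xb = logcpm[group_b].to_numpy()
    lfc = xb.mean(axis=1) - xa.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(xb, xa, axis=1, equal_var=False)
    flat = (xa.std(axis=1) == 0) & (xb.std(axis=1) == 0)
    if flat.any():
        logger.info("%d genes constant in both groups; p set to 1", int(flat.sum()))
    p = np.where(flat | np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {"lfc": lfc, "p": p, "q": benjamini_hochberg(p)}, index=counts.index
    )


def select_trend_genes(
    de_np_ptf: pd.DataFrame,
    de_ptf_lnm: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Select genes with a consistent monotone trend across disease stages.

    ``de_np_ptf`` and ``de_ptf_lnm`` are DE tables (lfc, q indexed by
    gene) for the normal-to-primary and primary-to-metastasis steps.  A
    gene trends "up" when both fold changes are positive and both
    q-values fall below ``alpha``; "down" symmetrically; otherwise
    "none".  Genes missing from either table are "none" (logged).
    """
    merged = de_np_ptf[["lfc", "q"]].join(
        de_ptf_lnm[["lfc", "q"]], how="outer", lsuffix="_np_ptf", rsuffix="_ptf_lnm"
    )
    missing = merged.isna().any(axis=1)
    if missing.any():
        logger.info("%d genes missing from one DE table; trend set to none", int(missing.sum()))
    l1, q1 = merged["lfc_np_ptf"], merged["q_np_ptf"]
    l2, q2 = merged["lfc_ptf_lnm"], merged["q_ptf_lnm"]
    sig = (q1 < alpha) & (q2 < alpha) & ~missing
    trend = np.where(
        sig & (l1 > 0) & (l2 > 0),
        "up",
        np.where(sig & (l1 < 0) & (l2 < 0), "down", "none"),
    )
    merged["trend"] = trend
    return merged


def signature_zscore(logcpm: pd.DataFrame, geneset: GeneSet | Iterable[str]) -> pd.Series:
    """Composite z-score of a gene set per sample.

    Each gene's normalized expression is z-scored across samples; the
    score of a sample is the mean z over gene-set members present in
    the matrix.  Genes with zero cross-sample variance are dropped with
    a warning.  Scores sum to zero across samples by construction.
    """
    if logcpm.shape[1] < 2:
        raise ValueError("z-scores need at least two samples")
    genes = list(geneset)
    present = [g for g in genes if g in logcpm.index]
    if not present:
        raise ValueError("no gene-set member present in the expression matrix")
    sub = logcpm.loc[present]
    sd = sub.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("dropping %d constant gene(s) from the signature", int(flat.sum()))
        sub = sub.loc[~flat]
        sd = sd.loc[~flat]
    if sub.empty:
        raise ValueError("all gene-set members are constant across samples")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    score = z.mean(axis=0)
    score.name = "score"
    return score


def compare_score_by_stage(
    scores: pd.Series,
    stage_labels: Mapping[str, str] | pd.Series,
    order: Sequence[str] = STAGE_ORDER,
) -> dict:
    """Ordered-trend test of signature scores across disease stages.

    Runs the Jonckheere-Terpstra test for the ordered alternative
    (scores increase along ``order``, default NP < PTF < LNM), with an
    exact permutation p-value at small n and a normal approximation
    otherwise.  Stages with fewer than two samples are excluded with a
    warning.

    Returns a dict with the statistic J, standardized z, two-sided p,
    the stages used and their per-stage mean scores.
    """
    labels = pd.Series(stage_labels)
    groups, used = [], []
    means = {}
    for stage in order:
        ids = labels.index[labels == stage]
        vals = scores.reindex(ids).dropna().to_numpy()
        if len(vals) < 2:
            if len(vals):
                logger.warning("stage %s has <2 samples; excluded from trend test", stage)
            continue
        groups.append(vals)
        used.append(stage)
        means[stage] = float(vals.mean())
    if len(groups) < 2:
        raise ValueError("need at least two stages with two or more samples")
    j, z, p = jonckheere_terpstra(groups)
    return {"J": j, "z": z, "p": p, "stages": used, "stage_means": means}
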