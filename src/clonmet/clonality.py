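"""Per-patient clonality analysis on allele-fraction matrices.

Given the significant somatic variants of a patient and raw read counts
across all of the patient's sequenced samples, this module

* builds a variants x samples allele-fraction (AF) matrix, back-filling
  AFs at sites that were significant in a sister sample,
* clusters samples by AF (average linkage on pairwise-complete
  Euclidean distances),
* classifies each primary tumor focus as metastatic-clone /
  non-metastatic-clone / clonally independent from shared-mutation
  counts and Jaccard overlap against the patient's nodal metastases,
* summarizes the cohort-level fraction of primary foci descended from a
  common ancestor with their patient's other tumors, and
* tests each variant for allele-frequency enrichment in metastases by
  pooling read counts per compartment (clonal selection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from statsmodels.stats.proportion import proportion_confint

from clonmet.somatic_filter import variant_key
from clonmet.stats import benjamini_hochberg, fisher_exact_many

__all__ = [
    "AlleleFractionMatrix",
    "ClusterResult",
    "RelatednessCall",
    "build_af_matrix",
    "classify_clonal_relatedness",
    "cluster_samples_by_af",
    "common_ancestor_fraction",
    "test_lnm_af_enrichment",
]

logger = logging.getLogger(__name__)

TUMOR_SITES = ("PTF", "LNM")


@dataclass
class AlleleFractionMatrix:
    """Variants x samples AF matrix with per-entry depths.

    ``af`` holds allele fractions in [0, 1] with NaN marking entries
    whose depth fell below the calling threshold (never silently
    imputed as 0); ``depth`` holds the matching total read depths.
    """

    af: pd.DataFrame
    depth: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.af.index.equals(self.depth.index) or not self.af.columns.equals(
            self.depth.columns
        ):
            raise ValueError("af and depth matrices must share index and columns")
        vals = self.af.to_numpy()
        if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
            raise ValueError("allele fractions must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.af.columns)

    @property
    def variants(self) -> list[str]:
        return list(self.af.index)

    def presence(self, threshold: float = 0.05) -> pd.DataFrame:
        """Boolean presence matrix: AF >= threshold with adequate depth."""
        return (self.af >= threshold) & self.af.notna()


def build_af_matrix(
    filtered_variants: pd.DataFrame,
    raw_counts: pd.DataFrame,
    min_depth: int = 40,
) -> AlleleFractionMatrix:
    """Build the patient's AF matrix over variants significant in any sample.

    Parameters
    ----------
    filtered_variants
        Retained variant calls for the patient (any subset of samples);
        rows define the variant union.
    raw_counts
        Raw per-site counts for every sample of the patient at (at
        least) the union sites; used to back-fill AFs in samples where
        the variant was not itself called.  Entries with depth below
        ``min_depth`` are set missing (NaN).
    """
    if filtered_variants.empty:
        raise ValueError("no significant variants: AF matrix undefined")
    union = pd.Index(sorted(variant_key(filtered_variants).unique()), name="variant")
    raw = raw_counts.copy()
    raw["_key"] = variant_key(raw)
    raw = raw[raw["_key"].isin(set(union))]
    samples = sorted(raw["sample_id"].unique())

    depth_tab = pd.DataFrame(np.nan, index=union, columns=samples)
    af_tab = pd.DataFrame(np.nan, index=union, columns=samples)
    grouped = raw.groupby(["_key", "sample_id"])[["ref_count", "alt_count"]].sum()
    depth_vals = grouped["ref_count"] + grouped["alt_count"]
    af_vals = grouped["alt_count"] / depth_vals.where(depth_vals > 0)
    depth_tab.update(depth_vals.unstack("sample_id"))
    af_tab.update(af_vals.unstack("sample_id"))

    shallow = depth_tab < min_depth
    af_tab = af_tab.mask(shallow)
    n_missing = int(af_tab.isna().sum().sum())
    if n_missing:
        logger.info(
            "AF matrix: %d of %d entries missing (no counts or depth < %d)",
            n_missing,
            af_tab.size,
            min_depth,
        )
    return AlleleFractionMatrix(af=af_tab, depth=depth_tab)


@dataclass
class ClusterResult:
    """Hierarchical clustering of samples by allele fraction."""

    linkage: np.ndarray
    sample_ids: list[str]  # order matching the linkage leaves (input order)
    leaf_order: list[str]  # samples in dendrogram left-to-right order
    flat_clusters: pd.Series  # sample -> cluster id
    distances: pd.DataFrame


def _pairwise_complete_euclidean(af: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Condensed distance over pairwise-complete AF vectors.

    The summed squared difference over jointly observed variants is
    rescaled by (total variants / jointly observed) so pairs with many
    missing entries are comparable to complete pairs.  Pairs with zero
    jointly observed variants get a distance just above the global
    maximum, which isolates such samples as late-merging singletons.
    """
    cols = sorted(af.columns)
    x = af[cols].to_numpy(dtype=float)
    m, k = x.shape
    dist = np.zeros((k, k))
    empty_pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            both = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            n_both = int(both.sum())
            if n_both == 0:
                empty_pairs.append((i, j))
                dist[i, j] = dist[j, i] = np.nan
            else:
                ss = float(np.sum((x[both, i] - x[both, j]) ** 2))
                dist[i, j] = dist[j, i] = np.sqrt(ss * m / n_both)
    if empty_pairs:
        fill = 1.01 * np.nanmax(dist) if np.isfinite(np.nanmax(dist)) else 1.0
        for i, j in empty_pairs:
            dist[i, j] = dist[j, i] = fill
        bad = sorted({cols[i] for i, j in empty_pairs} | {cols[j] for i, j in empty_pairs})
        logger.warning(
            "samples with no jointly observed variants placed as singletons: %s", bad
        )
    return dist[np.triu_indices(k, 1)], cols


def cluster_samples_by_af(
    matrix: AlleleFractionMatrix, n_clusters: int | None = None
) -> ClusterResult:
    """Average-linkage hierarchical clustering of samples on AF profiles.

    Deterministic: samples are processed in lexicographic id order and
    distances are pairwise-complete Euclidean.  ``n_clusters`` selects
    the flat cut (default: cut at 70% of the maximum merge height, the
    conventional dendrogram coloring threshold).
    """
    if matrix.af.shape[1] < 2:
        raise ValueError("clustering needs at least two samples")
    condensed, cols = _pairwise_complete_euclidean(matrix.af)
    z = hierarchy.linkage(condensed, method="average")
    leaves = hierarchy.leaves_list(z)
    if n_clusters is not None:
        flat = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    else:
        cut = 0.7 * z[:, 2].max() if len(z) else 0.0
        flat = hierarchy.fcluster(z, t=cut, criterion="distance")
    k = len(cols)
    sq = np.zeros((k, k))
    sq[np.triu_indices(k, 1)] = condensed
    sq += sq.T
    return ClusterResult(
        linkage=z,
        sample_ids=cols,
        leaf_order=[cols[i] for i in leaves],
        flat_clusters=pd.Series(flat, index=cols, name="cluster"),
        distances=pd.DataFrame(sq, index=cols, columns=cols),
    )


@dataclass
class RelatednessCall:
    """Clonal-relatedness call for one tumor sample."""

    sample_id: str
    call: str  # metastatic-clone | non-metastatic-clone | independent
    n_private: int
    n_shared: dict[str, int] = field(default_factory=dict)  # per-LNM shared counts
    jaccard: dict[str, float] = field(default_factory=dict)  # per-LNM Jaccard


def _jaccard(a: np.ndarray, b: np.ndarray) -> tuple[int, float]:
    shared = int(np.sum(a & b))
    union = int(np.sum(a | b))
    return shared, (shared / union if union else 0.0)


def classify_clonal_relatedness(
    matrix: AlleleFractionMatrix,
    site_labels: Mapping[str, str],
    min_shared: int = 5,
    min_jaccard: float = 0.2,
    presence_threshold: float = 0.05,
    independence_threshold: float = 0.05,
) -> list[RelatednessCall]:
    """Classify each tumor sample's clonal relationship to the metastases.

    A variant is "present" in a sample when its AF is at least
    ``presence_threshold`` at adequate depth.  A primary focus is called
    metastatic-clone when, against at least one LNM, it shares at least
    ``min_shared`` variants with Jaccard >= ``min_jaccard``; clonally
    independent when its Jaccard against every other tumor sample of
    the patient is below ``independence_threshold``; otherwise
    non-metastatic-clone.  LNM samples are metastatic-clone by
    definition.  With no LNM present all foci are non-metastatic-clone
    by convention (independence is still assessed).
    """
    present = matrix.presence(presence_threshold)
    tumor_samples = sorted(
        s for s in matrix.samples if site_labels.get(s) in TUMOR_SITES
    )
    if not tumor_samples:
        logger.warning("no tumor samples to classify")
        return []
    lnm = [s for s in tumor_samples if site_labels[s] == "LNM"]
    calls: list[RelatednessCall] = []
    for s in tumor_samples:
        vec = present[s].to_numpy()
        n_shared: dict[str, int] = {}
        jac: dict[str, float] = {}
        for other in lnm:
            if other == s:
                continue
            sh, jc = _jaccard(vec, present[other].to_numpy())
            n_shared[other] = sh
            jac[other] = jc
        others = [o for o in tumor_samples if o != s]
        max_jaccard_any = max(
            (_jaccard(vec, present[o].to_numpy())[1] for o in others), default=0.0
        )
        shared_any = np.zeros_like(vec)
        for o in others:
            shared_any |= vec & present[o].to_numpy()
        n_private = int(np.sum(vec & ~shared_any))

        if site_labels[s] == "LNM":
            call = "metastatic-clone"
        elif any(
            n_shared[o] >= min_shared and jac[o] >= min_jaccard for o in n_shared
        ):
            call = "metastatic-clone"
        elif max_jaccard_any < independence_threshold:
            call = "independent"
        else:
            call = "non-metastatic-clone"
        calls.append(
            RelatednessCall(
                sample_id=s, call=call, n_private=n_private, n_shared=n_shared, jaccard=jac
            )
        )
    return calls


def relatedness_to_frame(calls: Sequence[RelatednessCall]) -> pd.DataFrame:
    """Flatten relatedness calls to a tidy table (one row per sample)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "call": c.call,
                "n_private": c.n_private,
                "max_shared_lnm": max(c.n_shared.values(), default=0),
                "max_jaccard_lnm": max(c.jaccard.values(), default=0.0),
            }
        )
    return pd.DataFrame(rows)


def common_ancestor_fraction(
    calls_by_patient: Mapping[str, Sequence[RelatednessCall]],
    site_labels: Mapping[str, str],
    ci_alpha: float = 0.05,
) -> tuple[float, tuple[float, float], pd.DataFrame]:
    """Cohort fraction of primary foci sharing a common ancestor.

    The fraction is (primary foci NOT called independent) / (all
    classified primary foci), with an exact (Clopper-Pearson) binomial
    confidence interval.  Returns (fraction, (lo, hi), per-patient
    table).
    """
    rows = []
    for patient, calls in calls_by_patient.items():
        foci = [c for c in calls if site_labels.get(c.sample_id) == "PTF"]
        if not foci:
            continue
        n_ind = sum(c.call == "independent" for c in foci)
        rows.append(
            {
                "patient_id": patient,
                "n_foci": len(foci),
                "n_independent": n_ind,
                "fraction_related": 1.0 - n_ind / len(foci),
            }
        )
    per_patient = pd.DataFrame(rows)
    if per_patient.empty:
        raise ValueError("no classified primary foci in the cohort")
    total = int(per_patient["n_foci"].sum())
    related = total - int(per_patient["n_independent"].sum())
    lo, hi = proportion_confint(related, total, alpha=ci_alpha, method="beta")
    return related / total, (float(lo), float(hi)), per_patient


def test_lnm_af_enrichment(
    raw_counts: pd.DataFrame,
    site_labels: Mapping[str, str],
    variants: Sequence[str] | None = None,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Pooled Fisher test of per-variant AF differences LNM vs primary foci.

    Alt/ref read counts are pooled across all LNM samples and across
    all primary foci of the patient; each variant gets a two-sided
    Fisher exact p on the pooled 2x2 and a BH q across the patient's
    variants.  A variant is called enriched (clonal selection) when
    q < ``alpha`` and the pooled LNM AF exceeds the pooled primary AF,
    depleted when q < ``alpha`` with the opposite sign.

    Parameters
    ----------
    raw_counts
        Per-sample variant table for the patient (MAF-lite columns).
    variants
        Optional subset of variant keys to test (default: all observed).
    """
    raw = raw_counts.copy()
    raw["_key"] = variant_key(raw)
    raw["_site"] = raw["sample_id"].map(site_labels)
    if not (raw["_site"] == "LNM").any() or not (raw["_site"] == "PTF").any():
        raise ValueError("need at least one LNM and one primary focus")
    raw = raw[raw["_site"].isin(("LNM", "PTF"))]
    if variants is not None:
        raw = raw[raw["_key"].isin(set(variants))]
    pooled = (
        raw.groupby(["_key", "_site"])[["ref_count", "alt_count"]]
        .sum()
        .unstack("_site", fill_value=0)
    )
    alt_l = pooled[("alt_count", "LNM")].to_numpy()
    ref_l = pooled[("ref_count", "LNM")].to_numpy()
    alt_p = pooled[("alt_count", "PTF")].to_numpy()
    ref_p = pooled[("ref_count", "PTF")].to_numpy()
    ok = (alt_l + ref_l > 0) & (alt_p + ref_p > 0)
    if (~ok).any():
        logger.info("skipping %d variants with zero pooled depth in a class", int((~ok).sum()))
    keys = pooled.index.to_numpy()[ok]
    alt_l, ref_l, alt_p, ref_p = alt_l[ok], ref_l[ok], alt_p[ok], ref_p[ok]
    p = fisher_exact_many(np.stack([alt_l, ref_l, alt_p, ref_p], axis=1))
    q = benjamini_hochberg(p)
    af_l = alt_l / (alt_l + ref_l)
    af_p = alt_p / (alt_p + ref_p)
    delta = af_l - af_p
    status = np.where(
        (q < alpha) & (delta > 0),
        "enriched",
        np.where((q < alpha) & (delta < 0), "depleted", "none"),
    )
    return pd.DataFrame(
        {
            "variant": keys,
            "lnm_alt": alt_l,
            "lnm_ref": ref_l,
            "primary_alt": alt_p,
            "primary_ref": ref_p,
            "af_lnm": af_l,
            "af_primary": af_p,
            "af_delta": delta,
            "p": p,
            "q": q,
            "status": status,
        }
    ).sort_values("variant", ignore_index=True)
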