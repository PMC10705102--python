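"""Significance filtering of somatic variants against a matched normal.

A candidate somatic variant is retained when, in the tumor sample and
the matched normal of the same patient,

* both sites reach the minimum read depth (default 40),
* the allele-frequency difference (tumor - normal) exceeds the minimum
  (default 0.05, strict; an absolute-difference mode is available), and
* the Benjamini-Hochberg q-value of the two-sided Fisher exact test of
  tumor alt/ref vs normal alt/ref counts is below the FDR threshold
  (default 0.1), with BH applied across all depth-qualified variants of
  the tumor sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from clonmet.stats import benjamini_hochberg, fisher_exact_many

__all__ = ["FilterParams", "VariantRecord", "call_somatic_significant", "variant_key"]

logger = logging.getLogger(__name__)

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]
VARIANT_COLUMNS = [
    "patient_id",
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_count",
    "alt_count",
    "gene",
]
RESULT_COLUMNS = VARIANT_COLUMNS + ["af_tumor", "af_normal", "af_diff", "p", "q"]


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant observed in one sample (1-based position)."""

    patient_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def af(self) -> float:
        if self.depth == 0:
            raise ValueError("allele fraction undefined at zero depth")
        return self.alt_count / self.depth


@dataclass
class FilterParams:
    """Thresholds of the somatic significance filter."""

    min_depth: int = 40
    min_af_diff: float = 0.05
    fdr_alpha: float = 0.1
    af_diff_mode: str = "signed"  # or "absolute"
    # If set, unmatched tumor variants are tested against a synthetic
    # normal with this many reference reads and zero alt reads;
    # otherwise unmatched variants are dropped (with a logged count).
    assume_normal_depth: int | None = None

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.min_af_diff < 0:
            raise ValueError("min_af_diff must be >= 0")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.af_diff_mode not in ("signed", "absolute"):
            raise ValueError("af_diff_mode must be 'signed' or 'absolute'")


def variant_key(df: pd.DataFrame) -> pd.Series:
    """'chrom:pos:ref:alt' string key identifying a variant within a patient."""
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(int).astype(str)
        + ":"
        + df["ref"].astype(str)
        + ":"
        + df["alt"].astype(str)
    )


def _check_counts(df: pd.DataFrame, label: str) -> None:
    if ((df["ref_count"] < 0) | (df["alt_count"] < 0)).any():
        raise ValueError(f"negative read counts in {label} records")


def call_somatic_significant(
    tumor_records: pd.DataFrame,
    normal_records: pd.DataFrame,
    params: FilterParams | None = None,
    return_all: bool = False,
) -> pd.DataFrame:
    """Apply the somatic significance filter to one patient's tumor samples.

    Parameters
    ----------
    tumor_records, normal_records
        Variant tables (MAF-lite columns) for the tumor sample(s) and the
        matched normal of the same patient; variants are matched on
        (chrom, pos, ref, alt).  Multiple tumor samples may be stacked;
        BH adjustment is applied per tumor sample.
    return_all
        If True, return every depth-qualified (tested) variant annotated
        with p/q and retention status instead of the retained subset.

    Returns
    -------
    DataFrame with the input columns plus af_tumor, af_normal, af_diff,
    p, q (and ``retained`` when ``return_all``).
    """
    params = params or FilterParams()
    if tumor_records.empty:
        logger.warning("empty tumor variant table; returning empty result")
        return pd.DataFrame(columns=RESULT_COLUMNS)
    _check_counts(tumor_records, "tumor")
    if not normal_records.empty:
        _check_counts(normal_records, "normal")

    tumor = tumor_records.copy()
    tumor["_key"] = variant_key(tumor)
    if normal_records.empty:
        normal_by_key = pd.DataFrame(columns=["_key", "ref_count_n", "alt_count_n"])
    else:
        normal = normal_records.copy()
        normal["_key"] = variant_key(normal)
        normal_by_key = (
            normal.groupby("_key", as_index=False)[["ref_count", "alt_count"]]
            .sum()
            .rename(columns={"ref_count": "ref_count_n", "alt_count": "alt_count_n"})
        )

    merged = tumor.merge(normal_by_key, on="_key", how="left")
    unmatched = merged["ref_count_n"].isna()
    if unmatched.any():
        if params.assume_normal_depth is not None:
            merged.loc[unmatched, "ref_count_n"] = params.assume_normal_depth
            merged.loc[unmatched, "alt_count_n"] = 0
        else:
            logger.info(
                "dropping %d tumor variants with no matched normal counts",
                int(unmatched.sum()),
            )
            merged = merged.loc[~unmatched]
    if merged.empty:
        logger.warning("no variants with matched normal counts; returning empty result")
        return pd.DataFrame(columns=RESULT_COLUMNS)

    merged["ref_count_n"] = merged["ref_count_n"].astype(int)
    merged["alt_count_n"] = merged["alt_count_n"].astype(int)
    depth_t = merged["ref_count"] + merged["alt_count"]
    depth_n = merged["ref_count_n"] + merged["alt_count_n"]
    tested = (depth_t >= params.min_depth) & (depth_n >= params.min_depth)
    merged = merged.loc[tested].copy()
    if merged.empty:
        logger.warning("no variants pass the depth threshold")
        return pd.DataFrame(columns=RESULT_COLUMNS)

    depth_t = merged["ref_count"] + merged["alt_count"]
    depth_n = merged["ref_count_n"] + merged["alt_count_n"]
    merged["af_tumor"] = merged["alt_count"] / depth_t
    merged["af_normal"] = merged["alt_count_n"] / depth_n
    merged["af_diff"] = merged["af_tumor"] - merged["af_normal"]

    tables = merged[["alt_count", "ref_count", "alt_count_n", "ref_count_n"]].to_numpy()
    merged["p"] = fisher_exact_many(tables)
    merged["q"] = np.nan
    for _, idx in merged.groupby("sample_id").groups.items():
        merged.loc[idx, "q"] = benjamini_hochberg(merged.loc[idx, "p"].to_numpy())

    effect = merged["af_diff"].abs() if params.af_diff_mode == "absolute" else merged["af_diff"]
    merged["retained"] = (effect > params.min_af_diff) & (merged["q"] < params.fdr_alpha)

    merged = merged.drop(columns=["_key", "ref_count_n", "alt_count_n"])
    if return_all:
        return merged.reset_index(drop=True)
    out = merged.loc[merged["retained"]].drop(columns=["retained"])
    return out.reset_index(drop=True)
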