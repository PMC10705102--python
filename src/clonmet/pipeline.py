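"""End-to-end pipeline: simulate -> filter -> clonality -> scores -> meta.

`run_pipeline` executes the five stages on a directory layout and
writes a run manifest recording the package version, seed, parameter
hash and per-stage row counts.  With a fixed seed and configuration the
output files are byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

import clonmet
from clonmet import io
from clonmet.clonality import (
    build_af_matrix,
    classify_clonal_relatedness,
    cluster_samples_by_af,
    common_ancestor_fraction,
    relatedness_to_frame,
    test_lnm_af_enrichment,
)
from clonmet.expression import (
    GeneSet,
    compare_score_by_stage,
    normalize_log_cpm,
    select_trend_genes,
    signature_zscore,
    simple_de_test,
)
from clonmet.meta import test_met_vs_primary_enrichment
from clonmet.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_expression_cohort,
    simulate_mutation_cohort,
)
from clonmet.somatic_filter import FilterParams, call_somatic_significant

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_patients": 6,
        "n_primary_foci": 3,
        "n_lnm": 2,
        "fraction_independent_foci": 0.13,
        "n_clones": 3,
        "n_truncal_mutations": 30,
        "n_private_mean": 10.0,
        "depth_mean": 149.0,
        "depth_dispersion": 12.0,
        "purity_range": [0.5, 0.9],
        "error_rate": 0.001,
    },
    "filter": {"min_depth": 40, "min_af_diff": 0.05, "fdr_alpha": 0.1},
    "clonality": {
        "min_shared": 5,
        "min_jaccard": 0.2,
        "presence_threshold": 0.05,
        "independence_threshold": 0.05,
        "selection_alpha": 0.1,
    },
    "expression": {
        "n_per_group": {"NP": 30, "PTF": 30, "LNM": 30},
        "n_genes": 1000,
        "geneset_size": 105,
        "effect_sd": 2.0,
    },
    "trend_alpha": 0.01,
    "meta": {
        "n_primary": 800,
        "n_met": 550,
        "n_genes": 100,
        "n_enriched": 5,
        "baseline_rate": 0.02,
        "odds_ratio": 3.0,
        "alpha": 0.05,
    },
}


def _merge(base: Mapping, override: Mapping | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: Mapping | None, out_dir: str | Path, seed: int = 0) -> dict:
    """Run the full synthetic-cohort pipeline and write all stage outputs.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    Any stage failure raises with the stage name; outputs of completed
    stages are preserved.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phash = io.params_hash(cfg)
    meta_kw = {"version": clonmet.__version__, "seed": seed, "phash": phash}
    manifest: dict = {
        "tool": "clonmet",
        "version": clonmet.__version__,
        "seed": seed,
        "params_hash": phash,
        "config": cfg,
        "stages": {},
    }
    stage = "simulate"
    try:
        sim_cfg = SimulationConfig(
            seed=seed, **{k: tuple(v) if k == "purity_range" else v for k, v in cfg["simulate"].items()}
        )
        variants, truth, metadata = simulate_cohort(sim_cfg)
        io.write_variant_table(variants, out / "simulated_variants.tsv", **meta_kw)
        io.write_table_tsv(truth, out / "simulated_truth.tsv", **meta_kw)
        io.write_table_tsv(metadata, out / "sample_metadata.tsv", **meta_kw)
        manifest["stages"]["simulate"] = {
            "n_variant_records": len(variants),
            "n_samples": len(metadata),
        }

        stage = "filter"
        fparams = FilterParams(**cfg["filter"])
        filtered_parts = []
        site = metadata.set_index("sample_id")["site_label"]
        for patient, pvars in variants.groupby("patient_id"):
            normal_ids = [
                s for s in pvars["sample_id"].unique() if site.get(s) in ("BLN", "NP")
            ]
            tumor = pvars[~pvars["sample_id"].isin(normal_ids)]
            normal = pvars[pvars["sample_id"].isin(normal_ids)]
            filtered_parts.append(call_somatic_significant(tumor, normal, fparams))
        filtered = pd.concat(filtered_parts, ignore_index=True)
        io.write_table_tsv(filtered, out / "filtered_variants.tsv", **meta_kw)
        manifest["stages"]["filter"] = {
            "n_retained": len(filtered),
            "per_patient": {
                p: int(n) for p, n in filtered.groupby("patient_id").size().items()
            },
        }

        stage = "clonality"
        clon = cfg["clonality"]
        calls_by_patient = {}
        selection_parts = []
        clon_dir = out / "clonality"
        for patient, pfilt in filtered.groupby("patient_id"):
            praw = variants[variants["patient_id"] == patient]
            tumor_raw = praw[praw["sample_id"].map(site).isin(("PTF", "LNM"))]
            mat = build_af_matrix(pfilt, tumor_raw, min_depth=fparams.min_depth)
            io.write_matrix_tsv(mat.af, clon_dir / f"{patient}_af_matrix.tsv", **meta_kw)
            if len(mat.samples) >= 2:
                clust = cluster_samples_by_af(mat)
                io.write_newick(
                    clust.linkage, clust.sample_ids, clon_dir / f"{patient}_dendrogram.nwk"
                )
            calls = classify_clonal_relatedness(
                mat,
                site.to_dict(),
                min_shared=clon["min_shared"],
                min_jaccard=clon["min_jaccard"],
                presence_threshold=clon["presence_threshold"],
                independence_threshold=clon["independence_threshold"],
            )
            calls_by_patient[patient] = calls
            if (
                site.reindex(mat.samples).eq("LNM").any()
                and site.reindex(mat.samples).eq("PTF").any()
            ):
                sel = test_lnm_af_enrichment(
                    tumor_raw,
                    site.to_dict(),
                    variants=mat.variants,
                    alpha=clon["selection_alpha"],
                )
                sel.insert(0, "patient_id", patient)
                selection_parts.append(sel)
        calls_df = pd.concat(
            [
                relatedness_to_frame(c).assign(patient_id=p)
                for p, c in calls_by_patient.items()
            ],
            ignore_index=True,
        )
        io.write_table_tsv(calls_df, out / "relatedness_calls.tsv", **meta_kw)
        selection = pd.concat(selection_parts, ignore_index=True)
        io.write_table_tsv(selection, out / "clonal_selection.tsv", **meta_kw)
        frac, (lo, hi), per_patient = common_ancestor_fraction(
            calls_by_patient, site.to_dict()
        )
        io.write_table_tsv(per_patient, out / "common_ancestor_per_patient.tsv", **meta_kw)
        manifest["stages"]["clonality"] = {
            "n_relatedness_calls": len(calls_df),
            "n_selection_tests": len(selection),
            "common_ancestor_fraction": round(frac, 6),
            "common_ancestor_ci95": [round(lo, 6), round(hi, 6)],
        }

        stage = "scores"
        expr = cfg["expression"]
        geneset_path = expr.get("geneset")
        n_genes = expr["n_genes"]
        if geneset_path:
            geneset = next(iter(io.read_gmt(geneset_path).values()))
        else:
            geneset = GeneSet(
                "SIMULATED_SET", [f"G{i + 1:04d}" for i in range(expr["geneset_size"])]
            )
        counts, stages_lab = simulate_expression_cohort(
            expr["n_per_group"],
            list(geneset),
            effect_sd=expr["effect_sd"],
            n_genes=n_genes,
            seed=seed,
        )
        io.write_matrix_tsv(counts, out / "expression_counts.tsv", **meta_kw)
        by_stage = {
            s: list(stages_lab.index[stages_lab == s]) for s in ("NP", "PTF", "LNM")
        }
        de1 = simple_de_test(counts, by_stage["NP"], by_stage["PTF"])
        de2 = simple_de_test(counts, by_stage["PTF"], by_stage["LNM"])
        io.write_matrix_tsv(de1, out / "de_np_vs_ptf.tsv", **meta_kw)
        io.write_matrix_tsv(de2, out / "de_ptf_vs_lnm.tsv", **meta_kw)
        trend = select_trend_genes(de1, de2, alpha=cfg["trend_alpha"])
        io.write_matrix_tsv(trend, out / "trend_genes.tsv", **meta_kw)
        score = signature_zscore(normalize_log_cpm(counts), geneset)
        score_df = score.to_frame()
        score_df["stage"] = stages_lab
        io.write_matrix_tsv(score_df, out / "signature_scores.tsv", **meta_kw)
        trend_test = compare_score_by_stage(score, stages_lab)
        manifest["stages"]["scores"] = {
            "n_genes": int(len(counts)),
            "n_trend_up": int((trend["trend"] == "up").sum()),
            "n_trend_down": int((trend["trend"] == "down").sum()),
            "trend_test_p": float(trend_test["p"]),
            "stage_means": {k: round(v, 6) for k, v in trend_test["stage_means"].items()},
        }

        stage = "meta"
        mc = cfg["meta"]
        gene_names = [f"MG{i + 1:04d}" for i in range(mc["n_genes"])]
        rates = {g: mc["baseline_rate"] for g in gene_names}
        enriched = {g: mc["odds_ratio"] for g in gene_names[: mc["n_enriched"]]}
        table, labels = simulate_mutation_cohort(
            mc["n_primary"], mc["n_met"], rates, enriched, seed=seed
        )
        io.write_matrix_tsv(table.T, out / "mutation_matrix.tsv", **meta_kw)
        io.write_table_tsv(
            labels.rename_axis("sample_id").reset_index(), out / "mutation_labels.tsv", **meta_kw
        )
        enr = test_met_vs_primary_enrichment(table.T, labels, alpha=mc["alpha"])
        io.write_table_tsv(enr, out / "meta_enrichment.tsv", **meta_kw)
        manifest["stages"]["meta"] = {
            "n_genes_tested": len(enr),
            "n_metastasis_enriched": int((enr["direction"] == "metastasis-enriched").sum()),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
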