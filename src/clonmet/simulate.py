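"""Seeded synthetic clonal-evolution cohorts.

Generates the four kinds of synthetic data the analysis stages consume:

* clone trees with truncal and branch-private mutations (perfect
  phylogeny under the infinite-sites assumption),
* multi-focus read counts: per sample, sequencing depth is
  negative-binomial around a configurable mean (default 149x, a typical
  whole-exome depth) and alt reads are binomial with success
  probability theta = purity * CCF / 2 for a diploid heterozygous
  mutation (CCF = summed fraction of clones carrying it),
* expression count matrices with a stage-graded log-mean shift on a
  designated gene set (emulating a pathway signature that rises from
  normal prostate through primary tumor to nodal metastasis),
* cohort-scale binary mutation tables with genes enriched in the
  metastasis arm at a chosen odds ratio.

One integer seed drives named substreams (tree / reads / expression /
cohort) so each generator is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CloneTree",
    "SampleTruth",
    "SimulationConfig",
    "simulate_clone_tree",
    "simulate_cohort",
    "simulate_expression_cohort",
    "simulate_mutation_cohort",
    "simulate_patient",
    "simulate_patient_reads",
]

GERMLINE = "germline"
SITE_LABELS = ("NP", "PTF", "BLN", "LNM")
STAGE_ORDER = ("NP", "PTF", "LNM")
BASES = np.array(list("ACGT"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode()) & 0x7FFFFFFF])
    )


@dataclass
class CloneTree:
    """Perfect-phylogeny clone tree rooted at the germline.

    ``parent`` maps each clone to its parent (the germline root has
    parent ``None``); ``branch_mutations`` holds the mutations acquired
    on the branch *into* each clone.  Under infinite sites every
    mutation is acquired once and inherited by the whole subtree.
    """

    clone_ids: list[str]
    parent: dict[str, str | None]
    branch_mutations: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        roots = [c for c in self.clone_ids if self.parent.get(c) is None]
        if roots != [GERMLINE] and len(roots) != 1:
            raise ValueError("clone tree must have exactly one root")
        seen: set[str] = set()
        for c in self.clone_ids:
            muts = self.branch_mutations.get(c, set())
            if seen & muts:
                raise ValueError("mutation identifiers must be unique across branches")
            seen |= muts
        for c in self.clone_ids:  # acyclicity: every clone reaches the root
            hops, node = 0, c
            while self.parent.get(node) is not None:
                node = self.parent[node]
                hops += 1
                if hops > len(self.clone_ids):
                    raise ValueError("parent relation contains a cycle")

    @property
    def root(self) -> str:
        return next(c for c in self.clone_ids if self.parent.get(c) is None)

    @property
    def tumor_clones(self) -> list[str]:
        return [c for c in self.clone_ids if c != self.root]

    def mutations_of(self, clone: str) -> set[str]:
        """All mutations carried by ``clone`` (own branch plus ancestral)."""
        out: set[str] = set()
        node: str | None = clone
        while node is not None:
            out |= self.branch_mutations.get(node, set())
            node = self.parent.get(node)
        return out

    def all_mutations(self) -> list[str]:
        return sorted(set().union(*(self.branch_mutations.get(c, set()) for c in self.clone_ids)))

    def carriers(self, mutation: str) -> set[str]:
        """Set of clones carrying ``mutation`` (the subtree below its branch)."""
        return {c for c in self.tumor_clones if mutation in self.mutations_of(c)}


@dataclass
class SampleTruth:
    """Ground-truth description of one sequenced sample."""

    sample_id: str
    site_label: str
    purity: float
    clone_fractions: dict[str, float]
    patient_id: str
    truth_relatedness: str  # metastatic-clone | non-metastatic-clone | independent | benign

    def __post_init__(self) -> None:
        if self.site_label not in SITE_LABELS:
            raise ValueError(f"unknown site label {self.site_label!r}")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")
        if self.site_label in ("BLN", "NP"):
            if self.purity != 0.0:
                raise ValueError("benign samples must have purity 0")
        else:
            if self.site_label == "LNM" and self.purity <= 0:
                raise ValueError("LNM purity must be positive")
            total = sum(self.clone_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"clone fractions must sum to 1, got {total}")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    ``depth_mean`` defaults to 149, a typical whole-exome median depth;
    ``depth_dispersion`` is the negative-binomial size parameter (larger
    means tighter around the mean).  ``purity_range`` bounds the uniform
    tumor-purity draw.  Copy number is fixed diploid heterozygous, so
    the expected somatic allele fraction is purity * CCF / 2.
    """

    seed: int = 0
    n_patients: int = 20
    n_primary_foci: int = 3
    n_lnm: int = 2
    fraction_independent_foci: float = 0.13
    n_clones: int = 3
    n_truncal_mutations: int = 30
    n_private_mean: float = 10.0
    depth_mean: float = 149.0
    depth_dispersion: float = 12.0
    purity_range: tuple[float, float] = (0.5, 0.9)
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_primary_foci", "n_clones", "n_truncal_mutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_lnm < 0 or self.n_private_mean < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.fraction_independent_foci <= 1.0:
            raise ValueError("fraction_independent_foci must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must satisfy 0 < lo <= hi <= 1")


def simulate_clone_tree(
    n_clones: int,
    n_truncal: int = 30,
    n_private_mean: float = 10.0,
    seed: int | np.random.Generator = 0,
    prefix: str = "",
) -> CloneTree:
    """Simulate a clone tree with one truncal branch and random private branches.

    The first tumor clone descends from the germline and carries exactly
    ``n_truncal`` truncal mutations; each further clone attaches to a
    uniformly chosen existing tumor clone and acquires a
    Poisson(``n_private_mean``) number of private mutations.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if n_truncal < 0:
        raise ValueError("n_truncal must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "tree")
    clone_ids = [GERMLINE] + [f"{prefix}C{i + 1}" for i in range(n_clones)]
    parent: dict[str, str | None] = {GERMLINE: None, clone_ids[1]: GERMLINE}
    counter = 0

    def new_mutations(k: int) -> set[str]:
        nonlocal counter
        out = {f"{prefix}M{counter + i:05d}" for i in range(k)}
        counter += k
        return out

    branch_mutations = {GERMLINE: set(), clone_ids[1]: new_mutations(n_truncal)}
    for clone in clone_ids[2:]:
        parent[clone] = clone_ids[1 + rng.integers(0, len(parent) - 1)]
        branch_mutations[clone] = new_mutations(int(rng.poisson(n_private_mean)))
    return CloneTree(clone_ids, parent, branch_mutations)


def _attach_independent_origin(
    tree: CloneTree, origin_index: int, n_truncal: int, rng: np.random.Generator
) -> str:
    """Graft a clonally independent origin (own trunk) onto the germline root."""
    clone = f"I{origin_index}C1"
    muts = {f"I{origin_index}M{i:05d}" for i in range(n_truncal)}
    tree.clone_ids.append(clone)
    tree.parent[clone] = GERMLINE
    tree.branch_mutations[clone] = muts
    tree.validate()
    return clone


def _mutation_loci(mutations: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic genomic coordinates, alleles and gene symbols per mutation."""
    n = len(mutations)
    chroms = [f"chr{(i % 22) + 1}" for i in range(n)]
    pos = 10_000 + 1_000 * np.arange(n)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    genes = [f"G{(i % 200) + 1:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "mutation": list(mutations),
            "chrom": chroms,
            "pos": pos,
            "ref": BASES[ref_idx],
            "alt": BASES[alt_idx],
            "gene": genes,
        }
    )


def simulate_patient_reads(
    tree: CloneTree,
    samples: Sequence[SampleTruth],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-site read counts for every (mutation, sample) pair.

    Depth is negative-binomial with mean ``config.depth_mean``; alt
    reads are Binomial(depth, theta) with theta = purity * CCF / 2 for
    tumor samples (floored at the sequencing error rate) and theta =
    error rate for benign samples.

    Returns
    -------
    (variants, truth) : variants is a MAF-lite table (patient_id,
    sample_id, chrom, pos, ref, alt, ref_count, alt_count, gene,
    mutation); truth records theta and carrier status per pair.
    """
    for s in samples:
        for clone in s.clone_fractions:
            if clone not in tree.clone_ids:
                raise ValueError(f"sample {s.sample_id} references unknown clone {clone!r}")
    rng = rng if rng is not None else substream(config.seed, "reads")
    mutations = tree.all_mutations()
    loci = _mutation_loci(mutations, rng)
    carrier_sets = {m: tree.carriers(m) for m in mutations}

    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.depth_mean)
    var_rows, truth_rows = [], []
    for s in samples:
        if s.site_label in ("BLN", "NP"):
            theta = np.full(len(mutations), config.error_rate)
            carried = np.zeros(len(mutations), dtype=bool)
        else:
            ccf = np.array(
                [
                    sum(s.clone_fractions.get(c, 0.0) for c in carrier_sets[m])
                    for m in mutations
                ]
            )
            theta = np.maximum(s.purity * ccf / 2.0, config.error_rate)
            carried = ccf > 0
        depth = rng.negative_binomial(nb_n, nb_p, size=len(mutations))
        alt = rng.binomial(depth, theta)
        var_rows.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "sample_id": s.sample_id,
                    "chrom": loci["chrom"],
                    "pos": loci["pos"],
                    "ref": loci["ref"],
                    "alt": loci["alt"],
                    "ref_count": depth - alt,
                    "alt_count": alt,
                    "gene": loci["gene"],
                    "mutation": loci["mutation"],
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "sample_id": s.sample_id,
                    "mutation": mutations,
                    "theta": theta,
                    "carried": carried,
                }
            )
        )
    variants = pd.concat(var_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return variants, truth


def simulate_patient(
    patient_id: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CloneTree, list[SampleTruth], pd.DataFrame, pd.DataFrame]:
    """Simulate one patient: clone tree, sample truths, read counts.

    The patient carries a main clone tree shared by clonally related
    foci and metastases.  Each primary focus is independently declared
    clonally independent with probability
    ``config.fraction_independent_foci``; an independent focus gets its
    own trunk grafted at the germline, so it shares zero somatic
    mutations with the rest of the patient.  One benign lymph node
    (purity 0) serves as the matched normal.
    """
    rng = rng if rng is not None else substream(config.seed, f"patient:{patient_id}")
    tree = simulate_clone_tree(
        config.n_clones,
        config.n_truncal_mutations,
        config.n_private_mean,
        seed=rng,
        prefix=f"{patient_id}.",
    )
    main_clones = tree.tumor_clones
    lo, hi = config.purity_range
    samples: list[SampleTruth] = []
    samples.append(
        SampleTruth(f"{patient_id}_BLN", "BLN", 0.0, {}, patient_id, "benign")
    )
    has_lnm = config.n_lnm > 0
    n_independent_origins = 0
    for i in range(config.n_primary_foci):
        independent = rng.random() < config.fraction_independent_foci
        if independent:
            n_independent_origins += 1
            clone = _attach_independent_origin(
                tree, n_independent_origins, config.n_truncal_mutations, rng
            )
            fractions = {clone: 1.0}
            label = "independent"
        else:
            frac = rng.dirichlet(np.ones(len(main_clones)))
            fractions = dict(zip(main_clones, frac))
            label = "metastatic-clone" if has_lnm else "non-metastatic-clone"
        samples.append(
            SampleTruth(
                f"{patient_id}_PTF{i + 1}",
                "PTF",
                float(rng.uniform(lo, hi)),
                fractions,
                patient_id,
                label,
            )
        )
    for i in range(config.n_lnm):
        frac = rng.dirichlet(np.ones(len(main_clones)))
        samples.append(
            SampleTruth(
                f"{patient_id}_LNM{i + 1}",
                "LNM",
                float(rng.uniform(lo, hi)),
                dict(zip(main_clones, frac)),
                patient_id,
                "metastatic-clone",
            )
        )
    variants, truth = simulate_patient_reads(tree, samples, config, rng=rng)
    return tree, samples, variants, truth


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-patient WES cohort.

    Returns
    -------
    (variants, truth, metadata) : stacked per-patient read-count and
    truth tables plus a sample-metadata table (sample_id, patient_id,
    site_label, purity, truth_relatedness).
    """
    all_vars, all_truth, meta_rows = [], [], []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        _, samples, variants, truth = simulate_patient(pid, config)
        all_vars.append(variants)
        all_truth.append(truth)
        for s in samples:
            meta_rows.append(
                {
                    "sample_id": s.sample_id,
                    "patient_id": s.patient_id,
                    "site_label": s.site_label,
                    "purity": s.purity,
                    "truth_relatedness": s.truth_relatedness,
                }
            )
    return (
        pd.concat(all_vars, ignore_index=True),
        pd.concat(all_truth, ignore_index=True),
        pd.DataFrame(meta_rows),
    )


def simulate_expression_cohort(
    n_per_group: Mapping[str, int],
    geneset: Iterable[str],
    effect_sd: float = 1.0,
    n_genes: int = 2000,
    seed: int = 0,
    base_log2_mean: float = 7.0,
    base_log2_sd: float = 1.5,
    dispersion: float = 8.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a genes x samples count matrix with a stage-graded gene-set shift.

    Counts are negative-binomial.  Genes in ``geneset`` get a log2-mean
    shift of 0, effect_sd/2 and effect_sd for the NP, PTF and LNM
    stages respectively; all other genes have no stage effect.

    Returns (counts, labels) with labels a sample -> stage Series.
    """
    rng = substream(seed, "expression")
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    gene_index = pd.Index(genes)
    geneset = list(geneset)
    missing = set(geneset) - set(genes)
    if missing:
        raise ValueError(f"gene-set members absent from gene universe: {sorted(missing)[:5]}")
    stages = [s for s in STAGE_ORDER if s in n_per_group]
    shift_per_stage = {"NP": 0.0, "PTF": effect_sd / 2.0, "LNM": effect_sd}
    base_mean = 2.0 ** rng.normal(base_log2_mean, base_log2_sd, size=n_genes)
    in_set = gene_index.isin(geneset)

    cols, labels = [], []
    counts = []
    for stage in stages:
        for i in range(int(n_per_group[stage])):
            mu = base_mean * np.where(in_set, 2.0 ** shift_per_stage[stage], 1.0)
            p = dispersion / (dispersion + mu)
            counts.append(rng.negative_binomial(dispersion, p))
            cols.append(f"{stage}_{i + 1:03d}")
            labels.append(stage)
    mat = pd.DataFrame(np.column_stack(counts), index=gene_index, columns=cols)
    return mat, pd.Series(labels, index=cols, name="stage")


def metastasis_rate(baseline_rate: float, odds_ratio: float) -> float:
    """Bernoulli rate in the metastasis arm given a baseline rate and odds ratio."""
    odds = odds_ratio * baseline_rate / (1.0 - baseline_rate)
    return odds / (1.0 + odds)


def simulate_mutation_cohort(
    n_primary: int,
    n_met: int,
    gene_rates: Mapping[str, float],
    enriched: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a cohort-scale binary gene-mutation table.

    Each gene mutates independently per sample: primaries at the gene's
    baseline rate, metastases at the rate whose odds are the baseline
    odds scaled by the gene's odds ratio (1 if not in ``enriched``).

    Returns (table, labels): table is samples x genes binary with one
    row per sample; labels maps sample -> {primary, metastasis}.
    """
    if n_primary < 1 or n_met < 1:
        raise ValueError("both arms need at least one sample")
    enriched = dict(enriched or {})
    for g, r in gene_rates.items():
        if not 0.0 < r < 1.0:
            raise ValueError(f"baseline rate for {g} must lie in (0, 1)")
    for g, o in enriched.items():
        if o <= 0:
            raise ValueError(f"odds ratio for {g} must be positive")
    rng = substream(seed, "cohort")
    genes = list(gene_rates)
    sample_ids = [f"PRI{i + 1:05d}" for i in range(n_primary)] + [
        f"MET{i + 1:05d}" for i in range(n_met)
    ]
    labels = pd.Series(
        ["primary"] * n_primary + ["metastasis"] * n_met, index=sample_ids, name="arm"
    )
    cols = {}
    for g in genes:
        base = gene_rates[g]
        met = metastasis_rate(base, enriched.get(g, 1.0))
        cols[g] = np.concatenate(
            [
                rng.binomial(1, base, size=n_primary),
                rng.binomial(1, met, size=n_met),
            ]
        )
    table = pd.DataFrame(cols, index=sample_ids)
    return table, labels
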