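"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates, offline and with planted truth, the four kinds of
input the pipeline consumes:

* multi-database target prediction tables (continuous scores, so the true
  within-database top decile is known per interaction);
* flat annotation tables (GO-like term names carrying planted category
  keywords; disease evidence counts; tissue confidence scores) whose true
  filter outcomes are recorded;
* GMT gene-set libraries with one planted enriched term, oversampled into a
  designated query set;
* qPCR cohorts: paired pre/post CT triplicates with planted post/pre fold
  changes, and biomarkers tied to a chosen miRNA's post-run log-expression
  through a Gaussian copula with Pearson parameter r = 2*sin(pi*rho_S/6),
  so a target Spearman correlation holds without calibration loops.

Defaults mirror the emulated study: 55 input miRNAs, 14 prediction
databases, 23 cohort subjects, a planted post/pre fold change of 2.0 and a
planted Spearman of -0.632 between miR-1-3p and post-run hs-CRP.  All
randomness flows from one integer seed; a fixed seed reproduces outputs
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_sets import DEFAULT_CATEGORY_KEYWORDS, DEFAULT_TISSUE_WHITELIST

__all__ = [
    "GeneratorConfig",
    "TruthBundle",
    "gen_prediction_table",
    "gen_annotation_tables",
    "gen_gene_set_library",
    "gen_cohort",
    "write_fixtures",
]

#: miRNA panel measured in the emulated cohort (one planted non-detectable).
DEFAULT_COHORT_MIRNAS = [
    "hsa-miR-1-3p",
    "hsa-miR-126",
    "hsa-miR-223",
    "hsa-miR-125a-5p",
    "hsa-miR-15a",
    "hsa-miR-15b",
    "hsa-miR-106a-5p",
]


@dataclass
class GeneratorConfig:
    seed: int = 0
    # prediction tables
    n_mirnas: int = 55
    n_genes: int = 2000
    n_databases: int = 14
    prediction_density: float = 0.02
    # annotation tables
    planted_category_sizes: dict[str, int] = field(
        default_factory=lambda: {cat: 60 for cat in DEFAULT_CATEGORY_KEYWORDS}
    )
    # enrichment library
    n_terms: int = 50
    term_size_range: tuple[int, int] = (20, 80)
    query_size: int = 60
    planted_oversample: float = 0.6  # fraction of the query drawn from the planted term
    # cohort
    cohort_n: int = 23
    cohort_mirnas: list[str] = field(default_factory=lambda: list(DEFAULT_COHORT_MIRNAS))
    undetectable_mirnas: list[str] = field(default_factory=lambda: ["hsa-miR-106a-5p"])
    planted_fold_changes: dict[str, float] = field(
        default_factory=lambda: {"hsa-miR-126": 2.0}
    )
    planted_spearman: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("hsa-miR-1-3p", "hs_crp"): -0.632}
    )
    replicate_sd: float = 0.15  # CT cycles, within-triplicate
    subject_sd: float = 1.0  # CT cycles, between-subject baseline

    def __post_init__(self) -> None:
        if self.cohort_n < 4:
            raise ValueError("cohort_n must be >= 4")
        for fc in self.planted_fold_changes.values():
            if fc <= 0:
                raise ValueError("fold changes must be > 0")
        for rho in self.planted_spearman.values():
            if not -1 < rho < 1:
                raise ValueError("planted Spearman rho must lie in (-1, 1)")
        if not 0 < self.prediction_density <= 1:
            raise ValueError("prediction_density must be in (0, 1]")


@dataclass
class TruthBundle:
    """Ground truth recorded while generating; consistent with the emitted
    tables by construction."""

    top_decile: np.ndarray | None = None  # per-row flag of the prediction table
    support: dict[tuple[str, str], int] | None = None  # over top-decile rows
    category_members: dict[str, set[str]] | None = None
    disease_members: set[str] | None = None
    tissue_members: set[str] | None = None
    planted_term: str | None = None
    query_genes: set[str] | None = None
    fold_changes: dict[str, float] | None = None
    spearman: dict[tuple[str, str], float] | None = None
    undetectable: list[str] | None = None


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


def _mirna_names(n: int) -> list[str]:
    arms = ["", "-3p", "-5p"]
    return [f"hsa-miR-{9000 + i}{arms[i % 3]}" for i in range(n)]


# ---------------------------------------------------------------------------
# prediction tables


def gen_prediction_table(config: GeneratorConfig) -> tuple[pd.DataFrame, TruthBundle]:
    """Per-database i.i.d. continuous scores over random (miRNA, gene) pairs.

    Truth flags each row's membership in its database's top decile (ties
    absent almost surely) and records the support counts a correct
    filter+aggregate pass must reproduce."""
    rng = np.random.default_rng(config.seed)
    mirnas = _mirna_names(config.n_mirnas)
    genes = _gene_names(config.n_genes)
    n_pairs = config.n_mirnas * config.n_genes
    n_per_db = int(round(config.prediction_density * n_pairs))
    if n_per_db == 0:
        raise ValueError("prediction_density yields zero interactions")

    frames = []
    flags = []
    for d in range(config.n_databases):
        db = f"DB{d + 1:02d}"
        pair_idx = rng.choice(n_pairs, size=n_per_db, replace=False)
        scores = rng.uniform(size=n_per_db)
        frames.append(
            pd.DataFrame(
                {
                    "mirna": [mirnas[i // config.n_genes] for i in pair_idx],
                    "gene": [genes[i % config.n_genes] for i in pair_idx],
                    "database": db,
                    "score": scores,
                }
            )
        )
        cut = np.sort(scores)[::-1][math.ceil(0.10 * n_per_db) - 1]
        flags.append(scores >= cut)

    table = pd.concat(frames, ignore_index=True)
    top = np.concatenate(flags)
    support: dict[tuple[str, str], int] = {}
    for m, g in zip(table.loc[top, "mirna"], table.loc[top, "gene"]):
        support[(m, g)] = support.get((m, g), 0) + 1
    return table, TruthBundle(top_decile=top, support=support)


# ---------------------------------------------------------------------------
# annotation tables


def gen_annotation_tables(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthBundle]:
    """GO-like, disease-evidence and tissue-confidence tables with planted
    filter outcomes."""
    rng = np.random.default_rng(config.seed + 1)
    genes = np.array(_gene_names(config.n_genes))

    # process categories: members get a term whose name carries the keyword
    go_rows = []
    members: dict[str, set[str]] = {}
    term_counter = 1
    for cat, size in config.planted_category_sizes.items():
        if size > config.n_genes:
            raise ValueError(f"category {cat!r} larger than gene pool")
        keyword = DEFAULT_CATEGORY_KEYWORDS[cat][0]
        chosen = rng.choice(genes, size=size, replace=False)
        members[cat] = set(chosen)
        for g in chosen:
            go_rows.append(
                (f"GO:{term_counter:07d}", f"regulation of {keyword} signaling", g)
            )
            term_counter += 1
    # decoy annotations whose names contain no category keyword
    for g in rng.choice(genes, size=config.n_genes // 2, replace=False):
        go_rows.append((f"GO:{term_counter:07d}", "housekeeping ribosome assembly", g))
        term_counter += 1
    go = pd.DataFrame(go_rows, columns=["term_id", "term_name", "gene"])

    pubs = rng.poisson(3.0, size=config.n_genes)
    variants = rng.poisson(1.5, size=config.n_genes)
    disease = pd.DataFrame(
        {"gene": genes, "n_publications": pubs, "n_variants": variants}
    )
    disease_truth = set(genes[(pubs >= 5) | (variants >= 3)])

    tissues = np.array(DEFAULT_TISSUE_WHITELIST + ["Liver", "Kidney", "Brain", "Lung"])
    tis_choice = tissues[rng.integers(0, len(tissues), size=config.n_genes)]
    conf = np.round(rng.uniform(0, 5, size=config.n_genes), 3)
    tissue = pd.DataFrame({"gene": genes, "tissue": tis_choice, "confidence": conf})
    whitelisted = np.isin(tis_choice, DEFAULT_TISSUE_WHITELIST)
    tissue_truth = set(genes[whitelisted & (conf >= 1.0)])

    truth = TruthBundle(
        category_members=members,
        disease_members=disease_truth,
        tissue_members=tissue_truth,
    )
    return go, disease, tissue, truth


# ---------------------------------------------------------------------------
# enrichment library


def gen_gene_set_library(
    config: GeneratorConfig,
) -> tuple[dict[str, set[str]], set[str], TruthBundle]:
    """Random GMT-style library with one planted term.

    Returns (terms, query, truth): the query gene set draws a fraction
    ``planted_oversample`` of its genes from the planted term and the rest
    uniformly from the universe, so at the default oversampling the planted
    term should dominate the enrichment ranking."""
    if config.n_terms < 2:
        raise ValueError("need at least two terms")
    rng = np.random.default_rng(config.seed + 2)
    genes = np.array(_gene_names(config.n_genes))
    lo, hi = config.term_size_range
    terms: dict[str, set[str]] = {}
    for t in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        terms[f"TERM_{t + 1:03d}"] = set(rng.choice(genes, size=size, replace=False))
    planted = "TERM_001"

    n_plant = int(round(config.planted_oversample * config.query_size))
    planted_genes = np.array(sorted(terms[planted]))
    q = set(rng.choice(planted_genes, size=min(n_plant, planted_genes.size), replace=False))
    while len(q) < config.query_size:
        q.add(str(rng.choice(genes)))
    truth = TruthBundle(planted_term=planted, query_genes=set(q))
    return terms, set(q), truth


# ---------------------------------------------------------------------------
# cohort


_SPIKE_CT = 22.0
_BIOMARKER_MARGINS = {
    # column -> (family, params) for the post-run margin used by the copula
    "hs_crp": ("lognormal", (math.log(3.2), 0.8)),
    "hs_tnt": ("lognormal", (math.log(14.0), 0.6)),
    "glucose": ("normal", (93.0, 10.0)),
    "lactate_max": ("normal", (4.0, 1.5)),
    "race_time": ("normal", (10.5, 1.5)),
}


def _margin_transform(z: np.ndarray, column: str) -> np.ndarray:
    family, (a, b) = _BIOMARKER_MARGINS[column]
    if family == "lognormal":
        return np.exp(a + b * z)
    return a + b * z


def gen_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthBundle]:
    """Paired pre/post cohort with CT triplicates and biomarkers.

    Each (subject, miRNA) has a latent baseline u ~ N(0,1) mapped to CT as
    ``base_ct - subject_sd * u`` (higher u -> lower CT -> higher
    expression); the post-run CT is additionally shifted by
    -log2(fold change).  For a planted (miRNA, biomarker) Spearman rho, the
    miRNA's latent and the biomarker's Gaussian-copula latent are drawn
    bivariate normal with Pearson r = 2*sin(pi*rho/6)."""
    rng = np.random.default_rng(config.seed + 3)
    n = config.cohort_n
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    mirnas = list(config.cohort_mirnas)

    planted_by_mirna = {m: (bio, rho) for (m, bio), rho in config.planted_spearman.items()}
    if len(planted_by_mirna) < len(config.planted_spearman):
        raise ValueError("at most one planted correlation per miRNA")
    for m, _ in config.planted_spearman:
        if m not in mirnas:
            raise ValueError(f"planted miRNA {m!r} not in cohort panel")

    # latent subject effects per miRNA, with copula coupling where planted
    latents: dict[str, np.ndarray] = {}
    bio_latents: dict[str, np.ndarray] = {}
    for m in mirnas:
        if m in planted_by_mirna:
            bio, rho = planted_by_mirna[m]
            r = 2.0 * math.sin(math.pi * rho / 6.0)
            z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
            latents[m] = z[:, 0]
            bio_latents[bio] = z[:, 1]
        else:
            latents[m] = rng.standard_normal(n)

    # CT table
    base_ct = {m: 27.0 + 0.5 * i for i, m in enumerate(mirnas)}
    ct_rows = []
    for m in mirnas:
        undet = m in config.undetectable_mirnas
        lfc = math.log2(config.planted_fold_changes.get(m, 1.0))
        for s in range(n):
            pre_center = base_ct[m] - config.subject_sd * latents[m][s]
            for tp, center in (("pre", pre_center), ("post", pre_center - lfc)):
                ct = (
                    [float("nan")] * 3
                    if undet
                    else list(center + config.replicate_sd * rng.standard_normal(3))
                )
                spike = list(_SPIKE_CT + config.replicate_sd * rng.standard_normal(3))
                ct_rows.append([subjects[s], m, tp, *ct, *spike])
    ct_df = pd.DataFrame(
        ct_rows,
        columns=["subject_id", "mirna", "timepoint",
                 "ct_1", "ct_2", "ct_3", "spike_1", "spike_2", "spike_3"],
    )

    # biomarkers: post margins (copula-coupled when planted), independent pre
    def post_values(col: str) -> np.ndarray:
        z = bio_latents.get(col, rng.standard_normal(n))
        return _margin_transform(z, col)

    hs_crp_post = post_values("hs_crp")
    hs_tnt_post = post_values("hs_tnt")
    glucose_post = post_values("glucose")
    lactate_max = np.clip(post_values("lactate_max"), 0.5, None)
    race_time = np.clip(post_values("race_time"), 6.0, None)
    hs_crp_pre = np.exp(math.log(0.7) + 0.5 * rng.standard_normal(n))
    hs_tnt_pre = np.exp(math.log(5.0) + 0.5 * rng.standard_normal(n))
    glucose_pre = 89.0 + 8.0 * rng.standard_normal(n)
    sex = np.where(rng.uniform(size=n) < 20 / 23, "M", "F")
    finished = rng.uniform(size=n) < 0.6
    distance = np.where(finished, 100.0, np.round(rng.uniform(52, 91, size=n), 1))

    cohort_rows = []
    for s in range(n):
        common = dict(
            subject_id=subjects[s], sex=sex[s],
            lactate_max=lactate_max[s], race_time=race_time[s],
            distance=distance[s],
        )
        cohort_rows.append(
            {**common, "timepoint": "pre", "hs_crp": hs_crp_pre[s],
             "hs_tnt": hs_tnt_pre[s], "glucose": glucose_pre[s]}
        )
        cohort_rows.append(
            {**common, "timepoint": "post", "hs_crp": hs_crp_post[s],
             "hs_tnt": hs_tnt_post[s], "glucose": glucose_post[s]}
        )
    cohort_df = pd.DataFrame(cohort_rows)[
        ["subject_id", "sex", "timepoint", "hs_crp", "hs_tnt",
         "glucose", "lactate_max", "race_time", "distance"]
    ]

    truth = TruthBundle(
        fold_changes=dict(config.planted_fold_changes),
        spearman=dict(config.planted_spearman),
        undetectable=list(config.undetectable_mirnas),
    )
    return cohort_df, ct_df, truth


# ---------------------------------------------------------------------------
# fixture emission


def write_fixtures(config: GeneratorConfig, outdir) -> dict[str, str]:
    """Emit every synthetic input as TSV/GMT under ``outdir`` plus a truth
    JSON; returns the path map."""
    import json

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    pred, pred_truth = gen_prediction_table(config)
    pred.to_csv(out / "predictions.tsv", sep="\t", index=False, float_format="%.10g")
    paths["predictions"] = str(out / "predictions.tsv")

    go, disease, tissue, ann_truth = gen_annotation_tables(config)
    for name, df in [("go", go), ("disease", disease), ("tissue", tissue)]:
        df.to_csv(out / f"{name}_annotations.tsv", sep="\t", index=False,
                  float_format="%.10g")
        paths[name] = str(out / f"{name}_annotations.tsv")

    terms, query, lib_truth = gen_gene_set_library(config)
    with open(out / "library.gmt", "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, "synthetic", *sorted(genes)]) + "\n")
    paths["library"] = str(out / "library.gmt")
    with open(out / "query_genes.txt", "w") as fh:
        fh.write("\n".join(sorted(query)) + "\n")
    paths["query"] = str(out / "query_genes.txt")

    cohort, ct, cohort_truth = gen_cohort(config)
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False, float_format="%.10g")
    ct.to_csv(out / "ct.tsv", sep="\t", index=False, float_format="%.10g")
    paths["cohort"] = str(out / "cohort.tsv")
    paths["ct"] = str(out / "ct.tsv")

    truth_json = {
        "n_top_decile": int(pred_truth.top_decile.sum()),
        "category_sizes": {k: len(v) for k, v in ann_truth.category_members.items()},
        "n_disease_members": len(ann_truth.disease_members),
        "n_tissue_members": len(ann_truth.tissue_members),
        "planted_term": lib_truth.planted_term,
        "fold_changes": cohort_truth.fold_changes,
        "spearman": {f"{m}|{b}": r for (m, b), r in cohort_truth.spearman.items()},
        "undetectable": cohort_truth.undetectable,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
    paths["truth"] = str(out / "truth.json")
    return paths
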