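"""End-to-end orchestration: simulate or ingest counts, normalize, fit the
factorial model, quantify genetic variation for plasticity, and run the
coding-sequence polymorphism comparisons, from a single config.

All randomness flows from named seeds recorded in the report; a rerun with
the same config reproduces every number bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import factorial, io, normalize, plasticity, popgen, simulate, tree

log = logging.getLogger("plastigene")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``simulation`` holds SimulationParams fields (without tissue/seed,
    which the pipeline manages); set ``counts_path``/``design_path``
    instead to ingest real data for a single tissue.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    tissues: list[str] = field(default_factory=lambda: ["abdomen", "thorax"])
    simulation: dict = field(default_factory=dict)
    counts_path: str | None = None
    design_path: str | None = None
    min_samples: int = 3
    min_mean_cpm: float = 0.25
    fdr: float = 0.05
    fc_threshold: float | None = None
    min_cum_variance: float = 0.60
    n_pcs: int | None = None
    haplotypes: dict = field(
        default_factory=lambda: {
            "n_haplotypes": 20,
            "sites_per_gene": 20,
            "sfs_mode": "neutral",
            "sequence_length": 1000,
        }
    )
    permutation_draws: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisReport:
    config: dict
    seeds: dict
    per_tissue: dict
    cross_tissue: dict
    popgen: dict
    timings: dict

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=indent, default=_jsonable)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _tissue_seed(base: int, i: int) -> int:
    # keep derived seeds deterministic and below 2**31
    return int((base * 1_000_003 + 7919 * (i + 1)) % (2**31 - 1))


def analyze_tissue(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    config: PipelineConfig,
    out: Path | None = None,
) -> dict:
    """Run normalization, factorial inference and plasticity metrics for
    one tissue; returns the stage summaries and (optionally) persists the
    stage tables under ``out``."""
    filt = normalize.filter_low_expression(
        counts, min_samples=config.min_samples, min_mean_cpm=config.min_mean_cpm
    )
    log.info("filter: %d genes kept, %d removed", len(filt.kept), len(filt.removed))
    factors = normalize.tmm_factors(filt.counts)
    cpm_mat = normalize.cpm(filt.counts, factors)
    log2_mat = normalize.transform(cpm_mat, "log2_cpm")
    log10_mat = normalize.transform(cpm_mat, "log10_cpm")
    z_mat = normalize.transform(cpm_mat, "z_per_gene")

    results = factorial.fit_factorial(log2_mat, design)
    bias = factorial.classify_season_bias(
        results, fdr=config.fdr, lfc_threshold=config.fc_threshold
    )
    sig_counts = {
        term: int((factorial.term_table(results, term)["q"] < config.fdr).sum())
        for term in factorial.TERMS
    }

    rn = plasticity.reaction_norms(z_mat, design)
    slope_vs_intercept = plasticity.compare_slope_intercept(rn, measure="sd")
    corr_p = plasticity.cross_env_correlation(z_mat, design, method="pearson")
    corr_s = plasticity.cross_env_correlation(z_mat, design, method="spearman")

    pcs = plasticity.pca(log10_mat)
    pc_assoc = plasticity.pc_anova(pcs, design, n_pcs=config.n_pcs)
    dist = plasticity.euclidean_distances(log10_mat)
    newick = tree.nj_tree(dist)

    n_genes = len(filt.kept)
    summary = {
        "n_samples": int(counts.shape[1]),
        "n_genes_input": int(counts.shape[0]),
        "n_genes_retained": n_genes,
        "tmm_factor_range": [float(factors.min()), float(factors.max())],
        "significant_genes": sig_counts,
        "significant_fractions": {
            t: c / n_genes for t, c in sig_counts.items()
        },
        "season_bias": {k: len(v) for k, v in bias.items()},
        "slope_vs_intercept": dataclasses.asdict(slope_vs_intercept),
        "median_cross_env_rho_pearson": corr_p.median,
        "median_cross_env_rho_spearman": corr_s.median,
        "n_pcs_tested": int(pc_assoc["pc"].nunique()),
        "pc1_variance_fraction": float(pcs.variance_fraction[0]),
        "pc_interaction_significant": int(
            ((pc_assoc["term"] == "season:family") & (pc_assoc["q"] < config.fdr)).sum()
        ),
    }
    stage = {
        "summary": summary,
        "results": results,
        "bias": bias,
        "reaction_norms": rn,
        "newick": newick,
    }
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        io.write_counts(filt.counts, out / "counts_filtered.tsv")
        factors.to_csv(out / "tmm_factors.tsv", sep="\t")
        results.to_csv(out / "term_results.tsv", sep="\t", index=False)
        rn.summary.to_csv(out / "reaction_norms.tsv", sep="\t", index_label="gene")
        pd.DataFrame(
            {"pearson": corr_p.rho, "spearman": corr_s.rho}
        ).to_csv(out / "cross_env_correlation.tsv", sep="\t", index_label="gene")
        pc_assoc.to_csv(out / "pc_anova.tsv", sep="\t", index=False)
        io.write_phylip_distances(dist, out / "distances.phy")
        io.write_newick(newick, out / "nj_tree.nwk")
        for name, ids in bias.items():
            io.write_geneset(ids, out / f"genes_{name}.txt")
    return stage


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute every stage in order; see PipelineConfig for knobs."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    seeds: dict[str, int] = {}
    per_tissue: dict[str, dict] = {}
    stages: dict[str, dict] = {}

    if config.counts_path is not None:
        if config.design_path is None:
            raise ValueError("counts_path requires design_path")
        counts = io.read_counts(config.counts_path)
        design = io.read_design(config.design_path)
        tissues = list(design.get("tissue", pd.Series(["tissue"])).unique())[:1]
        tissue_inputs = {tissues[0]: (counts, design, None)}
    else:
        tissue_inputs = {}
        for i, t in enumerate(config.tissues):
            seed_i = _tissue_seed(config.seed, i)
            seeds[f"simulate_{t}"] = seed_i
            params = simulate.SimulationParams(
                **config.simulation, tissue=t, seed=seed_i
            )
            design = simulate.simulate_design(params)
            counts, truth = simulate.simulate_counts(design, params)
            tissue_inputs[t] = (counts, design, truth)

    for t, (counts, design, truth) in tissue_inputs.items():
        tdir = out / t
        tdir.mkdir(parents=True, exist_ok=True)
        io.write_counts(counts, tdir / "counts_raw.tsv")
        io.write_design(design, tdir / "design.tsv")
        if truth is not None:
            truth.to_csv(tdir / "truth.tsv", sep="\t", index_label="gene")
        t1 = time.time()
        try:
            stages[t] = analyze_tissue(counts, design, config, out=tdir)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage failed for tissue {t!r}: {exc}") from exc
        per_tissue[t] = stages[t]["summary"]
        timings[t] = time.time() - t1

    cross: dict = {}
    names = list(stages)
    if len(names) >= 2:
        conc = factorial.cross_tissue_concordance(
            stages[names[0]]["results"],
            stages[names[1]]["results"],
            fdr=config.fdr,
            names=(names[0], names[1]),
        )
        cross = {"season_response": conc.counts}

    t1 = time.time()
    pg: dict = {}
    first = names[0]
    retained = list(stages[first]["results"]["gene"].unique())
    hap_seed = _tissue_seed(config.seed, 97)
    seeds["haplotypes"] = hap_seed
    haps = simulate.simulate_haplotypes(
        n_genes=len(retained), seed=hap_seed, **config.haplotypes
    )
    for h, gene in zip(haps, retained):
        h.gene_id = gene
    div = popgen.diversity_table(haps)
    div.to_csv(out / "diversity_stats.tsv", sep="\t")
    gxe_genes = [
        g
        for g in factorial.term_table(stages[first]["results"], "season:family")
        .query("q < @config.fdr")
        .index
    ]
    if gxe_genes:
        perm_seed = _tissue_seed(config.seed, 101)
        seeds["permutation"] = perm_seed
        comp = popgen.compare_gene_sets(
            div["tajimas_d"],
            gxe_genes,
            n_draws=config.permutation_draws,
            seed=perm_seed,
        )
        pg["gxe_vs_rest_tajimas_d"] = dataclasses.asdict(comp)
    pg["median_tajimas_d"] = float(div["tajimas_d"].median())
    pg["n_genes"] = int(len(div))
    timings["popgen"] = time.time() - t1
    timings["total"] = time.time() - t0

    report = AnalysisReport(
        config=config.to_dict(),
        seeds=seeds,
        per_tissue=per_tissue,
        cross_tissue=cross,
        popgen=pg,
        timings=timings,
    )
    report.to_json(out / "report.json")
    return report
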