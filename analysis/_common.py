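"""Shared cohort for the analysis scripts.

The reference experiment: two tissues (abdomen, thorax) sampled from the
same 72 females of seven full-sib families reared in two seasonal
environments crossed with two food treatments; 2,000 genes per tissue with
the reference effect fractions (46% season, 50% family, 5% food, 1% GxE).
Scripts either read the cohort from results/data (written by
01_simulate_cohort.py) or regenerate it deterministically.
"""

from pathlib import Path

from plastigene import SimulationParams, io, simulate_counts, simulate_design

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

COHORT_SEED = 20
N_GENES = 2000
TISSUES = ("abdomen", "thorax")


def cohort_params(tissue: str) -> SimulationParams:
    offset = TISSUES.index(tissue)
    return SimulationParams(n_genes=N_GENES, tissue=tissue, seed=COHORT_SEED + offset)


def load_cohort():
    """(counts, design, truth) per tissue, from disk if available."""
    out = {}
    for tissue in TISSUES:
        tdir = DATA / tissue
        if (tdir / "counts.tsv").exists():
            counts = io.read_counts(tdir / "counts.tsv")
            design = io.read_design(tdir / "design.tsv")
            import pandas as pd

            truth = pd.read_csv(tdir / "truth.tsv", sep="\t", index_col="gene")
        else:
            params = cohort_params(tissue)
            design = simulate_design(params)
            counts, truth = simulate_counts(design, params)
        out[tissue] = (counts, design, truth)
    return out
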