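"""Per-gene factorial inference for season, food, family and interactions.

Each gene's log-scale expression is fit with a fixed-effects linear model

    y ~ season + food + family + season:family + food:family
        + season:food + season:food:family

under sum-to-zero coding. Terms are tested with drop-one-term F tests
respecting marginality: the three-way interaction in the full model, each
two-way interaction in the model without the three-way, and each main
effect in the purely additive model. P-values are adjusted per term across
genes with the Benjamini-Hochberg step-up procedure.

Fold changes are log2 and follow the wet-over-dry (stress-over-control)
sign convention: a positive season logFC means higher expression in the
wet season. Terms involving family are summarized as the mean |log2 FC|
over the F-1 mutually orthogonal Helmert contrasts between families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import NormalizedMatrix

TERMS = (
    "season",
    "food",
    "family",
    "season:family",
    "food:family",
    "season:food",
    "season:food:family",
)

_FAMILY_TERMS = ("family", "season:family", "food:family", "season:food:family")


class AliasedDesignError(ValueError):
    """The design matrix is rank-deficient (confounded factors)."""


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, original order, NaN
    entries propagated unchanged."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return np.clip(q, 0.0, 1.0, out=q)


def _helmert_contrasts(k: int) -> np.ndarray:
    """(k-1) x k matrix of normalized Helmert contrasts.

    Contrast j compares level j+1 with the unweighted mean of levels
    0..j, scaled so the contrast value is that difference of means (a
    directly interpretable log2 fold change).
    """
    c = np.zeros((k - 1, k))
    for j in range(1, k):
        c[j - 1, :j] = -1.0 / j
        c[j - 1, j] = 1.0
    return c


def _design_blocks(design: pd.DataFrame) -> tuple[dict[str, np.ndarray], list[str]]:
    families = sorted(design["family"].unique())
    f_codes = pd.Categorical(design["family"], categories=families).codes
    season = np.where(design["season"].to_numpy() == "wet", 0.5, -0.5)
    food = np.where(design["food"].to_numpy() == "stress", 0.5, -0.5)
    helm = _helmert_contrasts(len(families)) if len(families) > 1 else np.zeros((0, 1))
    fam_cols = helm.T[f_codes]  # n x (F-1), sum-to-zero coding
    blocks = {
        "season": season[:, None],
        "food": food[:, None],
        "family": fam_cols,
        "season:food": (season * food)[:, None],
        "season:family": fam_cols * season[:, None],
        "food:family": fam_cols * food[:, None],
        "season:food:family": fam_cols * (season * food)[:, None],
    }
    return blocks, families


def _rss(Y: np.ndarray, cols: list[np.ndarray]) -> tuple[np.ndarray, int]:
    """Residual sum of squares of every gene (rows of Y) under the model
    spanned by an intercept plus the given column blocks."""
    n = Y.shape[1]
    X = np.column_stack([np.ones(n)] + cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise AliasedDesignError(
            "design matrix is rank-deficient; some factor combinations are confounded"
        )
    q, _ = np.linalg.qr(X)
    proj = Y @ q
    rss = np.einsum("ij,ij->i", Y, Y) - np.einsum("ij,ij->i", proj, proj)
    return np.maximum(rss, 0.0), X.shape[1]


def _to_log2(expr) -> tuple[pd.DataFrame, pd.Index]:
    if isinstance(expr, NormalizedMatrix):
        if expr.transform == "log10_cpm":
            data = expr.data / np.log10(2.0)
        elif expr.transform in ("log2_cpm",):
            data = expr.data
        else:
            raise ValueError(
                f"fit_factorial expects log10_cpm or log2_cpm input, got {expr.transform!r}"
            )
    else:
        data = pd.DataFrame(expr)
    return data, data.index


def _cell_means(Y: np.ndarray, design: pd.DataFrame, families: list[str]) -> np.ndarray:
    """Means per (family, season, food) cell: array (F, 2, 2, genes) with
    season index 0=dry,1=wet and food index 0=control,1=stress."""
    F = len(families)
    out = np.full((F, 2, 2, Y.shape[0]), np.nan)
    fam_arr = design["family"].to_numpy()
    season_arr = design["season"].to_numpy()
    food_arr = design["food"].to_numpy()
    for fi, fam in enumerate(families):
        for si, season in enumerate(("dry", "wet")):
            for oi, food in enumerate(("control", "stress")):
                mask = (fam_arr == fam) & (season_arr == season) & (food_arr == food)
                if mask.any():
                    out[fi, si, oi] = Y[:, mask].mean(axis=1)
    return out


def _contrast_mean_abs(per_family: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Mean (or max) |contrast value| over normalized Helmert contrasts.

    ``per_family`` is (F, genes): a per-family quantity (mean expression,
    season difference, ...) to be contrasted between families.
    """
    F = per_family.shape[0]
    if F < 2:
        return np.zeros(per_family.shape[1])
    helm = _helmert_contrasts(F)
    vals = np.abs(helm @ per_family)  # (F-1, genes)
    if mode == "max":
        return vals.max(axis=0)
    return vals.mean(axis=0)


def _term_logfcs(
    cm: np.ndarray, families: list[str], contrast_mode: str = "mean"
) -> dict[str, np.ndarray]:
    # cm: (F, season, food, genes); unweighted (least-squares) means across cells
    fam_mean = cm.mean(axis=(1, 2))  # (F, genes)
    season_diff = cm[:, 1, :, :].mean(axis=1) - cm[:, 0, :, :].mean(axis=1)
    food_diff = cm[:, :, 1, :].mean(axis=1) - cm[:, :, 0, :].mean(axis=1)
    threeway = (cm[:, 1, 1] - cm[:, 1, 0]) - (cm[:, 0, 1] - cm[:, 0, 0])
    m = cm.mean(axis=0)  # (season, food, genes)
    return {
        "season": season_diff.mean(axis=0),
        "food": food_diff.mean(axis=0),
        "season:food": (m[1, 1] - m[1, 0]) - (m[0, 1] - m[0, 0]),
        "family": _contrast_mean_abs(fam_mean, contrast_mode),
        "season:family": _contrast_mean_abs(season_diff, contrast_mode),
        "food:family": _contrast_mean_abs(food_diff, contrast_mode),
        "season:food:family": _contrast_mean_abs(threeway, contrast_mode),
    }


def fit_factorial(
    expr, design: pd.DataFrame, contrast_mode: str = "mean"
) -> pd.DataFrame:
    """Fit the full factorial model to every gene.

    Parameters
    ----------
    expr
        ``NormalizedMatrix`` with transform log10_cpm or log2_cpm, or a
        plain genes x samples DataFrame already on log2 scale.
    design
        Sample sheet with family/season/food columns, indexed by sample
        id, covering exactly the expression columns.
    contrast_mode
        "mean" (default) or "max": how per-contrast |log2 FC| values of
        family terms are aggregated.

    Returns a long DataFrame with one row per gene x term: columns
    gene, term, logfc, F, df_num, df_den, p, q.
    """
    data, genes = _to_log2(expr)
    design = design.loc[data.columns]
    Y = data.to_numpy(dtype=float)
    n = Y.shape[1]
    blocks, families = _design_blocks(design)

    additive = ["season", "food", "family"]
    twoway = additive + ["season:family", "food:family", "season:food"]
    full = twoway + ["season:food:family"]

    rss_cache: dict[tuple[str, ...], tuple[np.ndarray, int]] = {}

    def rss_of(terms: list[str]) -> tuple[np.ndarray, int]:
        key = tuple(terms)
        if key not in rss_cache:
            rss_cache[key] = _rss(Y, [blocks[t] for t in terms])
        return rss_cache[key]

    _, p_full = rss_of(full)
    if n - p_full < 1:
        raise ValueError("full-model residual df < 1; add replication")

    tests = {t: additive for t in additive}
    tests.update({t: twoway for t in twoway if t not in additive})
    tests["season:food:family"] = full

    total_var = Y.var(axis=1)
    degenerate = total_var <= 1e-24

    logfcs = _term_logfcs(_cell_means(Y, design, families), families, contrast_mode)

    rows = []
    for term in TERMS:
        model = tests[term]
        reduced = [t for t in model if t != term]
        rss_m, p_m = rss_of(model)
        rss_r, _ = rss_of(reduced)
        df_num = blocks[term].shape[1]
        df_den = n - p_m
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = ((rss_r - rss_m) / df_num) / (rss_m / df_den)
        f_stat = np.where(degenerate, 0.0, f_stat)
        pvals = stats.f.sf(f_stat, df_num, df_den)
        pvals = np.where(degenerate, 1.0, pvals)
        # a perfect fit (rss_m == 0) on a non-degenerate gene is maximal evidence
        pvals = np.where(np.isinf(f_stat), 0.0, pvals)
        lfc = np.where(degenerate, 0.0, logfcs[term])
        rows.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "term": term,
                    "logfc": lfc,
                    "F": f_stat,
                    "df_num": df_num,
                    "df_den": df_den,
                    "p": pvals,
                    "q": bh_fdr(pvals),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def term_table(results: pd.DataFrame, term: str) -> pd.DataFrame:
    """Per-gene slice of a fit_factorial result for one model term."""
    if term not in TERMS:
        raise ValueError(f"unknown term {term!r}")
    return results[results["term"] == term].set_index("gene")


def family_contrast_logfc(
    expr, design: pd.DataFrame, term: str = "family", mode: str = "mean"
) -> pd.Series:
    """Mean (or max) |log2 FC| over orthogonal family contrasts for one
    family-involving term, computed from cell means."""
    if term not in _FAMILY_TERMS:
        raise ValueError(f"term must be one of {_FAMILY_TERMS}")
    data, genes = _to_log2(expr)
    design = design.loc[data.columns]
    _, families = _design_blocks(design)
    cm = _cell_means(data.to_numpy(dtype=float), design, families)
    if np.isnan(cm).any():
        raise ValueError("some family x season x food cells are empty")
    vals = _term_logfcs(cm, families, mode)[term]
    return pd.Series(vals, index=genes, name=f"{term}_mean_abs_log2fc")


def classify_season_bias(
    results: pd.DataFrame, fdr: float = 0.05, lfc_threshold: float | None = None
) -> dict[str, list[str]]:
    """Partition genes into wet-biased / dry-biased / unbiased by the
    season term (q < fdr, sign of log2 FC, optional |logFC| threshold)."""
    tab = term_table(results, "season")
    sig = tab["q"] < fdr
    if lfc_threshold is not None:
        sig &= tab["logfc"].abs() > lfc_threshold
    wet = sig & (tab["logfc"] > 0)
    dry = sig & (tab["logfc"] < 0)
    return {
        "wet_biased": list(tab.index[wet]),
        "dry_biased": list(tab.index[dry]),
        "unbiased": list(tab.index[~(wet | dry)]),
    }


@dataclass
class ConcordanceResult:
    categories: pd.Series
    counts: dict[str, int]


def cross_tissue_concordance(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    fdr: float = 0.05,
    names: tuple[str, str] = ("abdomen", "thorax"),
) -> ConcordanceResult:
    """Classify shared genes by agreement of their seasonal response in
    two tissues: concordant (significant in both, same sign), opposite,
    significant in exactly one, or neither."""
    ta = term_table(results_a, "season")
    tb = term_table(results_b, "season")
    shared = ta.index.intersection(tb.index)
    if shared.empty:
        raise ValueError("no shared genes between the two tissues")
    ta, tb = ta.loc[shared], tb.loc[shared]
    sig_a, sig_b = ta["q"] < fdr, tb["q"] < fdr
    same_sign = np.sign(ta["logfc"]) == np.sign(tb["logfc"])
    cat = pd.Series("neither", index=shared, name="concordance")
    cat[sig_a & ~sig_b] = f"{names[0]}_only"
    cat[~sig_a & sig_b] = f"{names[1]}_only"
    cat[sig_a & sig_b & same_sign] = "concordant"
    cat[sig_a & sig_b & ~same_sign] = "opposite"
    counts = cat.value_counts().to_dict()
    for key in ("concordant", "opposite", f"{names[0]}_only", f"{names[1]}_only", "neither"):
        counts.setdefault(key, 0)
    return ConcordanceResult(categories=cat, counts=counts)


@dataclass
class PairedComparison:
    statistic: float
    p: float
    n: int
    median_pct_difference: float
    mean_pct_difference: float


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank: exact distribution for small
    samples without zeros/ties, otherwise normal approximation with Pratt
    zero handling."""
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    n = d.size
    no_zeros = not np.any(d == 0)
    no_ties = len(np.unique(np.abs(d[d != 0]))) == np.count_nonzero(d)
    if n <= 25 and no_zeros and no_ties:
        res = stats.wilcoxon(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            a, b, alternative="two-sided", zero_method="pratt", method="approx"
        )
    return float(res.statistic), float(res.pvalue)


def compare_fc_magnitudes(values_a: pd.Series, values_b: pd.Series) -> PairedComparison:
    """Paired comparison of two per-gene |log2 FC| vectors (e.g. the GxE
    term against the family main effect).

    Reports the signed-rank test over genes, the median per-gene relative
    difference 100*(a-b)/b, and the mean-based percent difference
    100*(mean(a)-mean(b))/mean(b).
    """
    a, b = values_a.align(values_b, join="inner")
    ok = a.notna() & b.notna()
    a, b = a[ok].to_numpy(float), b[ok].to_numpy(float)
    if a.size == 0:
        raise ValueError("no overlapping genes")
    stat, p = _paired_wilcoxon(a, b)
    nonzero_b = b != 0
    median_pct = (
        float(np.median((a[nonzero_b] - b[nonzero_b]) / b[nonzero_b]) * 100)
        if nonzero_b.any()
        else 0.0
    )
    mean_pct = (
        float((a.mean() - b.mean()) / b.mean() * 100) if b.mean() != 0 else 0.0
    )
    return PairedComparison(
        statistic=stat,
        p=p,
        n=int(a.size),
        median_pct_difference=median_pct,
        mean_pct_difference=mean_pct,
    )
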