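"""Reaction norms, cross-environment genetic correlations, PCA with
per-component factorial ANOVA, and expression distance matrices.

These are the complementary quantifications of genetic variation for
plasticity: per-family seasonal reaction norms (intercept = dry-season
expression, slope = wet-minus-dry change) whose across-family variability
separates genetic variation in average expression from genetic variation
in plasticity; correlations of family means across the two seasonal
environments; and an unsupervised view (PCA scores tested against season,
family and their interaction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .factorial import PairedComparison, _paired_wilcoxon, bh_fdr
from .normalize import NormalizedMatrix

_CV_GUARD = 1e-8


def _expr_frame(expr) -> pd.DataFrame:
    return expr.data if isinstance(expr, NormalizedMatrix) else pd.DataFrame(expr)


@dataclass
class ReactionNormTable:
    """Per-gene x family reaction norm parameters and their across-family
    variability.

    ``intercept``/``slope``: genes x families frames. With season coded
    dry=0, wet=1 the OLS intercept is the family's dry-season mean and the
    slope its wet-minus-dry mean difference, exactly. ``summary`` holds
    per-gene across-family SD and CV (SD/|mean|) of both parameters; CV is
    NaN-flagged when |mean| < 1e-8 (common for Z-scaled expression).
    """

    intercept: pd.DataFrame
    slope: pd.DataFrame
    summary: pd.DataFrame
    families: list[str] = field(default_factory=list)
    dropped_families: list[str] = field(default_factory=list)


def reaction_norms(expr, design: pd.DataFrame) -> ReactionNormTable:
    """Family-wise OLS of expression on season (dry=0, wet=1) per gene."""
    data = _expr_frame(expr)
    design = design.loc[data.columns]
    fams = sorted(design["family"].unique())
    Y = data.to_numpy(float)
    season = design["season"].to_numpy()
    fam_arr = design["family"].to_numpy()

    used, dropped = [], []
    intercepts, slopes = [], []
    for fam in fams:
        dry = (fam_arr == fam) & (season == "dry")
        wet = (fam_arr == fam) & (season == "wet")
        if not dry.any() or not wet.any():
            dropped.append(fam)
            continue
        used.append(fam)
        dry_mean = Y[:, dry].mean(axis=1)
        wet_mean = Y[:, wet].mean(axis=1)
        intercepts.append(dry_mean)
        slopes.append(wet_mean - dry_mean)
    if dropped:
        warnings.warn(f"families missing a season were dropped: {dropped}")
    if len(used) < 2:
        raise ValueError("need >= 2 families observed in both seasons")

    inter = pd.DataFrame(np.column_stack(intercepts), index=data.index, columns=used)
    slope = pd.DataFrame(np.column_stack(slopes), index=data.index, columns=used)

    def _variability(frame: pd.DataFrame, name: str) -> pd.DataFrame:
        mean = frame.mean(axis=1)
        sd = frame.std(axis=1, ddof=1)
        cv = sd / mean.abs().where(mean.abs() >= _CV_GUARD)
        return pd.DataFrame(
            {f"mean_{name}": mean, f"sd_{name}": sd, f"cv_{name}": cv}
        )

    summary = pd.concat(
        [_variability(inter, "intercept"), _variability(slope, "slope")], axis=1
    )
    return ReactionNormTable(
        intercept=inter, slope=slope, summary=summary,
        families=used, dropped_families=dropped,
    )


def compare_slope_intercept(
    rn: ReactionNormTable, measure: str = "sd"
) -> PairedComparison:
    """Paired signed-rank test of across-family slope variability against
    intercept variability over genes.

    ``median_pct_difference`` is the median of 100*(slope_v - int_v)/int_v,
    so a value of -57 means slope variability is 57% lower.
    """
    if measure not in ("sd", "cv"):
        raise ValueError("measure must be 'sd' or 'cv'")
    s = rn.summary[f"{measure}_slope"]
    i = rn.summary[f"{measure}_intercept"]
    ok = s.notna() & i.notna()
    s, i = s[ok].to_numpy(float), i[ok].to_numpy(float)
    if s.size < 6:
        raise ValueError("need >= 6 genes with defined variability")
    stat, p = _paired_wilcoxon(s, i)
    nz = i != 0
    median_pct = float(np.median((s[nz] - i[nz]) / i[nz]) * 100) if nz.any() else 0.0
    mean_pct = float((s.mean() - i.mean()) / i.mean() * 100) if i.mean() != 0 else 0.0
    return PairedComparison(
        statistic=stat, p=p, n=int(s.size),
        median_pct_difference=median_pct, mean_pct_difference=mean_pct,
    )


@dataclass
class CrossEnvCorr:
    """Per-gene correlation, across families, of family-mean expression in
    the wet versus the dry season."""

    rho: pd.Series
    method: str
    n_families: int

    @property
    def median(self) -> float:
        return float(self.rho.median())


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def cross_env_correlation(
    expr, design: pd.DataFrame, method: str = "pearson"
) -> CrossEnvCorr:
    """Cross-environment genetic correlation per gene.

    Family means are taken within each season (pooling food treatments and
    replicates), then correlated across families. Genes whose family means
    are constant in either season are NaN-flagged and excluded from the
    median.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    data = _expr_frame(expr)
    design = design.loc[data.columns]
    fams = sorted(design["family"].unique())
    if len(fams) < 3:
        raise ValueError("need >= 3 families")
    Y = data.to_numpy(float)
    season = design["season"].to_numpy()
    fam_arr = design["family"].to_numpy()
    wet = np.column_stack(
        [Y[:, (fam_arr == f) & (season == "wet")].mean(axis=1) for f in fams]
    )
    dry = np.column_stack(
        [Y[:, (fam_arr == f) & (season == "dry")].mean(axis=1) for f in fams]
    )
    if method == "spearman":
        wet = stats.rankdata(wet, axis=1)
        dry = stats.rankdata(dry, axis=1)
    rho = _rowwise_pearson(wet, dry)
    return CrossEnvCorr(
        rho=pd.Series(rho, index=data.index, name=f"rho_{method}"),
        method=method, n_families=len(fams),
    )


@dataclass
class PCDecomposition:
    scores: pd.DataFrame       # samples x k
    loadings: pd.DataFrame     # genes x k
    variance_fraction: np.ndarray
    center: pd.Series


def pca(expr, n_components: int | None = None) -> PCDecomposition:
    """SVD-based principal components of samples in gene space.

    Samples are observations and genes variables; variables are centered
    but not scaled. The sign of each component is fixed so the gene with
    the largest |loading| loads positively.
    """
    data = _expr_frame(expr)
    if data.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    X = data.to_numpy(float).T  # samples x genes
    center = X.mean(axis=0)
    Xc = X - center
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var_frac = s**2 / (s**2).sum() if (s**2).sum() > 0 else np.zeros_like(s)
    k = len(s) if n_components is None else min(n_components, len(s))
    u, s, vt, var_frac = u[:, :k], s[:k], vt[:k], var_frac[:k]
    # deterministic sign: largest-|loading| gene positive
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    names = [f"PC{j + 1}" for j in range(k)]
    return PCDecomposition(
        scores=pd.DataFrame(u * s, index=data.columns, columns=names),
        loadings=pd.DataFrame(vt.T, index=data.index, columns=names),
        variance_fraction=var_frac,
        center=pd.Series(center, index=data.index),
    )


def default_n_pcs(pcs: PCDecomposition, min_cum_variance: float = 0.60) -> int:
    """Smallest number of leading PCs whose cumulative variance fraction
    reaches ``min_cum_variance``."""
    cum = np.cumsum(pcs.variance_fraction)
    idx = np.searchsorted(cum, min_cum_variance)
    return int(min(idx + 1, len(cum)))


def pc_anova(
    pcs: PCDecomposition, design: pd.DataFrame, n_pcs: int | None = None
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (season, family, interaction) on the
    scores of each tested PC; BH adjustment across PCs per term.

    Returns a long DataFrame: pc, term, F, p, q, variance_fraction.
    """
    if n_pcs is None:
        n_pcs = default_n_pcs(pcs)
    if n_pcs > pcs.scores.shape[1]:
        raise ValueError("n_pcs exceeds available components")
    design = design.loc[pcs.scores.index]
    rows = []
    for j in range(n_pcs):
        df = pd.DataFrame(
            {
                "score": pcs.scores.iloc[:, j].to_numpy(),
                "season": design["season"].to_numpy(),
                "family": design["family"].to_numpy(),
            }
        )
        fit = smf.ols(
            "score ~ C(season, Sum) * C(family, Sum)", data=df
        ).fit()
        tab = anova_lm(fit, typ=2)
        for term, label in (
            ("C(season, Sum)", "season"),
            ("C(family, Sum)", "family"),
            ("C(season, Sum):C(family, Sum)", "season:family"),
        ):
            rows.append(
                {
                    "pc": pcs.scores.columns[j],
                    "term": label,
                    "F": float(tab.loc[term, "F"]),
                    "p": float(tab.loc[term, "PR(>F)"]),
                    "variance_fraction": float(pcs.variance_fraction[j]),
                }
            )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for label in out["term"].unique():
        mask = out["term"] == label
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out


def euclidean_distances(expr) -> pd.DataFrame:
    """Symmetric sample x sample Euclidean distance matrix in gene space."""
    data = _expr_frame(expr)
    d = squareform(pdist(data.to_numpy(float).T, metric="euclidean"))
    return pd.DataFrame(d, index=data.columns, columns=data.columns)
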