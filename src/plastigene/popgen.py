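"""Per-gene nucleotide diversity statistics and gene-repertoire tests.

Implements pairwise nucleotide diversity (pi), Watterson's theta (S/a1)
and Tajima's D with the standard constants:

    a1 = sum_{i=1}^{n-1} 1/i          a2 = sum 1/i^2
    b1 = (n+1)/(3(n-1))               b2 = 2(n^2+n+3)/(9n(n-1))
    c1 = b1 - 1/a1                    c2 = b2 - (n+2)/(a1 n) + a2/a1^2
    e1 = c1/a1                        e2 = c2/(a1^2 + a2)
    D  = (pi - S/a1) / sqrt(e1 S + e2 S (S-1))

Repertoire comparisons follow the two-route convention: a two-sided
Mann-Whitney U test of the test set against its complement, plus a
size-matched permutation null (random draws of |test| genes from the
background) when set sizes are very unbalanced. The 2x2 contingency test
uses the Yates-corrected chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import HaplotypeMatrix


def tajima_constants(n: int) -> dict[str, float]:
    """The sample-size constants of Tajima's D for n haplotypes."""
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


@dataclass
class DiversityStats:
    """Diversity summary for one gene.

    ``pi`` and ``theta_w`` are totals over the gene; the ``*_per_site``
    fields divide by the coding-sequence length. ``tajimas_d`` is NaN
    when undefined (S = 0, or n < 4 where the variance normalization is
    unreliable).
    """

    gene_id: str
    n: int
    S: int
    pi: float
    theta_w: float
    pi_per_site: float
    theta_w_per_site: float
    tajimas_d: float


def diversity_stats(h: HaplotypeMatrix) -> DiversityStats:
    """pi, Watterson's theta and Tajima's D for one haplotype matrix.

    pi is the average pairwise difference count over all n(n-1)/2
    haplotype pairs, computed per site from the allele counts:
    site with k derived copies contributes 2 k (n-k) / (n (n-1)).
    """
    n = h.n_haplotypes
    k = h.sites.sum(axis=0).astype(float)
    S = int(h.n_sites)
    pairs = n * (n - 1) / 2.0
    pi = float(np.sum(k * (n - k)) / pairs)
    const = tajima_constants(n)
    theta_w = S / const["a1"]
    if S == 0 or n < 4:
        d = float("nan")
    else:
        var = const["e1"] * S + const["e2"] * S * (S - 1)
        d = float((pi - theta_w) / np.sqrt(var))
    L = float(h.sequence_length)
    return DiversityStats(
        gene_id=h.gene_id, n=n, S=S, pi=pi, theta_w=theta_w,
        pi_per_site=pi / L, theta_w_per_site=theta_w / L, tajimas_d=d,
    )


def diversity_table(haplotypes) -> pd.DataFrame:
    """Diversity statistics for a collection of genes, indexed by gene id."""
    rows = [diversity_stats(h).__dict__ for h in haplotypes]
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class GeneSetComparison:
    n_test: int
    n_background: int
    median_test: float
    median_rest: float
    mannwhitney_u: float
    mannwhitney_p: float
    permutation_p: float
    n_draws: int
    seed: int


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration for small samples
    without ties, tie-corrected normal approximation otherwise."""
    small = min(x.size, y.size) <= 8
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if small and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_gene_sets(
    values: pd.Series,
    test_ids,
    background_ids=None,
    n_draws: int = 1000,
    seed: int = 0,
) -> GeneSetComparison:
    """Compare a gene set's statistic against the rest of the transcriptome.

    Two-sided Mann-Whitney U of the test set versus its complement, plus a
    size-matched permutation null: ``n_draws`` random without-replacement
    draws of |test| genes from the background, with

        p_perm = min(1, 2 * (1 + #{more extreme tail}) / (n_draws + 1))

    using the median as the draw statistic. NaN values are excluded.
    """
    values = values.dropna()
    if background_ids is None:
        background_ids = list(values.index)
    # sorted ids make the permutation draws invariant to input gene order
    test_ids = sorted(g for g in set(test_ids) if g in values.index)
    background_ids = sorted(g for g in set(background_ids) if g in values.index)
    if not test_ids:
        raise ValueError("test set is empty (after NaN removal)")
    if len(test_ids) > len(background_ids):
        raise ValueError("test set larger than background")
    test_vals = values.loc[test_ids].to_numpy(float)
    rest_ids = [g for g in background_ids if g not in set(test_ids)]
    rest_vals = values.loc[rest_ids].to_numpy(float)
    if rest_vals.size == 0:
        raise ValueError("background contains only the test set")
    u, p_mw = _mannwhitney(test_vals, rest_vals)

    rng = np.random.default_rng(seed)
    bg = values.loc[background_ids].to_numpy(float)
    k = len(test_ids)
    idx = np.argsort(rng.random((n_draws, bg.size)), axis=1)[:, :k]
    draw_medians = np.median(bg[idx], axis=1)
    obs = float(np.median(test_vals))
    n_ge = int(np.sum(draw_medians >= obs))
    n_le = int(np.sum(draw_medians <= obs))
    p_perm = min(1.0, 2.0 * (1 + min(n_ge, n_le)) / (n_draws + 1))

    return GeneSetComparison(
        n_test=k, n_background=len(background_ids),
        median_test=obs, median_rest=float(np.median(rest_vals)),
        mannwhitney_u=u, mannwhitney_p=p_mw,
        permutation_p=p_perm, n_draws=n_draws, seed=seed,
    )


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi2: float
    p: float
    df: int
    row_proportions: tuple[float, float]


def contingency_chi2(table) -> ContingencyResult:
    """Yates-corrected chi-square test of independence on a 2x2 table.

    chi2 = N (|ad - bc| - N/2)^2 / (r1 r2 c1 c2), with the continuity
    correction floored at zero; p from the upper tail of chi-square(1).
    ``row_proportions`` gives each row's first-column fraction as a
    percentage (one decimal's worth of precision is meaningful for the
    usual repertoire tables).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cells must be non-negative")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("all margins must be > 0")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    chi2 = float(n * num**2 / (r1 * r2 * c1 * c2))
    p = float(stats.chi2.sf(chi2, df=1))
    return ContingencyResult(
        table=t.astype(int), chi2=chi2, p=p, df=1,
        row_proportions=(float(a / r1 * 100), float(c / r2 * 100)),
    )
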