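"""Low-expression filtering and TMM/CPM normalization.

Implements the trimmed-mean-of-M-values (TMM) scaling of Robinson &
Oshlack: per-sample factors from doubly trimmed, precision-weighted log2
expression ratios against a reference sample, rescaled to geometric mean
one. CPM divides counts by the effective library size (library size x TMM
factor) times 1e6. Downstream transforms are log10(CPM+1), log2(CPM+1)
and a per-gene Z transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class EmptyResultError(ValueError):
    """A filtering step removed everything."""


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D genes x samples frame")
    if (counts.values < 0).any():
        gi, si = np.argwhere(counts.values < 0)[0]
        raise ValueError(
            f"negative count at gene {counts.index[gi]!r}, sample {counts.columns[si]!r}"
        )
    if not counts.index.is_unique or not counts.columns.is_unique:
        raise ValueError("gene and sample ids must be unique")


@dataclass
class FilterResult:
    counts: pd.DataFrame
    kept: list[str]
    removed: list[str]


def filter_low_expression(
    counts: pd.DataFrame, min_samples: int = 3, min_mean_cpm: float = 0.25
) -> FilterResult:
    """Drop genes expressed in fewer than ``min_samples`` samples or with
    mean CPM below ``min_mean_cpm``.

    "Expressed" means count > 0. CPM here uses the pre-filter library
    sizes (raw column sums), so the rule does not depend on which other
    genes are removed, and applying the filter twice is a no-op.
    """
    validate_counts(counts)
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(counts.columns[lib <= 0])
        raise ValueError(f"samples with zero library size: {bad}")
    n_expressed = (counts > 0).sum(axis=1)
    mean_cpm = (counts / lib * 1e6).mean(axis=1)
    keep = (n_expressed >= min_samples) & (mean_cpm >= min_mean_cpm)
    if not keep.any():
        raise EmptyResultError("low-expression filter removed every gene")
    return FilterResult(
        counts=counts.loc[keep],
        kept=list(counts.index[keep]),
        removed=list(counts.index[~keep]),
    )


def _quantile_reference(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> int:
    """Index of the sample whose upper-quartile scaled count is closest to
    the across-sample mean (the standard TMM reference choice)."""
    uq = np.quantile(counts / lib[None, :], p, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_logfc: float,
    trim_abs: float,
) -> float:
    """Unscaled TMM factor of one library against the reference.

    M = log2((obs/N_o)/(ref/N_r)) and A = mean log2 abundance are computed
    over genes expressed in both libraries; genes in the upper/lower
    ``trim_logfc`` tail of M or ``trim_abs`` tail of A are trimmed, and the
    surviving M values are averaged weighted by the inverse of the
    binomial approximate variance v = (N_o-y_o)/(N_o y_o) + (N_r-y_r)/(N_r y_r).
    """
    both = (obs > 0) & (ref > 0)
    if not both.any():
        warnings.warn("no genes co-expressed with the TMM reference; factor set to 1")
        return 1.0
    o = obs[both].astype(float)
    r = ref[both].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = np.floor(n * trim_logfc) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_abs) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame, trim_logfc: float = 0.30, trim_abs: float = 0.05
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1."""
    validate_counts(counts)
    if counts.shape[1] < 2:
        return pd.Series(1.0, index=counts.columns, name="tmm_factor")
    x = counts.values.astype(float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    ref_i = _quantile_reference(x, lib)
    ref = x[:, ref_i]
    f = np.array(
        [
            _tmm_pair(x[:, j], ref, lib[j], lib[ref_i], trim_logfc, trim_abs)
            for j in range(x.shape[1])
        ]
    )
    f /= np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


@dataclass
class NormalizedMatrix:
    """Expression matrix plus its normalization provenance.

    ``transform`` is one of cpm, log10_cpm, log2_cpm, z_per_gene.
    ``constant_genes`` lists genes whose row was constant before a Z
    transform (mapped to all-zeros).
    """

    data: pd.DataFrame
    transform: str
    tmm_factors: pd.Series | None = None
    constant_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> NormalizedMatrix:
    """Counts per million over the effective library size.

    value = count / (library_size * tmm_factor) * 1e6. With all factors 1
    each column sums to exactly 1e6.
    """
    validate_counts(counts)
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns, name="tmm_factor")
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        raise ValueError("TMM factors do not cover all samples")
    eff = lib * factors
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    return NormalizedMatrix(
        data=counts / eff * 1e6, transform="cpm", tmm_factors=factors
    )


def transform(norm: NormalizedMatrix, mode: str, log_offset: float = 1.0) -> NormalizedMatrix:
    """Apply a downstream transform to a CPM matrix.

    ``log10_cpm``/``log2_cpm``: log(CPM + log_offset); the +1 default maps
    zero counts to 0. ``z_per_gene``: per-gene (x - mean)/SD across all
    samples (sample SD, ddof=1); constant genes become all-zero rows and
    are recorded in ``constant_genes``.
    """
    if norm.transform != "cpm":
        raise ValueError(f"expected a cpm matrix, got {norm.transform!r}")
    x = norm.data
    if mode == "log10_cpm":
        out = np.log10(x + log_offset)
        return NormalizedMatrix(out, "log10_cpm", norm.tmm_factors)
    if mode == "log2_cpm":
        out = np.log2(x + log_offset)
        return NormalizedMatrix(out, "log2_cpm", norm.tmm_factors)
    if mode == "z_per_gene":
        mu = x.mean(axis=1)
        sd = x.std(axis=1, ddof=1)
        constant = sd <= 0
        safe_sd = sd.where(~constant, 1.0)
        z = x.sub(mu, axis=0).div(safe_sd, axis=0)
        z.loc[constant] = 0.0
        return NormalizedMatrix(
            z, "z_per_gene", norm.tmm_factors, constant_genes=list(x.index[constant])
        )
    raise ValueError(f"unknown transform mode {mode!r}")
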