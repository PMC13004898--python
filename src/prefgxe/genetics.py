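"""Polygenic scores, ancestry principal components, and group descriptives.

A polygenic score is the weighted sum of a person's allele counts over the
scored SNPs, weights taken from external GWAS summary statistics; scores are
standardized within the analysed sample before entering any model.  Ancestry
principal components are the leading PCs of the column-standardized genotype
matrix and are used as covariates to absorb population-structure confounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypePanel",
    "ScoreVector",
    "AncestryPCs",
    "compute_pgs",
    "standardize",
    "ancestry_pcs",
    "group_gap",
    "pearson_ci",
]


@dataclass(frozen=True)
class GenotypePanel:
    """Allele-count matrix (individuals x SNPs) with per-SNP effect weights.

    Counts are expected in {0, 1, 2}; fractional dosages are accepted with a
    warning since the score formula is coding-agnostic.
    """

    genotypes: np.ndarray
    weights: np.ndarray
    snp_ids: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if g.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (individuals x SNPs)")
        if w.ndim != 1 or w.shape[0] != g.shape[1]:
            raise ValueError(
                f"weight length {w.shape} does not match SNP count {g.shape[1]}"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.nanmin(g, initial=0) < 0 or np.nanmax(g, initial=0) > 2:
            raise ValueError("allele counts must lie in [0, 2]")
        if not np.all(np.isin(g[np.isfinite(g)], (0.0, 1.0, 2.0))):
            warnings.warn("fractional genotype dosages detected; treating as dosages")
        object.__setattr__(self, "genotypes", g)
        object.__setattr__(self, "weights", w)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


@dataclass(frozen=True)
class ScoreVector:
    raw: np.ndarray
    standardized: np.ndarray


@dataclass(frozen=True)
class AncestryPCs:
    """Top-k PC coordinates; explained variance fractions are non-increasing."""

    coordinates: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray = field(repr=False, default=None)


def standardize(x: np.ndarray) -> np.ndarray:
    """(x - mean) / SD with the n-1 (sample) SD convention."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a zero-variance vector")
    return (x - x.mean()) / sd


def compute_pgs(panel: GenotypePanel) -> ScoreVector:
    """Per-individual weighted allele-count sum, raw and standardized."""
    if np.isnan(panel.genotypes).any():
        raise ValueError("genotype matrix contains missing values")
    raw = panel.genotypes @ panel.weights
    return ScoreVector(raw=raw, standardized=standardize(raw))


def ancestry_pcs(panel: GenotypePanel, k: int = 10) -> AncestryPCs:
    """Leading principal components of the column-standardized genotype matrix.

    Zero-variance SNP columns are dropped before the decomposition.  Each
    component's sign is fixed by making its largest-magnitude loading
    positive, so results are deterministic across SVD implementations.
    """
    g = panel.genotypes
    n = g.shape[0]
    sd = g.std(axis=0, ddof=1)
    keep = sd > 0
    if k >= min(n, int(keep.sum())):
        raise ValueError(
            f"k={k} must be smaller than min(n individuals, informative SNPs)"
            f" = {min(n, int(keep.sum()))}"
        )
    z = (g[:, keep] - g[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    coords = u[:, :k] * s[:k]
    loadings = vt[:k].T
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(k):
        top = np.argmax(np.abs(loadings[:, j]))
        if loadings[top, j] < 0:
            loadings[:, j] *= -1
            coords[:, j] *= -1
    var = s**2 / max(np.sum(s**2), np.finfo(float).tiny)
    return AncestryPCs(
        coordinates=coords,
        explained_variance_ratio=var[:k],
        loadings=loadings,
    )


def group_gap(scores: np.ndarray, group: np.ndarray) -> dict:
    """Two-sample comparison of a score across a binary grouping.

    Pooled-variance t-test (df = n-2), Cohen's d with the pooled SD, and a
    normal-approximation 95% CI on d.
    """
    scores = np.asarray(scores, dtype=float)
    group = np.asarray(group).astype(int)
    x0, x1 = scores[group == 0], scores[group == 1]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each group needs at least two members")
    n0, n1 = len(x0), len(x1)
    df = n0 + n1 - 2
    sp2 = ((n0 - 1) * x0.var(ddof=1) + (n1 - 1) * x1.var(ddof=1)) / df
    mean_diff = x0.mean() - x1.mean()
    se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    t = mean_diff / se if se > 0 else 0.0
    p = 2.0 * stats.t.sf(abs(t), df)
    d = mean_diff / np.sqrt(sp2) if sp2 > 0 else 0.0
    se_d = np.sqrt((n0 + n1) / (n0 * n1) + d**2 / (2.0 * df))
    return {
        "mean_diff": mean_diff,
        "t": t,
        "df": df,
        "p": p,
        "cohens_d": d,
        "ci": (d - 1.96 * se_d, d + 1.96 * se_d),
        "n": (n0, n1),
    }


def pearson_ci(x: np.ndarray, y: np.ndarray, conf: float = 0.95) -> dict:
    """Pearson correlation with t-based p-value and Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations for a correlation CI")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    z = np.arctanh(r)
    half = zcrit / np.sqrt(n - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    return {"r": float(r), "p": float(p), "ci": (float(lo), float(hi)), "df": n - 2, "n": n}


def format_correlation(res: dict) -> str:
    """Render a correlation result in the conventional r(df) = ..., CI style."""
    lo, hi = res["ci"]
    return (
        f"r({res['df']}) = {res['r']:.3f}, p = {res['p']:.3g}, "
        f"95% CI [{lo:.3f}, {hi:.3f}]"
    )
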