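"""Single-variant association on inbred-line means.

A deliberately simple GWA layer for panels of fully inbred, homozygous
lines: covariates are regressed out of the line means first, then each
biallelic site with minor allele frequency above the cutoff is tested by
comparing the adjusted means of the two homozygote classes (algebraically
identical to regressing on allele dosage). Relatedness corrections are out
of scope; arbitrary covariates (e.g. endosymbiont infection status or
inversion karyotypes) enter through the covariate matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "single_variant_tests",
    "dimorphism_phenotype",
    "nominal_candidates",
]


def _residualize(y: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    """Residuals of y on [1, C]; idempotent, constant columns are harmless."""
    n = len(y)
    if covariates is None or covariates.shape[1] == 0:
        return y - y.mean()
    X = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def single_variant_tests(
    line_means: pd.Series,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    maf_min: float = 0.05,
    min_class_size: int = 3,
) -> pd.DataFrame:
    """Per-site two-class tests of adjusted line means against allele.

    ``genotypes`` is a lines x sites 0/1 table (homozygous lines, one allele
    per line). Sites are kept when MAF is strictly greater than ``maf_min``
    and both allele classes contain at least ``min_class_size`` lines;
    excluded sites appear in the result with a ``skip_reason``. The p-value
    comes from the t distribution with n_lines - 2 degrees of freedom.
    """
    lines = line_means.index
    G = genotypes.loc[lines]
    y = _residualize(line_means.to_numpy(dtype=float), covariates)
    n = len(y)
    g = G.to_numpy(dtype=float)
    freq = g.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    n1 = g.sum(axis=0)
    n0 = n - n1

    # regression of adjusted means on allele, vectorized over sites
    gc = g - freq
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    sxy = gc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        syy = float((yc**2).sum())
        rss = syy - beta * sxy
        df = n - 2
        se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)

    keep = (maf > maf_min) & (n1 >= min_class_size) & (n0 >= min_class_size)
    reason = np.where(
        maf == 0, "monomorphic",
        np.where(maf <= maf_min, "maf<=min",
                 np.where(keep, "", "class<min")),
    )
    out = pd.DataFrame(
        {
            "site": genotypes.columns,
            "maf": maf,
            "n_ref": n0.astype(int),
            "n_alt": n1.astype(int),
            "effect": np.where(keep, beta, np.nan),
            "t": np.where(keep, t, np.nan),
            "p": np.where(keep, p, np.nan),
            "skip_reason": reason,
        }
    )
    return out


def dimorphism_phenotype(male_means: pd.Series, female_means: pd.Series) -> pd.Series:
    """Per-line sexual-dimorphism phenotype: male minus female line mean."""
    if set(male_means.index) != set(female_means.index):
        raise ValueError("male and female line sets must match")
    return (male_means - female_means.reindex(male_means.index)).rename("dimorphism")


def nominal_candidates(results: pd.DataFrame, threshold: float = 5e-5) -> pd.DataFrame:
    """Variants with p strictly below the nominal significance threshold."""
    if results.empty:
        raise ValueError("results table is empty")
    return results[results["p"] < threshold].copy()
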