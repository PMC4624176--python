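"""Extreme-QTL mapping statistics for pooled sequencing of phenotypic extremes.

The mapping design phenotypes a large outbred cohort, pools the most
sensitive and most resistant fraction, sequences each pool, and asks at every
segregating site whether the pooled allele frequencies diverge more than
drift and sequencing noise allow. The per-site test statistic is

    Z = (p_S - p_R) / sqrt( p0 (1 - p0) (2/n + 1/d_S + 1/d_R) )

where p_S, p_R are the estimated alt-allele frequencies in the sensitive and
resistant pools, p0 = (p_S + p_R)/2 is the pooled null frequency, n is the
number of chromosomes per pool (2 x pool size for autosomes) and d_S, d_R
the sequencing depths. The 2/n term is the binomial sampling variance of the
individuals that entered each pool; the 1/d terms are the read-sampling
variances. Z is treated as standard normal under H0: p_S = p_R, with
two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SiteTest",
    "segregating_sites",
    "z_test",
    "z_test_arrays",
    "bonferroni_threshold",
    "run_xqtl",
    "select_extremes",
]

_TINY = np.finfo(float).tiny  # p-value floor keeps -log10(p) finite


@dataclass(frozen=True)
class SiteTest:
    """Result of the pooled allele-frequency Z test at one site."""

    p_S: float
    p_R: float
    p_0: float
    n: float
    z: float
    p_value: float
    degenerate: bool = False


def segregating_sites(panel) -> pd.DataFrame:
    """Sites of the founder panel where both alleles are present.

    Returns the site table rows (original index preserved) at which at least
    one founder line carries the ref and one the alt allele.
    """
    if panel.n_sites == 0:
        raise ValueError("panel has no sites")
    counts = panel.genotypes.sum(axis=1)
    mask = (counts > 0) & (counts < panel.n_lines)
    return panel.sites.loc[mask]


def z_test_arrays(alt_S, d_S, alt_R, d_R, n) -> tuple[np.ndarray, ...]:
    """Vectorized Z test. Returns (p_S, p_R, p_0, z, p_value, degenerate)."""
    alt_S, d_S, alt_R, d_R = (np.asarray(x, dtype=float) for x in (alt_S, d_S, alt_R, d_R))
    n = np.asarray(n, dtype=float)
    if np.any(d_S <= 0) or np.any(d_R <= 0) or np.any(n <= 0):
        raise ValueError("depths and chromosomes-per-pool must be > 0")
    if np.any(alt_S > d_S) or np.any(alt_R > d_R) or np.any(alt_S < 0) or np.any(alt_R < 0):
        raise ValueError("alt counts must lie in [0, depth]")
    p_S = alt_S / d_S
    p_R = alt_R / d_R
    p_0 = (p_S + p_R) / 2.0
    degenerate = (p_0 <= 0.0) | (p_0 >= 1.0)
    var = p_0 * (1.0 - p_0) * (2.0 / n + 1.0 / d_S + 1.0 / d_R)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, (p_S - p_R) / np.sqrt(np.where(degenerate, 1.0, var)))
    p = np.where(degenerate, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    p = np.clip(p, _TINY, 1.0)
    return p_S, p_R, p_0, z, p, degenerate


def z_test(alt_S: int, d_S: int, alt_R: int, d_R: int, n: float) -> SiteTest:
    """Pooled allele-frequency Z test at a single site."""
    p_S, p_R, p_0, z, p, deg = (np.asarray(v).item() for v in z_test_arrays(
        alt_S, d_S, alt_R, d_R, n
    ))
    return SiteTest(p_S=p_S, p_R=p_R, p_0=p_0, n=float(n), z=z, p_value=p,
                    degenerate=bool(deg))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def run_xqtl(
    counts: pd.DataFrame,
    n,
    alpha: float = 0.05,
    nominal_threshold: float = 1e-5,
) -> pd.DataFrame:
    """Z tests and significance calls for a pool-counts table.

    ``counts`` needs columns ``chrom, pos, alt_S, d_S, alt_R, d_R``. ``n`` is
    the chromosomes per pool, either a scalar or a ``{chrom: n}`` mapping
    (e.g. halved on X for male pools). Two thresholds are reported: the
    Bonferroni family-wise threshold alpha/m and a fixed nominal threshold.
    """
    if counts.empty:
        raise ValueError("counts table is empty")
    n_arr = counts["chrom"].map(n).to_numpy() if isinstance(n, dict) else n
    p_S, p_R, p_0, z, p, deg = z_test_arrays(
        counts["alt_S"], counts["d_S"], counts["alt_R"], counts["d_R"], n_arr
    )
    out = counts.copy()
    out["p_S"], out["p_R"], out["p_0"] = p_S, p_R, p_0
    out["z"], out["p_value"], out["degenerate"] = z, p, deg
    m = len(out)
    thr = bonferroni_threshold(alpha, m)
    out["sig_bonferroni"] = out["p_value"] < thr
    out["sig_nominal"] = out["p_value"] < nominal_threshold
    out.attrs["bonferroni_threshold"] = thr
    out.attrs["n_tests"] = m
    return out


def select_extremes(
    elutions: pd.DataFrame,
    fraction: float,
    seed: int = 0,
    value: str = "minutes",
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the most sensitive and most resistant fraction of flies.

    Sensitive flies elute earliest (lowest minutes), resistant flies latest.
    Because elution times are discretized to whole-minute bins, ties at the
    boundary bin are broken by a seeded uniform draw so that pool sizes are
    exact. Returns integer positions into ``elutions``.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    n = len(elutions)
    k = int(fraction * n)
    if k < 1:
        raise ValueError(f"fraction {fraction} of {n} flies selects no fly")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(size=n)
    order = np.lexsort((jitter, elutions[value].to_numpy()))
    return order[:k], order[-k:]
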