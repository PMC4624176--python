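"""Quantitative genetics of inebriometer elution data.

Implements the variance partition of a balanced line x factor design with
replicate runs nested in cells,

    Y = mu + L + F + LxF + Rep(LxF) + eps,

where L (line) is random, F is sex or exposure, and Rep is the inebriometer
run. Method-of-moments estimates follow the expected mean squares of the
balanced nested-factorial ANOVA:

    sigma2_eps = MS_within
    sigma2_Rep = (MS_Rep - MS_within) / f
    sigma2_LxF = (MS_LxF - MS_Rep)  / (r f)
    sigma2_L   = (MS_L   - MS_LxF)  / (s r f)

with f flies per replicate, r replicates per cell and s factor levels.
Total genotypic variance is sigma2_G = sigma2_L + sigma2_LxF, phenotypic
variance sigma2_P = sigma2_G + sigma2_eps (replicate variance excluded by
default, optionally included), and broad-sense heritability
H2 = sigma2_G / sigma2_P. Negative component estimates are truncated to
zero after all components are solved, which keeps H2 in [0, 1].

Also provided: per-stratum control adjustment, per-line tolerance scores
T_i = (E2_i - E1_i) / (mean(E2) - mean(E1)), cross-condition correlations of
line means, and the factorial fixed-effect ANOVA used for mutant validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "adjust_to_control",
    "partition_variance",
    "varcomp_from_array",
    "rebalance",
    "tolerance_scores",
    "cross_correlations",
    "mutant_anova",
    "combined_sem",
]


@dataclass
class VarianceComponents:
    """Variance components and heritability from the balanced mixed model."""

    sigma2_L: float
    sigma2_LxF: float
    sigma2_Rep: float
    sigma2_eps: float
    F_label: str
    anova: pd.DataFrame = field(repr=False)
    include_rep_in_P: bool = False

    @property
    def sigma2_G(self) -> float:
        return self.sigma2_L + self.sigma2_LxF

    @property
    def sigma2_P(self) -> float:
        extra = self.sigma2_Rep if self.include_rep_in_P else 0.0
        return self.sigma2_G + extra + self.sigma2_eps

    @property
    def H2(self) -> float:
        return 0.0 if self.sigma2_P == 0 else self.sigma2_G / self.sigma2_P


def adjust_to_control(
    raw: pd.DataFrame,
    control_line_id: str,
    line: str = "id",
    date: str = "date",
    sex: str = "sex",
    value: str = "minutes",
) -> pd.DataFrame:
    """Express observations as deviations from the control-line mean.

    Each observation is replaced by its value minus the mean of the control
    line measured on the same date and in the same sex; control rows are
    dropped from the output. Raises if any (date, sex) stratum lacks control
    observations.
    """
    is_ctrl = raw[line] == control_line_id
    ctrl_means = raw[is_ctrl].groupby([date, sex])[value].mean()
    strata = raw[[date, sex]].drop_duplicates()
    missing = [
        tuple(row)
        for row in strata.itertuples(index=False)
        if tuple(row) not in ctrl_means.index
    ]
    if missing:
        raise ValueError(f"strata without control observations: {missing}")
    out = raw[~is_ctrl].copy()
    keys = pd.MultiIndex.from_frame(out[[date, sex]])
    out[value] = out[value].to_numpy() - ctrl_means.loc[keys].to_numpy()
    return out.reset_index(drop=True)


def _anova_from_array(arr: np.ndarray, f_label: str) -> pd.DataFrame:
    a, b, r, f = arr.shape
    grand = arr.mean()
    m_l = arr.mean(axis=(1, 2, 3))
    m_f = arr.mean(axis=(0, 2, 3))
    m_lf = arr.mean(axis=(2, 3))
    m_rep = arr.mean(axis=3)

    ss_l = b * r * f * ((m_l - grand) ** 2).sum()
    ss_f = a * r * f * ((m_f - grand) ** 2).sum()
    ss_lf = r * f * ((m_lf - m_l[:, None] - m_f[None, :] + grand) ** 2).sum()
    ss_rep = f * ((m_rep - m_lf[:, :, None]) ** 2).sum()
    ss_within = ((arr - m_rep[:, :, :, None]) ** 2).sum()

    df = np.array([a - 1, b - 1, (a - 1) * (b - 1), a * b * (r - 1), a * b * r * (f - 1)])
    ss = np.array([ss_l, ss_f, ss_lf, ss_rep, ss_within])
    ms = ss / df
    # mixed-model denominators: L and F against LxF, LxF against Rep, Rep
    # against the within-run residual
    denom = np.array([ms[2], ms[2], ms[3], ms[4], np.nan])
    denom_df = np.array([df[2], df[2], df[3], df[4], np.nan])
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = ms / denom
    pvals = [
        stats.f.sf(fv, dfn, dfd) if np.isfinite(fv) else np.nan
        for fv, dfn, dfd in zip(fstat, df, denom_df)
    ]
    return pd.DataFrame(
        {
            "term": ["L", f_label, f"Lx{f_label}", "Rep(cell)", "within"],
            "df": df,
            "SS": ss,
            "MS": ms,
            "F": fstat,
            "p": pvals,
        }
    )


def varcomp_from_array(
    arr: np.ndarray,
    f_label: str = "sex",
    include_rep_in_P: bool = False,
) -> VarianceComponents:
    """Variance components from a balanced (lines, levels, reps, flies) array."""
    a, b, r, f = arr.shape
    if min(a, r) < 2 or b < 2 or f < 2:
        raise ValueError("need >= 2 lines, >= 2 factor levels, >= 2 replicates, >= 2 flies")
    table = _anova_from_array(arr, f_label)
    ms = dict(zip(table["term"], table["MS"]))
    s2_eps = ms["within"]
    s2_rep = (ms["Rep(cell)"] - ms["within"]) / f
    s2_lxf = (ms[f"Lx{f_label}"] - ms["Rep(cell)"]) / (r * f)
    s2_l = (ms["L"] - ms[f"Lx{f_label}"]) / (b * r * f)
    # truncate negatives only after every component is solved
    s2_l, s2_lxf, s2_rep, s2_eps = (max(0.0, v) for v in (s2_l, s2_lxf, s2_rep, s2_eps))
    return VarianceComponents(
        sigma2_L=s2_l,
        sigma2_LxF=s2_lxf,
        sigma2_Rep=s2_rep,
        sigma2_eps=s2_eps,
        F_label=f_label,
        anova=table,
        include_rep_in_P=include_rep_in_P,
    )


def partition_variance(
    data: pd.DataFrame,
    crossed_factor: str = "sex",
    line: str = "line",
    replicate: str = "replicate",
    value: str = "minutes",
    include_rep_in_P: bool = False,
) -> VarianceComponents:
    """Partition elution variance for a balanced line x factor design.

    Requires a fully balanced table: equal replicates per (line, factor)
    cell and equal flies per replicate; otherwise raises with a pointer to
    :func:`rebalance`.
    """
    counts = data.groupby([line, crossed_factor, replicate], sort=True).size()
    lines = data[line].unique()
    levels = data[crossed_factor].unique()
    reps = data[replicate].unique()
    if len(counts) != len(lines) * len(levels) * len(reps) or counts.nunique() != 1:
        raise ValueError(
            "design is unbalanced (unequal replicates per cell or flies per "
            "replicate); use aipqtl.quantgen.rebalance to subsample to balance"
        )
    f = int(counts.iloc[0])
    ordered = data.sort_values([line, crossed_factor, replicate], kind="mergesort")
    arr = ordered[value].to_numpy().reshape(len(lines), len(levels), len(reps), f)
    return varcomp_from_array(arr, f_label=crossed_factor, include_rep_in_P=include_rep_in_P)


def rebalance(
    data: pd.DataFrame,
    seed: int = 0,
    line: str = "line",
    crossed_factor: str = "sex",
    replicate: str = "replicate",
) -> pd.DataFrame:
    """Seeded subsample restoring balance: equal flies in every replicate.

    Keeps min(cell replicate count) replicates per cell and min(flies per
    kept replicate) flies per replicate, sampled without replacement.
    """
    rng = np.random.default_rng(seed)
    rep_counts = data.groupby([line, crossed_factor])[replicate].nunique()
    n_reps = int(rep_counts.min())
    sizes = data.groupby([line, crossed_factor, replicate]).size()
    n_flies = int(sizes.min())
    parts = []
    for (_, _), cell in data.groupby([line, crossed_factor]):
        reps = sorted(cell[replicate].unique())
        keep = list(rng.choice(reps, size=n_reps, replace=False))
        for rep in keep:
            rows = cell[cell[replicate] == rep]
            idx = rng.choice(rows.index.to_numpy(), size=n_flies, replace=False)
            parts.append(data.loc[np.sort(idx)])
    return pd.concat(parts).reset_index(drop=True)


def tolerance_scores(line_means_E1: pd.Series, line_means_E2: pd.Series) -> pd.DataFrame:
    """Per-line tolerance T_i = (E2_i - E1_i) / (mean(E2) - mean(E1)).

    The denominators are unweighted averages of line means, so the mean of
    T over lines is exactly 1. Undefined when the population means of the
    two exposures coincide.
    """
    e1 = pd.Series(line_means_E1)
    e2 = pd.Series(line_means_E2)
    if set(e1.index) != set(e2.index):
        raise ValueError("E1 and E2 must cover the same lines")
    e2 = e2.reindex(e1.index)
    denom = e2.mean() - e1.mean()
    if denom == 0:
        raise ValueError("tolerance undefined: population means of E1 and E2 are equal")
    return pd.DataFrame({"E1": e1, "E2": e2, "T": (e2 - e1) / denom})


def cross_correlations(line_means: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of line means across sex/exposure conditions.

    ``line_means`` is a lines x conditions table (e.g. columns F_E1, M_E1,
    F_E2, M_E2). Conditions with zero variance yield NaN and are reported in
    the result's ``attrs['degenerate']``.
    """
    if len(line_means) < 3:
        raise ValueError("need >= 3 lines")
    degenerate = [c for c in line_means.columns if line_means[c].nunique() <= 1]
    corr = line_means.corr(method="pearson")
    if degenerate:
        corr.loc[degenerate, :] = np.nan
        corr.loc[:, degenerate] = np.nan
    corr.attrs["degenerate"] = degenerate
    return corr


def combined_sem(se_mutant: float, se_control: float) -> float:
    """Pooled standard error sqrt(SEm^2 + SEc^2) of a mutant-control contrast."""
    if se_mutant < 0 or se_control < 0:
        raise ValueError("standard errors must be >= 0")
    return math.hypot(se_mutant, se_control)


def mutant_anova(
    data: pd.DataFrame,
    genotype: str = "genotype",
    sex: str = "sex",
    exposure: str = "exposure",
    replicate: str = "replicate",
    value: str = "minutes",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Factorial fixed-effect ANOVA for a mutant-vs-control elution assay.

    Model: Y = mu + G + S + E + GxS + GxE + SxE + GxSxE + Rep(GxSxE) + eps.
    Replicate runs nested in cells form the error stratum for all factorial
    terms; Rep itself is tested against the within-run residual. Returns the
    ANOVA table and a per sex/exposure effect summary (mutant mean - control
    mean with the pooled SEM of the two groups).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data.rename(
        columns={genotype: "G", sex: "S", exposure: "E", replicate: "Rep", value: "y"}
    )
    for col, expect in (("G", None), ("S", None), ("E", None)):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col} needs both levels present")
    cells = df.groupby(["G", "S", "E"]).size()
    if len(cells) != df["G"].nunique() * df["S"].nunique() * df["E"].nunique():
        raise ValueError("missing genotype x sex x exposure cell")

    model = smf.ols("y ~ C(G) * C(S) * C(E) + C(Rep):C(G):C(S):C(E)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    rep_term = "C(Rep):C(G):C(S):C(E)"
    ms = table["sum_sq"] / table["df"]
    ms_rep, df_rep = ms[rep_term], table.loc[rep_term, "df"]
    ms_res, df_res = ms["Residual"], table.loc["Residual", "df"]

    rows = []
    factorial = [t for t in table.index if t not in (rep_term, "Residual")]
    for term in factorial:
        if ms_rep > 0:
            fv = ms[term] / ms_rep
            p = stats.f.sf(fv, table.loc[term, "df"], df_rep)
        else:  # noise-free degenerate stratum: no evidence of an effect
            fv, p = (np.nan, 1.0) if ms[term] == 0 else (np.inf, 0.0)
        rows.append((term, table.loc[term, "df"], table.loc[term, "sum_sq"], ms[term], fv, p))
    f_rep = ms_rep / ms_res if ms_res > 0 else np.nan
    p_rep = stats.f.sf(f_rep, df_rep, df_res) if np.isfinite(f_rep) else np.nan
    rows.append((rep_term, df_rep, table.loc[rep_term, "sum_sq"], ms_rep, f_rep, p_rep))
    rows.append(("Residual", df_res, table.loc["Residual", "sum_sq"], ms_res, np.nan, np.nan))
    anova = pd.DataFrame(rows, columns=["term", "df", "SS", "MS", "F", "p"])

    genos = sorted(df["G"].unique())
    control = [g for g in genos if str(g).lower().startswith("control")]
    ctrl = control[0] if control else genos[0]
    mut = [g for g in genos if g != ctrl][0]
    summaries = []
    for (s, e), cell in df.groupby(["S", "E"]):
        gm = cell[cell["G"] == mut]["y"]
        gc = cell[cell["G"] == ctrl]["y"]
        sem_m = gm.std(ddof=1) / math.sqrt(len(gm)) if len(gm) > 1 else 0.0
        sem_c = gc.std(ddof=1) / math.sqrt(len(gc)) if len(gc) > 1 else 0.0
        summaries.append((s, e, gm.mean() - gc.mean(), combined_sem(sem_m, sem_c)))
    effects = pd.DataFrame(summaries, columns=["sex", "exposure", "effect", "sem"])
    return anova, effects
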