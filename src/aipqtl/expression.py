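"""qPCR expression comparison between sensitive and resistant pools.

Raw cycle-threshold (Ct) values are normalized to a reference gene within
each (sex, pool, biological replicate) stratum: technical replicates are
averaged first, then dCt = Ct(gene) - Ct(reference). Lower dCt means higher
relative expression. Pools are compared per gene and sex by Student's
two-sample t-test on dCt across biological replicates, and the fraction of
transcripts with altered expression among candidates versus randomly chosen
genes is compared with a one-sided Fisher exact test (the directional claim
being that candidates are altered more often).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "delta_ct",
    "pool_ttest",
    "pool_ttest_all",
    "altered_proportion_test",
]


def delta_ct(table: pd.DataFrame, reference: str = "Gpdh") -> pd.DataFrame:
    """Reference-normalized dCt per (gene, sex, pool, biological replicate).

    Technical replicates are averaged before normalization; the reference
    gene must be present in every stratum that contains a target gene.
    """
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    means = (
        table.groupby(["gene", "sex", "pool", "bio_rep"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref = means[means["gene"] == reference].set_index(["sex", "pool", "bio_rep"])["ct"]
    targets = means[means["gene"] != reference].copy()
    keys = pd.MultiIndex.from_frame(targets[["sex", "pool", "bio_rep"]])
    missing = sorted(set(keys) - set(ref.index))
    if missing:
        raise ValueError(f"reference gene {reference!r} missing in strata: {missing}")
    targets["delta_ct"] = targets["ct"].to_numpy() - ref.loc[keys].to_numpy()
    return targets[["gene", "sex", "pool", "bio_rep", "delta_ct"]].reset_index(drop=True)


@dataclass(frozen=True)
class PoolTestResult:
    gene: str
    sex: str
    t: float
    p_value: float
    direction: int  # +1: higher expression in resistant pool, -1: lower, 0: none
    mean_sensitive: float
    mean_resistant: float
    n_sensitive: int
    n_resistant: int


def pool_ttest(
    delta_cts: pd.DataFrame,
    gene: str,
    sex: str,
    equal_var: bool = True,
) -> PoolTestResult:
    """Student's t-test of dCt between sensitive and resistant pools.

    Direction is the sign of expression change in the resistant pool:
    lower dCt in the resistant pool means higher expression there (+1).
    """
    sub = delta_cts[(delta_cts["gene"] == gene) & (delta_cts["sex"] == sex)]
    s = sub[sub["pool"] == "sensitive"]["delta_ct"].to_numpy()
    r = sub[sub["pool"] == "resistant"]["delta_ct"].to_numpy()
    if len(s) < 2 or len(r) < 2:
        raise ValueError("need >= 2 biological replicates per pool")
    if s.std(ddof=1) == 0 and r.std(ddof=1) == 0:
        if s.mean() == r.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(s.mean() - r.mean()), 0.0
    else:
        t, p = stats.ttest_ind(s, r, equal_var=equal_var)
    direction = int(np.sign(s.mean() - r.mean()))
    return PoolTestResult(
        gene=gene,
        sex=sex,
        t=float(t),
        p_value=float(p),
        direction=direction,
        mean_sensitive=float(s.mean()),
        mean_resistant=float(r.mean()),
        n_sensitive=len(s),
        n_resistant=len(r),
    )


def pool_ttest_all(delta_cts: pd.DataFrame, equal_var: bool = True) -> pd.DataFrame:
    """Pool t-tests for every (gene, sex) transcript in a dCt table."""
    rows = [
        pool_ttest(delta_cts, gene, sex, equal_var=equal_var).__dict__
        for gene, sex in delta_cts[["gene", "sex"]].drop_duplicates().itertuples(index=False)
    ]
    return pd.DataFrame(rows)


def altered_proportion_test(
    candidate_results: pd.DataFrame,
    random_results: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Are candidate transcripts altered more often than random transcripts?

    A transcript counts as altered when its pool t-test p-value is below
    ``alpha``. Builds the 2x2 table (candidate/random x altered/not) and
    computes the one-sided Fisher exact p-value (hypergeometric upper tail).
    """
    if candidate_results.empty or random_results.empty:
        raise ValueError("both result tables must be non-empty")
    c_alt = int((candidate_results["p_value"] < alpha).sum())
    r_alt = int((random_results["p_value"] < alpha).sum())
    table = np.array(
        [
            [c_alt, len(candidate_results) - c_alt],
            [r_alt, len(random_results) - r_alt],
        ]
    )
    _, p = stats.fisher_exact(table, alternative="greater")
    return {
        "table": table,
        "p_value": float(p),
        "prop_candidate": c_alt / len(candidate_results),
        "prop_random": r_alt / len(random_results),
    }
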