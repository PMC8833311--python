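"""Inferential statistics for group comparisons.

The core test is a permutation t-test: the observed Welch t statistic is
compared against its null distribution under random relabelling of group
membership, giving an exact-style p-value
``(1 + #{|t*| >= |t|}) / (n_perm + 1)``.  Pairwise connectivity maps are
corrected with Benjamini–Hochberg FDR.  Dynamics metrics use two-way
(group x state) ANOVAs with type-II sums of squares, with Kruskal–Wallis /
Tukey / permutation t-tests post hoc; occurrence rates use the pooled
two-proportion z-test.  Severity associations are plain Pearson
correlations, uncorrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .connectivity import residualize_fc

__all__ = [
    "GroupTestResult",
    "AnovaResult",
    "perm_ttest",
    "fdr_bh",
    "cohens_d",
    "twoway_anova",
    "kruskal_wallis",
    "tukey_hsd",
    "ztest_proportions",
    "severity_correlation",
    "statewise_fc_test",
    "rank_sum",
]


@dataclass
class GroupTestResult:
    unit: str
    t_stat: float
    p_uncorr: float
    p_fdr: float
    cohens_d: float
    n_a: int
    n_b: int
    significant: bool = False


@dataclass
class AnovaResult:
    factor: str  # group | state | interaction
    F: float
    p: float
    df: tuple[float, float]


def _welch_t_matrix(X: np.ndarray, g1: np.ndarray) -> np.ndarray:
    """Welch t per column of X for grouping masks g1 (rows: groupings)."""
    n = X.shape[0]
    n1 = g1.sum(axis=1, keepdims=True).astype(float)
    n2 = n - n1
    s = g1 @ X  # per-grouping sums of group-1 rows
    sq = g1 @ (X**2)
    tot = X.sum(axis=0, keepdims=True)
    tot_sq = (X**2).sum(axis=0, keepdims=True)
    m1 = s / n1
    m2 = (tot - s) / n2
    v1 = (sq - n1 * m1**2) / (n1 - 1)
    v2 = (tot_sq - sq - n2 * m2**2) / (n2 - 1)
    v1 = np.clip(v1, 0.0, None)
    v2 = np.clip(v2, 0.0, None)
    se = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    return np.where(se > 0, t, 0.0)


def perm_ttest(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    two_sided: bool = True,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Permutation test on the Welch t statistic.

    ``x`` and ``y`` are the two groups' samples; 1-D arrays test a single
    variable, 2-D arrays (observations x variables) test every column with
    a shared set of label permutations.  Returns (t, p) with the shapes of
    the input columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 1
    if x.ndim == 1:
        x, y = x[:, None], y[:, None]
    if x.shape[0] < 2 or y.shape[0] < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.vstack([x, y])
    n1, n = x.shape[0], pooled.shape[0]

    mask_obs = np.zeros((1, n), dtype=float)
    mask_obs[0, :n1] = 1.0
    t_obs = _welch_t_matrix(pooled, mask_obs)[0]

    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=float)
    for b in range(n_perm):
        masks[b, rng.permutation(n)[:n1]] = 1.0
    t_null = _welch_t_matrix(pooled, masks)
    if two_sided:
        exceed = np.abs(t_null) >= np.abs(t_obs)[None, :]
    else:
        exceed = t_null >= t_obs[None, :]
    p = (1.0 + exceed.sum(axis=0)) / (n_perm + 1.0)
    # degenerate: no variance anywhere and equal means -> p = 1
    degen = (pooled.std(axis=0) == 0) & (t_obs == 0)
    p = np.where(degen, 1.0, p)
    if scalar and np.asarray(t_obs).size == 1:
        return float(t_obs[0]), float(p[0])
    return t_obs, p


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg adjusted p-values and the significance mask at q."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-SD standardized mean difference (positive: x above y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def twoway_anova(
    values: np.ndarray,
    group_factor: np.ndarray,
    state_factor: np.ndarray,
) -> list[AnovaResult]:
    """Group x state ANOVA with type-II sums of squares (unbalanced-safe)."""
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "group": np.asarray(group_factor).astype(str),
        "state": np.asarray(state_factor).astype(str),
    })
    for col in ("group", "state"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least 2 levels")
    if np.var(df["value"].to_numpy()) == 0:
        # constant response: no variance to attribute to any effect
        cells = df.groupby(["group", "state"]).size()
        resid_df = float(len(df) - cells.size)
        dfs = {"group": df["group"].nunique() - 1.0,
               "state": df["state"].nunique() - 1.0}
        dfs["interaction"] = dfs["group"] * dfs["state"]
        return [AnovaResult(factor=f, F=0.0, p=1.0, df=(dfs[f], resid_df))
                for f in ("group", "state", "interaction")]
    model = ols("value ~ C(group) * C(state)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-equal data emits 0/0 warnings
        table = anova_lm(model, typ=2)
    name_map = {
        "C(group)": "group",
        "C(state)": "state",
        "C(group):C(state)": "interaction",
    }
    resid_df = float(table.loc["Residual", "df"])
    out = []
    for row, factor in name_map.items():
        F = float(table.loc[row, "F"])
        p = float(table.loc[row, "PR(>F)"])
        if not np.isfinite(F):  # zero residual variance => no evidence of effect
            F, p = 0.0, 1.0
        out.append(AnovaResult(factor=factor, F=F, p=p,
                               df=(float(table.loc[row, "df"]), resid_df)))
    return out


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H with midrank tie correction."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 values")
    if all(np.array_equal(np.sort(g), np.sort(groups[0])) for g in groups):
        return 0.0, 1.0  # identical samples: H = 0 by construction
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def tukey_hsd(groups: list[np.ndarray]) -> np.ndarray:
    """Pairwise adjusted p-values (studentized range), matrix form."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 values")
    res = sps.tukey_hsd(*groups)
    return np.asarray(res.pvalue)


def rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney normal approximation): z and p."""
    z, p = sps.ranksums(x, y)
    return float(z), float(p)


def ztest_proportions(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n and n >= 1")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0  # degenerate: all or none visit in both groups
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def severity_correlation(values: np.ndarray, severity: np.ndarray) -> tuple[float, float]:
    """Pearson r (two-sided p) between a metric and severity; uncorrected."""
    values = np.asarray(values, dtype=float)
    severity = np.asarray(severity, dtype=float)
    keep = ~(np.isnan(values) | np.isnan(severity))
    values, severity = values[keep], severity[keep]
    if values.size < 4:
        raise ValueError("need >= 4 paired observations")
    if values.std() == 0 or severity.std() == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(values, severity)
    return float(r), float(p)


def statewise_fc_test(
    fc_by_subject: dict[str, np.ndarray],
    groups: dict[str, str],
    covariates: dict[str, np.ndarray] | None = None,
    n_perm: int = 10000,
    q: float = 0.05,
    seed: int = 0,
    group_a: str = "A",
    group_b: str = "B",
) -> list[GroupTestResult] | None:
    """Per-pair group comparison of subject-level state-mean FC vectors.

    ``fc_by_subject`` maps subject id -> length-P pair vector (mean
    Fisher-z FC over the subject's windows in one state; visitors only).
    Covariates (e.g. age, sex, mean FD) are residualized out across
    subjects before testing.  Each pair gets a permutation Welch t-test
    and Benjamini–Hochberg correction over all P pairs; effect sizes are
    Cohen's d on the residualized values.

    Returns None (skip status) when either group has < 2 visitors.
    """
    sids = list(fc_by_subject)
    a_ids = [s for s in sids if groups[s] == group_a]
    b_ids = [s for s in sids if groups[s] == group_b]
    if len(a_ids) < 2 or len(b_ids) < 2:
        return None
    Y = np.vstack([fc_by_subject[s] for s in a_ids + b_ids])
    if covariates is not None:
        X = np.vstack([np.atleast_1d(covariates[s]) for s in a_ids + b_ids])
        Y = residualize_fc(Y, X)
    Xa, Xb = Y[: len(a_ids)], Y[len(a_ids):]
    t, p = perm_ttest(Xa, Xb, n_perm=n_perm, seed=seed)
    p_adj, reject = fdr_bh(p, q=q)
    results = []
    for j in range(Y.shape[1]):
        results.append(GroupTestResult(
            unit=f"pair{j}", t_stat=float(t[j]), p_uncorr=float(p[j]),
            p_fdr=float(p_adj[j]), cohens_d=cohens_d(Xa[:, j], Xb[:, j]),
            n_a=len(a_ids), n_b=len(b_ids), significant=bool(reject[j]),
        ))
    return results
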