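"""Sex-stratified inference and the cone-crop homogeneity check.

Male and female squirrels differ in reproductive energetics, so the
analysis compares pit counts and midden aspect between sexes with Welch
(unequal-variance) t-tests, reports the percent male/female difference
in cache size, and regresses raw pit counts on linearized aspect within
each sex.  Moran's I with a permutation test checks that cone production
is spatially homogeneous, validating conifer density as a local
food-availability proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "WelchResult",
    "SlopeResult",
    "MoranResult",
    "welch_t",
    "sex_pit_difference",
    "per_sex_aspect_regression",
    "morans_i",
    "sex_report",
]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float  # Welch-Satterthwaite degrees of freedom
    p: float  # two-sided
    mean_a: float
    mean_b: float

    @property
    def percent_difference(self) -> float:
        """(mean_A − mean_B) / mean_B × 100."""
        return (self.mean_a - self.mean_b) / self.mean_b * 100.0


@dataclass(frozen=True)
class SlopeResult:
    beta: float  # pits per degree of linearized aspect
    t: float
    p: float
    n: int
    intercept: float


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float  # −1/(n−1)
    p: float
    permutations: int


def welch_t(group_a, group_b) -> WelchResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups constant: Welch statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / a.size, vb / b.size
    df = (se2a + se2b) ** 2 / (
        se2a**2 / (a.size - 1) + se2b**2 / (b.size - 1)
    )
    return WelchResult(
        t=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def _sex_groups(df: pd.DataFrame, column: str) -> tuple[np.ndarray, np.ndarray]:
    males = df.loc[df["sex"] == "male", column].to_numpy(float)
    females = df.loc[df["sex"] == "female", column].to_numpy(float)
    if males.size < 2 or females.size < 2:
        raise ValueError("need at least 2 middens of each sex")
    return males, females


def sex_pit_difference(df: pd.DataFrame) -> float:
    """Percent by which male middens out-pit female middens, on raw
    counts; unknown-sex middens are excluded."""
    males, females = _sex_groups(df, "n_pits")
    return float((males.mean() - females.mean()) / females.mean() * 100.0)


def per_sex_aspect_regression(
    df: pd.DataFrame, sex: str, response: str = "n_pits"
) -> SlopeResult:
    """OLS of the pit count on linearized aspect within one sex.

    Raw counts by default (``response="log_pits"`` switches to the log
    scale used in the model-selection stage).
    """
    sub = df.loc[df["sex"] == sex]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 middens of sex {sex!r}, got {len(sub)}")
    x = sub["aspect_lin"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("all aspects identical: slope undefined")
    y = sub[response].to_numpy(float)
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return SlopeResult(
        beta=float(res.params[1]),
        t=float(res.tvalues[1]),
        p=float(res.pvalues[1]),
        n=len(sub),
        intercept=float(res.params[0]),
    )


def inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    """Row-standardized inverse-distance spatial weights, zero diagonal."""
    coords = np.asarray(coords, dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    if np.any((d == 0) & ~np.eye(len(d), dtype=bool)):
        raise ValueError("coincident locations: inverse-distance weight undefined")
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def morans_i(
    values,
    coordinates,
    permutations: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
    weights: np.ndarray | None = None,
) -> MoranResult:
    """Global Moran's I with a permutation p-value.

    I = (n/S0) Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ² on centered values z, with
    row-standardized inverse-distance weights by default (S0 = n, so the
    normalization cancels).  The null expectation is −1/(n−1); the
    p-value compares the observed I with ``permutations`` random
    relabelings of the values over the locations.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Moran's I needs n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in values")
    coords = np.asarray(coordinates, dtype=float)
    if len(np.unique(coords, axis=0)) < 2:
        raise ValueError("need at least 2 distinct locations")
    W = inverse_distance_weights(coords) if weights is None else np.asarray(weights, float)
    s0 = W.sum()

    z = x - x.mean()
    denom = (z**2).sum()
    observed = (n / s0) * float(z @ W @ z) / denom
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(z) for _ in range(permutations)])
    sim = (n / s0) * np.einsum("bi,ij,bj->b", perms, W, perms) / denom
    if alternative == "greater":
        extreme = sim >= observed
    elif alternative == "less":
        extreme = sim <= observed
    elif alternative == "two-sided":
        extreme = np.abs(sim - expected) >= abs(observed - expected)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + int(extreme.sum())) / (permutations + 1)
    return MoranResult(I=observed, expected_I=expected, p=float(p), permutations=permutations)


def sex_report(df: pd.DataFrame) -> pd.DataFrame:
    """Summary table of all sex-stratified results for a midden table.

    Rows: Welch t on pit counts, Welch t on linearized aspect, percent
    male excess, and the per-sex aspect slopes.  Unknown-sex middens are
    excluded throughout.
    """
    pits = welch_t(*_sex_groups(df, "n_pits"))
    aspect = welch_t(*_sex_groups(df, "aspect_lin"))
    male = per_sex_aspect_regression(df, "male")
    female = per_sex_aspect_regression(df, "female")
    return pd.DataFrame(
        [
            {"analysis": "pits_by_sex_welch", "estimate": pits.t, "df": pits.df,
             "p": pits.p, "detail": f"male mean {pits.mean_a:.1f}, female mean {pits.mean_b:.1f}"},
            {"analysis": "percent_male_excess", "estimate": pits.percent_difference,
             "df": np.nan, "p": np.nan, "detail": "(mean_m - mean_f)/mean_f * 100, raw counts"},
            {"analysis": "aspect_by_sex_welch", "estimate": aspect.t, "df": aspect.df,
             "p": aspect.p, "detail": "linearized aspect, male vs female"},
            {"analysis": "male_aspect_slope", "estimate": male.beta, "df": float(male.n - 2),
             "p": male.p, "detail": f"t = {male.t:.3f}, n = {male.n}"},
            {"analysis": "female_aspect_slope", "estimate": female.beta, "df": float(female.n - 2),
             "p": female.p, "detail": f"t = {female.t:.3f}, n = {female.n}"},
        ]
    )
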