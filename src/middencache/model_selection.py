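"""AICc multimodel inference over small additive Gaussian GLMs.

The candidate set is the null model (one random covariate) plus every
one- and two-covariate additive model on the retained variables; the
response is the log pit count, so the Gaussian identity-link GLM is an
ordinary least-squares fit.  Models are ranked by the small-sample
corrected Akaike criterion; Akaike weights give each model's relative
likelihood, and a nonparametric bootstrap gives πi — the frequency with
which each model wins (lowest AICc) across resamples of the middens.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("middencache")

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ModelRow",
    "SelectionTable",
    "build_model_set",
    "add_null_covariate",
    "fit_gaussian_glm",
    "aicc",
    "rank_and_weight",
    "bootstrap_pi",
    "deviance_explained",
    "select_models",
]

NULL_COVARIATE = "_null"


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: up to two additive covariates on log pit count.

    The null model carries a single column of random numbers so that it
    competes with the same parameter count as the one-covariate models.
    """

    label: str
    terms: tuple[str, ...]
    response: str = "log_pits"

    def __post_init__(self) -> None:
        base = [t for t in self.terms if ":" not in t]
        if len(base) > 2:
            raise ValueError("at most two covariates per model")

    @property
    def design_columns(self) -> tuple[str, ...]:
        return self.terms if self.terms else (NULL_COVARIATE,)


@dataclass(frozen=True)
class ModelFit:
    spec: ModelSpec
    n: int
    k: int  # coefficients (incl. intercept) + 1 for the residual variance
    coefficients: pd.Series
    loglik: float  # maximized Gaussian log-likelihood (ML variance)
    residual_deviance: float
    null_deviance: float

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)


@dataclass
class ModelRow:
    spec: ModelSpec
    k: int
    loglik: float
    aicc: float
    delta_aicc: float
    waicc: float
    pi: float | None = None


@dataclass
class SelectionTable:
    rows: list[ModelRow]
    n: int
    bootstrap_reps: int | None = None
    seed: int | None = None
    redraws: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model_label": [r.spec.label for r in self.rows],
                "terms": [" + ".join(r.spec.terms) or "(null)" for r in self.rows],
                "k": [r.k for r in self.rows],
                "loglik": [r.loglik for r in self.rows],
                "aicc": [r.aicc for r in self.rows],
                "delta_aicc": [r.delta_aicc for r in self.rows],
                "waicc": [r.waicc for r in self.rows],
                "pi": [np.nan if r.pi is None else r.pi for r in self.rows],
            }
        )

    @property
    def best(self) -> ModelRow:
        return self.rows[0]


def build_model_set(
    covariates: list[str],
    name_map: dict[str, str] | None = None,
    include_interactions: bool = False,
) -> list[ModelSpec]:
    """Null + all singletons + all additive pairs (11 models for 4
    covariates).  Interaction specs can be added for exploration but are
    excluded from the default set."""
    if not covariates:
        raise ValueError("need at least one covariate")
    if len(covariates) > 6:
        raise ValueError("candidate covariate set larger than 6; reduce first")
    name_map = name_map or {}
    pretty = lambda c: name_map.get(c, c)
    specs = [ModelSpec(label="Null", terms=())]
    for c in sorted(covariates):
        specs.append(ModelSpec(label=pretty(c), terms=(c,)))
    for a, b in combinations(sorted(covariates), 2):
        specs.append(ModelSpec(label=f"{pretty(a)} + {pretty(b)}", terms=(a, b)))
        if include_interactions:
            specs.append(
                ModelSpec(label=f"{pretty(a)} x {pretty(b)}", terms=(a, b, f"{a}:{b}"))
            )
    return specs


def add_null_covariate(data: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Attach the null model's random covariate: one standard-normal draw
    per midden, generated once from the run seed and frozen so it travels
    with its row through every resample."""
    out = data.copy()
    rng = np.random.default_rng(seed)
    out[NULL_COVARIATE] = rng.normal(0.0, 1.0, len(out))
    logger.info("null covariate drawn with seed %d", seed)
    return out


def _design(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    cols = []
    for term in spec.design_columns:
        if ":" in term:
            a, b = term.split(":")
            cols.append(data[a].to_numpy(float) * data[b].to_numpy(float))
        else:
            cols.append(data[term].to_numpy(float))
    return np.column_stack([np.ones(len(data))] + cols)


def fit_gaussian_glm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """OLS fit of the spec (Gaussian family, identity link).

    The log-likelihood uses the ML variance estimate RSS/n, and
    k = #coefficients + 1 counts the variance as an estimated parameter
    (so one-covariate models have k=3, two-covariate models k=4).
    """
    y = data[spec.response].to_numpy(float)
    X = _design(data, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"model {spec.label!r}: n={n} too small for {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"model {spec.label!r}: rank-deficient design "
                         f"(aliased columns among {spec.design_columns})")
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    tss = float(((y - y.mean()) ** 2).sum())
    names = ["intercept", *spec.design_columns]
    return ModelFit(
        spec=spec,
        n=n,
        k=p + 1,
        coefficients=pd.Series(res.params, index=names),
        loglik=float(res.llf),
        residual_deviance=rss,
        null_deviance=tss,
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion:
    −2ℓ + 2k + 2k(k+1)/(n−k−1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: need n > k + 1 (n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def deviance_explained(fit: ModelFit) -> float:
    """1 − residual/null deviance (= R² for Gaussian identity models)."""
    if fit.null_deviance == 0:
        raise ValueError("null deviance is zero: response is constant")
    return 1.0 - fit.residual_deviance / fit.null_deviance


def rank_and_weight(fits: list[ModelFit]) -> SelectionTable:
    """Rank fits by AICc and attach ΔAICc and Akaike weights.

    w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2).  Ties in AICc are broken by
    fewer parameters, then label order.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to rank")
    sizes = {f.n for f in fits}
    if len(sizes) != 1:
        raise ValueError(f"fits come from differing sample sizes: {sorted(sizes)}")
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    order = sorted(
        range(len(fits)), key=lambda i: (aiccs[i], fits[i].k, fits[i].spec.label)
    )
    rows = [
        ModelRow(
            spec=fits[i].spec,
            k=fits[i].k,
            loglik=fits[i].loglik,
            aicc=float(aiccs[i]),
            delta_aicc=float(delta[i]),
            waicc=float(w[i]),
        )
        for i in order
    ]
    return SelectionTable(rows=rows, n=fits[0].n)


class BootstrapInstabilityError(RuntimeError):
    """Too many resamples produced rank-deficient designs."""


def bootstrap_pi(
    specs: list[ModelSpec],
    data: pd.DataFrame,
    B: int = 10000,
    seed: int = 0,
    with_replacement: bool = True,
    strict: bool = False,
    max_redraw_fraction: float = 0.10,
) -> tuple[dict[ModelSpec, float], int]:
    """Bootstrap model-selection frequencies πi.

    Draw B resamples of the middens (rows, with replacement by default;
    subsampling of 80% of rows without replacement as the alternative),
    refit every candidate on each resample, and count how often each
    model attains the lowest AICc.  Rows carry all covariates — including
    the frozen null covariate — with them.  Resamples on which any model
    is numerically rank-deficient are redrawn (count returned; a redraw
    rate above ``max_redraw_fraction`` raises under ``strict``).

    Returns ``(pi_by_spec, n_redraws)``; Σπi = 1 by construction.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(data)
    y = data[specs[0].response].to_numpy(float)
    designs = [_design(data, s) for s in specs]
    ks = np.array([X.shape[1] + 1 for X in designs])
    if np.any(n - ks - 1 <= 0):
        raise ValueError("sample too small for some candidate model's AICc")
    # resolve AICc ties exactly as rank_and_weight: fewer params, then label
    tie_order = sorted(range(len(specs)), key=lambda i: (ks[i], specs[i].label))
    m = n if with_replacement else max(int(round(0.8 * n)), max(ks) + 2)

    rng = np.random.default_rng(seed)
    const = 0.5 * (math.log(2 * math.pi) + 1)  # per-obs constant in the ML loglik

    def _aicc_matrix(idx: np.ndarray) -> np.ndarray:
        """AICc for every (resample, model); NaN where the fit failed."""
        nb = idx.shape[0]
        out = np.empty((nb, len(specs)))
        yb = y[idx]  # nb x m
        yy = np.einsum("bi,bi->b", yb, yb)
        for j, X in enumerate(designs):
            Xb = X[idx]  # nb x m x p
            G = np.einsum("bip,biq->bpq", Xb, Xb)
            c = np.einsum("bip,bi->bp", Xb, yb)
            with np.errstate(all="ignore"):
                try:
                    beta = np.linalg.solve(G, c[..., None])[..., 0]
                except np.linalg.LinAlgError:
                    beta = np.full((nb, X.shape[1]), np.nan)
                    for b in range(nb):
                        try:
                            beta[b] = np.linalg.solve(G[b], c[b])
                        except np.linalg.LinAlgError:
                            pass
                rss = yy - np.einsum("bp,bp->b", beta, c)
                rss = np.where(rss <= 0, np.nan, rss)
                ll = -0.5 * m * np.log(rss / m) - m * const
                k = ks[j]
                out[:, j] = -2.0 * ll + 2.0 * k + 2.0 * k * (k + 1) / (m - k - 1)
        return out

    def _draw(nb: int) -> np.ndarray:
        if with_replacement:
            return rng.integers(0, n, size=(nb, m))
        return np.array([rng.choice(n, m, replace=False) for _ in range(nb)])

    wins = np.zeros(len(specs), dtype=int)
    remaining, redraws = B, 0
    while remaining > 0:
        idx = _draw(remaining)
        scores = _aicc_matrix(idx)
        ok = np.all(np.isfinite(scores), axis=1)
        redraws += int((~ok).sum())
        if redraws > max_redraw_fraction * B:
            msg = f"bootstrap redraw count {redraws} exceeds {max_redraw_fraction:.0%} of B={B}"
            if strict:
                raise BootstrapInstabilityError(msg)
            logger.warning(msg)
        good = scores[ok][:, tie_order]  # tie-break by column order under argmin
        winners = np.argmin(good, axis=1)
        for w in winners:
            wins[tie_order[w]] += 1
        remaining -= int(ok.sum())
    pi = wins / B
    logger.info("bootstrap pi: B=%d seed=%d redraws=%d", B, seed, redraws)
    return {specs[i]: float(pi[i]) for i in range(len(specs))}, redraws


def select_models(
    data: pd.DataFrame,
    covariates: list[str],
    name_map: dict[str, str] | None = None,
    bootstrap_reps: int = 10000,
    seed: int = 0,
    response: str = "log_pits",
    with_replacement: bool = True,
) -> SelectionTable:
    """End-to-end candidate-set build, fit, ranking and bootstrap πi."""
    specs = [
        ModelSpec(label=s.label, terms=s.terms, response=response)
        for s in build_model_set(covariates, name_map=name_map)
    ]
    work = add_null_covariate(data, seed=seed)
    fits = [fit_gaussian_glm(s, work) for s in specs]
    table = rank_and_weight(fits)
    if bootstrap_reps:
        pi, redraws = bootstrap_pi(
            specs, work, B=bootstrap_reps, seed=seed + 1,
            with_replacement=with_replacement,
        )
        for row in table.rows:
            row.pi = pi[row.spec]
        table.bootstrap_reps = bootstrap_reps
        table.redraws = redraws
    table.seed = seed
    return table
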