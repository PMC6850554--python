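"""Iterative PCA / correlation pruning of the candidate covariates.

With ~19 covariates on ~28 middens the candidate set must be thinned
before model selection.  The procedure splits covariates into biotic and
abiotic groups, projects each group onto its first two principal
components (correlation-matrix PCA, eigenvalue-scaled loadings), scores
every variable by how *dissimilar* its loading vector is from the rest,
and — among significantly Pearson-correlated pairs — deletes the member
with the smaller dissimilarity.  One deletion per round, re-running the
PCA each time; once each group is internally uncorrelated the survivors
are pooled and the loop runs once more on the combined set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = ["ReductionRound", "ReductionTrace", "pca_first_two", "iterative_reduce"]


@dataclass(frozen=True)
class ReductionRound:
    group: str  # biotic | abiotic | combined
    loadings: pd.DataFrame  # variables x (PC1, PC2), eigenvalue-scaled
    dissimilarity: dict[str, float]
    eliminated_variable: str
    partner_variable: str
    pearson_r: float
    p_value: float


@dataclass
class ReductionTrace:
    rounds: list[ReductionRound] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    @property
    def eliminated(self) -> list[str]:
        return [r.eliminated_variable for r in self.rounds]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": range(1, len(self.rounds) + 1),
                "group": [r.group for r in self.rounds],
                "eliminated_variable": [r.eliminated_variable for r in self.rounds],
                "partner_variable": [r.partner_variable for r in self.rounds],
                "pearson_r": [r.pearson_r for r in self.rounds],
                "p_value": [r.p_value for r in self.rounds],
            }
        )


def pca_first_two(df: pd.DataFrame):
    """First two principal components of z-scored variables.

    Returns ``(loadings, scores, explained_variance_ratio)`` where the
    loadings are scaled by the square roots of the eigenvalues — the
    correlation-biplot convention, under which a loading is the
    correlation between the variable and the component.
    """
    if df.shape[0] <= 2:
        raise ValueError("PCA needs more than 2 rows")
    sd = df.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant column(s): {', '.join(constant)}")
    z = (df - df.mean()) / sd
    n_comp = min(2, df.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(z.to_numpy())
    loadings = pd.DataFrame(
        pca.components_.T * np.sqrt(pca.explained_variance_),
        index=df.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    if n_comp == 1:  # degenerate two-variable edge handled upstream; keep shape
        loadings["PC2"] = 0.0
    return loadings, scores, pca.explained_variance_ratio_


def dissimilarity_scores(loadings: pd.DataFrame, metric: str = "euclidean") -> dict[str, float]:
    """Per-variable mean distance of its PC1–PC2 loading vector to all
    the others' (``euclidean``), or mean angular separation (``angular``)."""
    vecs = loadings[["PC1", "PC2"]].to_numpy()
    names = list(loadings.index)
    out = {}
    for i, name in enumerate(names):
        others = np.delete(np.arange(len(names)), i)
        if metric == "euclidean":
            d = np.linalg.norm(vecs[others] - vecs[i], axis=1)
        elif metric == "angular":
            a, b = vecs[others], vecs[i]
            cosine = (a @ b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b) + 1e-300
            )
            d = np.arccos(np.clip(cosine, -1.0, 1.0))
        else:
            raise ValueError(f"unknown dissimilarity metric {metric!r}")
        out[name] = float(d.mean())
    return out


def _one_round(df: pd.DataFrame, group: str, alpha: float, metric: str):
    """One deletion step inside a group; None when no correlated pair is left."""
    cols = sorted(df.columns)
    significant = []
    for a, b in combinations(cols, 2):
        r, p = stats.pearsonr(df[a], df[b])
        if p < alpha:
            significant.append((abs(r), a, b, r, p))
    if not significant:
        return None
    # most redundant pair first: largest |r|, label order breaks ties
    significant.sort(key=lambda t: (-t[0], t[1], t[2]))
    _, a, b, r, p = significant[0]
    loadings, _, _ = pca_first_two(df)
    diss = dissimilarity_scores(loadings, metric=metric)
    # delete the less dissimilar member; tie -> later alphabetical name
    if diss[a] < diss[b] or (diss[a] == diss[b] and a > b):
        eliminated, partner = a, b
    else:
        eliminated, partner = b, a
    return ReductionRound(
        group=group,
        loadings=loadings,
        dissimilarity=diss,
        eliminated_variable=eliminated,
        partner_variable=partner,
        pearson_r=float(r),
        p_value=float(p),
    )


def iterative_reduce(
    data: pd.DataFrame,
    group_labels: dict[str, str],
    alpha: float = 0.05,
    metric: str = "euclidean",
) -> ReductionTrace:
    """Run the full biotic → abiotic → combined elimination loop.

    ``group_labels`` maps each column of ``data`` to ``"biotic"`` or
    ``"abiotic"``.  Terminates after at most (variables − 1) deletions;
    every deletion is recorded with its justifying correlation.
    """
    unknown = set(data.columns) - set(group_labels)
    if unknown:
        raise ValueError(f"columns without group label: {sorted(unknown)}")
    bad = set(group_labels.values()) - {"biotic", "abiotic"}
    if bad:
        raise ValueError(f"group labels must be biotic|abiotic, got {sorted(bad)}")

    trace = ReductionTrace()
    survivors: list[str] = []
    for group in ("biotic", "abiotic"):
        cols = sorted(c for c in data.columns if group_labels[c] == group)
        if len(cols) < 2:
            survivors.extend(cols)
            continue
        while len(cols) >= 2:
            rnd = _one_round(data[cols], group, alpha, metric)
            if rnd is None:
                break
            trace.rounds.append(rnd)
            cols.remove(rnd.eliminated_variable)
        survivors.extend(cols)

    cols = sorted(survivors)
    while len(cols) >= 2:
        rnd = _one_round(data[cols], "combined", alpha, metric)
        if rnd is None:
            break
        trace.rounds.append(rnd)
        cols.remove(rnd.eliminated_variable)

    trace.retained = cols
    return trace
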