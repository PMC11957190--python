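"""Model validation: cross-validated rank correlation and cross-wave checks.

Predictive performance of an NB regression is summarised as the Spearman
correlation between held-out outcomes and fitted means over 10-fold
cross-validation (folds are a seeded permutation cut into near-equal
contiguous chunks; dispersion is re-profiled within each training fold).
Because Spearman is invariant to monotone transforms, ranking fitted means
under the log link is equivalent to ranking linear predictors.

Cross-wave consistency asks whether the miRNAs flagged as modifiers in a
discovery wave still carry elevated modulation scores in the other wave:
a one-sided Wilcoxon rank-sum of hits versus the remaining miRNAs, exact
when both groups are small and tie-free, normal approximation with tie
correction otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import nb_glm
from .errors import ValidationError


def spearman(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("inputs must be equal-length vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("Spearman undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class CVResult:
    k: int
    per_fold_rho: list[float]  # NaN marks folds excluded (constant held-out y)
    mean_rho: float
    seed: int
    model_spec: list[str]


def kfold_assignments(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded permutation cut into k contiguous chunks of near-equal size."""
    if n < 2 * k:
        raise ValidationError(f"need n >= 2k (n={n}, k={k})")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def kfold_cv_spearman(
    y, X: pd.DataFrame, k: int = 10, seed: int = 0, link: str = "log"
) -> CVResult:
    """Mean held-out Spearman correlation over k-fold cross-validation.

    Each fold's model (coefficients and dispersion) is refitted on the
    remaining k-1 folds; predictions are the fitted NB means.
    """
    y = np.asarray(y, dtype=float)
    folds = kfold_assignments(len(y), k, seed)
    rhos: list[float] = []
    for test_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        fit = nb_glm.fit_nb(y[mask], X.iloc[mask], link=link)
        pred = nb_glm.predict_mean(fit, X.iloc[test_idx])
        y_test = y[test_idx]
        if np.all(y_test == y_test[0]) or np.all(pred == pred[0]):
            warnings.warn("fold with constant held-out outcome excluded from CV mean")
            rhos.append(float("nan"))
            continue
        rhos.append(spearman(y_test, pred))
    valid = [r for r in rhos if not np.isnan(r)]
    if not valid:
        raise ValidationError("no fold yielded a defined Spearman correlation")
    return CVResult(
        k=k,
        per_fold_rho=rhos,
        mean_rho=float(np.mean(valid)),
        seed=seed,
        model_spec=list(X.columns),
    )


def rank_sum_greater(hits: np.ndarray, others: np.ndarray) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum testing hits > others.

    Returns (W, p) where W is the Mann-Whitney U of the hit group.  Exact
    enumeration when both groups have <= 10 members and there are no ties;
    normal approximation with tie correction otherwise.
    """
    hits = np.asarray(hits, dtype=float)
    others = np.asarray(others, dtype=float)
    if hits.size == 0 or others.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([hits, others])
    if np.all(pooled == pooled[0]):
        return float(hits.size * others.size / 2.0), 0.5
    has_ties = np.unique(pooled).size < pooled.size
    if hits.size <= 10 and others.size <= 10 and not has_ties:
        res = stats.mannwhitneyu(hits, others, alternative="greater", method="exact")
    else:
        res = stats.mannwhitneyu(
            hits, others, alternative="greater", method="asymptotic"
        )
    return float(res.statistic), float(res.pvalue)


def cross_wave_consistency(
    scores_all: Mapping[str, float], hit_ids: Iterable[str]
) -> tuple[float, float]:
    """Do discovery-wave hits keep elevated modulation scores in the other wave?

    ``scores_all`` maps every screened miRNA to its validation-wave
    modulation score; ``hit_ids`` names the discovery-wave hits.  Tests
    hits > non-hits by one-sided rank-sum.
    """
    hit_ids = set(hit_ids)
    if not hit_ids:
        raise ValidationError("hit set is empty")
    unknown = hit_ids - set(scores_all)
    if unknown:
        raise ValidationError(f"hit ids missing from score map: {sorted(unknown)}")
    if hit_ids == set(scores_all):
        raise ValidationError("hit set must be a strict subset of scored miRNAs")
    hits = np.array([v for k, v in scores_all.items() if k in hit_ids])
    others = np.array([v for k, v in scores_all.items() if k not in hit_ids])
    return rank_sum_greater(hits, others)
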