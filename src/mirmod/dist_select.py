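"""Outcome-distribution selection by maximum likelihood and BIC.

Fits the four candidate families for the PTSS outcome -- Poisson, Gamma,
negative binomial and Weibull -- by maximum likelihood, ranks them by the
Bayesian Information Criterion (k*ln(n) - 2*loglik, lower is better), and
compares two families by refitting on bootstrap resamples of individuals.

Gamma and Weibull are continuous, strictly-positive families; on
integer-valued outcomes they are fitted on the raw values (PCL-C sums are
>= 17, so the positivity constraint rarely binds), with an optional +0.5
shift flag for outcomes that include zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FitError, ValidationError
from .nb_glm import THETA_CAP, nb_loglik, profile_theta

FAMILIES = ("poisson", "gamma", "negative_binomial", "weibull")

#: Free-parameter count per family.
K_PARAMS = {"poisson": 1, "gamma": 2, "negative_binomial": 2, "weibull": 2}


@dataclass
class DistFitResult:
    family: str
    params: dict[str, float]
    loglik: float
    n: int
    k: int
    bic: float
    boundary: bool = False  # parameter pinned at a domain boundary (e.g. theta cap)


@dataclass
class SelectionResult:
    """Fittable families ranked by ascending BIC, plus per-family failures."""

    fits: list[DistFitResult]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def best(self) -> DistFitResult:
        return self.fits[0]

    def rank(self) -> list[str]:
        return [f.family for f in self.fits]


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian Information Criterion: k*ln(n) - 2*loglik."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if k < 0:
        raise ValidationError("k must be >= 0")
    return float(k * np.log(n) - 2.0 * loglik)


def _check_integer(y: np.ndarray, family: str) -> None:
    if np.any(y != np.round(y)):
        raise ValidationError(f"{family} requires integer-valued outcomes")


def fit_distribution(y, family: str, shift_zeros: bool = False) -> DistFitResult:
    """Maximum-likelihood fit of one candidate family.

    ``shift_zeros`` adds 0.5 to every value before fitting the strictly
    positive continuous families (Gamma, Weibull) on outcomes containing
    zeros; by default those families refuse zero-valued data.
    """
    if family not in FAMILIES:
        raise ValidationError(f"unknown family {family!r}; choose from {FAMILIES}")
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValidationError("need at least two observations")
    if np.any(y < 0):
        raise ValidationError("outcome must be nonnegative")
    n = int(y.size)
    k = K_PARAMS[family]
    all_equal = bool(np.all(y == y[0]))

    if family == "poisson":
        _check_integer(y, family)
        lam = float(np.mean(y))
        if lam <= 0:
            raise FitError("Poisson rate is zero (all-zero data)")
        ll = float(np.sum(stats.poisson.logpmf(y.astype(int), lam)))
        return DistFitResult(family, {"lam": lam}, ll, n, k, bic(ll, k, n))

    if family == "negative_binomial":
        _check_integer(y, family)
        mu = float(np.mean(y))
        if mu <= 0:
            raise FitError("NB mean is zero (all-zero data)")
        # for an intercept-only NB the ML mean is the sample mean; profile theta
        theta, capped = profile_theta(y, np.full(n, mu))
        ll = nb_loglik(y, np.full(n, mu), theta)
        return DistFitResult(
            family, {"mu": mu, "theta": theta}, ll, n, k, bic(ll, k, n), boundary=capped
        )

    # continuous, strictly positive families
    yc = y + 0.5 if shift_zeros else y
    if np.any(yc <= 0):
        raise FitError(
            f"{family} requires strictly positive data "
            "(use shift_zeros=True for integer outcomes with zeros)"
        )
    if all_equal:
        raise FitError(f"{family} MLE degenerate on constant data")
    if family == "gamma":
        shape, _, scale = stats.gamma.fit(yc, floc=0)
        ll = float(np.sum(stats.gamma.logpdf(yc, shape, scale=scale)))
        params = {"shape": float(shape), "scale": float(scale)}
    else:  # weibull
        shape, _, scale = stats.weibull_min.fit(yc, floc=0)
        ll = float(np.sum(stats.weibull_min.logpdf(yc, shape, scale=scale)))
        params = {"shape": float(shape), "scale": float(scale)}
    if not np.isfinite(ll):
        raise FitError(f"{family} likelihood not finite at the fitted parameters")
    return DistFitResult(family, params, ll, n, k, bic(ll, k, n))


def select_distribution(
    y, families=FAMILIES, shift_zeros: bool = False
) -> SelectionResult:
    """Fit every requested family and rank the fittable ones by BIC."""
    fits: list[DistFitResult] = []
    failures: dict[str, str] = {}
    for fam in families:
        try:
            fits.append(fit_distribution(y, fam, shift_zeros=shift_zeros))
        except (FitError, ValidationError) as exc:
            failures[fam] = str(exc)
    if not fits:
        raise FitError(f"no family could be fitted: {failures}")
    fits.sort(key=lambda f: f.bic)
    return SelectionResult(fits=fits, failures=failures)


@dataclass
class BootstrapComparison:
    """ΔBIC = BIC_a - BIC_b over bootstrap resamples of individuals."""

    family_a: str
    family_b: str
    delta_bic: np.ndarray
    mean_delta: float
    p: float  # fraction of replicates with ΔBIC > 0, ties counted 1/2
    n_replicates: int
    n_failed: int


def bootstrap_bic_compare(
    y, family_a: str, family_b: str, B: int = 1000, seed: int = 0,
    shift_zeros: bool = False,
) -> BootstrapComparison:
    """Compare two families by refitting both on B resamples of individuals.

    Each replicate draws n individuals with replacement, fits both families,
    and records the BIC difference.  p is the fraction of replicates where
    family_a's BIC exceeds family_b's (ties counted 1/2): small p means
    family_a fits better nearly always, p near 0.5 means the families are
    interchangeable on these data.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    y = np.asarray(y, dtype=float)
    # verify both families are fittable on the full data before resampling
    for fam in (family_a, family_b):
        fit_distribution(y, fam, shift_zeros=shift_zeros)
    rng = np.random.default_rng(seed)
    deltas: list[float] = []
    failed = 0
    for _ in range(B):
        yb = y[rng.integers(0, y.size, y.size)]
        try:
            fa = fit_distribution(yb, family_a, shift_zeros=shift_zeros)
            fb = fit_distribution(yb, family_b, shift_zeros=shift_zeros)
        except (FitError, ValidationError):
            failed += 1
            continue
        deltas.append(fa.bic - fb.bic)
    if failed > 0.1 * B:
        raise FitError(f"{failed}/{B} bootstrap replicates failed to fit")
    d = np.asarray(deltas)
    p = float((np.sum(d > 0) + 0.5 * np.sum(d == 0)) / d.size)
    return BootstrapComparison(
        family_a=family_a,
        family_b=family_b,
        delta_bic=d,
        mean_delta=float(d.mean()),
        p=p,
        n_replicates=int(d.size),
        n_failed=failed,
    )
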