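"""Synthetic longitudinal cohort generator.

Emulates the statistical structure the screens assume, so every stage of
the pipeline is testable without any cohort download:

* five social-adversity exposures with realistic marginals (cumulative
  trauma as an overdispersed count with mean ~7; binary financial and
  emotional stressors with prevalences ~0.63 and ~0.32; discrimination and
  loneliness as truncated-normal scale scores), mutually correlated through
  a Gaussian copula;
* miRNA read counts with per-sample library-size variation, negative-
  binomial counting noise, and a per-participant latent abundance shared
  across collection waves so expression is highly stable within person;
* an NB-distributed PTSS outcome driven by a log-linear predictor over the
  adversities, miRNA abundances, and planted adversity x miRNA interactions.

Effect sizes are specified in log-link units per standard deviation: the
generator z-scores adversities and log2-CPM expression before forming the
linear predictor.  Because z-scoring is affine and the screens include all
main effects, the planted interaction lies exactly in the span of the
screen's raw-scale design; only the coefficient units differ, and the
modulation score (a z statistic) is invariant to that rescaling.

Ground truth (realized coefficients, linear predictors, modifier flags) is
recorded for every draw so recovery and calibration tests can grade the
screens against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ADVERSITIES, ADVERSITY_COLUMNS, ExpressionMatrix, PhenotypeTable
from .errors import ValidationError


@dataclass
class AdversityParams:
    """Marginal specs for the five exposures plus their copula correlation."""

    trauma_mean: float = 6.8
    trauma_theta: float = 3.0
    financial_prevalence: float = 0.625
    emotional_prevalence: float = 0.316
    discrimination_mean: float = 3.4
    discrimination_sd: float = 0.5
    loneliness_mean: float = 1.4
    loneliness_sd: float = 0.5
    copula_correlation: float = 0.2

    def validate(self) -> None:
        for name in ("financial_prevalence", "emotional_prevalence"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        for name in ("trauma_theta", "discrimination_sd", "loneliness_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not -0.2 <= self.copula_correlation < 1:
            raise ValidationError("copula_correlation must lie in [-0.2, 1)")


@dataclass
class ExpressionParams:
    """miRNA abundance, library-size and within-person stability settings."""

    log2_abundance_range: tuple[float, float] = (2.0, 12.0)
    library_size_range: tuple[float, float] = (5e5, 2e6)
    count_dispersion: float = 20.0
    biological_sd: float = 0.5  # per-participant latent deviation (natural log)
    wave_sd: float = 0.25  # wave-specific fluctuation around the latent

    def validate(self) -> None:
        if self.count_dispersion <= 0:
            raise ValidationError("count_dispersion must be positive")
        if self.library_size_range[0] <= 0 or (
            self.library_size_range[1] < self.library_size_range[0]
        ):
            raise ValidationError("library_size_range must be positive and ordered")


@dataclass
class EffectSpec:
    """Linear-predictor coefficients, in log-link units per SD of each term.

    ``intercept=None`` auto-resolves to log(target_mean) minus half the
    total effect variance (the lognormal moment correction, treating each
    standardized term as unit-variance), so the average PTSS lands near the
    configured target.  ``c`` maps (mirna_id, adversity) pairs to
    interaction coefficients; miRNAs with an entry are the planted modifiers.
    """

    intercept: float | None = None
    target_mean: float = 35.0
    a: dict[str, float] = field(
        default_factory=lambda: {
            "trauma": 0.15,
            "financial": 0.08,
            "emotional": 0.03,
            "discrimination": 0.12,
            "loneliness": 0.10,
        }
    )
    b: dict[str, float] = field(default_factory=dict)
    c: dict[tuple[str, str], float] = field(default_factory=dict)

    def resolved_intercept(self) -> float:
        if self.intercept is not None:
            return self.intercept
        var_eta = (
            sum(v**2 for v in self.a.values())
            + sum(v**2 for v in self.b.values())
            + sum(v**2 for v in self.c.values())
        )
        return float(np.log(self.target_mean) - 0.5 * var_eta)


@dataclass
class SimulationConfig:
    n_participants: int = 600
    n_mirnas: int = 200
    seed: int = 0
    adversity: AdversityParams = field(default_factory=AdversityParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    effects: EffectSpec = field(default_factory=EffectSpec)
    theta: float = 6.5  # PTSS dispersion: Var = mu + mu^2/theta
    link: str = "log"
    n_modifiers: int = 10  # planted modifiers when effects.c is empty
    modifier_effect: float = 0.15  # per-SD log-link units
    #: adversity the planted modifiers act on; "spread" cycles them over all
    #: five exposures (the study's modifiers likewise split across adversities)
    modifier_adversity: str = "spread"

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("n_participants must be >= 2")
        if self.n_mirnas < 1:
            raise ValidationError("n_mirnas must be >= 1")
        if self.theta <= 0:
            raise ValidationError("theta must be positive")
        if self.link not in ("log", "identity"):
            raise ValidationError("link must be 'log' or 'identity'")
        if self.modifier_adversity not in (*ADVERSITIES, "spread"):
            raise ValidationError(f"unknown adversity {self.modifier_adversity!r}")
        self.adversity.validate()
        self.expression.validate()
        for (mid, adv) in self.effects.c:
            if adv not in ADVERSITIES:
                raise ValidationError(f"planted interaction names unknown adversity {adv!r}")


@dataclass
class GroundTruth:
    """Realized effects and predictors behind one simulated cohort."""

    intercept: float
    a: dict[str, float]
    b: dict[str, float]
    c: dict[str, dict[str, float]]  # mirna -> adversity -> coefficient
    modifier_ids: list[str]
    theta: float
    link: str
    standardization: str
    eta: dict[str, list[float]]  # per outcome wave

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _nb_draw(rng: np.random.Generator, mean, theta: float) -> np.ndarray:
    """NB sample via the gamma-Poisson mixture (stable for any dispersion)."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


def gen_adversities(cfg: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Per-participant adversity block with copula-correlated marginals."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    p = cfg.adversity
    n = cfg.n_participants
    R = np.full((5, 5), p.copula_correlation)
    np.fill_diagonal(R, 1.0)
    z = rng.multivariate_normal(np.zeros(5), R, size=n, method="cholesky")
    u = stats.norm.cdf(z)

    theta, mu = p.trauma_theta, p.trauma_mean
    trauma = stats.nbinom.ppf(u[:, 0], theta, theta / (theta + mu)).astype(int)
    financial = (u[:, 1] < p.financial_prevalence).astype(int)
    emotional = (u[:, 2] < p.emotional_prevalence).astype(int)

    def trunc_norm(uu, m, s):
        a = (0.0 - m) / s
        return stats.truncnorm.ppf(uu, a, np.inf, loc=m, scale=s)

    discrimination = trunc_norm(u[:, 3], p.discrimination_mean, p.discrimination_sd)
    loneliness = trunc_norm(u[:, 4], p.loneliness_mean, p.loneliness_sd)
    return pd.DataFrame(
        {
            "trauma_lifetime": trauma,
            "financial_lifetime": financial,
            "emotional_lifetime": emotional,
            "discrimination": discrimination,
            "loneliness": loneliness,
        }
    )


def gen_expression(
    cfg: SimulationConfig,
    seed: int | None = None,
    waves: tuple[int, ...] = (2, 4),
) -> dict[int, ExpressionMatrix]:
    """miRNA count matrices per wave, sharing per-participant latent abundances."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    e = cfg.expression
    M, n = cfg.n_mirnas, cfg.n_participants
    mirna_ids = [f"sim-mir-{i + 1:04d}" for i in range(M)]

    lo, hi = e.log2_abundance_range
    base = rng.uniform(lo, hi, size=M) * np.log(2.0)  # natural-log abundance
    latent = rng.normal(0.0, e.biological_sd, size=(M, n))  # person effect, all waves
    out: dict[int, ExpressionMatrix] = {}
    for w in waves:
        fluct = rng.normal(0.0, e.wave_sd, size=(M, n))
        lam = np.exp(base[:, None] + latent + fluct)
        frac = lam / lam.sum(axis=0, keepdims=True)
        libs = np.exp(
            rng.uniform(np.log(e.library_size_range[0]), np.log(e.library_size_range[1]), size=n)
        )
        counts = _nb_draw(rng, frac * libs[None, :], e.count_dispersion)
        sample_ids = [f"P{i + 1:04d}_w{w}" for i in range(n)]
        out[w] = ExpressionMatrix(mirna_ids, sample_ids, counts)
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _log2_cpm(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=0)
    return np.log2(counts / totals * 1e6 + 1.0)


def gen_ptss(
    adversities: pd.DataFrame,
    expr: ExpressionMatrix,
    effects: EffectSpec,
    theta: float,
    link: str = "log",
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """NB-distributed PTSS from adversities, expression, and planted effects.

    The linear predictor uses z-scored adversities and z-scored log2-CPM
    expression, so coefficients read as effect per SD.
    """
    n = len(adversities)
    if len(expr.sample_ids) != n:
        raise ValidationError("expression and adversity sample counts disagree")
    logexpr = _log2_cpm(expr.counts)
    zadv = {a: _zscore(adversities[ADVERSITY_COLUMNS[a]].to_numpy(float)) for a in ADVERSITIES}
    eta = np.full(n, effects.resolved_intercept())
    for a, coef in effects.a.items():
        eta += coef * zadv[a]
    mirna_index = {m: i for i, m in enumerate(expr.mirna_ids)}
    for mid, coef in effects.b.items():
        eta += coef * _zscore(logexpr[mirna_index[mid]])
    c_nested: dict[str, dict[str, float]] = {}
    for (mid, adv), coef in effects.c.items():
        eta += coef * zadv[adv] * _zscore(logexpr[mirna_index[mid]])
        c_nested.setdefault(mid, {})[adv] = coef

    rng = np.random.default_rng(seed)
    n_bounded = 0
    if link == "log":
        # bound the predictor so extreme tail draws keep NB means below 1e4
        cap = float(np.log(1e4))
        n_bounded = int(np.sum(eta > cap))
        eta = np.minimum(eta, cap)
        mu = np.exp(eta)
    else:
        mu = eta
        if np.any(mu <= 0):
            raise ValidationError("identity link produced nonpositive means")
    y = _nb_draw(rng, mu, theta)
    truth = GroundTruth(
        intercept=effects.resolved_intercept(),
        a=dict(effects.a),
        b=dict(effects.b),
        c=c_nested,
        modifier_ids=sorted(c_nested),
        theta=theta,
        link=link,
        standardization="z-scored adversities and z-scored log2(CPM+1) expression",
        eta={"values": eta.tolist(), "n_bounded": n_bounded},
    )
    return y, truth


@dataclass
class CohortBundle:
    pheno: PhenotypeTable
    expr: dict[int, ExpressionMatrix]
    truth: GroundTruth
    config: SimulationConfig


def default_planted_effects(cfg: SimulationConfig) -> EffectSpec:
    """Resolve the effect spec, planting trauma modifiers when none are given."""
    eff = cfg.effects
    if eff.c or cfg.n_modifiers == 0:
        return eff
    ids = [f"sim-mir-{i + 1:04d}" for i in range(cfg.n_mirnas)]
    rng = np.random.default_rng(cfg.seed + 2)
    chosen = sorted(rng.choice(cfg.n_mirnas, size=min(cfg.n_modifiers, cfg.n_mirnas), replace=False))
    if cfg.modifier_adversity == "spread":
        targets = [ADVERSITIES[k % len(ADVERSITIES)] for k in range(len(chosen))]
    else:
        targets = [cfg.modifier_adversity] * len(chosen)
    c = {(ids[i], adv): cfg.modifier_effect for i, adv in zip(chosen, targets)}
    return EffectSpec(
        intercept=eff.intercept, target_mean=eff.target_mean, a=dict(eff.a), b=dict(eff.b), c=c
    )


def gen_dataset(cfg: SimulationConfig, outdir: str | Path | None = None) -> CohortBundle:
    """Full cohort bundle: phenotypes (waves 2-4), expression (waves 2 and 4).

    PTSS at waves 2 and 3 is generated from wave-2 expression, PTSS at wave
    4 from wave-4 expression, all under the same planted effect spec, so
    modulation signal is consistent across waves (within-person expression
    is shared up to wave noise).  Adversities are lifetime profiles, fixed
    per participant.
    """
    cfg.validate()
    adversities = gen_adversities(cfg)
    expr = gen_expression(cfg)
    effects = default_planted_effects(cfg)

    rows = []
    truth = None
    eta_store: dict[str, list[float]] = {}
    for wave, src_wave in ((2, 2), (3, 2), (4, 4)):
        y, t = gen_ptss(
            adversities, expr[src_wave], effects, cfg.theta, cfg.link,
            seed=cfg.seed + 10 + wave,
        )
        truth = t
        eta_store[str(wave)] = t.eta["values"]
        for i in range(cfg.n_participants):
            pid = f"P{i + 1:04d}"
            rows.append(
                {
                    "sample_id": f"{pid}_w{wave}",
                    "participant_id": pid,
                    "wave": wave,
                    "ptss": int(y[i]),
                    **{col: adversities[col].iloc[i] for col in adversities.columns},
                }
            )
    assert truth is not None
    pheno = PhenotypeTable(pd.DataFrame(rows))
    truth.eta = eta_store
    bundle = CohortBundle(pheno=pheno, expr=expr, truth=truth, config=cfg)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pheno.to_csv(outdir / "phenotypes.csv")
        for w, mat in expr.items():
            mat.to_tsv(outdir / f"counts_wave{w}.tsv")
        truth.to_json(outdir / "ground_truth.json")
        with open(outdir / "simulation_manifest.json", "w") as fh:
            json.dump(
                {"config": _config_to_dict(cfg), "seed": cfg.seed}, fh, indent=1
            )
    return bundle


def _config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["effects"]["c"] = {f"{m}|{a}": v for (m, a), v in cfg.effects.c.items()}
    return d


# ---------------------------------------------------------------------------
# synthetic target table and pathway sets (for enrichment closure)
# ---------------------------------------------------------------------------

def gen_targets_and_pathways(
    cfg: SimulationConfig,
    truth: GroundTruth,
    n_genes: int = 1500,
    targets_per_mirna: int = 30,
    n_pathways: int = 40,
    pathway_size: int = 50,
    planted_pathway_overlap: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Synthetic miRNA->gene target table and pathway sets.

    Planted-modifier miRNAs draw a fraction of their targets from the first
    pathway's gene pool, so that pathway is genuinely over-represented in
    the hits' pooled targets.  Scores are uniform on [50, 100]; the default
    binding-score cutoff of 80 keeps roughly the top 40%.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    genes = [f"SIMG{i + 1:05d}" for i in range(n_genes)]
    pathways: dict[str, list[str]] = {}
    for j in range(n_pathways):
        members = rng.choice(n_genes, size=pathway_size, replace=False)
        pathways[f"SIMPATH{j + 1:03d}"] = [genes[i] for i in sorted(members)]
    planted_pool = pathways["SIMPATH001"]

    mirna_ids = [f"sim-mir-{i + 1:04d}" for i in range(cfg.n_mirnas)]
    modifier = set(truth.modifier_ids)
    rows = []
    for mid in mirna_ids:
        n_t = targets_per_mirna
        if mid in modifier:
            n_planted = int(round(planted_pathway_overlap * n_t))
            chosen = list(rng.choice(planted_pool, size=n_planted, replace=False))
            chosen += [genes[i] for i in rng.choice(n_genes, size=n_t - n_planted, replace=False)]
        else:
            chosen = [genes[i] for i in rng.choice(n_genes, size=n_t, replace=False)]
        for g in dict.fromkeys(chosen):
            rows.append((mid, g, float(np.round(rng.uniform(50, 100), 2))))
    table = pd.DataFrame(rows, columns=["mirna", "gene", "score"])
    return table, pathways


def write_targets_and_pathways(
    table: pd.DataFrame, pathways: dict[str, list[str]], outdir: str | Path
) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tpath = outdir / "targets.tsv"
    table.to_csv(tpath, sep="\t", index=False)
    gpath = outdir / "pathways.gmt"
    with open(gpath, "w") as fh:
        for pid, genes in pathways.items():
            fh.write("\t".join([pid, f"synthetic pathway {pid}", *genes]) + "\n")
    return tpath, gpath
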