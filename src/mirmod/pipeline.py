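"""End-to-end orchestration: simulate -> distfit -> screen -> validate -> enrich.

A single YAML config drives the whole run; every stage writes its outputs
under the run directory and registers decisions and row counts in a
reproducibility manifest.  One master seed determines every random draw
(per-stage seeds are derived deterministically from it).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError as PydanticValidationError

from . import __version__, dist_select, enrichment, screen, synthetic, validate as validate_mod
from .data_io import ADVERSITIES, ADVERSITY_COLUMNS, align_samples, cpm_log_normalize, filter_low_expression
from .errors import ValidationError
from .nb_glm import build_design


class SimulateConfig(BaseModel):
    n_participants: int = 600
    n_mirnas: int = 200
    n_modifiers: int = 10
    modifier_effect: float = 0.15
    modifier_adversity: str = "spread"
    theta: float = 6.5


class FilterConfig(BaseModel):
    min_cpm: float = 1.0
    min_fraction: float = 0.5


class DistfitConfig(BaseModel):
    families: list[str] = list(dist_select.FAMILIES)
    bootstrap_b: int = 200
    compare: tuple[str, str] = ("negative_binomial", "gamma")


class ScreenConfig(BaseModel):
    adversities: list[str] | Literal["all"] = "all"
    pairings: list[tuple[int, int]] = [(2, 3), (4, 4)]
    fdr: float = 0.1
    standardize: bool = False
    link: str = "log"


class ValidateConfig(BaseModel):
    k: int = 10


class CrosswaveConfig(BaseModel):
    adversity: str = "trauma"
    discovery: tuple[int, int] = (2, 3)
    validation: tuple[int, int] = (4, 4)


class EnrichConfig(BaseModel):
    score_cutoff: float = 80.0
    fdr: float = 0.1


class PipelineConfig(BaseModel):
    seed: int = Field(...)  # mandatory: no silent default randomness
    simulate: SimulateConfig = SimulateConfig()
    filter: FilterConfig = FilterConfig()
    distfit: DistfitConfig = DistfitConfig()
    screen: ScreenConfig = ScreenConfig()
    validation: ValidateConfig = Field(default_factory=ValidateConfig, alias="validate")
    crosswave: CrosswaveConfig = CrosswaveConfig()
    enrich: EnrichConfig = EnrichConfig()

    model_config = {"extra": "forbid", "populate_by_name": True}


class ConfigError(ValidationError):
    """Config failed schema validation (CLI exit code 2)."""


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except PydanticValidationError as exc:
        raise ConfigError(str(exc)) from exc


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage in dependency order; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(cfg.seed).spawn(8)]
    manifest: dict = {
        "tool_version": __version__,
        "config_hash": config_hash(cfg),
        "master_seed": cfg.seed,
        "stages": {},
    }

    def _stage(name: str, **info) -> None:
        manifest["stages"][name] = {"timestamp": time.time(), **info}
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    # -- simulate -----------------------------------------------------------
    sim = cfg.simulate
    sim_cfg = synthetic.SimulationConfig(
        n_participants=sim.n_participants,
        n_mirnas=sim.n_mirnas,
        seed=seeds[0],
        theta=sim.theta,
        n_modifiers=sim.n_modifiers,
        modifier_effect=sim.modifier_effect,
        modifier_adversity=sim.modifier_adversity,
    )
    data_dir = outdir / "data"
    bundle = synthetic.gen_dataset(sim_cfg, outdir=data_dir)
    ttable, pathways = synthetic.gen_targets_and_pathways(sim_cfg, bundle.truth)
    tpath, gpath = synthetic.write_targets_and_pathways(ttable, pathways, data_dir)
    _stage(
        "simulate",
        n_participants=sim.n_participants,
        n_mirnas=sim.n_mirnas,
        planted_modifiers=bundle.truth.modifier_ids,
        seed=seeds[0],
    )

    # -- distfit ------------------------------------------------------------
    y3 = bundle.pheno.for_wave(3)["ptss"].to_numpy()
    # continuous families need strictly positive data; shift when zeros occur
    shift = bool((y3 == 0).any())
    sel = dist_select.select_distribution(y3, families=cfg.distfit.families, shift_zeros=shift)
    pd.DataFrame(
        [
            {"family": f.family, "loglik": f.loglik, "k": f.k, "n": f.n, "bic": f.bic,
             **{f"param_{k}": v for k, v in f.params.items()}}
            for f in sel.fits
        ]
    ).to_csv(outdir / "distfit.tsv", sep="\t", index=False)
    boot = dist_select.bootstrap_bic_compare(
        y3, *cfg.distfit.compare, B=cfg.distfit.bootstrap_b, seed=seeds[1],
        shift_zeros=shift,
    )
    with open(outdir / "distfit_bootstrap.json", "w") as fh:
        json.dump(
            {
                "family_a": boot.family_a, "family_b": boot.family_b,
                "mean_delta_bic": boot.mean_delta, "p": boot.p,
                "n_replicates": boot.n_replicates, "n_failed": boot.n_failed,
            },
            fh, indent=1,
        )
    _stage(
        "distfit", ranking=sel.rank(), failures=sel.failures, bootstrap_p=boot.p,
        shift_zeros=shift,
    )

    # -- screen -------------------------------------------------------------
    adversities = list(ADVERSITIES) if cfg.screen.adversities == "all" else cfg.screen.adversities
    screen_records: dict[tuple[str, tuple[int, int]], list[screen.ScreenRecord]] = {}
    counts: dict[str, dict] = {}
    for pairing in cfg.screen.pairings:
        expr = bundle.expr.get(pairing[0])
        if expr is None:
            raise ValidationError(f"no expression matrix for wave {pairing[0]}")
        expr = filter_low_expression(expr, cfg.filter.min_cpm, cfg.filter.min_fraction)
        norm = cpm_log_normalize(expr)
        aligned = align_samples(norm, bundle.pheno, *pairing)
        aligned.write_dropped_manifest(outdir / f"dropped_w{pairing[0]}w{pairing[1]}.tsv")
        tag = f"w{pairing[0]}_w{pairing[1]}"
        main = screen.main_effect_screen(aligned, link=cfg.screen.link, standardize=cfg.screen.standardize)
        screen.write_records(main, outdir / f"screen_main_{tag}.tsv")
        counts[f"main_{tag}"] = {
            "n_mirnas": len(main),
            "hits": len(screen.significant_hits(main, cfg.screen.fdr)),
        }
        for adv in adversities:
            recs = screen.interaction_screen(
                aligned, adversity_j=adv, link=cfg.screen.link, standardize=cfg.screen.standardize
            )
            screen_records[(adv, pairing)] = recs
            screen.write_records(recs, outdir / f"screen_interaction_{adv}_{tag}.tsv")
            counts[f"interaction_{adv}_{tag}"] = {
                "n_mirnas": len(recs),
                "hits": len(screen.significant_hits(recs, cfg.screen.fdr)),
            }
    _stage(
        "screen",
        fdr_family="BH within each (adversity, wave-pair) screen",
        fdr_threshold=cfg.screen.fdr,
        link=cfg.screen.link,
        counts=counts,
    )

    # -- validate -----------------------------------------------------------
    w3 = bundle.pheno.for_wave(3).dropna(subset=["ptss"])
    X = build_design(w3.rename(columns={v: k for k, v in ADVERSITY_COLUMNS.items()}), list(ADVERSITIES))
    cv = validate_mod.kfold_cv_spearman(
        w3["ptss"].to_numpy(), X, k=cfg.validation.k, seed=seeds[2]
    )
    cw = cfg.crosswave
    disc = screen_records.get((cw.adversity, tuple(cw.discovery)))
    vali = screen_records.get((cw.adversity, tuple(cw.validation)))
    crosswave_out: dict = {"skipped": True}
    if disc is not None and vali is not None:
        hit_ids = {r.mirna_id for r in screen.significant_hits(disc, cfg.screen.fdr)}
        scores = {r.mirna_id: r.score for r in vali if r.score is not None}
        hit_ids &= set(scores)
        if hit_ids and hit_ids < set(scores):
            W, p = validate_mod.cross_wave_consistency(scores, hit_ids)
            crosswave_out = {"skipped": False, "W": W, "p": p, "n_hits": len(hit_ids)}
    with open(outdir / "validation.json", "w") as fh:
        json.dump(
            {
                "cv": {"k": cv.k, "mean_rho": cv.mean_rho, "per_fold_rho": cv.per_fold_rho,
                       "model": cv.model_spec},
                "crosswave": crosswave_out,
            },
            fh, indent=1,
        )
    _stage("validate", cv_mean_rho=cv.mean_rho, crosswave=crosswave_out)

    # -- enrich -------------------------------------------------------------
    targets = enrichment.read_target_table(tpath, score_cutoff=cfg.enrich.score_cutoff)
    sets = enrichment.read_gmt(gpath)
    cwadv, cwpair = cw.adversity, tuple(cw.discovery)
    hits = screen.significant_hits(screen_records.get((cwadv, cwpair), []), cfg.screen.fdr)
    hit_ids = [r.mirna_id for r in hits if r.mirna_id in targets.mirnas]
    if hit_ids:
        table = enrichment.enrich_all(hit_ids, targets, sets, fdr_threshold=cfg.enrich.fdr)
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        n_sig = int(table["significant"].sum())
    else:
        n_sig = 0
    _stage(
        "enrich",
        universe="target-table genes union pathway genes",
        score_cutoff=cfg.enrich.score_cutoff,
        n_hit_mirnas=len(hit_ids),
        n_significant_pathways=n_sig,
    )

    return manifest
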