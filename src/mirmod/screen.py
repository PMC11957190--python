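"""Transcriptome-wide screens for miRNA effects on PTSS.

Two screens over every miRNA in an aligned analysis set:

* main effect -- PTSS ~ sum_i a_i * adversity_i + b * miRNA, testing b;
* interaction -- PTSS ~ sum_i a_i * adversity_i + b * miRNA
  + c * (adversity_j * miRNA), testing the moderation coefficient c.

All five adversities are retained additively in both screens, so each
interaction test controls for the remaining exposures.  The modulation
score of a miRNA is the Wald z of c (c divided by its standard error):
positive scores mean higher expression strengthens the adversity-PTSS
association, negative scores mean it buffers it.  Per screen, two-sided
Wald p-values are Benjamini-Hochberg adjusted across the miRNA axis and
hits are declared at q strictly below the FDR threshold (default 0.1).

Non-estimable miRNAs (constant expression) and non-converged fits are
excluded from the FDR denominator and carried through flagged, never
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nb_glm
from .data_io import (
    ADVERSITIES,
    ADVERSITY_COLUMNS,
    AlignedSet,
    NormalizedExpression,
    PhenotypeTable,
    align_samples,
)
from .errors import FitError, ValidationError

_MIRNA_TERM = "mirna"
_INTERACTION_TERM = "adversity_x_mirna"


@dataclass
class ScreenRecord:
    """One (miRNA, adversity, wave-pair) test result."""

    mirna_id: str
    adversity: str  # one of ADVERSITIES, or "none" for the main-effect screen
    expr_wave: int
    outcome_wave: int
    estimate: float | None
    se: float | None
    score: float | None  # modulation score z = estimate / se
    p: float | None
    q: float | None
    n_used: int
    converged: bool
    note: str = ""


def modulation_score(estimate: float, se: float) -> float:
    """Wald z of the interaction coefficient: estimate / se."""
    if se <= 0:
        raise ValidationError("standard error must be positive")
    return estimate / se


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def median_stratify(expr_row) -> np.ndarray:
    """Binary high/low labels about the median (ties go to low)."""
    x = np.asarray(expr_row, dtype=float)
    if x.size == 0:
        raise ValidationError("empty expression vector")
    return (x > np.median(x)).astype(int)


def _resolve_aligned(
    expr: NormalizedExpression | AlignedSet,
    pheno: PhenotypeTable | None,
    pairing: tuple[int, int] | None,
) -> AlignedSet:
    if isinstance(expr, AlignedSet):
        return expr
    if pheno is None or pairing is None:
        raise ValidationError("pass either an AlignedSet or (expr, pheno, pairing)")
    return align_samples(expr, pheno, pairing[0], pairing[1])


def _run_screen(
    aligned: AlignedSet,
    adversity_j: str | None,
    link: str,
    standardize: bool,
) -> list[ScreenRecord]:
    pheno = aligned.pheno
    missing = [
        ADVERSITY_COLUMNS[a] for a in ADVERSITIES if ADVERSITY_COLUMNS[a] not in pheno
    ]
    if missing:
        raise ValidationError(f"phenotype table missing adversity columns: {missing}")
    if adversity_j is not None and adversity_j not in ADVERSITIES:
        raise ValidationError(f"unknown adversity {adversity_j!r}")

    base = pd.DataFrame(
        {a: pheno[ADVERSITY_COLUMNS[a]].to_numpy(dtype=float) for a in ADVERSITIES}
    )
    y_all = pheno["ptss"].to_numpy(dtype=float)
    complete = ~(base.isna().any(axis=1) | np.isnan(y_all))
    base = base.loc[complete.to_numpy()].reset_index(drop=True)
    y = y_all[complete.to_numpy()]
    V = aligned.expr.values_matrix[:, complete.to_numpy()].astype(float)

    records: list[ScreenRecord] = []
    ew, ow = aligned.expr_wave, aligned.outcome_wave
    label = adversity_j if adversity_j is not None else "none"
    term = _INTERACTION_TERM if adversity_j is not None else _MIRNA_TERM
    for i, mid in enumerate(aligned.expr.mirna_ids):
        x = V[i]
        sd = x.std()
        if sd == 0:
            records.append(
                ScreenRecord(
                    mid, label, ew, ow, None, None, None, None, None,
                    n_used=len(y), converged=False, note="non-estimable: constant expression",
                )
            )
            continue
        xm = (x - x.mean()) / sd if standardize else x
        X = base.copy()
        X.insert(0, "intercept", 1.0)
        X[_MIRNA_TERM] = xm
        if adversity_j is not None:
            X[_INTERACTION_TERM] = X[adversity_j].to_numpy() * xm
        try:
            fit = nb_glm.fit_nb(y, X, link=link)
        except (FitError, ValidationError) as exc:
            records.append(
                ScreenRecord(
                    mid, label, ew, ow, None, None, None, None, None,
                    n_used=len(y), converged=False, note=f"fit failed: {exc}",
                )
            )
            continue
        if not fit.converged:
            records.append(
                ScreenRecord(
                    mid, label, ew, ow, None, None, None, None, None,
                    n_used=fit.n_used, converged=False, note="did not converge",
                )
            )
            continue
        est = float(fit.params[term])
        se = float(fit.se[term])
        z, p = nb_glm.wald_test(fit, term)
        records.append(
            ScreenRecord(
                mid, label, ew, ow, est, se, z, p, None,
                n_used=fit.n_used, converged=True,
            )
        )

    # BH across the estimable miRNA axis of this screen only
    ok = [r for r in records if r.converged]
    if ok:
        q = bh_fdr([r.p for r in ok])
        for r, qi in zip(ok, q):
            r.q = float(qi)
    return records


def main_effect_screen(
    expr: NormalizedExpression | AlignedSet,
    pheno: PhenotypeTable | None = None,
    pairing: tuple[int, int] | None = None,
    link: str = "log",
    standardize: bool = False,
) -> list[ScreenRecord]:
    """Per-miRNA Wald test of the miRNA main effect b, FDR-adjusted."""
    aligned = _resolve_aligned(expr, pheno, pairing)
    return _run_screen(aligned, None, link, standardize)


def interaction_screen(
    expr: NormalizedExpression | AlignedSet,
    pheno: PhenotypeTable | None = None,
    adversity_j: str = "trauma",
    pairing: tuple[int, int] | None = None,
    link: str = "log",
    standardize: bool = False,
) -> list[ScreenRecord]:
    """Per-miRNA Wald test of the adversity_j x miRNA interaction c."""
    aligned = _resolve_aligned(expr, pheno, pairing)
    return _run_screen(aligned, adversity_j, link, standardize)


def significant_hits(records: list[ScreenRecord], fdr_threshold: float = 0.1) -> list[ScreenRecord]:
    """Records with q strictly below the threshold, by q then |score| descending."""
    hits = [r for r in records if r.q is not None and r.q < fdr_threshold]
    hits.sort(key=lambda r: (r.q, -abs(r.score)))
    return hits


def records_to_frame(records: list[ScreenRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def write_records(records: list[ScreenRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
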