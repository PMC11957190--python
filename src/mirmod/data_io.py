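"""Tabular input/output and survey aggregation.

Containers for the two primary inputs of the analysis -- a per-sample
phenotype table and a miRNA x sample count matrix -- together with the
arithmetic that builds the analysis variables from raw survey items:

* PTSS (post-traumatic stress symptom severity) is the PCL-C checklist sum
  over 17 symptoms, each scored 1-5, hence ranging 17-85.
* Lifetime cumulative trauma is the sum of per-wave trauma counts.
* Lifetime binary stressors (financial problems, emotional mistreatment)
  are "ever experienced" indicators across waves.
* Perceived discrimination (9-item Everyday Discrimination Scale) and
  loneliness (3-item scale) are item sums (means available by flag).

Expression handling is log2(CPM+1) normalization with a configurable
low-expression filter, and wave-aware alignment of expression samples to
outcome phenotypes (e.g. wave-2 expression paired with wave-3 outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The five social-adversity exposures, keyed by short name.
ADVERSITIES = ("trauma", "financial", "emotional", "discrimination", "loneliness")

#: Phenotype-table column carrying each adversity.
ADVERSITY_COLUMNS = {
    "trauma": "trauma_lifetime",
    "financial": "financial_lifetime",
    "emotional": "emotional_lifetime",
    "discrimination": "discrimination",
    "loneliness": "loneliness",
}

PHENO_REQUIRED_COLUMNS = (
    "sample_id",
    "participant_id",
    "wave",
    "ptss",
    "trauma_lifetime",
    "financial_lifetime",
    "emotional_lifetime",
    "discrimination",
    "loneliness",
)

#: Optional covariate columns recognised by the schema.
COVARIATE_COLUMNS = (
    "age",
    "sex",
    "prs",
    "cell_bcell",
    "cell_cd8t",
    "cell_cd4t",
    "cell_nk",
    "cell_mono",
    "cell_gran",
)

_CELL_COLUMNS = tuple(c for c in COVARIATE_COLUMNS if c.startswith("cell_"))


# ---------------------------------------------------------------------------
# survey aggregation
# ---------------------------------------------------------------------------

def ptss_from_items(items: Sequence[float]) -> int:
    """Sum the 17 PCL-C symptom items (each 1-5) into a PTSS score in [17, 85]."""
    items = np.asarray(items, dtype=float)
    if items.shape != (17,):
        raise ValidationError(f"PCL-C requires exactly 17 items, got {items.size}")
    if np.any(items < 1) or np.any(items > 5) or np.any(items != np.round(items)):
        raise ValidationError("PCL-C items must be integers in [1, 5]")
    return int(items.sum())


def lifetime_trauma(per_wave_counts: Sequence[float]) -> int:
    """Total cumulative trauma exposure across all reported waves."""
    counts = np.asarray(per_wave_counts, dtype=float)
    if counts.size == 0:
        raise ValidationError("at least one wave of trauma counts is required")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValidationError("trauma counts must be nonnegative integers")
    return int(counts.sum())


def lifetime_any(per_wave_flags: Sequence[float]) -> int:
    """Ever-experienced indicator: 1 iff any wave flag is 1."""
    flags = np.asarray(per_wave_flags, dtype=float)
    if flags.size == 0:
        raise ValidationError("at least one wave of flags is required")
    if not np.all(np.isin(flags, (0, 1))):
        raise ValidationError("stressor flags must be binary (0/1)")
    return int(flags.any())


def scale_score(items: Sequence[float], expected_len: int, *, mean: bool = False) -> float:
    """Aggregate a multi-item scale (9-item discrimination, 3-item loneliness).

    Items are summed by default; ``mean=True`` averages instead.
    """
    items = np.asarray(items, dtype=float)
    if items.size != expected_len:
        raise ValidationError(
            f"scale expects {expected_len} items, got {items.size}"
        )
    return float(items.mean() if mean else items.sum())


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Per-sample outcome, adversity, covariate and wave-label records."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENO_REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        dup = self.df["sample_id"][self.df["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicated sample_id values: {sorted(set(dup))}")
        for col in ("financial_lifetime", "emotional_lifetime"):
            vals = self.df[col].dropna()
            if not vals.isin((0, 1)).all():
                raise ValidationError(f"{col} must be binary (0/1)")
        for col in ("ptss", "trauma_lifetime", "discrimination", "loneliness"):
            vals = self.df[col].dropna()
            if (vals < 0).any():
                raise ValidationError(f"{col} must be nonnegative")
        for col in _CELL_COLUMNS:
            if col in self.df.columns:
                vals = self.df[col].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise ValidationError(f"{col} proportions must lie in [0, 1]")
        # one biospecimen per participant per wave: duplicates are an error
        dup_pw = self.df.duplicated(subset=["participant_id", "wave"])
        if dup_pw.any():
            bad = self.df.loc[dup_pw, ["participant_id", "wave"]]
            raise ValidationError(
                f"duplicate participant/wave records: {bad.values.tolist()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def for_wave(self, wave: int) -> pd.DataFrame:
        return self.df[self.df["wave"] == wave]

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhenotypeTable":
        df = pd.read_csv(
            path,
            dtype={"sample_id": str, "participant_id": str},
            float_precision="round_trip",
        )
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        # %.17g round-trips IEEE doubles exactly through text
        self.df.to_csv(path, index=False, float_format="%.17g")


@dataclass
class ExpressionMatrix:
    """miRNA x sample matrix of nonnegative integer read counts."""

    mirna_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.sample_ids)} samples"
            )
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValidationError("duplicated miRNA ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicated sample ids")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")
        if np.any(self.counts != np.round(self.counts)):
            raise ValidationError("counts must be integer-valued")
        self.counts = self.counts.astype(np.int64)

    @property
    def values_matrix(self) -> np.ndarray:
        return self.counts

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=self.mirna_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="mirna_id"
        )


@dataclass
class NormalizedExpression:
    """log2(CPM+1)-normalized twin of :class:`ExpressionMatrix`."""

    mirna_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise ValidationError("value matrix shape does not match id lists")
        if np.any(self.values < 0):
            raise ValidationError("log2(CPM+1) values must be nonnegative")

    @property
    def values_matrix(self) -> np.ndarray:
        return self.values

    def row(self, mirna_id: str) -> np.ndarray:
        return self.values[self.mirna_ids.index(mirna_id)]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NormalizedExpression":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.mirna_ids, columns=self.sample_ids).to_csv(
            path, sep="\t", index_label="mirna_id", float_format="%.17g"
        )


# ---------------------------------------------------------------------------
# expression preprocessing
# ---------------------------------------------------------------------------

def cpm(expr: ExpressionMatrix) -> np.ndarray:
    """Counts-per-million matrix; errors on zero-total samples."""
    totals = expr.counts.sum(axis=0)
    zero = np.asarray(totals == 0).nonzero()[0]
    if zero.size:
        names = [expr.sample_ids[i] for i in zero]
        raise ValidationError(f"samples with zero total counts: {names}")
    return expr.counts / totals * 1e6


def cpm_log_normalize(expr: ExpressionMatrix) -> NormalizedExpression:
    """log2(CPM + 1) normalization, the default expression scale downstream."""
    return NormalizedExpression(
        list(expr.mirna_ids), list(expr.sample_ids), np.log2(cpm(expr) + 1.0)
    )


def filter_low_expression(
    expr: ExpressionMatrix, min_cpm: float = 1.0, min_fraction: float = 0.5
) -> ExpressionMatrix:
    """Retain miRNAs with CPM >= ``min_cpm`` in at least ``min_fraction`` of samples."""
    if not 0 <= min_fraction <= 1:
        raise ValidationError("min_fraction must lie in [0, 1]")
    frac = (cpm(expr) >= min_cpm).mean(axis=1)
    keep = frac >= min_fraction
    return ExpressionMatrix(
        [m for m, k in zip(expr.mirna_ids, keep) if k],
        list(expr.sample_ids),
        expr.counts[keep],
    )


# ---------------------------------------------------------------------------
# wave-aware alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedSet:
    """One row per participant joining outcome-wave phenotypes to expression.

    ``expr`` keeps its miRNA axis but its columns are reordered (and
    relabelled to participant ids) to match ``pheno`` rows.  ``dropped``
    is a manifest of records excluded by the join and why.
    """

    participants: list[str]
    pheno: pd.DataFrame  # indexed by participant_id, outcome-wave rows
    expr: NormalizedExpression | ExpressionMatrix
    expr_wave: int
    outcome_wave: int
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason"])
    )

    @property
    def n(self) -> int:
        return len(self.participants)

    def write_dropped_manifest(self, path: str | Path) -> None:
        self.dropped.to_csv(path, sep="\t", index=False)


def align_samples(
    expr: ExpressionMatrix | NormalizedExpression,
    pheno: PhenotypeTable,
    expr_wave: int,
    outcome_wave: int,
) -> AlignedSet:
    """Pair expression samples from one wave with outcomes from another.

    Expression columns are resolved to participants through the phenotype
    rows of ``expr_wave``; outcomes and adversities come from the rows of
    ``outcome_wave``.  Returns the participant intersection plus a manifest
    of every dropped record with its reason.
    """
    expr_rows = pheno.for_wave(expr_wave)
    out_rows = pheno.for_wave(outcome_wave).set_index("participant_id")
    sample_to_participant = dict(
        zip(expr_rows["sample_id"], expr_rows["participant_id"])
    )

    dropped: list[tuple[str, str]] = []
    participants: list[str] = []
    col_idx: list[int] = []
    for j, sid in enumerate(expr.sample_ids):
        pid = sample_to_participant.get(sid)
        if pid is None:
            dropped.append((sid, f"no wave-{expr_wave} phenotype record"))
            continue
        if pid not in out_rows.index:
            dropped.append((sid, f"participant lacks wave-{outcome_wave} outcome"))
            continue
        if pd.isna(out_rows.loc[pid, "ptss"]):
            dropped.append((sid, f"missing PTSS at wave {outcome_wave}"))
            continue
        participants.append(pid)
        col_idx.append(j)

    for sid, pid in sample_to_participant.items():
        if sid not in expr.sample_ids:
            dropped.append((sid, "no expression profile"))

    if not participants:
        raise ValidationError(
            f"no participants shared between wave-{expr_wave} expression and "
            f"wave-{outcome_wave} outcomes"
        )

    sub = expr.values_matrix[:, col_idx]
    if isinstance(expr, ExpressionMatrix):
        expr_out: ExpressionMatrix | NormalizedExpression = ExpressionMatrix(
            list(expr.mirna_ids), participants, sub
        )
    else:
        expr_out = NormalizedExpression(list(expr.mirna_ids), participants, sub)

    return AlignedSet(
        participants=participants,
        pheno=out_rows.loc[participants],
        expr=expr_out,
        expr_wave=expr_wave,
        outcome_wave=outcome_wave,
        dropped=pd.DataFrame(dropped, columns=["sample_id", "reason"]),
    )
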