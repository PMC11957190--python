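"""Target-gene pathway enrichment for screened miRNAs.

Significant miRNAs are mapped to their predicted target genes (miRDB-style
table, binding score >= 80 by default), the targets are pooled as a set
union, and each pathway gene set is tested for over-representation with an
upper-tail hypergeometric test.  Pathway p-values are Benjamini-Hochberg
adjusted and terms with q < 0.1 flagged as enriched.

The gene universe defaults to all genes in the score-filtered target table
united with all pathway genes; an explicit universe can be supplied.  The
universe is the dominant analytic degree of freedom here and is always
recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .screen import bh_fdr


@dataclass
class TargetTable:
    """Score-filtered miRNA -> target-gene mapping."""

    df: pd.DataFrame  # columns: mirna, gene, score
    score_cutoff: float = 80.0

    def targets_of(self, mirna_ids: Iterable[str]) -> set[str]:
        ids = set(mirna_ids)
        return set(self.df.loc[self.df["mirna"].isin(ids), "gene"])

    @property
    def genes(self) -> set[str]:
        return set(self.df["gene"])

    @property
    def mirnas(self) -> set[str]:
        return set(self.df["mirna"])


@dataclass
class GeneSetCollection:
    """Named pathway gene sets plus the gene universe they live in."""

    sets: dict[str, tuple[str, frozenset[str]]]  # id -> (name, genes)
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        all_genes = frozenset().union(*(g for _, g in self.sets.values())) if self.sets else frozenset()
        if not self.universe:
            self.universe = all_genes
        elif not all_genes <= self.universe:
            raise ValidationError("every pathway gene must belong to the universe")
        for pid, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"pathway {pid} has an empty gene set")


def read_target_table(path: str | Path, score_cutoff: float = 80.0) -> TargetTable:
    """Read a (mirna, gene, score) TSV, keep rows with score >= cutoff.

    Duplicate (mirna, gene) pairs are collapsed keeping the maximum score.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = [c.lower() for c in df.columns]
    if not {"mirna", "gene", "score"} <= set(cols):
        raise ValidationError(
            f"target table must have columns (mirna, gene, score), got {list(df.columns)}"
        )
    df.columns = cols
    score = pd.to_numeric(df["score"], errors="coerce")
    bad = np.asarray(~np.isfinite(score)).nonzero()[0]
    if bad.size:
        # +2: header line plus 1-based numbering
        raise ValidationError(f"malformed score at line {int(bad[0]) + 2} of {path}")
    df = df.assign(score=score)
    df = (
        df.sort_values("score")
        .drop_duplicates(subset=["mirna", "gene"], keep="last")
        .sort_index()
    )
    df = df[df["score"] >= score_cutoff].reset_index(drop=True)
    return TargetTable(df=df[["mirna", "gene", "score"]], score_cutoff=score_cutoff)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read pathway gene sets in GMT format (name, description, genes...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not any(g.strip() for g in fields[2:]):
                warnings.warn(f"skipping gene set with no genes at line {lineno}")
                continue
            pid, name = fields[0], fields[1]
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets[pid] = (name, genes)
    if not sets:
        raise ValidationError(f"no gene sets found in {path}")
    return GeneSetCollection(
        sets=sets, universe=frozenset(universe) if universe is not None else frozenset()
    )


def hypergeom_enrich(target_genes: set, pathway: set, universe: set) -> float:
    """Upper-tail hypergeometric p-value P(X >= overlap).

    The draw is targets intersected with the universe; the urn's successes
    are the pathway genes.
    """
    if not universe:
        raise ValidationError("gene universe is empty")
    if not set(pathway) <= set(universe):
        raise ValidationError("pathway must be a subset of the universe")
    draws = set(target_genes) & set(universe)
    k = len(draws & set(pathway))
    return float(stats.hypergeom.sf(k - 1, len(universe), len(pathway), len(draws)))


def enrich_all(
    hit_mirnas: Iterable[str],
    targets: TargetTable,
    sets: GeneSetCollection,
    fdr_threshold: float = 0.1,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test every pathway for over-representation of the hits' pooled targets.

    Returns the full table (pathway_id, name, overlap, K, n, N, p, q,
    significant) sorted by p; significance is q < ``fdr_threshold``.
    """
    hit_mirnas = set(hit_mirnas)
    if not hit_mirnas:
        raise ValidationError("no hit miRNAs supplied")
    orphan = sorted(m for m in hit_mirnas if not targets.targets_of([m]))
    if orphan:
        raise ValidationError(f"hit miRNAs with no retained targets: {orphan}")
    pooled = targets.targets_of(hit_mirnas)
    uni = set(universe) if universe is not None else targets.genes | set(sets.universe)
    draws = pooled & uni

    rows = []
    for pid, (name, genes) in sets.sets.items():
        gene_set = set(genes) & uni
        k = len(draws & gene_set)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(gene_set), len(draws)))
        rows.append((pid, name, k, len(gene_set), len(draws), len(uni), p))
    table = pd.DataFrame(
        rows, columns=["pathway_id", "name", "overlap", "K", "n", "N", "p"]
    )
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["significant"] = table["q"] < fdr_threshold
    return table.sort_values(["p", "pathway_id"], kind="stable").reset_index(drop=True)
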