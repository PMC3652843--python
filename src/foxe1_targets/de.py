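"""Differential-expression significance filtering and two-comparison intersection.

The screening design compares FoxE1-silenced thyroid cells against both
wild-type and scrambled-siRNA controls; a gene counts as FoxE1-regulated
only if it is significant (adjusted p strictly below 0.005) in *both*
comparisons with a consistent direction.  This module consumes
probe-level result tables (probe, gene, log2 fold change, adjusted p-value)
produced upstream by a linear-model fit; it never re-adjusts p-values.

Probe-to-gene collapse: unannotated probes (empty gene symbol) count toward
probe totals but are dropped from gene-level calls with a logged count,
and genes whose significant probes disagree in fold-change sign are
excluded (conservative handling, logged) rather than majority-voted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.005

#: separators that mark a probe annotated to multiple genes
_MULTI_GENE_SEPS = (";", ",", "|", "///")


@dataclass(frozen=True)
class DERecord:
    """One probe-level differential-expression result."""

    probe: str
    gene: str  # empty string for unannotated probes
    logfc: float
    adj_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.adj_p <= 1.0:
            raise ValueError(f"probe {self.probe}: adj_p {self.adj_p} outside [0, 1]")


@dataclass(frozen=True)
class GeneCall:
    """Gene-level call within one comparison."""

    gene: str
    direction: str  # "up" or "down"
    n_probes_supporting: int


@dataclass(frozen=True)
class DEGeneCall:
    """Gene-level verdict after the two-comparison intersection."""

    gene: str
    direction: str
    n_probes_supporting: int
    comparisons: frozenset[str]


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a tab-delimited DE table with header ``probe gene logfc adj_p``.

    Probes annotated to multiple genes (separator characters in the gene
    field) are rejected at load with a warning; probes must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe": str, "gene": str})
    required = {"probe", "gene", "logfc", "adj_p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    if df["probe"].duplicated().any():
        dups = df.loc[df["probe"].duplicated(), "probe"].tolist()
        raise ValueError(f"duplicate probe ids: {dups[:5]}")
    df["gene"] = df["gene"].fillna("")
    multi = df["gene"].str.contains("|".join(map(re.escape, _MULTI_GENE_SEPS)))
    if multi.any():
        logger.warning(
            "dropping %d probes annotated to multiple genes", int(multi.sum())
        )
        df = df[~multi]
    return [
        DERecord(probe=r.probe, gene=r.gene, logfc=float(r.logfc), adj_p=float(r.adj_p))
        for r in df.itertuples(index=False)
    ]


def filter_significant(
    table: Iterable[DERecord], alpha: float = DEFAULT_ALPHA
) -> list[DERecord]:
    """Keep records with adjusted p strictly below ``alpha``.

    The threshold is strict ("<"), so records sitting exactly at ``alpha``
    are excluded.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1]")
    out = [rec for rec in table if rec.adj_p < alpha]
    logger.info("significance filter (adj_p < %g): %d records survive", alpha, len(out))
    return out


def collapse_probes(records: Sequence[DERecord]) -> list[GeneCall]:
    """Collapse significance-filtered probes to gene-level directional calls."""
    n_unannotated = sum(1 for r in records if not r.gene)
    if n_unannotated:
        logger.info("dropping %d unannotated probes from gene-level calls", n_unannotated)
    by_gene: dict[str, list[DERecord]] = {}
    for rec in records:
        if rec.gene:
            by_gene.setdefault(rec.gene, []).append(rec)
    calls: list[GeneCall] = []
    for gene, recs in by_gene.items():
        signs = {int(np.sign(r.logfc)) for r in recs}
        if signs == {1}:
            direction = "up"
        elif signs == {-1}:
            direction = "down"
        else:
            logger.warning(
                "gene %s excluded: significant probes disagree in direction "
                "(signs %s)", gene, sorted(signs),
            )
            continue
        calls.append(GeneCall(gene=gene, direction=direction, n_probes_supporting=len(recs)))
    return calls


def intersect_comparisons(
    a: Sequence[GeneCall],
    b: Sequence[GeneCall],
    labels: tuple[str, str] = ("siFoxE1_vs_siScramble", "siFoxE1_vs_wt"),
) -> tuple[list[DEGeneCall], dict[str, int]]:
    """Genes significant in both comparisons with matching direction.

    Returns the intersected calls plus a summary block
    ``{"total": ..., "up": ..., "down": ...}`` with total == up + down.
    Direction conflicts between the two comparisons exclude the gene.
    """
    b_by_gene = {c.gene: c for c in b}
    calls: list[DEGeneCall] = []
    for ca in a:
        cb = b_by_gene.get(ca.gene)
        if cb is None:
            continue
        if ca.direction != cb.direction:
            logger.warning(
                "gene %s excluded from intersection: %s in %s but %s in %s",
                ca.gene, ca.direction, labels[0], cb.direction, labels[1],
            )
            continue
        calls.append(
            DEGeneCall(
                gene=ca.gene,
                direction=ca.direction,
                n_probes_supporting=ca.n_probes_supporting + cb.n_probes_supporting,
                comparisons=frozenset(labels),
            )
        )
    calls.sort(key=lambda c: c.gene)
    summary = {
        "total": len(calls),
        "up": sum(1 for c in calls if c.direction == "up"),
        "down": sum(1 for c in calls if c.direction == "down"),
    }
    return calls, summary


def run_intersection(
    table_a: Iterable[DERecord],
    table_b: Iterable[DERecord],
    alpha: float = DEFAULT_ALPHA,
    labels: tuple[str, str] = ("siFoxE1_vs_siScramble", "siFoxE1_vs_wt"),
) -> tuple[list[DEGeneCall], dict]:
    """Full pipeline: filter both tables, collapse probes, intersect.

    The summary block mirrors the probes/genes layout of a two-comparison
    screening: per-comparison significant probe and gene counts plus the
    common gene counts split by direction.
    """
    sig_a = filter_significant(table_a, alpha)
    sig_b = filter_significant(table_b, alpha)
    genes_a = collapse_probes(sig_a)
    genes_b = collapse_probes(sig_b)
    calls, common = intersect_comparisons(genes_a, genes_b, labels)
    summary = {
        "alpha": alpha,
        labels[0]: {
            "probes": len(sig_a),
            "genes": len(genes_a),
            "up": sum(1 for c in genes_a if c.direction == "up"),
            "down": sum(1 for c in genes_a if c.direction == "down"),
        },
        labels[1]: {
            "probes": len(sig_b),
            "genes": len(genes_b),
            "up": sum(1 for c in genes_b if c.direction == "up"),
            "down": sum(1 for c in genes_b if c.direction == "down"),
        },
        "common": common,
    }
    return calls, summary


def calls_to_table(calls: Sequence[DEGeneCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.gene, c.direction, c.n_probes_supporting, ",".join(sorted(c.comparisons)))
            for c in calls
        ],
        columns=["gene", "direction", "n_probes_supporting", "comparisons"],
    )
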