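"""Ortholog-conservation summaries of the composite motif.

For each gene with a composite hit in its reference promoter, the promoters
of its orthologs are rescanned with the same motif definition and summarized
as: the percentage of ortholog promoters carrying at least one composite
hit, and the mean/min/max spacer length over ortholog hits.  By default the
spacer statistics pool every hit from every ortholog member; a
one-minimal-spacer-per-member mode is available behind a flag.  Percentages
and means are reported to one decimal, rounding half away from zero,
matching the display precision of published conservation tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .motif import CompositeMotifConfig, MotifHit, scan_sequence

logger = logging.getLogger(__name__)


def _round1(x: float) -> float:
    """Round to 1 decimal, half away from zero (values here are >= 0)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OrthologSet:
    """Ortholog promoter panel for one gene: (species id, sequence) pairs."""

    gene: str
    members: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        species = [sp for sp, _ in self.members]
        if len(set(species)) != len(species):
            raise ValueError(f"{self.gene}: duplicate species ids in ortholog set")


@dataclass(frozen=True)
class ConservationSummary:
    gene: str
    n_orthologs: int
    n_with_motif: int
    pct_with_motif: float
    mean_spacer: float | None  # None when no ortholog carries the motif
    min_spacer: int | None
    max_spacer: int | None


def summarize_orthologs(
    gene: str,
    orthologs: OrthologSet,
    config: CompositeMotifConfig | None = None,
    one_per_member: bool = False,
) -> ConservationSummary:
    """Scan each ortholog promoter and summarize composite-motif conservation.

    ``one_per_member=True`` contributes only the minimal spacer of each
    motif-positive member to the spacer statistics instead of pooling all
    hits of all members.
    """
    config = config or CompositeMotifConfig()
    if not orthologs.members:
        raise ValueError(f"{gene}: ortholog set is empty")
    spacers: list[int] = []
    n_with = 0
    for species, seq in orthologs.members:
        hits = scan_sequence(seq, config, source_id=f"{gene}|{species}")
        if hits:
            n_with += 1
            if one_per_member:
                spacers.append(min(h.spacer_len for h in hits))
            else:
                spacers.extend(h.spacer_len for h in hits)
    n = len(orthologs.members)
    pct = _round1(100.0 * n_with / n)
    if spacers:
        mean = _round1(sum(spacers) / len(spacers))
        lo, hi = min(spacers), max(spacers)
    else:
        mean = lo = hi = None
    return ConservationSummary(
        gene=gene, n_orthologs=n, n_with_motif=n_with, pct_with_motif=pct,
        mean_spacer=mean, min_spacer=lo, max_spacer=hi,
    )


CONSERVATION_COLUMNS = [
    "gene", "spacer_len", "strand", "annotated",
    "pct_with_motif", "mean_spacer", "min_spacer", "max_spacer",
    "n_orthologs", "n_with_motif",
]


def conservation_table(
    reference_hits: Sequence[MotifHit],
    ortholog_sets: Mapping[str, OrthologSet],
    config: CompositeMotifConfig | None = None,
    one_per_member: bool = False,
) -> pd.DataFrame:
    """One row per (gene, reference-promoter hit), joined with conservation.

    Every hit of a gene is summarized against the same ortholog panel (the
    panel is not matched to a particular motif instance), so two rows of one
    gene share their conservation columns.  Genes without an ortholog set
    get empty conservation fields and a warning.  Rows are sorted by
    ``pct_with_motif`` descending, as conservation tables are conventionally
    displayed.
    """
    config = config or CompositeMotifConfig()
    summaries: dict[str, ConservationSummary] = {}
    rows = []
    for hit in reference_hits:
        gene = hit.source_id
        if gene not in summaries:
            if gene in ortholog_sets:
                summaries[gene] = summarize_orthologs(
                    gene, ortholog_sets[gene], config, one_per_member=one_per_member
                )
            else:
                warnings.warn(f"no ortholog set for gene {gene!r}", stacklevel=2)
                summaries[gene] = ConservationSummary(
                    gene=gene, n_orthologs=0, n_with_motif=0,
                    pct_with_motif=float("nan"),
                    mean_spacer=None, min_spacer=None, max_spacer=None,
                )
        s = summaries[gene]
        rows.append(
            (
                gene, hit.spacer_len, hit.strand, hit.annotated,
                s.pct_with_motif, s.mean_spacer, s.min_spacer, s.max_spacer,
                s.n_orthologs, s.n_with_motif,
            )
        )
    df = pd.DataFrame(rows, columns=CONSERVATION_COLUMNS)
    return df.sort_values(
        "pct_with_motif", ascending=False, kind="stable", na_position="last"
    ).reset_index(drop=True)
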