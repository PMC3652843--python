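"""Sequence and interval I/O with explicit coordinate conventions.

All coordinates are 0-based, half-open internally; BED output follows the
same convention.  Promoter windows are anchored on the transcription start
site (TSS) of each gene and oriented 5'->3' on the gene's coding strand, so
position 0 of an extracted sequence is always the most-upstream base with
respect to the gene.

Only the characters A, C, G, T and N are accepted in sequences; other IUPAC
ambiguity codes are rejected at read time because the downstream scanner's
matching semantics are defined over this alphabet only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


def _validate_seq(seq: str, context: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(
            f"{context} contains characters outside A/C/G/T/N: {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence in uppercase canonical form."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "seq", _validate_seq(self.seq, f"record {self.id!r}"))

    def __len__(self) -> int:
        return len(self.seq)


class SequenceSet:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    def __init__(self, records: Iterable[SequenceRecord] = ()) -> None:
        self._records: dict[str, SequenceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SequenceRecord) -> None:
        if rec.id in self._records:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        self._records[rec.id] = rec

    def __getitem__(self, key: str) -> SequenceRecord:
        return self._records[key]

    def __contains__(self, key: str) -> bool:
        return key in self._records

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def ids(self) -> list[str]:
        return list(self._records)


@dataclass(frozen=True)
class GeneAnnotation:
    """TSS anchor for one gene: symbol, contig, 0-based position, strand."""

    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene}: tss must be >= 0")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene}: strand must be '+' or '-'")


@dataclass(frozen=True)
class PromoterRecord:
    """A TSS-anchored window, sequence oriented on the gene's coding strand."""

    gene: str
    chrom: str
    start: int  # 0-based half-open genomic interval on the plus strand
    end: int
    strand: str
    seq: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.gene}: start must be >= 0")
        if self.end - self.start != len(self.seq):
            raise ValueError(
                f"{self.gene}: interval length {self.end - self.start} "
                f"!= sequence length {len(self.seq)}"
            )


def _revcomp(seq: str) -> str:
    # local helper; the scanner module exposes the validated public revcomp
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a (possibly wrapped) multi-record FASTA into a SequenceSet.

    Sequences are uppercased; duplicate ids and non-A/C/G/T/N characters are
    rejected.  An empty file yields an empty set.
    """
    path = Path(path)
    out = SequenceSet()
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: not FASTA (first character {first!r})")
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        out.add(SequenceRecord(id=bio_rec.id, seq=str(bio_rec.seq)))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(rec.seq), id=rec.id, description="") for rec in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a tab-delimited annotation table with header ``gene chrom tss strand``."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    required = {"gene", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns {sorted(missing)}")
    return [
        GeneAnnotation(gene=r.gene, chrom=r.chrom, tss=int(r.tss), strand=r.strand)
        for r in df.itertuples(index=False)
    ]


def write_annotations(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.gene, a.chrom, a.tss, a.strand) for a in annotations],
        columns=["gene", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)


def _window_for(ann: GeneAnnotation, upstream: int, downstream: int) -> tuple[int, int]:
    """Genomic plus-strand interval of the promoter window of a gene.

    For a plus-strand gene the window is [tss - upstream, tss + downstream);
    for a minus-strand gene the same genomic interval mirrored around the TSS,
    [tss - downstream, tss + upstream).  With upstream == downstream the two
    intervals coincide, so extracting for one strand and reverse-complementing
    equals extracting for the opposite strand.
    """
    if ann.strand == "+":
        return ann.tss - upstream, ann.tss + downstream
    return ann.tss - downstream, ann.tss + upstream


def extract_promoters(
    genome: SequenceSet,
    annotations: Iterable[GeneAnnotation],
    upstream: int = 1000,
    downstream: int = 1000,
) -> list[PromoterRecord]:
    """Extract TSS-anchored promoter windows, clipped at contig boundaries.

    Default window is +/-1000 bp around the TSS.  Minus-strand sequences are
    reverse-complemented so that position 0 is the most-upstream base relative
    to the gene.  Windows extending past a contig edge are clipped with a
    logged warning rather than rejected.
    """
    out: list[PromoterRecord] = []
    for ann in annotations:
        if ann.chrom not in genome:
            raise KeyError(f"{ann.gene}: chrom {ann.chrom!r} not in genome")
        contig = genome[ann.chrom].seq
        start, end = _window_for(ann, upstream, downstream)
        cstart, cend = max(start, 0), min(end, len(contig))
        if cend < cstart:
            cstart = cend = min(max(cstart, 0), len(contig))
        if (cstart, cend) != (start, end):
            logger.warning(
                "%s: promoter window [%d, %d) clipped to [%d, %d) on %s",
                ann.gene, start, end, cstart, cend, ann.chrom,
            )
        seq = contig[cstart:cend]
        if ann.strand == "-":
            seq = _revcomp(seq)
        out.append(
            PromoterRecord(
                gene=ann.gene, chrom=ann.chrom, start=cstart, end=cend,
                strand=ann.strand, seq=seq,
            )
        )
    return out


def extract_region(
    genome: SequenceSet,
    annotation: GeneAnnotation,
    rel_start: int,
    rel_end: int,
    inclusive: bool = True,
) -> PromoterRecord:
    """Extract a TSS-relative window on the gene's orientation.

    Offsets are gene-oriented: 0 is the TSS base itself and negative offsets
    lie upstream of the gene.  By default both printed endpoints are included
    (``inclusive=True``), matching how enhancer boundaries such as the Nis
    upstream enhancer (-2495 to -2264, 232 nt) are reported in the literature;
    set ``inclusive=False`` for a half-open window.  Windows falling outside
    the contig raise an error (no clipping).
    """
    if rel_start >= rel_end:
        raise ValueError("rel_start must be < rel_end")
    if annotation.chrom not in genome:
        raise KeyError(f"{annotation.gene}: chrom {annotation.chrom!r} not in genome")
    contig = genome[annotation.chrom].seq
    extra = 1 if inclusive else 0
    if annotation.strand == "+":
        start = annotation.tss + rel_start
        end = annotation.tss + rel_end + extra
    else:
        # gene-oriented offset k maps to plus-strand position tss - k
        start = annotation.tss - rel_end - extra + 1
        end = annotation.tss - rel_start + 1
    if start < 0 or end > len(contig):
        raise ValueError(
            f"{annotation.gene}: window [{start}, {end}) outside contig "
            f"{annotation.chrom} of length {len(contig)}"
        )
    seq = contig[start:end]
    if annotation.strand == "-":
        seq = _revcomp(seq)
    return PromoterRecord(
        gene=annotation.gene, chrom=annotation.chrom, start=start, end=end,
        strand=annotation.strand, seq=seq,
    )


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(hits, path: str | Path) -> None:
    """Write composite-motif hits as BED6 (0-based half-open).

    ``name`` is ``gene:upstreamCore-downstreamCore``, ``score`` the spacer
    length, ``strand`` the genomic strand of the hit.  Hits scanned from bare
    sequences (no genomic coordinates attached) are rejected.
    """
    rows = []
    for hit in hits:
        if hit.chrom is None or hit.genome_start is None:
            raise ValueError(
                f"hit on {hit.source_id!r} lacks genomic coordinates; "
                "scan PromoterRecords (not bare sequences) to attach them"
            )
        rows.append(
            (
                hit.chrom,
                hit.genome_start,
                hit.genome_end,
                f"{hit.source_id}:{hit.core_label}",
                hit.spacer_len,
                hit.genome_strand,
            )
        )
    pd.DataFrame(rows, columns=BED_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file back into a DataFrame (round-trip helper)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS)
    return df
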