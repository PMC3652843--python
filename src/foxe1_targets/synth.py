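"""Seeded generators for every input the pipeline consumes, with planted truth.

The generators emulate the study's input conditions so each stage is testable
without external downloads:

* promoters: +/-1000 bp TSS windows (2 kb) whose background is rejection-
  scrubbed of chance composite occurrences, with the NF1/CTF-FoxE1 composite
  planted at known offsets, spacers and strands;
* ortholog panels per gene carrying the motif at a controlled conservation
  rate, spacers jittered within the 5-30 bp window;
* two probe-level differential-expression tables whose significant sets
  mirror the published two-comparison screening shape (74 probes / 64 genes
  and 211 / 183, sharing 55 genes: 17 up, 38 down), including unannotated
  probes and records sitting exactly on the 0.005 threshold;
* ChIP qPCR cycle-threshold tables back-computed from planted enrichment
  ratios (defaults are the published IP ratios 22.8, 3.6, 12.6, 28.1, 9.3)
  under the efficiency model plus Gaussian Ct noise;
* qRT-PCR expression tables with planted knockdown/induction folds against a
  Gus normalizer, and dual-luciferase reporter tables with planted fold
  activation and multiplicative noise.

All randomness flows from one top-level seed through per-generator
spawned streams, so identical configs produce byte-identical outputs and
each ``gen_*`` function is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .conservation import OrthologSet
from .motif import CompositeMotifConfig, revcomp, scan_sequence
from .seqio import (
    GeneAnnotation,
    SequenceRecord,
    SequenceSet,
    write_annotations,
    write_fasta,
)

_BASES = np.array(list("ACGT"))

# fixed stream keys so each generator is reproducible on its own
_STREAMS = {"promoters": 0, "orthologs": 1, "de": 2, "chip": 3,
            "expression": 4, "reporter": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


class PromoterPlan(BaseModel):
    n_genes: int = 20
    upstream: int = 1000
    downstream: int = 1000
    gc_content: float = Field(default=0.45, ge=0.0, le=1.0)
    motif_presence_rate: float = Field(default=1.0, ge=0.0, le=1.0)
    strand_minus_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    max_scrub_rounds: int = 200

    @property
    def promoter_len(self) -> int:
        return self.upstream + self.downstream


class OrthologPlan(BaseModel):
    panel_size: int = 12
    conservation_rate: float = Field(default=0.5, ge=0.0, le=1.0)
    promoter_len: int = 2000
    spacer_jitter: int = 3


class DEPlan(BaseModel):
    """Planted two-comparison screening shape (defaults mirror the study).

    Comparison A is silenced-vs-scrambled, comparison B silenced-vs-wild-type.
    Unannotated significant probes create the probe>gene count gap.
    """

    n_genes_universe: int = 1000
    n_probes: int = 1500  # per table, including non-significant filler
    common_up: int = 17
    common_down: int = 38
    a_genes_up: int = 24
    a_genes_down: int = 40
    b_genes_up: int = 87
    b_genes_down: int = 96
    a_unannotated_up: int = 0
    a_unannotated_down: int = 10
    b_unannotated_up: int = 12
    b_unannotated_down: int = 16
    n_boundary: int = 3  # records sitting exactly at alpha, never significant
    alpha: float = 0.005

    @model_validator(mode="after")
    def _check_counts(self) -> "DEPlan":
        if self.common_up > min(self.a_genes_up, self.b_genes_up):
            raise ValueError("common_up exceeds a per-comparison up count")
        if self.common_down > min(self.a_genes_down, self.b_genes_down):
            raise ValueError("common_down exceeds a per-comparison down count")
        n_sig = (
            self.a_genes_up + self.a_genes_down + self.b_genes_up + self.b_genes_down
            - self.common_up - self.common_down
        )
        if n_sig + self.n_boundary > self.n_genes_universe:
            raise ValueError("gene universe too small for the planted counts")
        if n_sig + self.a_unannotated_up + self.a_unannotated_down > self.n_probes:
            raise ValueError("n_probes too small for the planted counts")
        return self


class ChipPlan(BaseModel):
    antibody: str = "FoxE1"
    planted_ratios: dict[str, float] = Field(
        default_factory=lambda: {
            "Tg": 22.8, "Tpo": 3.6, "NUE": 12.6,
            "Duox2-1": 28.1, "Duox2-2": 9.3, "Gad1": 1.0,
        }
    )
    negctrl: str = "Afm"
    ct_noise_sd: float = 0.1
    n_experiments: int = 2
    n_replicates: int = 3
    efficiency: float = 2.0
    base_input_ct: float = 24.0
    # negative-control IP recovers 2^-3 of input; cancels in all ratios
    ctrl_log2_recovery: float = -3.0


class ExpressionPlan(BaseModel):
    """qRT-PCR validation plan: folds are treated/reference expression ratios."""

    planted_folds: dict[str, float] = Field(
        default_factory=lambda: {
            "FoxE1": 0.15, "Nis": 0.3, "Tg": 0.5, "Tpo": 0.4,
            "Duox2": 1.8, "Cdh1": 1.6,
        }
    )
    normalizer: str = "Gus"
    treated_label: str = "siFoxE1"
    reference_label: str = "siScramble"
    ct_noise_sd: float = 0.1
    n_experiments: int = 4
    n_replicates: int = 3
    efficiency: float = 2.0


class ReporterPlan(BaseModel):
    planted_folds: dict[str, float] = Field(
        default_factory=lambda: {
            "FoxE1": 2.0, "NF1/CTF": 2.0, "FoxE1+NF1/CTF": 4.0,
        }
    )
    control_condition: str = "empty"
    cv: float = 0.10  # multiplicative noise on luciferase readings
    n_experiments: int = 6
    n_replicates: int = 3
    base_renilla: float = 1e5
    base_ratio: float = 0.5  # control luciferase/renilla ratio


class GeneratorConfig(BaseModel):
    seed: int = 0
    upstream_core: str = "TTGG"
    downstream_core: str = "AAACA"
    min_spacer: int = 5
    max_spacer: int = 30
    promoters: PromoterPlan = Field(default_factory=PromoterPlan)
    orthologs: OrthologPlan = Field(default_factory=OrthologPlan)
    de: DEPlan = Field(default_factory=DEPlan)
    chip: ChipPlan = Field(default_factory=ChipPlan)
    expression: ExpressionPlan = Field(default_factory=ExpressionPlan)
    reporter: ReporterPlan = Field(default_factory=ReporterPlan)

    def motif_config(self) -> CompositeMotifConfig:
        return CompositeMotifConfig(
            upstream_core=self.upstream_core,
            downstream_core=self.downstream_core,
            min_spacer=self.min_spacer,
            max_spacer=self.max_spacer,
        )


@dataclass(frozen=True)
class PlantedMotifTruth:
    """Ground truth for one planted composite instance (promoter-oriented)."""

    gene: str
    strand: int
    spacer_len: int
    upstream_core_start: int


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _scrub(
    seq: str, motif: CompositeMotifConfig, rng: np.random.Generator,
    gc: float, max_rounds: int,
) -> str:
    """Rejection-resample every window matching the composite pattern.

    Guarantees the returned background contains no chance composite hit, so
    false-positive tests on generated data are exact.
    """
    for _ in range(max_rounds):
        hits = scan_sequence(seq, motif)
        if not hits:
            return seq
        chars = list(seq)
        for h in hits:
            span = h.span(motif)
            chars[h.leftmost : h.leftmost + span] = _random_seq(rng, span, gc)
        seq = "".join(chars)
    raise RuntimeError(
        "could not scrub background of composite hits within "
        f"{max_rounds} rounds (pathological GC content?)"
    )


def _plant(
    background: str,
    motif: CompositeMotifConfig,
    rng: np.random.Generator,
    gc: float,
    strand: int,
    spacer_len: int,
    max_tries: int = 100,
) -> tuple[str, int]:
    """Overwrite a window of the scrubbed background with one composite
    instance; re-draw until the planted hit is the only hit in the sequence.

    Returns ``(sequence, upstream_core_start)`` with the offset pointing at
    the named upstream (NF1/CTF) core on the given strand.
    """
    span = len(motif.upstream_core) + spacer_len + len(motif.downstream_core)
    if span > len(background):
        raise ValueError("promoter shorter than the composite span")
    for _ in range(max_tries):
        offset = int(rng.integers(0, len(background) - span + 1))
        spacer = _random_seq(rng, spacer_len, gc)
        instance = motif.upstream_core + spacer + motif.downstream_core
        if strand == -1:
            instance = revcomp(instance)
        seq = background[:offset] + instance + background[offset + span :]
        hits = scan_sequence(seq, motif)
        if len(hits) == 1 and hits[0].strand == strand and (
            hits[0].spacer_len == spacer_len
        ):
            if strand == 1:
                up_start = offset
            else:
                up_start = offset + len(motif.downstream_core) + spacer_len
            assert hits[0].upstream_core_start == up_start
            return seq, up_start
    raise RuntimeError("could not plant a unique composite instance")


def gen_promoters(
    config: GeneratorConfig,
) -> tuple[SequenceSet, list[GeneAnnotation], list[PlantedMotifTruth]]:
    """Synthetic genome of one contig per gene with planted promoter motifs.

    Each contig is a scrubbed promoter-sized window with its TSS at the
    window midpoint; genes alternate between plus and minus genomic strands
    (per ``strand_minus_prob``), and the planted motif strand/spacer/offset
    is recorded promoter-oriented in the truth list.
    """
    plan = config.promoters
    motif = config.motif_config()
    rng = _rng(config.seed, "promoters")
    genome = SequenceSet()
    annotations: list[GeneAnnotation] = []
    truths: list[PlantedMotifTruth] = []
    for i in range(plan.n_genes):
        gene = f"g{i + 1:04d}"
        background = _scrub(
            _random_seq(rng, plan.promoter_len, plan.gc_content),
            motif, rng, plan.gc_content, plan.max_scrub_rounds,
        )
        if rng.random() < plan.motif_presence_rate:
            strand = -1 if rng.random() < 0.5 else 1
            spacer = int(rng.integers(motif.min_spacer, motif.max_spacer + 1))
            promoter, up_start = _plant(
                background, motif, rng, plan.gc_content, strand, spacer
            )
            truths.append(
                PlantedMotifTruth(
                    gene=gene, strand=strand, spacer_len=spacer,
                    upstream_core_start=up_start,
                )
            )
        else:
            promoter = background
        gene_strand = "-" if rng.random() < plan.strand_minus_prob else "+"
        contig = promoter if gene_strand == "+" else revcomp(promoter)
        chrom = f"chr_{gene}"
        genome.add(SequenceRecord(id=chrom, seq=contig))
        annotations.append(
            GeneAnnotation(gene=gene, chrom=chrom, tss=plan.upstream, strand=gene_strand)
        )
    return genome, annotations, truths


def gen_ortholog_sets(
    config: GeneratorConfig, truths: list[PlantedMotifTruth]
) -> dict[str, OrthologSet]:
    """Per-gene ortholog panels carrying the motif at the conservation rate.

    Motif-positive members inherit the reference spacer jittered within the
    allowed window (uniform draw for genes without a reference instance).
    """
    plan = config.orthologs
    motif = config.motif_config()
    rng = _rng(config.seed, "orthologs")
    truth_by_gene = {t.gene: t for t in truths}
    gc = config.promoters.gc_content
    out: dict[str, OrthologSet] = {}
    for gene in sorted({t.gene for t in truths}):
        members = []
        for j in range(plan.panel_size):
            species = f"sp{j + 1:03d}"
            seq = _scrub(
                _random_seq(rng, plan.promoter_len, gc),
                motif, rng, gc, config.promoters.max_scrub_rounds,
            )
            if rng.random() < plan.conservation_rate:
                ref = truth_by_gene.get(gene)
                if ref is not None:
                    jitter = int(rng.integers(-plan.spacer_jitter, plan.spacer_jitter + 1))
                    spacer = int(
                        np.clip(ref.spacer_len + jitter, motif.min_spacer, motif.max_spacer)
                    )
                else:
                    spacer = int(rng.integers(motif.min_spacer, motif.max_spacer + 1))
                strand = -1 if rng.random() < 0.5 else 1
                seq, _ = _plant(seq, motif, rng, gc, strand, spacer)
            members.append((species, seq))
        out[gene] = OrthologSet(gene=gene, members=tuple(members))
    return out


def _de_table(
    rng: np.random.Generator,
    plan: DEPlan,
    prefix: str,
    up_genes: list[str],
    down_genes: list[str],
    n_unann_up: int,
    n_unann_down: int,
    boundary_genes: list[str],
    other_genes: list[str],
) -> pd.DataFrame:
    rows = []
    idx = 0

    def add(gene: str, logfc: float, adj_p: float) -> None:
        nonlocal idx
        idx += 1
        rows.append((f"{prefix}_{idx:05d}", gene, round(logfc, 4), adj_p))

    def sig_p() -> float:
        return float(rng.uniform(1e-6, plan.alpha * 0.9))

    def nonsig_p() -> float:
        return float(rng.uniform(plan.alpha * 1.5, 1.0))

    for gene in up_genes:
        add(gene, rng.uniform(0.5, 3.0), sig_p())
    for gene in down_genes:
        add(gene, -rng.uniform(0.5, 3.0), sig_p())
    for _ in range(n_unann_up):
        add("", rng.uniform(0.5, 3.0), sig_p())
    for _ in range(n_unann_down):
        add("", -rng.uniform(0.5, 3.0), sig_p())
    for gene in boundary_genes:
        add(gene, rng.uniform(0.5, 3.0), plan.alpha)  # exactly at threshold
    n_filler = plan.n_probes - len(rows)
    for _ in range(n_filler):
        gene = other_genes[int(rng.integers(0, len(other_genes)))]
        add(gene, rng.normal(0.0, 0.2), nonsig_p())
    df = pd.DataFrame(rows, columns=["probe", "gene", "logfc", "adj_p"])
    return df.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(
        drop=True
    )


def gen_de_tables(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two probe-level DE tables with a planted significant-in-both overlap.

    Returns ``(table_a, table_b, truth)`` where truth lists the planted
    per-comparison and common gene sets with directions.
    """
    plan = config.de
    rng = _rng(config.seed, "de")
    universe = [f"g{i + 1:04d}" for i in range(plan.n_genes_universe)]
    order = rng.permutation(plan.n_genes_universe)

    pool = [universe[i] for i in order]
    take = lambda n: [pool.pop() for _ in range(n)]

    common_up = take(plan.common_up)
    common_down = take(plan.common_down)
    a_only_up = take(plan.a_genes_up - plan.common_up)
    a_only_down = take(plan.a_genes_down - plan.common_down)
    b_only_up = take(plan.b_genes_up - plan.common_up)
    b_only_down = take(plan.b_genes_down - plan.common_down)
    boundary = take(plan.n_boundary)
    other = pool  # never significant

    table_a = _de_table(
        rng, plan, "A", common_up + a_only_up, common_down + a_only_down,
        plan.a_unannotated_up, plan.a_unannotated_down, boundary, other,
    )
    table_b = _de_table(
        rng, plan, "B", common_up + b_only_up, common_down + b_only_down,
        plan.b_unannotated_up, plan.b_unannotated_down, boundary, other,
    )
    truth = {
        "alpha": plan.alpha,
        "common": {
            "total": plan.common_up + plan.common_down,
            "up": sorted(common_up),
            "down": sorted(common_down),
        },
        "a": {"up": sorted(common_up + a_only_up), "down": sorted(common_down + a_only_down)},
        "b": {"up": sorted(common_up + b_only_up), "down": sorted(common_down + b_only_down)},
        "boundary_genes": sorted(boundary),
    }
    return table_a, table_b, truth


def gen_chip_qpcr(config: GeneratorConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """ChIP qPCR Ct table back-computed from planted enrichment ratios.

    For every amplicon and experiment the IP Ct is placed
    ``log_E(ratio) + ctrl_log2_recovery`` cycles below the input Ct, then
    replicate Cts get additive Gaussian noise.  With zero noise the
    quantification inverts the planted ratios exactly.
    """
    plan = config.chip
    rng = _rng(config.seed, "chip")
    rows = []
    amplicons = {**plan.planted_ratios, plan.negctrl: 1.0}
    for exp in range(1, plan.n_experiments + 1):
        for amplicon, ratio in amplicons.items():
            input_ct = plan.base_input_ct + float(rng.normal(0.0, 0.5))
            log_e_q = plan.ctrl_log2_recovery + np.log2(ratio) / np.log2(plan.efficiency)
            ip_ct = input_ct - log_e_q
            for sample, true_ct in (("IP", ip_ct), ("input", input_ct)):
                for rep in range(1, plan.n_replicates + 1):
                    ct = true_ct + float(rng.normal(0.0, plan.ct_noise_sd))
                    rows.append((sample, plan.antibody, amplicon, exp, rep, ct))
    df = pd.DataFrame(
        rows,
        columns=["sample", "antibody_or_condition", "amplicon", "experiment",
                 "replicate", "ct"],
    )
    return df, dict(plan.planted_ratios)


def gen_expression_qpcr(config: GeneratorConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """qRT-PCR Ct table with planted treated/reference expression folds."""
    plan = config.expression
    rng = _rng(config.seed, "expression")
    rows = []
    genes = {**plan.planted_folds, plan.normalizer: 1.0}
    for exp in range(1, plan.n_experiments + 1):
        for gene, fold in genes.items():
            ref_ct = 22.0 + float(rng.normal(0.0, 1.0))
            # expression fold f lifts treated Ct by -log_E(f) cycles
            treated_ct = ref_ct - np.log2(fold) / np.log2(plan.efficiency)
            for label, true_ct in (
                (plan.treated_label, treated_ct),
                (plan.reference_label, ref_ct),
            ):
                for rep in range(1, plan.n_replicates + 1):
                    ct = true_ct + float(rng.normal(0.0, plan.ct_noise_sd))
                    rows.append(("cDNA", label, gene, exp, rep, ct))
    df = pd.DataFrame(
        rows,
        columns=["sample", "antibody_or_condition", "amplicon", "experiment",
                 "replicate", "ct"],
    )
    return df, dict(plan.planted_folds)


def gen_reporter(config: GeneratorConfig) -> tuple[pd.DataFrame, dict[str, float]]:
    """Dual-luciferase readings with planted fold activation per condition."""
    plan = config.reporter
    rng = _rng(config.seed, "reporter")
    rows = []
    conditions = {plan.control_condition: 1.0, **plan.planted_folds}
    sigma = np.sqrt(np.log1p(plan.cv**2))  # lognormal sd giving the target CV
    for exp in range(1, plan.n_experiments + 1):
        for condition, fold in conditions.items():
            for rep in range(1, plan.n_replicates + 1):
                renilla = plan.base_renilla * float(
                    rng.lognormal(mean=0.0, sigma=0.05)
                )
                luciferase = (
                    renilla * plan.base_ratio * fold
                    * float(rng.lognormal(mean=-sigma**2 / 2, sigma=sigma))
                )
                rows.append((condition, exp, rep, round(luciferase, 2), round(renilla, 2)))
    df = pd.DataFrame(
        rows, columns=["condition", "experiment", "replicate", "luciferase", "renilla"]
    )
    return df, dict(plan.planted_folds)


def truths_to_table(truths: list[PlantedMotifTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.gene, t.strand, t.spacer_len, t.upstream_core_start) for t in truths],
        columns=["gene", "strand", "spacer_len", "upstream_core_start"],
    )


def write_bundle(config: GeneratorConfig, outdir: str | Path) -> dict[str, str]:
    """Write a complete, self-consistent input bundle for all pipeline stages.

    Emits the exact file dialects the pipeline reads (FASTA, annotation TSV,
    DE TSV, Ct TSV, reporter TSV) plus truth TSV/JSON files, and returns a
    manifest of the files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    genome, annotations, truths = gen_promoters(config)
    write_fasta(genome, outdir / "genome.fasta")
    write_annotations(annotations, outdir / "annotations.tsv")
    truths_to_table(truths).to_csv(outdir / "motif_truth.tsv", sep="\t", index=False)
    manifest.update(
        genome="genome.fasta", annotations="annotations.tsv",
        motif_truth="motif_truth.tsv",
    )

    ortho_dir = outdir / "orthologs"
    ortho_dir.mkdir(exist_ok=True)
    for gene, oset in gen_ortholog_sets(config, truths).items():
        write_fasta(
            (SequenceRecord(id=sp, seq=seq) for sp, seq in oset.members),
            ortho_dir / f"{gene}.fasta",
        )
    manifest["orthologs"] = "orthologs/"

    table_a, table_b, de_truth = gen_de_tables(config)
    table_a.to_csv(outdir / "de_siFoxE1_vs_siScramble.tsv", sep="\t", index=False)
    table_b.to_csv(outdir / "de_siFoxE1_vs_wt.tsv", sep="\t", index=False)
    (outdir / "de_truth.json").write_text(json.dumps(de_truth, indent=2))
    manifest.update(
        de_a="de_siFoxE1_vs_siScramble.tsv", de_b="de_siFoxE1_vs_wt.tsv",
        de_truth="de_truth.json",
    )

    chip, chip_truth = gen_chip_qpcr(config)
    chip.to_csv(outdir / "chip_ct.tsv", sep="\t", index=False)
    expr, expr_truth = gen_expression_qpcr(config)
    expr.to_csv(outdir / "expression_ct.tsv", sep="\t", index=False)
    reporter, reporter_truth = gen_reporter(config)
    reporter.to_csv(outdir / "reporter.tsv", sep="\t", index=False)
    (outdir / "quant_truth.json").write_text(
        json.dumps(
            {"chip_ratios": chip_truth, "expression_folds": expr_truth,
             "reporter_folds": reporter_truth},
            indent=2,
        )
    )
    manifest.update(
        chip="chip_ct.tsv", expression="expression_ct.tsv",
        reporter="reporter.tsv", quant_truth="quant_truth.json",
    )
    (outdir / "generator_config.json").write_text(config.model_dump_json(indent=2))
    manifest["config"] = "generator_config.json"
    return manifest
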