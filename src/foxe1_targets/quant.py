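"""Quantification of the validation assays: ChIP/ReChIP qPCR enrichment,
relative expression by qRT-PCR, and dual-luciferase fold activation.

qPCR quantities follow the efficiency model ``Q = E^(-Ct)`` up to a constant,
so the input-normalized recovered fraction of an amplicon is
``E^(Ct_input - Ct_IP)``; constant input-dilution factors cancel in every
downstream ratio.  ChIP enrichment is that quantity for a target amplicon
divided by the same quantity for a negative-control locus (e.g. Afm or
Gad1), averaged over biological experiments and reported as mean +/- SEM.
Relative expression uses the ddCt scheme against a normalizer gene (Gus),
with the reference condition evaluating to 1 by construction.  Reporter
activation is the luciferase/Renilla ratio relative to the control
transfection, reported as mean +/- SD with a two-tailed Welch t-test and
the conventional significance stars.

Technical triplicates are averaged on the Ct scale before exponentiation
(standard qPCR practice); amplification efficiency defaults to 2.0 (perfect
doubling per cycle) and is configurable per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_EFFICIENCY = 2.0

CT_COLUMNS = ["sample", "antibody_or_condition", "amplicon", "experiment", "replicate", "ct"]
REPORTER_COLUMNS = ["condition", "experiment", "replicate", "luciferase", "renilla"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-amplicon relative IP ratio (or expression fold) with dispersion."""

    amplicon: str
    relative_ip_ratio: float
    sem: float
    n_experiments: int


@dataclass(frozen=True)
class FoldActivation:
    condition: str
    fold: float
    sd: float
    p_value: float
    stars: str
    n_experiments: int


def _check_efficiency(efficiency: float) -> None:
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"efficiency {efficiency} outside (1, 2]")


def amplification_quantity(
    ct_mean: float, ct_input_mean: float, efficiency: float = DEFAULT_EFFICIENCY
) -> float:
    """Input-normalized recovered fraction ``efficiency^(Ct_input - Ct_IP)``."""
    _check_efficiency(efficiency)
    if not (math.isfinite(ct_mean) and math.isfinite(ct_input_mean)):
        raise ValueError("non-finite Ct value")
    return efficiency ** (ct_input_mean - ct_mean)


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def _group_ct(df: pd.DataFrame, amplicon: str) -> pd.DataFrame:
    """Per-(sample, experiment) mean Ct of technical triplicates for one amplicon."""
    sub = df[df["amplicon"] == amplicon]
    if sub.empty:
        raise ValueError(f"no Ct rows for amplicon {amplicon!r}")
    if not np.isfinite(sub["ct"]).all():
        raise ValueError(f"non-finite Ct for amplicon {amplicon!r}")
    return sub.groupby(["sample", "experiment"])["ct"].mean().unstack("sample")


def relative_ip_ratio(
    measurements: pd.DataFrame,
    target: str,
    negctrl: str,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> EnrichmentResult:
    """ChIP enrichment of ``target`` relative to the ``negctrl`` locus.

    ``measurements`` holds the Ct rows of one antibody (or one sequential
    ReChIP), with ``sample`` in {IP, input}.  Per experiment the IP/input
    recovered fractions of target and control are formed after averaging
    technical triplicates on the Ct scale; the per-experiment ratios are
    aggregated as mean +/- SEM over biological experiments.
    """
    _check_efficiency(efficiency)
    ratios = []
    ct_t = _group_ct(measurements, target)
    ct_n = _group_ct(measurements, negctrl)
    for grp, label in ((ct_t, target), (ct_n, negctrl)):
        if "IP" not in grp.columns or "input" not in grp.columns:
            raise ValueError(f"amplicon {label!r} lacks a paired IP/input sample")
    experiments = sorted(set(ct_t.index) & set(ct_n.index))
    if not experiments:
        raise ValueError("no experiment with both target and control measurements")
    for exp in experiments:
        q_t = amplification_quantity(ct_t.loc[exp, "IP"], ct_t.loc[exp, "input"], efficiency)
        q_n = amplification_quantity(ct_n.loc[exp, "IP"], ct_n.loc[exp, "input"], efficiency)
        ratios.append(q_t / q_n)
    arr = np.asarray(ratios, dtype=float)
    return EnrichmentResult(
        amplicon=target,
        relative_ip_ratio=float(arr.mean()),
        sem=_sem(arr),
        n_experiments=len(arr),
    )


def relative_expression(
    measurements: pd.DataFrame,
    target_gene: str,
    normalizer_gene: str,
    treated_label: str,
    reference_label: str,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> EnrichmentResult:
    """ddCt relative expression of ``target_gene`` in treated vs reference cells.

    Per experiment the normalizer-corrected quantity
    ``E^(Ct_normalizer - Ct_target)`` is formed for both conditions and their
    ratio taken; the reference condition therefore evaluates to 1 by
    construction.  Aggregated as mean +/- SEM over experiments.  Conditions
    are read from the ``antibody_or_condition`` column.
    """
    _check_efficiency(efficiency)

    def cts(gene: str, condition: str) -> pd.Series:
        sub = measurements[
            (measurements["amplicon"] == gene)
            & (measurements["antibody_or_condition"] == condition)
        ]
        if sub.empty:
            raise ValueError(f"no Ct rows for gene {gene!r}, condition {condition!r}")
        return sub.groupby("experiment")["ct"].mean()

    ct_tt = cts(target_gene, treated_label)
    ct_nt = cts(normalizer_gene, treated_label)
    ct_tr = cts(target_gene, reference_label)
    ct_nr = cts(normalizer_gene, reference_label)
    experiments = sorted(
        set(ct_tt.index) & set(ct_nt.index) & set(ct_tr.index) & set(ct_nr.index)
    )
    if not experiments:
        raise ValueError("no experiment with all four gene x condition groups")
    folds = []
    for exp in experiments:
        q_treated = efficiency ** (ct_nt[exp] - ct_tt[exp])
        q_reference = efficiency ** (ct_nr[exp] - ct_tr[exp])
        folds.append(q_treated / q_reference)
    arr = np.asarray(folds, dtype=float)
    return EnrichmentResult(
        amplicon=target_gene,
        relative_ip_ratio=float(arr.mean()),
        sem=_sem(arr),
        n_experiments=len(arr),
    )


def assign_stars(p_value: float) -> str:
    """Conventional significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def fold_activation(
    readings: pd.DataFrame,
    condition: str,
    control_condition: str,
) -> FoldActivation:
    """Reporter fold activation of ``condition`` over ``control_condition``.

    Per experiment the luciferase/Renilla ratio is averaged over replicate
    wells; the fold is the mean over paired experiments of condition/control
    ratios, reported +/- SD.  Significance is a two-tailed Welch t-test on
    the per-experiment normalized ratios of the two groups.
    """
    present = set(readings["condition"])
    for label in (condition, control_condition):
        if label not in present:
            raise KeyError(f"condition {label!r} not present in readings")
    if (readings["renilla"] <= 0).any():
        raise ValueError("renilla readings must be positive")
    norm = readings.assign(ratio=readings["luciferase"] / readings["renilla"])
    per_exp = norm.groupby(["condition", "experiment"])["ratio"].mean()
    cond = per_exp[condition]
    ctrl = per_exp[control_condition]
    experiments = sorted(set(cond.index) & set(ctrl.index))
    if len(experiments) < 2:
        raise ValueError("need >= 2 paired experiments per condition")
    folds = np.asarray([cond[e] / ctrl[e] for e in experiments], dtype=float)
    t_p = stats.ttest_ind(
        cond.loc[experiments], ctrl.loc[experiments], equal_var=False
    ).pvalue
    return FoldActivation(
        condition=condition,
        fold=float(folds.mean()),
        sd=float(np.std(folds, ddof=1)),
        p_value=float(t_p),
        stars=assign_stars(float(t_p)),
        n_experiments=len(experiments),
    )


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def read_reporter_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(REPORTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reporter table missing columns {sorted(missing)}")
    return df
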