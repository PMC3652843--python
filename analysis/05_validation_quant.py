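#!/usr/bin/env python
"""Quantify the simulated validation assays and compare against planted truth.

ChIP enrichment (relative IP ratios vs the Afm negative control, mean +/-
SEM over 2 experiments), qRT-PCR relative expression (ddCt vs the Gus
normalizer, silenced vs scrambled, 4 experiments), and dual-luciferase
fold activation (mean +/- SD over 6 experiments with Welch t-tests and
significance stars).
"""

import json
from pathlib import Path

from foxe1_targets import fold_activation, relative_expression, relative_ip_ratio
from foxe1_targets.quant import read_ct_table, read_reporter_table
from foxe1_targets.synth import GeneratorConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    bundle = RESULTS / "bundle"
    config = GeneratorConfig.model_validate_json(
        (bundle / "generator_config.json").read_text()
    )
    truth = json.loads((bundle / "quant_truth.json").read_text())
    results = {"chip": {}, "expression": {}, "reporter": {}}

    chip = read_ct_table(bundle / "chip_ct.tsv")
    print("ChIP relative IP ratios (vs Afm):")
    for amplicon, planted in truth["chip_ratios"].items():
        res = relative_ip_ratio(chip, amplicon, config.chip.negctrl)
        results["chip"][amplicon] = {
            "ratio": res.relative_ip_ratio, "sem": res.sem, "planted": planted,
        }
        print(f"  {amplicon:8s} {res.relative_ip_ratio:6.2f} +/- {res.sem:5.2f}"
              f"  (planted {planted})")

    expr = read_ct_table(bundle / "expression_ct.tsv")
    plan = config.expression
    print("relative expression (siFoxE1 vs siScramble, Gus-normalized):")
    for gene, planted in truth["expression_folds"].items():
        res = relative_expression(expr, gene, plan.normalizer,
                                  plan.treated_label, plan.reference_label)
        results["expression"][gene] = {
            "fold": res.relative_ip_ratio, "sem": res.sem, "planted": planted,
        }
        print(f"  {gene:8s} {res.relative_ip_ratio:6.2f} +/- {res.sem:5.2f}"
              f"  (planted {planted})")

    reporter = read_reporter_table(bundle / "reporter.tsv")
    print("reporter fold activation (vs empty vector):")
    for condition, planted in truth["reporter_folds"].items():
        res = fold_activation(reporter, condition, config.reporter.control_condition)
        results["reporter"][condition] = {
            "fold": res.fold, "sd": res.sd, "p_value": res.p_value,
            "stars": res.stars, "planted": planted,
        }
        print(f"  {condition:16s} {res.fold:5.2f} +/- {res.sd:4.2f}"
              f"  p={res.p_value:.2e} {res.stars:3s} (planted {planted})")

    (RESULTS / "validation_quant.json").write_text(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
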