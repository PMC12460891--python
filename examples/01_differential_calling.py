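"""Region-differential protein calling on a synthetic study.

Generates a study with planted region effects, compares the two muscle
regions (LD vs SD) at each stage under the region-DAP policy
(FC >= 1.2 or <= 0.833, raw p < 0.05), and scores recovery against the
planted truth.
"""

from omnifiber import (
    ContrastSpec,
    POLICIES,
    SimulationConfig,
    call_contrast,
    evaluate_recovery,
    generate_study,
)

study = generate_study(SimulationConfig(n_genes=1000, seed=17))
d = study.design

for stage in d.stages:
    contrast = ContrastSpec("region_within_stage", ("LD", stage), ("SD", stage))
    records = call_contrast(study.protein, d, contrast, POLICIES["region_dap"])
    n_called = sum(r.called for r in records)
    print(f"{stage}: {n_called:4d} DAPs called of {len(records)} tested proteins")

report = evaluate_recovery(study.truth, dap_records=records)
print(
    f"\nAt {stage}: sensitivity {report.dap_sensitivity:.3f}, "
    f"observed FDR {report.dap_observed_fdr:.3f}"
)
print(
    "Sensitivity is the fraction of proteins with a planted region effect that\n"
    "were called; observed FDR is the fraction of calls without one. The\n"
    "region policy uses raw p-values (a deliberately lenient choice for subtle\n"
    "between-region differences), so at low planted prevalence a sizable\n"
    "share of calls are false discoveries."
)
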