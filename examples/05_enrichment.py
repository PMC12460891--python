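"""Hypergeometric over-representation of a called protein set.

The planted differential proteins are tested against the simulated
annotation map (a few terms were constructed to be over-represented in
them). The background is the detected proteome, the standard guard
against detection bias.
"""

from omnifiber import SimulationConfig, enrich, generate_study, results_to_frame

study = generate_study(SimulationConfig(n_genes=1500, seed=31))
foreground = sorted(study.truth.planted_dap_ids)
background = study.protein.feature_ids

results = enrich(foreground, background, study.annotations)
top = results_to_frame(results).head(5)
print(top.round(6).to_string(index=False))

truly_enriched = study.truth.enriched_term_ids
hits = [r.term_id for r in results[: len(truly_enriched)]]
print(f"\nPlanted enriched terms: {sorted(truly_enriched)}")
print(f"Top-{len(truly_enriched)} reported terms: {hits}")
print(
    "k of K term members fall in the n-gene foreground from an N-gene\n"
    "background; p is the hypergeometric upper tail P(X >= k), q its BH\n"
    "adjustment, and fold enrichment (k/n)/(K/N)."
)
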