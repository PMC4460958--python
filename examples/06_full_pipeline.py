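"""The full repurposing pipeline on a planted scenario.

The generated scenario hides four repurposable drugs that share the
query target's drug family in both interaction profile and fingerprint
space, among structured distractor families and random decoys. The
pipeline should recover exactly the hidden drugs.
"""

import drugrepo as dr
from drugrepo.pipeline import run_pipeline, scenario_pipeline_config

scenario = dr.make_pipeline_scenario(seed=0)
config = scenario_pipeline_config(scenario, seed=0)
report = run_pipeline(
    config,
    interactions=scenario.interactions,
    drug_records=scenario.drug_records,
    descriptors=scenario.descriptors,
)

print(f"query target:       {report.query_target}")
print(f"known binders:      {len(report.known_set)} "
      f"({len(report.approved_known)} approved)")
print(f"ensemble selected:  {len(report.ensemble_candidates)} candidates")
print(f"clustering input:   {len(report.combined_set)} drugs")
for met, hits in report.per_metric_hits.items():
    print(f"  {met:<10} enriched-cluster candidates: {sorted(hits)}")
print(f"consensus hits:     {report.consensus_hits}")
print("final filtered hits (combo score vs known-drug reference):")
for h in report.filtered_hits:
    print(f"  {h['drug_id']}  {h['score']:.3f}")
print(f"planted truth:      {sorted(scenario.hidden_drugs)}")
# Final hits should coincide with the planted hidden drugs; distractors
# fail cluster enrichment and decoys fail the similarity threshold.
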