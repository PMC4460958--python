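"""Regulatory-status filtering and candidate-set arithmetic.

Builds a 35-drug known-binder roster in which 8 drugs are flagged
illicit or withdrawn, filters it down to the approved set, and combines
it with 74 ensemble-predicted candidates into the clustering input.
"""

import drugrepo as dr

roster = dr.make_known_roster(n_drugs=35, n_removed=8, seed=0)
approved = dr.filter_approved(roster)
predicted = {f"cand{i:03d}" for i in range(74)}
combined = dr.combine_candidate_set({r.drug_id for r in approved}, predicted)

print(f"known roster:        {len(roster)} drugs")
print(f"approved after flag: {len(approved)} drugs")
print(f"predicted set:       {len(predicted)} drugs")
print(f"combined input:      {len(combined)} drugs")
# The approved count drops by exactly the flagged 8; the combined set is
# the disjoint union that feeds the latent-vector clustering stage.
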