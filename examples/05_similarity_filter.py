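"""Combined-similarity reference expansion and threshold filtering.

Generates a synthetic library with planted fingerprint families, grows a
reference set around two known drugs, and filters a mixed hit list at
the combined-score threshold of 1.5 (out of a maximum 2.0).
"""

import drugrepo as dr

lib = dr.make_drug_library(n_molecules=40, n_families=4, seed=5)
descriptors = {d.drug_id: d for d in lib.descriptors}

known = lib.by_family(0)[:2]           # two known drugs from family 0
hits = [d.drug_id for d in lib.by_family(0)[2:5]] + \
       [d.drug_id for d in lib.by_family(1)[:3]]

# grow the reference around the knowns from the rest of the library
library = [d for d in lib.descriptors if d.drug_id not in hits]
reference = dr.expand_reference(known, library, threshold=1.5)
print(f"reference grew from {len(known)} known drugs to {len(reference)} members")
ranked = dr.similarity_filter(hits, descriptors, reference,
                              dr.SimilarityConfig(combo_threshold=1.5, fp_length=256))
for drug_id, score in ranked:
    print(f"  {drug_id}  combo={score:.3f}")
print(f"{len(ranked)} of {len(hits)} hits pass the 1.5 threshold")
# Family-0 hits score near 2 x the within-family Tanimoto (> 1.5) and
# survive; family-1 hits are structurally unrelated and are removed.
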