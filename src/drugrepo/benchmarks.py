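"""Recovery benchmarks on planted synthetic data.

These drive both the test suite and the reproduction script: they
measure, from scratch, how well the factorization recovers withheld
associations and how often the full pipeline recovers planted
repurposable drugs while rejecting decoys.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pmf import PMFConfig, heldout_auc, pmf_fit, predict_scores
from .pipeline import run_pipeline, scenario_pipeline_config
from .synthetic import make_pipeline_scenario, make_planted_dti


def pmf_recovery_auc(n_seeds: int = 20, seed0: int = 0,
                     pmf_config: PMFConfig | None = None) -> list[float]:
    """Held-out AUC of a default PMF fit on the default planted matrix,
    one value per seed (seed drives both the planted data and the fit)."""
    aucs = []
    for s in range(n_seeds):
        seed = seed0 + s
        dti = make_planted_dti(seed=seed)
        cfg = pmf_config or PMFConfig()
        f = pmf_fit(dti.R, PMFConfig(**{**cfg.__dict__, "seed": seed}))
        scores = predict_scores(f)
        aucs.append(heldout_auc(scores, dti.hidden_positives, dti.eval_negatives))
    return aucs


@dataclass
class RecoveryRates:
    hidden_recovery: float   # fraction of (replicate, hidden drug) pairs in final hits
    decoy_fp: float          # fraction of (replicate, decoy drug) pairs in final hits
    n_replicates: int


def planted_recovery(n_replicates: int = 20, seed0: int = 0) -> RecoveryRates:
    """Run the full pipeline on freshly planted scenarios and score the
    final filtered hits against the planted ground truth."""
    hid_hit = hid_tot = dec_hit = dec_tot = 0
    for rep in range(n_replicates):
        sc = make_pipeline_scenario(seed=seed0 + rep)
        cfg = scenario_pipeline_config(sc, seed=seed0 + 100_000 + rep)
        rpt = run_pipeline(cfg, interactions=sc.interactions,
                           drug_records=sc.drug_records,
                           descriptors=sc.descriptors)
        final = {h["drug_id"] for h in rpt.filtered_hits}
        hid_hit += len(final & sc.hidden_drugs)
        hid_tot += len(sc.hidden_drugs)
        dec_hit += len(final & sc.decoy_drugs)
        dec_tot += len(sc.decoy_drugs)
    return RecoveryRates(
        hidden_recovery=hid_hit / hid_tot,
        decoy_fp=dec_hit / dec_tot,
        n_replicates=n_replicates,
    )


__all__ = ["pmf_recovery_auc", "planted_recovery", "RecoveryRates"]
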