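"""Seeded PMF ensemble and candidate aggregation for one query target.

A single factorization of a sparse binary matrix is sensitive to its
random initialization and negative sample, so candidates are taken from
many independently seeded fits: run r uses seed_base + r, contributes its
top-k ranked drugs for the query target (known binders excluded), and a
drug is selected when it appears in at least ``freq_threshold`` of runs.
The production-scale protocol behind this design used 1e5 parallel runs
with top-10 per run; the desk-scale default is 100 runs, and results are
invariant to run order, so any parallel schedule gives the same table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .io import InteractionMatrix
from .pmf import PMFConfig, pmf_fit, predict_scores, rank_candidates


@dataclass(frozen=True)
class EnsembleConfig:
    n_runs: int = 100
    k: int = 10
    seed_base: int = 0
    freq_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 < self.freq_threshold <= 1.0):
            raise ValueError("freq_threshold must be in (0, 1]")


@dataclass
class CandidateTable:
    """Per-drug appearance counts across ensemble runs."""

    counts: dict[str, int]
    n_runs: int
    freq_threshold: float

    def frequency(self, drug_id: str) -> float:
        return self.counts.get(drug_id, 0) / self.n_runs

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug_id": d,
                "count": c,
                "frequency": c / self.n_runs,
                "selected": c / self.n_runs >= self.freq_threshold,
            }
            for d, c in self.counts.items()
        ]
        df = pd.DataFrame(rows, columns=["drug_id", "count", "frequency", "selected"])
        return df.sort_values(
            ["frequency", "drug_id"], ascending=[False, True], ignore_index=True
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_ensemble(
    R: InteractionMatrix,
    pmf_config: PMFConfig,
    ens_config: EnsembleConfig,
    target_id: str,
    known_set: set[str],
) -> CandidateTable:
    """Accumulate per-run top-k candidates for ``target_id`` over seeded fits.

    Fully deterministic given (seed_base, n_runs); a diverging fit aborts
    with the offending run index attached.
    """
    R.target_index(target_id)  # validate early
    counts: dict[str, int] = {}
    for r in range(ens_config.n_runs):
        cfg = replace(pmf_config, seed=ens_config.seed_base + r)
        try:
            factors = pmf_fit(R, cfg)
        except FloatingPointError as exc:
            raise FloatingPointError(f"ensemble run {r} (seed {cfg.seed}): {exc}") from exc
        scores = predict_scores(factors)
        for d in rank_candidates(scores, R, target_id, ens_config.k, exclude=known_set):
            counts[d] = counts.get(d, 0) + 1
    return CandidateTable(
        counts=counts, n_runs=ens_config.n_runs, freq_threshold=ens_config.freq_threshold
    )


def select_candidates(table: CandidateTable) -> list[str]:
    """Drugs with frequency >= threshold, by descending frequency then drug_id."""
    picked = [
        (d, c / table.n_runs)
        for d, c in table.counts.items()
        if c / table.n_runs >= table.freq_threshold
    ]
    picked.sort(key=lambda dc: (-dc[1], dc[0]))
    return [d for d, _ in picked]


__all__ = ["EnsembleConfig", "CandidateTable", "run_ensemble", "select_candidates"]
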