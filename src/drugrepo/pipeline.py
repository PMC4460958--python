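"""End-to-end repurposing pipeline: known-drug filtering, PMF ensemble,
latent-vector cluster enrichment under several metrics, consensus, and
chemical-similarity filtering.

Stage order (matching the screening flow the package implements):

1. read interactions / metadata / molecules;
2. collect the query target's known binders and drop non-approved ones;
3. seeded PMF ensemble -> candidate table -> frequency-selected candidates;
4. combined set = approved knowns + candidates; a small bank of
   representative PMF fits supplies drug latent geometry (pairwise
   distances averaged across fits); per metric: distances ->
   agglomeration -> known-drug-enriched clusters -> repurposable members;
5. consensus = candidates recovered under every metric;
6. reference expansion around the approved knowns' fingerprints and
   combined-similarity threshold filtering of the consensus hits.

One global seed derives every stage seed by fixed offsets, so a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

from .io import (
    DrugRecord,
    InteractionMatrix,
    PipelineReport,
    combine_candidate_set,
    filter_approved,
    read_drug_metadata,
    read_interactions,
)
from .pmf import PMFConfig, pmf_fit, predict_scores
from .ensemble import EnsembleConfig, run_ensemble, select_candidates
from .clustering import (
    agglomerate,
    consensus_hits,
    enriched_clusters,
    pairwise_distance,
)
from .similarity import (
    MoleculeDescriptor,
    SimilarityConfig,
    expand_reference,
    read_molecules,
    similarity_filter,
)
from .synthetic import PipelineScenario

logger = logging.getLogger(__name__)

# fixed stage-seed offsets derived from the single global seed
_ENSEMBLE_SEED_OFFSET = 1
_REPRESENTATIVE_SEED_OFFSET = 1_000_003
_SEED_MOD = 2**31


@dataclass
class PipelineConfig:
    query_target: str
    interactions_path: str | None = None
    metadata_path: str | None = None
    molecules_path: str | None = None
    pmf: PMFConfig = field(default_factory=PMFConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    metrics: tuple[str, ...] = ("euclidean", "cosine", "cityblock")
    n_representative_fits: int = 5
    linkage: str = "average"
    alpha: float = 0.05
    min_cluster_size: int = 3
    max_cluster_size: int | None = None
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    ref_threshold: float = 1.5
    enable_similarity: bool = True
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ValueError("metrics list must be non-empty")
        for met in self.metrics:
            if met not in ("euclidean", "cosine", "cityblock", "mahalanobis"):
                raise ValueError(f"unsupported metric {met!r}")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                **{k: v for k, v in asdict(self).items() if k != "output_dir"},
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; carries the stage name and partial report."""

    def __init__(self, stage: str, report: PipelineReport, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.report = report
        self.cause = cause


def scenario_pipeline_config(
    scenario: PipelineScenario, seed: int = 0
) -> PipelineConfig:
    """Pipeline configuration sized for the planted synthetic scenario.

    The ensemble k is sized to the expected candidate pool: a frequency
    cut at 0.5 can select at most 2k drugs, and the enrichment universe
    needs the structured distractors admitted alongside the hidden truths.
    """
    n_structured = len(scenario.hidden_drugs) + len(scenario.distractor_drugs)
    return PipelineConfig(
        query_target=scenario.query_target,
        pmf=PMFConfig(latent_dim=10, reg_u=0.05, reg_v=0.05,
                      learn_rate=0.05, max_iter=150, tol=1e-8),
        ensemble=EnsembleConfig(n_runs=20, k=n_structured, freq_threshold=0.5),
        similarity=scenario.similarity_config,
        ref_threshold=1.5,
        seed=seed,
    )


def run_pipeline(
    config: PipelineConfig,
    interactions: InteractionMatrix | None = None,
    drug_records: list[DrugRecord] | None = None,
    descriptors: dict[str, MoleculeDescriptor] | None = None,
) -> PipelineReport:
    """Execute the full flow; in-memory inputs override the configured paths.

    Any stage error aborts with the stage name and the partial report
    attached. The report is a pure function of (inputs, config, seed).
    """
    report = PipelineReport(
        query_target=config.query_target,
        seed=config.seed,
        config_hash=config.config_hash(),
        seed_list={
            "ensemble_seed_base": (config.seed + _ENSEMBLE_SEED_OFFSET) % _SEED_MOD,
            "representative_fit": (config.seed + _REPRESENTATIVE_SEED_OFFSET) % _SEED_MOD,
        },
    )
    stage = "read_inputs"
    try:
        if interactions is None:
            if config.interactions_path is None:
                raise ValueError("no interaction matrix provided")
            interactions = read_interactions(config.interactions_path)
        if drug_records is None and config.metadata_path is not None:
            drug_records = read_drug_metadata(config.metadata_path)
        if drug_records is None:
            raise ValueError("no drug metadata provided")
        if descriptors is None and config.molecules_path is not None:
            descriptors = read_molecules(config.molecules_path, config.similarity)
        records_by_id = {r.drug_id: r for r in drug_records}
        missing_meta = [d for d in interactions.drugs if d not in records_by_id]
        if missing_meta:
            raise ValueError(f"drugs missing from metadata: {missing_meta[:5]}...")
        report.completed_stages.append(stage)

        stage = "known_set"
        known = interactions.known_drugs_for(config.query_target)
        if not known:
            raise ValueError(f"query target {config.query_target!r} has no known drugs")
        report.known_set = sorted(known)
        approved = filter_approved([records_by_id[d] for d in sorted(known)])
        approved_ids = {r.drug_id for r in approved}
        report.approved_known = sorted(approved_ids)
        logger.info("known drugs: %d, approved: %d", len(known), len(approved_ids))
        report.completed_stages.append(stage)

        stage = "ensemble"
        ens_cfg = replace(
            config.ensemble,
            seed_base=(config.seed + _ENSEMBLE_SEED_OFFSET) % _SEED_MOD,
        )
        table = run_ensemble(interactions, config.pmf, ens_cfg,
                             config.query_target, known)
        candidates = select_candidates(table)
        report.ensemble_candidates = candidates
        if not candidates:
            report.warnings.append("ensemble selected no candidates")
        report.completed_stages.append(stage)

        stage = "combine"
        combined = combine_candidate_set(approved_ids, set(candidates))
        report.combined_set = sorted(combined)
        report.completed_stages.append(stage)

        stage = "clustering"
        per_metric: dict[str, set[str]] = {}
        if candidates and approved_ids and len(combined) >= 2:
            # latent geometry for clustering: pairwise distances averaged
            # over several representative fits (distances are invariant to
            # the rotation/sign indeterminacy that forbids averaging U
            # itself), which suppresses per-fit sampling noise
            combined_sorted = sorted(combined, key=interactions.drug_index)
            idx = [interactions.drug_index(d) for d in combined_sorted]
            factor_rows = []
            for i in range(config.n_representative_fits):
                rep_cfg = replace(
                    config.pmf,
                    seed=(config.seed + _REPRESENTATIVE_SEED_OFFSET + i) % _SEED_MOD,
                )
                factor_rows.append(pmf_fit(interactions, rep_cfg).U[idx])
            for met in config.metrics:
                D = np.mean(
                    [pairwise_distance(rows, met, ids=combined_sorted)
                     for rows in factor_rows],
                    axis=0,
                )
                dendro = agglomerate(D, config.linkage, combined_sorted, met)
                enriched = enriched_clusters(
                    dendro, approved_ids, config.alpha,
                    config.min_cluster_size, config.max_cluster_size,
                )
                hit_set: set[str] = set()
                for res in enriched:
                    hit_set |= set(res.members) - approved_ids
                per_metric[met] = hit_set
        else:
            per_metric = {met: set() for met in config.metrics}
            report.warnings.append("clustering skipped: empty candidate or known set")
        report.per_metric_hits = {met: sorted(h) for met, h in per_metric.items()}
        report.completed_stages.append(stage)

        stage = "consensus"
        consensus = consensus_hits(per_metric, set(candidates)) if per_metric else set()
        report.consensus_hits = sorted(consensus)
        report.completed_stages.append(stage)

        stage = "similarity_filter"
        if config.enable_similarity and descriptors is not None and consensus:
            known_desc = [descriptors[d] for d in sorted(approved_ids) if d in descriptors]
            if not known_desc:
                raise ValueError("no descriptors available for approved known drugs")
            library = list(descriptors.values())
            reference = expand_reference(known_desc, library, config.ref_threshold)
            ranked = similarity_filter(
                sorted(consensus), descriptors, reference, config.similarity
            )
            report.filtered_hits = [
                {"drug_id": d, "score": s} for d, s in ranked
            ]
        else:
            if config.enable_similarity and descriptors is None:
                report.warnings.append(
                    "similarity stage skipped: no molecule descriptors; "
                    "final hits are the consensus hits"
                )
            report.filtered_hits = [
                {"drug_id": d, "score": None} for d in sorted(consensus)
            ]
        report.completed_stages.append(stage)
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        raise PipelineStageError(stage, report, exc) from exc

    report.validate()
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
        table.to_csv(outdir / "candidates.csv")
    return report


__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "scenario_pipeline_config",
]
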