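"""Planted-structure generators for every pipeline stage.

Nothing in the pipeline requires a live database: these generators emit
(i) sparse binary drug-target matrices with exact planted low-rank
structure and a withheld set of hidden true associations, (ii) synthetic
drug libraries with planted fingerprint families, and (iii) a complete
end-to-end scenario in which known drugs and hidden repurposable drugs
share both a latent (interaction-profile) family and a fingerprint
family, surrounded by structured distractor families and unstructured
decoys. Every generator is a pure function of its seed.

Fingerprints in the synthetic libraries are random bit vectors serialized
as ``fp:<hex>:<hex>`` tokens in place of SMILES; the similarity module
decodes them transparently, so no chemistry backend is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    DrugRecord,
    DrugStatus,
    InteractionMatrix,
    write_drug_metadata,
    write_interactions,
)
from .similarity import (
    MoleculeDescriptor,
    SimilarityConfig,
    descriptor_to_token,
)


# ---------------------------------------------------------------------------
# planted low-rank drug-target matrices

@dataclass
class PlantedDTI:
    """A planted low-rank bipartite network with withheld true pairs.

    Positives are the top density-quantile of U_true @ V_true.T (exact
    thresholding, not Bernoulli sampling, so the planted rank structure
    is sharp); ``hidden_positives`` are true pairs withheld from training
    and ``eval_negatives`` are ground-truth-negative pairs of matching
    count for held-out ranking evaluation.
    """

    R: InteractionMatrix
    hidden_positives: list[tuple[int, int]]
    eval_negatives: list[tuple[int, int]]
    U_true: np.ndarray
    V_true: np.ndarray
    params: dict = field(default_factory=dict)


def make_planted_dti(
    n: int = 200,
    m: int = 50,
    d_true: int = 5,
    density: float = 0.05,
    n_hidden: int = 20,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> PlantedDTI:
    """Generate a planted rank-``d_true`` binary interaction matrix.

    ``n_hidden`` true positives are withheld from the training matrix;
    ``noise_rate`` flips that fraction of training labels (hidden pairs
    are never re-inserted, so they stay disjoint from the observed set).
    """
    if d_true > min(n, m):
        raise ValueError("d_true must not exceed min(n, m)")
    n_pos = int(round(density * n * m))
    if not (0 < n_pos <= n * m):
        raise ValueError("density yields an empty or overfull positive set")
    if n_hidden >= n_pos:
        raise ValueError("n_hidden must be smaller than the planted positive count")
    rng = np.random.default_rng(seed)
    U_true = rng.uniform(0.0, 1.0, size=(n, d_true))
    V_true = rng.uniform(0.0, 1.0, size=(m, d_true))
    S = U_true @ V_true.T
    order = np.argsort(S, axis=None, kind="stable")[::-1]  # ties by flat index
    pos_flat = order[:n_pos]
    hidden_flat = rng.choice(pos_flat, size=n_hidden, replace=False)
    hidden = {(int(f) // m, int(f) % m) for f in hidden_flat}
    observed = {(int(f) // m, int(f) % m) for f in pos_flat} - hidden

    if noise_rate > 0:
        keep = rng.random(len(observed)) >= noise_rate
        obs_list = sorted(observed)
        observed = {p for p, k in zip(obs_list, keep) if k}
        n_flip_in = int(round(noise_rate * (n * m - n_pos)))
        forbidden = set(observed) | hidden | {(int(f) // m, int(f) % m) for f in pos_flat}
        flat = rng.permutation(n * m)
        for f in flat:
            if n_flip_in == 0:
                break
            p = (int(f) // m, int(f) % m)
            if p not in forbidden:
                observed.add(p)
                n_flip_in -= 1
    if not observed:
        raise ValueError("noise_rate removed every training positive")

    # ground-truth negatives for held-out evaluation
    positive_set = {(int(f) // m, int(f) % m) for f in pos_flat}
    neg_pool = [
        (i, j) for i in range(n) for j in range(m)
        if (i, j) not in positive_set and (i, j) not in observed
    ]
    n_eval = min(n_hidden, len(neg_pool))
    eval_idx = rng.choice(len(neg_pool), size=n_eval, replace=False) if n_eval else []
    eval_negatives = sorted(neg_pool[int(i)] for i in eval_idx)

    drugs = [f"d{i:04d}" for i in range(n)]
    targets = [f"t{j:04d}" for j in range(m)]
    R = InteractionMatrix(drugs=drugs, targets=targets, observed=observed)
    return PlantedDTI(
        R=R,
        hidden_positives=sorted(hidden),
        eval_negatives=eval_negatives,
        U_true=U_true,
        V_true=V_true,
        params=dict(
            n=n, m=m, d_true=d_true, density=density,
            n_hidden=n_hidden, noise_rate=noise_rate, seed=seed,
        ),
    )


# ---------------------------------------------------------------------------
# planted fingerprint families

@dataclass
class PlantedLibrary:
    """Synthetic molecule library with planted similarity families."""

    descriptors: list[MoleculeDescriptor]
    family_labels: dict[str, int]
    params: dict = field(default_factory=dict)

    def by_family(self, fam: int) -> list[MoleculeDescriptor]:
        return [d for d in self.descriptors if self.family_labels[d.drug_id] == fam]


def _expected_within_tanimoto(bit_density: float, mutation_rate: float) -> float:
    # two members = prototype XOR independent Bernoulli(mu) flips, per bit
    p, mu = bit_density, mutation_rate
    inter = p * (1 - mu) ** 2 + (1 - p) * mu**2
    union = 1.0 - (p * mu**2 + (1 - p) * (1 - mu) ** 2)
    return inter / union


def _expected_between_tanimoto(bit_density: float) -> float:
    p = bit_density
    return p * p / (1.0 - (1.0 - p) ** 2)


def _mutate(proto: np.ndarray, mutation_rate: float, rng: np.random.Generator) -> np.ndarray:
    while True:
        bits = np.logical_xor(proto, rng.random(proto.shape) < mutation_rate)
        if bits.any():
            return bits


def make_drug_library(
    n_molecules: int = 60,
    n_families: int = 4,
    tau_in: float = 0.75,
    tau_out: float = 0.3,
    fp_length: int = 256,
    bit_density: float = 0.3,
    mutation_rate: float = 0.03,
    seed: int = 0,
    id_prefix: str = "L",
) -> PlantedLibrary:
    """Planted fingerprint families: per family a random prototype pair of
    bit vectors (structural + feature channel), members mutated copies.

    Parameters are validated against the planted-similarity contract:
    expected within-family Tanimoto must reach ``tau_in`` and expected
    between-family Tanimoto must stay below ``tau_out``.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if fp_length < 64:
        raise ValueError("fp_length must be >= 64")
    if tau_in <= tau_out:
        raise ValueError("tau_in must exceed tau_out")
    exp_in = _expected_within_tanimoto(bit_density, mutation_rate)
    if exp_in < tau_in:
        raise ValueError(
            f"mutation_rate {mutation_rate} too high: expected within-family "
            f"Tanimoto {exp_in:.3f} < tau_in {tau_in}"
        )
    exp_out = _expected_between_tanimoto(bit_density)
    if exp_out > tau_out:
        raise ValueError(
            f"bit_density {bit_density} too high: expected between-family "
            f"Tanimoto {exp_out:.3f} > tau_out {tau_out}"
        )
    rng = np.random.default_rng(seed)
    protos = [
        (rng.random(fp_length) < bit_density, rng.random(fp_length) < bit_density)
        for _ in range(n_families)
    ]
    descriptors: list[MoleculeDescriptor] = []
    labels: dict[str, int] = {}
    for i in range(n_molecules):
        fam = i % n_families
        ps, pf = protos[fam]
        drug_id = f"{id_prefix}{i:03d}"
        descriptors.append(
            MoleculeDescriptor(
                drug_id=drug_id,
                fp_structural=_mutate(ps, mutation_rate, rng),
                fp_feature=_mutate(pf, mutation_rate, rng),
            )
        )
        labels[drug_id] = fam
    return PlantedLibrary(
        descriptors=descriptors,
        family_labels=labels,
        params=dict(
            n_molecules=n_molecules, n_families=n_families, tau_in=tau_in,
            tau_out=tau_out, fp_length=fp_length, bit_density=bit_density,
            mutation_rate=mutation_rate, seed=seed,
        ),
    )


# ---------------------------------------------------------------------------
# worked-example roster (approved-drug filtering arithmetic)

def make_known_roster(
    n_drugs: int = 35, n_removed: int = 8, seed: int = 0
) -> list[DrugRecord]:
    """A known-drug roster in which ``n_removed`` drugs are flagged illicit
    or withdrawn and the rest are approved; flag positions are seeded."""
    if not (0 <= n_removed <= n_drugs):
        raise ValueError("n_removed must be in [0, n_drugs]")
    rng = np.random.default_rng(seed)
    flagged = set(rng.choice(n_drugs, size=n_removed, replace=False).tolist())
    records = []
    for i in range(n_drugs):
        if i in flagged:
            status = DrugStatus.ILLICIT if i % 2 == 0 else DrugStatus.WITHDRAWN
        else:
            status = DrugStatus.APPROVED
        records.append(DrugRecord(drug_id=f"K{i:03d}", name=f"known-{i}", status=status))
    return records


# ---------------------------------------------------------------------------
# end-to-end planted pipeline scenario

@dataclass
class PipelineScenario:
    """All inputs plus ground truth for one planted end-to-end run.

    The query target's known binders and the hidden repurposable drugs
    belong to one latent family (shared target block) and one fingerprint
    family; hidden drugs sit at the family consensus profile while known
    drugs are noisy satellites. Structured distractor families overlap
    the query family's target block so the ensemble admits non-family
    candidates (without them the combined set is saturated by the family
    and no cluster can be enriched); unstructured decoys have random
    interactions and random fingerprints.
    """

    interactions: InteractionMatrix
    drug_records: list[DrugRecord]
    descriptors: dict[str, MoleculeDescriptor]
    query_target: str
    known_drugs: set[str]           # all known binders of the query target
    approved_known: set[str]        # known binders that survive status filtering
    hidden_drugs: set[str]          # planted repurposable truths
    distractor_drugs: set[str]
    decoy_drugs: set[str]
    similarity_config: SimilarityConfig
    params: dict = field(default_factory=dict)


def make_pipeline_scenario(
    seed: int = 0,
    n_known: int = 14,
    n_known_flagged: int = 2,
    n_hidden: int = 4,
    n_distractor_families: int = 3,
    distractor_family_size: int = 10,
    n_decoys: int = 15,
    m_targets: int = 40,
    family_block: int = 10,
    family_edge_prob: float = 0.9,
    n_extra_edges: int = 1,
    fp_length: int = 256,
    fp_bit_density: float = 0.3,
    fp_mutation_known: float = 0.04,
    fp_mutation_hidden: float = 0.01,
) -> PipelineScenario:
    """Build the planted repurposing scenario.

    Target ``t00`` is the query. Known drugs bind a block of
    ``family_block`` targets including t00 (each edge kept with
    ``family_edge_prob`` plus ``n_extra_edges`` random extras, so the
    family is noisy); hidden drugs carry the exact family profile minus
    the withheld t00 edge. Each distractor family binds its own block
    overlapping the query family's, which gives its members elevated
    query scores without making them true hits. Decoys draw a handful of
    random targets (never t00) and random fingerprints.
    """
    if n_known_flagged >= n_known:
        raise ValueError("need at least one approved known drug")
    rng = np.random.default_rng(seed)
    targets = [f"t{j:02d}" for j in range(m_targets)]
    query = targets[0]
    fam_targets = list(range(family_block))  # t00..t(block-1)

    drug_ids: list[str] = []
    records: list[DrugRecord] = []
    edges: set[tuple[int, int]] = set()

    def add_drug(drug_id: str, status: DrugStatus, tjs: set[int]) -> None:
        idx = len(drug_ids)
        drug_ids.append(drug_id)
        records.append(DrugRecord(drug_id=drug_id, name=drug_id, status=status))
        for j in tjs:
            edges.add((idx, j))

    def noisy_block(block: list[int], forced: set[int], banned: set[int]) -> set[int]:
        tjs = {j for j in block if rng.random() < family_edge_prob}
        extras = rng.choice(range(1, m_targets), size=n_extra_edges, replace=False)
        tjs |= set(int(e) for e in extras)
        return (tjs | forced) - banned

    known_ids, approved_ids = [], []
    for i in range(n_known):
        drug_id = f"KN{i:02d}"
        flagged = i >= n_known - n_known_flagged
        status = DrugStatus.ILLICIT if flagged else DrugStatus.APPROVED
        add_drug(drug_id, status, noisy_block(fam_targets, forced={0}, banned=set()))
        known_ids.append(drug_id)
        if not flagged:
            approved_ids.append(drug_id)

    hidden_ids = []
    for i in range(n_hidden):
        drug_id = f"HD{i:02d}"
        # exact consensus profile, t00 withheld: the planted repurposable truth
        add_drug(drug_id, DrugStatus.APPROVED, set(fam_targets) - {0})
        hidden_ids.append(drug_id)

    distractor_ids = []
    for f in range(n_distractor_families):
        offset = 4 + 2 * f  # block overlaps the query family's but excludes t00
        block = [(offset + j) for j in range(family_block)]
        for i in range(distractor_family_size):
            drug_id = f"DS{f}{i:02d}"
            add_drug(drug_id, DrugStatus.APPROVED, noisy_block(block, forced=set(), banned={0}))
            distractor_ids.append(drug_id)

    decoy_ids = []
    for i in range(n_decoys):
        drug_id = f"DC{i:02d}"
        n_e = int(rng.integers(5, 9))
        tjs = set(int(t) for t in rng.choice(range(1, m_targets), size=n_e, replace=False))
        add_drug(drug_id, DrugStatus.APPROVED, tjs)
        decoy_ids.append(drug_id)

    R = InteractionMatrix(drugs=drug_ids, targets=targets, observed=edges)

    # fingerprints: one family prototype shared by known + hidden drugs,
    # one per distractor family, independent random vectors for decoys
    sim_cfg = SimilarityConfig(fp_length=fp_length)
    descriptors: dict[str, MoleculeDescriptor] = {}

    def proto() -> tuple[np.ndarray, np.ndarray]:
        return (rng.random(fp_length) < fp_bit_density,
                rng.random(fp_length) < fp_bit_density)

    fam_s, fam_f = proto()
    for drug_id in known_ids:
        descriptors[drug_id] = MoleculeDescriptor(
            drug_id, _mutate(fam_s, fp_mutation_known, rng),
            _mutate(fam_f, fp_mutation_known, rng))
    for drug_id in hidden_ids:
        descriptors[drug_id] = MoleculeDescriptor(
            drug_id, _mutate(fam_s, fp_mutation_hidden, rng),
            _mutate(fam_f, fp_mutation_hidden, rng))
    for f in range(n_distractor_families):
        ds, df = proto()
        fam_members = [d for d in distractor_ids if d.startswith(f"DS{f}")]
        for drug_id in fam_members:
            descriptors[drug_id] = MoleculeDescriptor(
                drug_id, _mutate(ds, fp_mutation_known, rng),
                _mutate(df, fp_mutation_known, rng))
    for drug_id in decoy_ids:
        ds, df = proto()
        descriptors[drug_id] = MoleculeDescriptor(drug_id, ds, df)

    return PipelineScenario(
        interactions=R,
        drug_records=records,
        descriptors=descriptors,
        query_target=query,
        known_drugs=set(known_ids),
        approved_known=set(approved_ids),
        hidden_drugs=set(hidden_ids),
        distractor_drugs=set(distractor_ids),
        decoy_drugs=set(decoy_ids),
        similarity_config=sim_cfg,
        params=dict(
            seed=seed, n_known=n_known, n_known_flagged=n_known_flagged,
            n_hidden=n_hidden, n_distractor_families=n_distractor_families,
            distractor_family_size=distractor_family_size, n_decoys=n_decoys,
            m_targets=m_targets, family_block=family_block,
            family_edge_prob=family_edge_prob, n_extra_edges=n_extra_edges,
            fp_length=fp_length, fp_bit_density=fp_bit_density,
            fp_mutation_known=fp_mutation_known, fp_mutation_hidden=fp_mutation_hidden,
        ),
    )


def write_scenario(scenario: PipelineScenario, outdir: str | Path) -> dict[str, Path]:
    """Write scenario inputs in the formats the io readers consume:
    edge-list TSV, metadata CSV, and a molecules file of fp: tokens."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": outdir / "interactions.tsv",
        "drugs": outdir / "drugs.csv",
        "molecules": outdir / "molecules.smi",
    }
    write_interactions(scenario.interactions, paths["interactions"])
    write_drug_metadata(scenario.drug_records, paths["drugs"])
    with paths["molecules"].open("w") as fh:
        for drug_id in scenario.interactions.drugs:
            token = descriptor_to_token(scenario.descriptors[drug_id])
            fh.write(f"{token} {drug_id}\n")
    return paths


__all__ = [
    "PlantedDTI",
    "PlantedLibrary",
    "PipelineScenario",
    "make_planted_dti",
    "make_drug_library",
    "make_known_roster",
    "make_pipeline_scenario",
    "write_scenario",
]
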