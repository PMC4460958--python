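"""Data model and I/O for drug-target interaction data.

The pipeline's primary input is a sparse binary bipartite association
matrix between drugs and protein targets (1 = annotated interaction),
read from a headerless two-column edge list, plus a drug metadata table
carrying each drug's regulatory status (approved / illicit / withdrawn).
Illicit and withdrawn drugs are removed before any repurposing inference.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class DrugStatus(enum.Enum):
    APPROVED = "approved"
    ILLICIT = "illicit"
    WITHDRAWN = "withdrawn"
    OTHER = "other"


@dataclass(frozen=True)
class DrugRecord:
    """One drug's metadata: id, display name, regulatory status, optional SMILES."""

    drug_id: str
    name: str = ""
    status: DrugStatus = DrugStatus.OTHER
    smiles: str | None = None


def parse_status(raw: str) -> DrugStatus:
    """Map a free-text status string to the enum; unknown strings become OTHER.

    Unknown statuses are treated as not-approved downstream, mirroring the
    conservative removal of illicit/withdrawn drugs from the analysis.
    """
    try:
        return DrugStatus(raw.strip().lower())
    except ValueError:
        logger.warning("unknown drug status %r mapped to 'other'", raw)
        return DrugStatus.OTHER


@dataclass
class InteractionMatrix:
    """Sparse binary drug x target association matrix.

    ``drugs`` and ``targets`` are ordered identifier registries (row and
    column order); ``observed`` holds (drug_index, target_index) pairs
    treated as positive associations. Identifier comparison is
    case-sensitive exact match throughout.
    """

    drugs: list[str]
    targets: list[str]
    observed: set[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.drugs or not self.targets:
            raise ValueError("interaction matrix needs at least one drug and one target")
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError("duplicate drug ids in registry")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("duplicate target ids in registry")
        n, m = self.shape
        for i, j in self.observed:
            if not (0 <= i < n and 0 <= j < m):
                raise ValueError(f"observed pair ({i}, {j}) out of bounds for {n}x{m}")
        self._drug_index = {d: i for i, d in enumerate(self.drugs)}
        self._target_index = {t: j for j, t in enumerate(self.targets)}

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.drugs), len(self.targets)

    def drug_index(self, drug_id: str) -> int:
        try:
            return self._drug_index[drug_id]
        except KeyError:
            raise KeyError(f"unknown drug id {drug_id!r}") from None

    def target_index(self, target_id: str) -> int:
        try:
            return self._target_index[target_id]
        except KeyError:
            raise KeyError(f"unknown target id {target_id!r}") from None

    def known_drugs_for(self, target_id: str) -> set[str]:
        """Drug ids with an observed association to ``target_id``."""
        j = self.target_index(target_id)
        return {self.drugs[i] for i, jj in self.observed if jj == j}

    def edges(self) -> list[tuple[str, str]]:
        """Observed pairs as (drug_id, target_id), in registry order."""
        return [
            (self.drugs[i], self.targets[j])
            for i, j in sorted(self.observed)
        ]


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_interactions(path: str | Path, header: bool = False) -> InteractionMatrix:
    """Read a drug-target edge list (TSV or CSV, columns drug_id, target_id).

    Registries are built in first-appearance order; duplicate edges are
    collapsed with a logged count. Malformed rows raise, naming the line.
    """
    path = Path(path)
    drugs: list[str] = []
    targets: list[str] = []
    drug_ix: dict[str, int] = {}
    target_ix: dict[str, int] = {}
    observed: set[tuple[int, int]] = set()
    n_dup = 0
    delim: str | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            parts = [p.strip() for p in line.split(delim)]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}: malformed edge-list row at line {lineno}: {line!r}")
            d, t = parts[0], parts[1]
            if d not in drug_ix:
                drug_ix[d] = len(drugs)
                drugs.append(d)
            if t not in target_ix:
                target_ix[t] = len(targets)
                targets.append(t)
            pair = (drug_ix[d], target_ix[t])
            if pair in observed:
                n_dup += 1
            else:
                observed.add(pair)
    if not observed:
        raise ValueError(f"{path}: no associations")
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_dup)
    return InteractionMatrix(drugs=drugs, targets=targets, observed=observed)


def write_interactions(matrix: InteractionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write the edge list in canonical (registry) order."""
    path = Path(path)
    with path.open("w") as fh:
        for d, t in matrix.edges():
            fh.write(f"{d}{delimiter}{t}\n")


def read_drug_metadata(path: str | Path) -> list[DrugRecord]:
    """Read a drug metadata CSV with header ``id,name,status,smiles``."""
    path = Path(path)
    records: list[DrugRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "status"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: metadata header must include columns 'id' and 'status'")
        for row in reader:
            drug_id = row["id"].strip()
            if not drug_id:
                raise ValueError(f"{path}: empty drug id in metadata row {row!r}")
            if drug_id in seen:
                raise ValueError(f"{path}: duplicate drug id {drug_id!r}")
            seen.add(drug_id)
            smiles = (row.get("smiles") or "").strip() or None
            records.append(
                DrugRecord(
                    drug_id=drug_id,
                    name=(row.get("name") or "").strip(),
                    status=parse_status(row["status"]),
                    smiles=smiles,
                )
            )
    return records


def write_drug_metadata(records: Sequence[DrugRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "status", "smiles"])
        for r in records:
            writer.writerow([r.drug_id, r.name, r.status.value, r.smiles or ""])


def filter_approved(drugs: Iterable[DrugRecord]) -> list[DrugRecord]:
    """Keep only approved drugs, preserving order.

    Illicit, withdrawn, and unknown-status drugs are all excluded: the
    screen only proposes repurposing of drugs that remain on the market.
    """
    kept = [d for d in drugs if d.status is DrugStatus.APPROVED]
    return kept


def combine_candidate_set(known_approved: set[str], predicted: set[str]) -> set[str]:
    """Union of the approved known-drug set and the ensemble-predicted set.

    In the reference analysis the two sets are disjoint (predictions
    exclude known binders); any overlap is logged, not an error.
    """
    overlap = known_approved & predicted
    if overlap:
        logger.warning("known and predicted sets overlap on %d drug(s)", len(overlap))
    return known_approved | predicted


@dataclass
class PipelineReport:
    """Stage-by-stage record of one pipeline run, serializable to JSON."""

    query_target: str = ""
    seed: int = 0
    config_hash: str = ""
    seed_list: dict[str, int] = field(default_factory=dict)
    known_set: list[str] = field(default_factory=list)
    approved_known: list[str] = field(default_factory=list)
    ensemble_candidates: list[str] = field(default_factory=list)
    combined_set: list[str] = field(default_factory=list)
    per_metric_hits: dict[str, list[str]] = field(default_factory=dict)
    consensus_hits: list[str] = field(default_factory=list)
    filtered_hits: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    completed_stages: list[str] = field(default_factory=list)

    def validate(self) -> None:
        consensus = set(self.consensus_hits)
        for metric, hits in self.per_metric_hits.items():
            if not consensus <= set(hits):
                raise ValueError(f"consensus hits not a subset of {metric} hits")
        final = {h["drug_id"] for h in self.filtered_hits}
        if not final <= consensus:
            raise ValueError("final hits not a subset of consensus hits")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "PipelineReport":
        return cls(**json.loads(text))
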