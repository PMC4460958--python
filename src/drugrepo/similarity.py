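"""Two-component chemical similarity scoring and threshold filtering.

The combined score sums two Tanimoto coefficients — one over a structural
fingerprint, one over a pharmacophoric-feature fingerprint — giving a
value in [0, 2] whose 1.5 cut marks strong structural-and-chemical
similarity. The default backend is a deterministic 2D surrogate built on
RDKit Morgan fingerprints (plain atom invariants for the structural
component, feature invariants for the pharmacophoric one); the scorer is
pluggable so a conformer-based 3D shape/color backend can be swapped in
without touching the filtering logic.

Molecules can also enter as pre-computed fingerprints serialized as hex
tokens (``fp:<hex>:<hex>``), which the synthetic library generator emits
in place of SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

FP_SURROGATE_PREFIX = "fp:"


@dataclass(frozen=True)
class SimilarityConfig:
    combo_threshold: float = 1.5
    fp_length: int = 2048
    radius: int = 2
    scorer: str = "tanimoto"

    def __post_init__(self) -> None:
        if not (0.0 <= self.combo_threshold <= 2.0):
            raise ValueError("combo_threshold must be in [0, 2]")
        if self.fp_length < 1:
            raise ValueError("fp_length must be positive")


@dataclass(frozen=True)
class MoleculeDescriptor:
    """Structural + pharmacophoric-feature bit vectors for one drug."""

    drug_id: str
    fp_structural: np.ndarray  # bool, fixed length
    fp_feature: np.ndarray     # bool, same length

    def __post_init__(self) -> None:
        if self.fp_structural.shape != self.fp_feature.shape:
            raise ValueError(f"{self.drug_id}: fingerprint length mismatch")


def _fp_to_array(fp, length: int) -> np.ndarray:
    arr = np.zeros(length, dtype=bool)
    arr[list(fp.GetOnBits())] = True
    return arr


def featurize(
    smiles: str, config: SimilarityConfig = SimilarityConfig(), drug_id: str = "?"
) -> MoleculeDescriptor:
    """Deterministic descriptor from a SMILES string (or hex surrogate token).

    RDKit canonicalizes on parse, so equivalent SMILES yield identical
    descriptors. Unparsable input raises, naming the drug.
    """
    if smiles.startswith(FP_SURROGATE_PREFIX):
        return descriptor_from_hex(smiles, config, drug_id)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES for drug {drug_id!r}: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.fp_length
    )
    feat_gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius,
        fpSize=config.fp_length,
        atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
    )
    fp_s = _fp_to_array(gen.GetFingerprint(mol), config.fp_length)
    fp_f = _fp_to_array(feat_gen.GetFingerprint(mol), config.fp_length)
    if not fp_s.any() or not fp_f.any():
        raise ValueError(f"empty molecule for drug {drug_id!r}: {smiles!r}")
    return MoleculeDescriptor(drug_id=drug_id, fp_structural=fp_s, fp_feature=fp_f)


def bits_to_hex(bits: np.ndarray) -> str:
    return np.packbits(bits.astype(np.uint8)).tobytes().hex()


def hex_to_bits(hexstr: str, length: int) -> np.ndarray:
    raw = np.unpackbits(np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8))
    if len(raw) < length:
        raise ValueError(f"hex fingerprint shorter than configured length {length}")
    return raw[:length].astype(bool)


def descriptor_to_token(desc: MoleculeDescriptor) -> str:
    """Serialize a descriptor as a ``fp:<hex>:<hex>`` surrogate token."""
    return FP_SURROGATE_PREFIX + bits_to_hex(desc.fp_structural) + ":" + bits_to_hex(desc.fp_feature)


def descriptor_from_hex(
    token: str, config: SimilarityConfig, drug_id: str
) -> MoleculeDescriptor:
    body = token[len(FP_SURROGATE_PREFIX):]
    try:
        hex_s, hex_f = body.split(":")
        fp_s = hex_to_bits(hex_s, config.fp_length)
        fp_f = hex_to_bits(hex_f, config.fp_length)
    except ValueError as exc:
        raise ValueError(f"malformed fingerprint token for drug {drug_id!r}: {exc}") from exc
    return MoleculeDescriptor(drug_id=drug_id, fp_structural=fp_s, fp_feature=fp_f)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|; two all-zero vectors count as identical (1.0)."""
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


Scorer = Callable[[np.ndarray, np.ndarray], float]


def combo_score(
    d1: MoleculeDescriptor,
    d2: MoleculeDescriptor,
    structural_scorer: Scorer = tanimoto,
    feature_scorer: Scorer = tanimoto,
) -> float:
    """Structural + feature similarity, symmetric, in [0, 2]."""
    if d1.fp_structural.shape != d2.fp_structural.shape:
        raise ValueError(
            f"descriptors from different configs: {d1.drug_id} vs {d2.drug_id}"
        )
    return structural_scorer(d1.fp_structural, d2.fp_structural) + feature_scorer(
        d1.fp_feature, d2.fp_feature
    )


def expand_reference(
    known_drugs: Sequence[MoleculeDescriptor],
    library: Sequence[MoleculeDescriptor],
    threshold: float,
    structural_scorer: Scorer = tanimoto,
    feature_scorer: Scorer = tanimoto,
) -> list[MoleculeDescriptor]:
    """Grow the reference set: library members whose best combined score
    against any known drug meets ``threshold`` (plus the knowns themselves)."""
    if not known_drugs:
        raise ValueError("empty known-drug set")
    out: dict[str, MoleculeDescriptor] = {d.drug_id: d for d in known_drugs}
    for mol in library:
        if mol.drug_id in out:
            continue
        best = max(
            combo_score(mol, kd, structural_scorer, feature_scorer) for kd in known_drugs
        )
        if best >= threshold:
            out[mol.drug_id] = mol
    return list(out.values())


def similarity_filter(
    hits: Iterable[str],
    descriptors: Mapping[str, MoleculeDescriptor],
    reference: Sequence[MoleculeDescriptor],
    config: SimilarityConfig = SimilarityConfig(),
    structural_scorer: Scorer = tanimoto,
    feature_scorer: Scorer = tanimoto,
) -> list[tuple[str, float]]:
    """Keep hits whose best combined score against the reference set meets
    the threshold, ranked by that score descending (ties by drug_id)."""
    hits = list(hits)
    missing = sorted(h for h in hits if h not in descriptors)
    if missing:
        raise ValueError(f"missing molecule descriptors for: {missing}")
    if not reference:
        return []
    scored = []
    for h in hits:
        best = max(
            combo_score(descriptors[h], ref, structural_scorer, feature_scorer)
            for ref in reference
        )
        if best >= config.combo_threshold:
            scored.append((h, best))
    scored.sort(key=lambda hs: (-hs[1], hs[0]))
    return scored


def read_molecules(
    path: str | Path, config: SimilarityConfig = SimilarityConfig()
) -> dict[str, MoleculeDescriptor]:
    """Read a SMILES file (one record per line: SMILES whitespace drug_id).

    Lines whose molecule field is an ``fp:`` hex token are decoded directly
    instead of being parsed as SMILES.
    """
    path = Path(path)
    out: dict[str, MoleculeDescriptor] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno} needs 'SMILES drug_id'")
            smiles, drug_id = parts[0], parts[1]
            out[drug_id] = featurize(smiles, config, drug_id=drug_id)
    return out


def write_descriptor_cache(
    descriptors: Mapping[str, MoleculeDescriptor], path: str | Path
) -> None:
    """Delimited-text cache (drug_id, hex structural, hex feature) for exact reuse."""
    with Path(path).open("w") as fh:
        for drug_id in sorted(descriptors):
            d = descriptors[drug_id]
            fh.write(f"{drug_id}\t{bits_to_hex(d.fp_structural)}\t{bits_to_hex(d.fp_feature)}\n")


def read_descriptor_cache(
    path: str | Path, config: SimilarityConfig = SimilarityConfig()
) -> dict[str, MoleculeDescriptor]:
    out: dict[str, MoleculeDescriptor] = {}
    for line in Path(path).read_text().splitlines():
        drug_id, hex_s, hex_f = line.split("\t")
        out[drug_id] = MoleculeDescriptor(
            drug_id=drug_id,
            fp_structural=hex_to_bits(hex_s, config.fp_length),
            fp_feature=hex_to_bits(hex_f, config.fp_length),
        )
    return out


__all__ = [
    "SimilarityConfig",
    "MoleculeDescriptor",
    "featurize",
    "tanimoto",
    "combo_score",
    "expand_reference",
    "similarity_filter",
    "read_molecules",
    "bits_to_hex",
    "hex_to_bits",
    "descriptor_to_token",
    "descriptor_from_hex",
    "write_descriptor_cache",
    "read_descriptor_cache",
]
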