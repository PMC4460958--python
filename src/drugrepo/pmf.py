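"""Probabilistic matrix factorization of the binary drug-target matrix.

The model approximates the n x m association matrix R by U V^T with
D-dimensional latent rows per drug (U) and per target (V), minimizing
the regularized squared loss over the observed positives plus an equal
number of seeded sampled negatives (the binary matrix carries no explicit
negatives, so unobserved pairs are subsampled 1:1, standard implicit-
feedback practice):

    L = sum_{(i,j) in S} (R_ij - U_i . V_j)^2 + reg_u ||U||^2 + reg_v ||V||^2

Optimization is full-batch gradient descent with backtracking halving of
the step, so the objective is non-increasing across accepted iterations
and every fit is a pure function of its seed. Scores are raw dot products
(no squashing): only the rank order feeds the downstream stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import InteractionMatrix

_MAX_HALVINGS = 40


@dataclass(frozen=True)
class PMFConfig:
    latent_dim: int = 20
    reg_u: float = 0.1
    reg_v: float = 0.1
    learn_rate: float = 0.01
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    init_scale: float = 0.1
    neg_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.reg_u < 0 or self.reg_v < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.learn_rate <= 0:
            raise ValueError("learn_rate must be positive")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")


@dataclass
class LatentFactors:
    """Fitted drug (U: n x D) and target (V: m x D) latent vectors."""

    U: np.ndarray
    V: np.ndarray
    config: PMFConfig
    final_objective: float
    n_iter: int = 0

    def __post_init__(self) -> None:
        if self.U.ndim != 2 or self.V.ndim != 2 or self.U.shape[1] != self.V.shape[1]:
            raise ValueError("U and V must be 2-D with a common latent dimension")
        if not (np.isfinite(self.U).all() and np.isfinite(self.V).all()):
            raise ValueError("latent factors contain non-finite entries")

    def save(self, path: str | Path) -> None:
        """Two-block delimited-text dump (config header, drug block, target block)."""
        cfg = self.config
        with Path(path).open("w") as fh:
            fh.write(
                "#config\t"
                f"latent_dim={cfg.latent_dim}\treg_u={cfg.reg_u!r}\treg_v={cfg.reg_v!r}\t"
                f"learn_rate={cfg.learn_rate!r}\tmax_iter={cfg.max_iter}\ttol={cfg.tol!r}\t"
                f"seed={cfg.seed}\tinit_scale={cfg.init_scale!r}\tneg_ratio={cfg.neg_ratio!r}\t"
                f"final_objective={self.final_objective!r}\tn_iter={self.n_iter}\n"
            )
            fh.write(f"#drugs\t{self.U.shape[0]}\n")
            for row in self.U:
                fh.write("\t".join(repr(float(x)) for x in row) + "\n")
            fh.write(f"#targets\t{self.V.shape[0]}\n")
            for row in self.V:
                fh.write("\t".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LatentFactors":
        lines = Path(path).read_text().splitlines()
        head = dict(kv.split("=", 1) for kv in lines[0].split("\t")[1:])
        cfg = PMFConfig(
            latent_dim=int(head["latent_dim"]),
            reg_u=float(head["reg_u"]),
            reg_v=float(head["reg_v"]),
            learn_rate=float(head["learn_rate"]),
            max_iter=int(head["max_iter"]),
            tol=float(head["tol"]),
            seed=int(head["seed"]),
            init_scale=float(head["init_scale"]),
            neg_ratio=float(head["neg_ratio"]),
        )
        n = int(lines[1].split("\t")[1])
        U = np.array([[float(x) for x in ln.split("\t")] for ln in lines[2 : 2 + n]])
        m = int(lines[2 + n].split("\t")[1])
        V = np.array([[float(x) for x in ln.split("\t")] for ln in lines[3 + n : 3 + n + m]])
        return cls(U=U, V=V, config=cfg,
                   final_objective=float(head["final_objective"]),
                   n_iter=int(head["n_iter"]))


def sample_negative_pairs(
    shape: tuple[int, int],
    exclude: set[tuple[int, int]],
    n_samples: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Sample distinct unobserved (i, j) pairs uniformly, excluding ``exclude``."""
    n, m = shape
    n_free = n * m - len(exclude)
    if n_samples > n_free:
        raise ValueError(f"cannot sample {n_samples} negatives: only {n_free} unobserved pairs")
    if n_samples > n_free // 2:
        # dense regime: enumerate the complement and choose without replacement
        taken = np.fromiter((i * m + j for i, j in exclude), dtype=np.int64, count=len(exclude))
        free = np.setdiff1d(np.arange(n * m, dtype=np.int64), taken)
        flat = rng.choice(free, size=n_samples, replace=False)
        return [(int(f) // m, int(f) % m) for f in flat]
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_samples:
        batch = rng.integers(0, n * m, size=2 * (n_samples - len(chosen)))
        for f in batch:
            pair = (int(f) // m, int(f) % m)
            if pair not in exclude and pair not in chosen:
                chosen.add(pair)
                if len(chosen) == n_samples:
                    break
    return sorted(chosen)


def _objective(U, V, ii, jj, r, reg_u, reg_v) -> float:
    err = r - np.einsum("ij,ij->i", U[ii], V[jj])
    return float(err @ err + reg_u * (U * U).sum() + reg_v * (V * V).sum())


def pmf_fit(R: InteractionMatrix, config: PMFConfig = PMFConfig()) -> LatentFactors:
    """Fit latent factors by seeded gradient descent with backtracking.

    Deterministic given ``config.seed``; raises if the objective becomes
    non-finite (diverging step) after exhausting backtracking halvings.

    The fit runs in a canonical identifier-sorted index space, so it is
    exactly label-invariant: permuting the registry order of drugs (or
    targets) permutes the returned factor rows and nothing else.
    """
    n, m = R.shape
    D = config.latent_dim
    # canonical space: rows/columns ordered by identifier
    drug_perm = np.array(sorted(range(n), key=lambda i: R.drugs[i]))
    target_perm = np.array(sorted(range(m), key=lambda j: R.targets[j]))
    drug_rank = np.empty(n, dtype=np.intp)
    drug_rank[drug_perm] = np.arange(n)
    target_rank = np.empty(m, dtype=np.intp)
    target_rank[target_perm] = np.arange(m)
    observed = {(int(drug_rank[i]), int(target_rank[j])) for i, j in R.observed}

    rng = np.random.default_rng(config.seed)
    U = rng.normal(0.0, config.init_scale, size=(n, D))
    V = rng.normal(0.0, config.init_scale, size=(m, D))

    pos = sorted(observed)
    n_neg = int(round(config.neg_ratio * len(pos)))
    n_neg = min(n_neg, n * m - len(pos))
    neg = sample_negative_pairs((n, m), observed, n_neg, rng) if n_neg > 0 else []
    pairs = pos + neg
    ii = np.array([p[0] for p in pairs], dtype=np.intp)
    jj = np.array([p[1] for p in pairs], dtype=np.intp)
    r = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])

    obj = _objective(U, V, ii, jj, r, config.reg_u, config.reg_v)
    if not np.isfinite(obj):
        raise FloatingPointError("initial objective non-finite; reduce init_scale")
    it = 0
    for it in range(1, config.max_iter + 1):
        err = r - np.einsum("ij,ij->i", U[ii], V[jj])
        gU = 2.0 * config.reg_u * U
        gV = 2.0 * config.reg_v * V
        np.subtract.at(gU, ii, 2.0 * err[:, None] * V[jj])
        np.subtract.at(gV, jj, 2.0 * err[:, None] * U[ii])

        step = config.learn_rate
        for _ in range(_MAX_HALVINGS):
            U_new = U - step * gU
            V_new = V - step * gV
            obj_new = _objective(U_new, V_new, ii, jj, r, config.reg_u, config.reg_v)
            if np.isfinite(obj_new) and obj_new <= obj:
                break
            step *= 0.5
        else:
            raise FloatingPointError(
                "PMF objective diverged despite backtracking; reduce learn_rate"
            )
        U, V = U_new, V_new
        delta = obj - obj_new
        obj = obj_new
        if delta < config.tol:
            break

    # map factors back to registry order
    U = U[drug_rank]
    V = V[target_rank]
    return LatentFactors(U=U, V=V, config=config, final_objective=obj, n_iter=it)


def predict_scores(factors: LatentFactors) -> np.ndarray:
    """Raw dot-product score matrix U V^T (n drugs x m targets)."""
    return factors.U @ factors.V.T


def rank_candidates(
    scores: np.ndarray,
    R: InteractionMatrix,
    target_id: str,
    k: int,
    exclude: set[str] = frozenset(),
) -> list[str]:
    """Top-k drugs by descending score for one target column.

    Drugs in ``exclude`` (typically the target's known binders) are removed
    first; ties break by ascending drug_id so rankings are deterministic.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    j = R.target_index(target_id)
    col = scores[:, j]
    candidates = [(-col[i], d) for i, d in enumerate(R.drugs) if d not in exclude]
    candidates.sort()
    return [d for _, d in candidates[:k]]


def heldout_auc(
    scores: np.ndarray,
    hidden_positives: Sequence[tuple[int, int]],
    sampled_negatives: Sequence[tuple[int, int]],
) -> float:
    """Exact pairwise AUC: P(random hidden positive outscores a random negative).

    Computed by enumerating every positive-negative pair (ties count 1/2),
    not by a trapezoid ROC approximation.
    """
    if len(hidden_positives) == 0:
        raise ValueError("empty hidden-positive set")
    if len(sampled_negatives) == 0:
        raise ValueError("empty sampled-negative set")
    ps = np.array([scores[i, j] for i, j in hidden_positives])
    ns = np.array([scores[i, j] for i, j in sampled_negatives])
    diff = ps[:, None] - ns[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (len(ps) * len(ns)))


__all__ = [
    "PMFConfig",
    "LatentFactors",
    "pmf_fit",
    "predict_scores",
    "rank_candidates",
    "heldout_auc",
    "sample_negative_pairs",
]
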