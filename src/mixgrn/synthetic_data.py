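"""Synthetic regression problems with the model's own generative structure.

Draws Y = X B + E with

* X: n x p standard-normal TF expression,
* B: row-structured sparse coefficients — a fixed fraction of TF rows is
  "active" and each active row hits a fixed fraction of the s targets with
  coefficients of magnitude ``b_scale`` and random signs (the planted
  master-regulator structure),
* E: rows i.i.d. multivariate normal with a sparse precision matrix
  (banded / random sparse / diagonal), globally rescaled so that
  ``||XB||_F^2 / ||E||_F^2`` hits the requested signal-to-noise ratio.

The planted support doubles as a gold standard (positives = planted edges,
negatives sampled uniformly from non-edges at a configurable ratio), so the
whole inference-evaluation pipeline runs without any external download.
Everything is a pure function of the spec, including its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    ExpressionDataset,
    GoldStandard,
    RegressionProblem,
    write_expression_table,
)
from .network import ConditionProfile

#: negative:positive sampling ratio of the synthetic gold standard
DEFAULT_NEGATIVE_RATIO = 1.0
#: preset mimicking the heavy class imbalance of curated gold standards
IMBALANCED_NEGATIVE_RATIO = 50.0


@dataclass
class SyntheticSpec:
    n: int = 100
    p: int = 20
    s: int = 50
    active_tf_fraction: float = 0.25
    within_row_density: float = 0.6
    b_scale: float = 1.0
    omega_structure: str = "banded"  # banded | random_sparse | diagonal
    omega_density: float = 0.1
    snr: float = 3.0
    n_conditions: int = 4
    negative_ratio: float = DEFAULT_NEGATIVE_RATIO
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n, self.p, self.s) < 2:
            raise ValueError("dimensions must be >= 2")
        for name in ("active_tf_fraction", "within_row_density"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.within_row_density * self.s < 1:
            raise ValueError("within_row_density too small: no edges per active row")
        if self.omega_structure not in ("banded", "random_sparse", "diagonal"):
            raise ValueError(f"unknown omega_structure {self.omega_structure!r}")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class SyntheticTruth:
    B_true: np.ndarray
    Omega_true: np.ndarray
    Sigma_true: np.ndarray
    planted_edges: set[tuple[str, str]]
    active_tfs: list[str]
    tf_ids: list[str] = field(default_factory=list)
    target_ids: list[str] = field(default_factory=list)


def _make_omega(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.s
    if spec.omega_structure == "diagonal":
        return np.eye(s)
    if spec.omega_structure == "banded":
        # tridiagonal, unit diagonal; eigenvalues 1 + 0.8 cos(t) > 0
        Om = np.eye(s)
        idx = np.arange(s - 1)
        Om[idx, idx + 1] = 0.4
        Om[idx + 1, idx] = 0.4
        return Om
    # random sparse, diagonally dominant; resample if indefinite (logged
    # implicitly by the loop bound)
    for _ in range(100):
        Om = np.zeros((s, s))
        iu = np.triu_indices(s, k=1)
        mask = rng.random(len(iu[0])) < spec.omega_density
        vals = rng.choice([-0.3, 0.3], size=mask.sum())
        Om[iu[0][mask], iu[1][mask]] = vals
        Om = Om + Om.T
        np.fill_diagonal(Om, np.abs(Om).sum(axis=1) + 0.5)
        if np.linalg.eigvalsh(Om)[0] > 0:
            return Om
    raise RuntimeError("failed to draw an SPD sparse precision matrix")


def generate_problem(
    spec: SyntheticSpec,
) -> tuple[RegressionProblem, SyntheticTruth, GoldStandard]:
    """Draw one seeded problem instance with known ground truth.

    The returned problem keeps the TF matrix X and target matrix Y disjoint
    (the clean generative draw); the file writer interleaves both gene sets
    into one expression table so the file-based pipeline — where the target
    set includes the TFs — runs end to end.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, s = spec.n, spec.p, spec.s
    tf_ids = [f"TF{i + 1:03d}" for i in range(p)]
    target_ids = [f"G{j + 1:04d}" for j in range(s)]

    X = rng.standard_normal((n, p))
    n_active = math.ceil(spec.active_tf_fraction * p)
    active_idx = np.sort(rng.choice(p, size=n_active, replace=False))
    n_hit = math.ceil(spec.within_row_density * s)
    B = np.zeros((p, s))
    for i in active_idx:
        cols = rng.choice(s, size=n_hit, replace=False)
        B[i, cols] = spec.b_scale * rng.choice([-1.0, 1.0], size=n_hit)

    Omega = _make_omega(spec, rng)
    Sigma = np.linalg.inv(Omega)
    L = np.linalg.cholesky(Sigma)
    E = rng.standard_normal((n, s)) @ L.T
    signal = X @ B
    noise_scale = np.linalg.norm(signal) / (
        math.sqrt(spec.snr) * np.linalg.norm(E)
    )
    E = E * noise_scale
    Y = signal + E

    planted = {
        (tf_ids[i], target_ids[j]) for i, j in zip(*np.nonzero(B))
    }
    labels = {pair: 1 for pair in sorted(planted)}
    non_edges = [
        (tf, tg)
        for tf in tf_ids
        for tg in target_ids
        if (tf, tg) not in planted
    ]
    n_neg = min(len(non_edges), int(round(spec.negative_ratio * len(planted))))
    neg_idx = rng.choice(len(non_edges), size=n_neg, replace=False)
    for k in np.sort(neg_idx):
        labels[non_edges[k]] = 0

    problem = RegressionProblem(
        X=X,
        Y=Y,
        tf_ids=tf_ids,
        target_ids=target_ids,
        tf_position_in_targets={},
        standardized=False,
    )
    truth = SyntheticTruth(
        B_true=B,
        Omega_true=Omega / noise_scale**2,
        Sigma_true=Sigma * noise_scale**2,
        planted_edges=planted,
        active_tfs=[tf_ids[i] for i in active_idx],
        tf_ids=tf_ids,
        target_ids=target_ids,
    )
    return problem, truth, GoldStandard(labels)


def generate_condition_profiles(
    spec: SyntheticSpec,
) -> tuple[list[ConditionProfile], dict[str, float]]:
    """Profiles with planted τ values: constant, single-spike, and 2:1 shaped.

    Returns the profiles and the map gene -> exact planted τ
    (0 for housekeeping-like, 1 for single-condition, 0.5 for the
    (2,1,...,1) shape).
    """
    if spec.n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    rng = np.random.default_rng(spec.seed + 1)
    nc = spec.n_conditions
    profiles, expected = [], {}
    for g in range(3):
        level = float(rng.uniform(0.5, 2.0))
        gid = f"HK{g + 1}"
        profiles.append(ConditionProfile(gid, np.full(nc, level)))
        expected[gid] = 0.0
        gid = f"SPIKE{g + 1}"
        x = np.zeros(nc)
        x[rng.integers(nc)] = float(rng.uniform(0.5, 2.0))
        profiles.append(ConditionProfile(gid, x))
        expected[gid] = 1.0
        gid = f"SHAPED{g + 1}"
        base = float(rng.uniform(0.5, 2.0))
        x = np.full(nc, base)
        x[rng.integers(nc)] = 2.0 * base
        profiles.append(ConditionProfile(gid, x))
        expected[gid] = 0.5
    return profiles, expected


def write_problem_files(
    problem: RegressionProblem,
    gold: GoldStandard,
    out_dir,
) -> dict[str, Path]:
    """Write expression/TF/gold files in the standard dialects.

    The expression table holds TF columns followed by target columns, so
    reading it back with the TF list and ``build_problem`` reconstructs the
    regression with the TG set including the TFs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = np.hstack([problem.X, problem.Y])
    gene_ids = list(problem.tf_ids) + list(problem.target_ids)
    ds = ExpressionDataset(
        matrix, gene_ids, [f"S{i + 1}" for i in range(problem.n)]
    )
    paths = {
        "expression": out / "expression.tsv",
        "tfs": out / "tfs.txt",
        "gold": out / "gold_standard.tsv",
    }
    write_expression_table(ds, paths["expression"])
    paths["tfs"].write_text("".join(f"{t}\n" for t in problem.tf_ids))
    with paths["gold"].open("w") as fh:
        for (tf, tg), lab in sorted(gold.labels.items()):
            fh.write(f"{tf}\t{tg}\t{lab}\n")
    return paths
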