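"""From fitted matrices to ranked edges, master regulators and τ-indices.

Edge scores use TF-wise maximum-absolute scaling: within each TF row of the
coefficient matrix, ``score = |beta_ij| / max_j |beta_ij|``, so every score
lies in [0, 1] and the top edge of every TF scores exactly 1.  Self-loops
(TF predicting its own expression column) are excluded.

A TF is a type-1 alpha-master-regulator (MR1) when at least an alpha
fraction of its (non-self) coefficient-row entries is nonzero; the type-2
call (MR2) first prunes coefficients lacking conditional-dependence support
in the precision matrix (a nonzero entry between the TF's own expression
column and the target), so MR2 implies MR1.

The τ-index summarizes condition specificity of an expression profile:
τ = Σ(1 − x̂_i)/(n − 1) with x̂ the max-normalized profile; τ → 0 for
uniformly expressed (housekeeping-like) genes, τ > 0.8 is called
condition-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: |B| entries at or below this count as zero for MR calling; IRLS smoothing
#: yields approximately rather than exactly sparse rows
DEFAULT_ZERO_THRESHOLD = 1e-6
#: decision threshold on tau for condition specificity
TAU_SPECIFIC_THRESHOLD = 0.8


@dataclass
class RankedEdgeList:
    """Ordered (tf, target, score) records, scores in [0, 1], no self-loops."""

    records: list[tuple[str, str, float]]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def top(self, k: int) -> "RankedEdgeList":
        return RankedEdgeList(self.records[:k], dict(self.provenance))


@dataclass
class MRConfig:
    alpha: float = 0.5
    zero_threshold: float = DEFAULT_ZERO_THRESHOLD

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.zero_threshold < 0:
            raise ValueError("zero_threshold must be >= 0")


@dataclass
class MasterRegulatorReport:
    """Per-TF out-degree table with MR flags at level alpha."""

    table: pd.DataFrame  # columns: tf, out_degree, fraction, is_mr
    alpha: float
    zero_threshold: float
    kind: str  # "mr1" or "mr2"
    pruned_edge_count: int = 0

    @property
    def flagged(self) -> list[str]:
        return self.table.loc[self.table["is_mr"], "tf"].tolist()


def score_edges(
    B: np.ndarray,
    tf_ids: list[str],
    target_ids: list[str],
    provenance: dict | None = None,
) -> RankedEdgeList:
    """TF-wise max-abs scaling of coefficients into a pooled ranked list.

    All-zero rows yield all-zero scores (no division by zero).  The global
    ordering is by score descending with lexicographic (tf, target)
    tie-breaks, so output is deterministic.
    """
    B = np.asarray(B, float)
    if not np.all(np.isfinite(B)):
        raise ValueError("B contains non-finite entries")
    absB = np.abs(B)
    row_max = absB.max(axis=1)
    scale = np.where(row_max > 0, row_max, 1.0)
    scores = absB / scale[:, None]
    records = []
    for i, tf in enumerate(tf_ids):
        for j, tg in enumerate(target_ids):
            if tf == tg:
                continue
            records.append((tf, tg, float(scores[i, j])))
    records.sort(key=lambda r: (-r[2], r[0], r[1]))
    return RankedEdgeList(records, provenance or {})


def _mr_table(
    B: np.ndarray,
    tf_ids: list[str],
    config: MRConfig,
    tf_position_in_targets: dict[str, int] | None,
    kind: str,
    pruned_edge_count: int = 0,
) -> MasterRegulatorReport:
    B = np.asarray(B, float)
    s = B.shape[1]
    pos = tf_position_in_targets or {}
    rows = []
    for i, tf in enumerate(tf_ids):
        nz = np.abs(B[i]) > config.zero_threshold
        denom = s
        if tf in pos:
            nz = nz.copy()
            nz[pos[tf]] = False  # self-edge never counts
            denom = s - 1
        count = int(nz.sum())
        frac = count / denom if denom else 0.0
        rows.append((tf, count, frac, frac >= config.alpha))
    table = pd.DataFrame(rows, columns=["tf", "out_degree", "fraction", "is_mr"])
    return MasterRegulatorReport(
        table=table,
        alpha=config.alpha,
        zero_threshold=config.zero_threshold,
        kind=kind,
        pruned_edge_count=pruned_edge_count,
    )


def identify_mr1(
    B: np.ndarray,
    tf_ids: list[str],
    config: MRConfig | None = None,
    tf_position_in_targets: dict[str, int] | None = None,
) -> MasterRegulatorReport:
    """Type-1 master regulators: alpha fraction of nonzero row entries."""
    return _mr_table(B, tf_ids, config or MRConfig(), tf_position_in_targets, "mr1")


def prune_by_precision(
    B: np.ndarray,
    Omega: np.ndarray,
    tf_ids: list[str],
    tf_position_in_targets: dict[str, int],
    zero_threshold: float = DEFAULT_ZERO_THRESHOLD,
) -> np.ndarray:
    """Keep B[i, j] only where the precision matrix supports the pair.

    Entry (i, j) survives iff |Omega[pos(tf_i), j]| > zero_threshold, i.e.
    the TF's own expression column is conditionally dependent on target j
    given all other genes.  Diagonal entries (self-pairs) never validate:
    the self column is zeroed.  Requires every TF to sit among the targets.
    """
    B = np.asarray(B, float)
    Omega = np.asarray(Omega, float)
    missing = [t for t in tf_ids if t not in tf_position_in_targets]
    if missing:
        raise ValueError(
            f"MR2 undefined: TFs absent from the target set: {missing[:10]}"
        )
    pruned = np.zeros_like(B)
    for i, tf in enumerate(tf_ids):
        t = tf_position_in_targets[tf]
        support = np.abs(Omega[t]) > zero_threshold
        support[t] = False
        pruned[i, support] = B[i, support]
    return pruned


def identify_mr2(
    B: np.ndarray,
    Omega: np.ndarray,
    tf_ids: list[str],
    tf_position_in_targets: dict[str, int],
    config: MRConfig | None = None,
) -> MasterRegulatorReport:
    """Type-2 master regulators: MR1 applied after precision pruning."""
    config = config or MRConfig()
    pruned = prune_by_precision(
        B, Omega, tf_ids, tf_position_in_targets, config.zero_threshold
    )
    n_pruned = int(
        (np.abs(np.asarray(B, float)) > config.zero_threshold).sum()
        - (np.abs(pruned) > config.zero_threshold).sum()
    )
    report = _mr_table(
        pruned, tf_ids, config, tf_position_in_targets, "mr2", n_pruned
    )
    return report


@dataclass
class ConditionProfile:
    """Per-condition expression of one gene, max-normalized for tau."""

    gene_id: str
    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        if self.x.ndim != 1 or self.x.size < 2:
            raise ValueError("profile needs at least 2 conditions")

    @property
    def normalized(self) -> np.ndarray:
        m = self.x.max()
        if m <= 0:
            raise ValueError(f"{self.gene_id}: max expression must be positive")
        return self.x / m


def tau_index(profile: ConditionProfile | np.ndarray) -> float:
    """Condition-specificity index in [0, 1].

    τ = Σ_i (1 − x̂_i) / (n − 1), x̂ the max-normalized profile.  0 for a
    constant profile, 1 for expression confined to a single condition.
    Requires non-negative values (shift beforehand if standardized data can
    go negative) with a positive maximum.
    """
    if not isinstance(profile, ConditionProfile):
        profile = ConditionProfile("<anon>", np.asarray(profile, float))
    if np.any(profile.x < 0):
        raise ValueError(
            f"{profile.gene_id}: tau requires non-negative values "
            "(shift the profile first)"
        )
    xhat = profile.normalized
    n = xhat.size
    return float(np.sum(1.0 - xhat) / (n - 1))


def tau_report(
    profiles: list[ConditionProfile], shift_negative: bool = True
) -> pd.DataFrame:
    """τ for each gene, with the τ > 0.8 condition-specificity call.

    ``shift_negative`` translates each profile to min 0 first (standardized
    expression can be negative; the index presupposes non-negative
    profiles).
    """
    rows = []
    for prof in profiles:
        x = prof.x
        if shift_negative and x.min() < 0:
            x = x - x.min()
        t = tau_index(ConditionProfile(prof.gene_id, x))
        rows.append((prof.gene_id, t, t > TAU_SPECIFIC_THRESHOLD))
    return pd.DataFrame(rows, columns=["gene", "tau", "condition_specific"])
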