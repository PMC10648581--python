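"""One-vs-rest differential-expression screen with permutation p-values.

For each miRNA the screen computes, on log2 expression:

* fold change — ``2**(mean(target) - mean(rest))``, the ratio of geometric
  means of the two groups on the linear scale;
* a two-sample pooled-variance Student t statistic (positive when the
  target group is higher);
* a two-sided permutation p-value obtained by reassigning the group labels
  uniformly at random, preserving group sizes, and recomputing |t|.  With B
  sampled reassignments ``p = (1 + #{|t_perm| >= |t_obs|}) / (B + 1)``, so
  p is never zero.  When the label-assignment space has at most B distinct
  assignments it is enumerated exhaustively and p is the exact proportion.

Significance is ``perm_p < alpha`` (default 0.05, no multiple-testing
correction; the record count is carried so users can post-correct).  A
separate effect-size filter keeps records with ``|FC - 1| > fc_threshold``
(default 0.5, i.e. FC above 1.5 or below 0.5, strict).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ContrastError, GroupContrast, MirnaExpressionMatrix

__all__ = [
    "DifferentialRecord",
    "ScreenResult",
    "fold_change",
    "student_t",
    "permutation_p",
    "run_screen",
    "fc_filter",
    "direction_counts",
]


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-miRNA result of a one-vs-rest contrast."""

    mirna_id: str
    fold_change: float
    t_stat: float
    perm_p: float
    direction: str = field(init=False)

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"fold change must be positive, got {self.fold_change}")
        if not (0.0 < self.perm_p <= 1.0):
            raise ValueError(f"permutation p must lie in (0, 1], got {self.perm_p}")
        object.__setattr__(self, "direction", "increased" if self.fold_change > 1 else "decreased")


@dataclass(frozen=True)
class ScreenResult:
    """All tested miRNAs of one contrast plus the screen parameters."""

    contrast_name: str
    records: tuple[DifferentialRecord, ...]
    alpha: float = 0.05
    n_permutations: int = 1000
    fc_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def significant(self) -> list[DifferentialRecord]:
        return [r for r in self.records if r.perm_p < self.alpha]

    def params(self) -> dict:
        return {
            "contrast": self.contrast_name,
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "fc_threshold": self.fc_threshold,
            "seed": self.seed,
            "n_tested": len(self.records),
        }

    def to_frame(self) -> pd.DataFrame:
        sig = {r.mirna_id for r in self.significant()}
        kept = {r.mirna_id for r in fc_filter(list(self.records), self.fc_threshold)}
        return pd.DataFrame(
            {
                "mirna_id": [r.mirna_id for r in self.records],
                "fold_change": [r.fold_change for r in self.records],
                "t_stat": [r.t_stat for r in self.records],
                "perm_p": [r.perm_p for r in self.records],
                "direction": [r.direction for r in self.records],
                "significant": [r.mirna_id in sig for r in self.records],
                "passes_fc_filter": [r.mirna_id in kept for r in self.records],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
        Path(path).with_suffix(".params.json").write_text(
            json.dumps(self.params(), indent=2, sort_keys=True) + "\n"
        )


# ---------------------------------------------------------------------------
# statistics kernels
# ---------------------------------------------------------------------------

def _batch_t(X: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """Pooled-variance t statistics for every row of X under every labelling.

    X is (m miRNAs, n samples); membership is (B, n) boolean, True marking
    the positive group (constant row sums).  Returns (m, B).  Zero pooled
    variance yields t = 0 for equal means, signed infinity otherwise.
    """
    X = np.asarray(X, dtype=float)
    P = membership.astype(float)
    n = X.shape[1]
    n1 = int(membership[0].sum())
    n2 = n - n1
    if n1 < 2 or n2 < 2:
        raise ContrastError(f"t-test needs >=2 samples per group (got {n1} vs {n2})")
    s1 = X @ P.T                      # (m, B) positive-group sums
    q1 = (X * X) @ P.T
    tot = X.sum(axis=1, keepdims=True)
    qtot = (X * X).sum(axis=1, keepdims=True)
    m1 = s1 / n1
    m2 = (tot - s1) / n2
    sse = np.maximum(q1 - n1 * m1 * m1, 0.0) + np.maximum((qtot - q1) - n2 * m2 * m2, 0.0)
    sp2 = sse / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_var = se == 0
    if np.any(zero_var):
        t = np.where(zero_var & np.isclose(diff, 0.0), 0.0, t)
        t = np.where(zero_var & (diff > 0) & ~np.isclose(diff, 0.0), np.inf, t)
        t = np.where(zero_var & (diff < 0) & ~np.isclose(diff, 0.0), -np.inf, t)
    return t


def _contrast_arrays(
    expr: MirnaExpressionMatrix, contrast: GroupContrast
) -> tuple[np.ndarray, np.ndarray]:
    """(values restricted to contrast samples, observed membership row)."""
    pos_idx, neg_idx = contrast.indices(expr)
    cols = np.concatenate([pos_idx, neg_idx])
    obs = np.zeros(cols.size, dtype=bool)
    obs[: pos_idx.size] = True
    return expr.expr[:, cols], obs


def _assignment_space(n: int, n_pos: int) -> int:
    return math.comb(n, n_pos)


def _permutation_memberships(
    n: int, n_pos: int, B: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """(B', n) boolean labellings; exhaustive when the space has <= B points."""
    total = _assignment_space(n, n_pos)
    if total <= B:
        M = np.zeros((total, n), dtype=bool)
        for b, pos in enumerate(combinations(range(n), n_pos)):
            M[b, list(pos)] = True
        return M, True
    # top-n_pos of a random uniform draw per row = uniform assignment
    order = np.argsort(rng.random((B, n)), axis=1)[:, :n_pos]
    M = np.zeros((B, n), dtype=bool)
    np.put_along_axis(M, order, True, axis=1)
    return M, False


def _perm_pvalues(
    X: np.ndarray, obs: np.ndarray, B: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed t and permutation p for every row of X (contrast columns only).

    ``obs`` must mark the first n_pos columns (callers order columns as
    positives then negatives).  The observed statistic is computed inside
    the same batched evaluation as the permuted ones, so the identity
    labelling can never lose to itself through floating-point noise.
    """
    n_pos = int(obs.sum())
    if not obs[:n_pos].all():
        raise AssertionError("contrast columns must be ordered positives first")
    X = X - X.mean(axis=1, keepdims=True)  # t is shift-invariant; improves conditioning
    M, exhaustive = _permutation_memberships(X.shape[1], n_pos, B, rng)
    if exhaustive:
        t_all = _batch_t(X, M)            # first combination is the identity labelling
        t_obs = t_all[:, 0]
        t_perm = t_all
        denom = M.shape[0]
        offset = 0.0
    else:
        t_all = _batch_t(X, np.vstack([obs[None, :], M]))
        t_obs = t_all[:, 0]
        t_perm = t_all[:, 1:]
        denom = M.shape[0] + 1
        offset = 1.0
    # tiny relative buffer keeps mirror-image labellings counting as ties
    threshold = np.abs(t_obs) * (1.0 - 1e-12)
    exceed = (np.abs(t_perm) >= threshold[:, None]).sum(axis=1)
    return t_obs, (offset + exceed) / denom


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def fold_change(
    expr: MirnaExpressionMatrix, contrast: GroupContrast, mirna_id: str
) -> float:
    """Ratio of geometric means, target group over rest."""
    x = expr.row(mirna_id)
    pos_idx, neg_idx = contrast.indices(expr)
    return float(2.0 ** (x[pos_idx].mean() - x[neg_idx].mean()))


def student_t(
    expr: MirnaExpressionMatrix, contrast: GroupContrast, mirna_id: str
) -> float:
    """Two-sample pooled-variance t on log2 expression (positive = target higher)."""
    x = expr.row(mirna_id)[None, :]
    pos_idx, neg_idx = contrast.indices(expr)
    X = x[:, np.concatenate([pos_idx, neg_idx])]
    obs = np.zeros(X.shape[1], dtype=bool)
    obs[: pos_idx.size] = True
    return float(_batch_t(X, obs[None, :])[0, 0])


def permutation_p(
    expr: MirnaExpressionMatrix,
    contrast: GroupContrast,
    mirna_id: str,
    B: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for one miRNA; exact for small contrasts."""
    if B < 1:
        raise ValueError(f"need at least one permutation, got B={B}")
    x = expr.row(mirna_id)[None, :]
    pos_idx, neg_idx = contrast.indices(expr)
    X = x[:, np.concatenate([pos_idx, neg_idx])]
    obs = np.zeros(X.shape[1], dtype=bool)
    obs[: pos_idx.size] = True
    _, p = _perm_pvalues(X, obs, B, np.random.default_rng(seed))
    return float(p[0])


def run_screen(
    expr: MirnaExpressionMatrix,
    contrast: GroupContrast,
    alpha: float = 0.05,
    B: int = 1000,
    fc_threshold: float = 0.5,
    seed: int = 0,
) -> ScreenResult:
    """Screen every miRNA of the matrix against one contrast.

    One set of B label reassignments is shared across all miRNAs (the null
    is the same for each), which keeps the screen a handful of matrix
    products rather than per-miRNA loops.
    """
    if B < 1:
        raise ValueError(f"need at least one permutation, got B={B}")
    X, obs = _contrast_arrays(expr, contrast)
    t_obs, p = _perm_pvalues(X, obs, B, np.random.default_rng(seed))
    pos_idx, neg_idx = contrast.indices(expr)
    lfc = expr.expr[:, pos_idx].mean(axis=1) - expr.expr[:, neg_idx].mean(axis=1)
    records = tuple(
        DifferentialRecord(mid, float(2.0**lfc[i]), float(t_obs[i]), float(p[i]))
        for i, mid in enumerate(expr.mirna_ids)
    )
    return ScreenResult(contrast.name, records, alpha, B, fc_threshold, seed)


def fc_filter(
    records: list[DifferentialRecord], fc_threshold: float = 0.5
) -> list[DifferentialRecord]:
    """Keep records with |FC - 1| strictly above the threshold.

    At the default 0.5 this keeps fold changes above 1.5 or below 0.5;
    boundary values (exactly 1.5 or 0.5) are excluded.
    """
    if not (0.0 < fc_threshold < 1.0):
        raise ValueError(f"fc_threshold must lie in (0, 1), got {fc_threshold}")
    return [r for r in records if abs(r.fold_change - 1.0) > fc_threshold]


def direction_counts(records: list[DifferentialRecord]) -> tuple[int, int]:
    """(number increased, number decreased) among the given records."""
    n_up = sum(r.direction == "increased" for r in records)
    return n_up, len(records) - n_up
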