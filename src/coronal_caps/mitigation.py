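"""Class-imbalance mitigation: resampling plans, Borderline-SMOTE-1,
random undersampling, and the imbalance-aware loss functions.

The three diagnostic classes arrive at roughly 43% AD / 34% MCI / 23% CN,
a max/min imbalance of about 1.9:1. Mitigation options mirror standard
practice for imbalanced medical imaging:

* inverse-frequency class weights feeding a weighted cross-entropy,
* Borderline-SMOTE oversampling of minority classes up to the majority
  count (training split only),
* random undersampling of majority classes down to the minority count,
* focal loss (gamma = 2, per-class alpha) down-weighting easy examples,
* capsule margin loss with m+ = 0.9, m- = 0.1, lambda = 0.5,
* a combined strategy: resample first, then train with focal loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .cohort import CLASSES

PROB_EPS = 1e-7

STRATEGIES = ("none", "smote", "undersample", "cost_sensitive", "focal", "combined")


@dataclass
class MitigationPlan:
    strategy: str
    synthesis: dict[str, int] = field(default_factory=dict)  # per-class rows to create
    removal: dict[str, int] = field(default_factory=dict)    # per-class rows to drop
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if any(v < 0 for v in self.synthesis.values()):
            raise ValueError("synthesis counts must be nonnegative")
        if any(v < 0 for v in self.removal.values()):
            raise ValueError("removal counts must be nonnegative")


@dataclass
class FocalParams:
    gamma: float = 2.0
    alpha: tuple[float, float, float] = (0.45, 0.34, 0.22)  # (CN, MCI, AD)

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if any(a <= 0 for a in self.alpha):
            raise ValueError("alpha components must be positive")


@dataclass
class MarginParams:
    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5
    reconstruction_weight: float = 0.0005

    def __post_init__(self) -> None:
        if not (0 < self.m_minus < self.m_plus < 1):
            raise ValueError("need 0 < m_minus < m_plus < 1")


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------


def _check_counts(counts: dict[str, int]) -> None:
    if not counts or all(v == 0 for v in counts.values()):
        raise ValueError("need at least one positive class count")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be nonnegative")


def class_weights(counts: dict[str, int]) -> dict[str, float]:
    """Inverse-frequency weights: w_c = max_count / count_c (2 decimals).

    The largest class gets weight exactly 1.0.
    """
    _check_counts(counts)
    if any(v == 0 for v in counts.values()):
        raise ValueError("all class counts must be positive for weighting")
    mx = max(counts.values())
    return {c: round(mx / n, 2) for c, n in counts.items()}


def smote_plan(counts: dict[str, int]) -> MitigationPlan:
    """Oversampling plan: synthesize up to the majority count per class."""
    _check_counts(counts)
    mx = max(counts.values())
    return MitigationPlan(strategy="smote",
                          synthesis={c: mx - n for c, n in counts.items()})


def undersample_plan(counts: dict[str, int]) -> MitigationPlan:
    """Undersampling plan: remove down to the minority count per class."""
    _check_counts(counts)
    mn = min(counts.values())
    return MitigationPlan(strategy="undersample",
                          removal={c: n - mn for c, n in counts.items()})


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def borderline_smote(
    features: np.ndarray,
    labels: np.ndarray,
    plan: MitigationPlan,
    m_neighbors: int = 10,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Borderline-SMOTE-1 synthesis according to ``plan``.

    A minority point is in DANGER if, among its ``m_neighbors`` nearest
    neighbors of any class, the number belonging to other classes lies in
    [m/2, m) — near the boundary but not pure noise. Synthetic rows are
    drawn by interpolating a DANGER seed toward one of its ``k_neighbors``
    nearest same-class neighbors: x_new = x + u (x_nn - x), u ~ U(0, 1).
    If no DANGER points exist the whole minority class seeds synthesis.

    Returns (features, labels, synthetic_flag); real rows are passed
    through unmodified, synthetic rows are appended and flagged. Only
    ever apply this to the training split.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, d) with matching labels")
    n_new_total = sum(plan.synthesis.values())
    flags = np.zeros(len(X), dtype=bool)
    if n_new_total == 0:
        return X.copy(), y.copy(), flags

    rng = np.random.default_rng(seed)
    nn_all = NearestNeighbors(n_neighbors=m_neighbors + 1).fit(X)
    new_X, new_y = [], []
    for cls in sorted(plan.synthesis):
        n_new = plan.synthesis[cls]
        if n_new == 0:
            continue
        cls_idx = np.flatnonzero(y == cls)
        if len(cls_idx) <= k_neighbors:
            raise ValueError(f"class {cls!r} has {len(cls_idx)} members, "
                             f"need > k_neighbors={k_neighbors}")
        # DANGER detection over the full dataset
        _, nbr = nn_all.kneighbors(X[cls_idx])
        other = (y[nbr[:, 1:]] != cls).sum(axis=1)
        danger = cls_idx[(other >= m_neighbors / 2) & (other < m_neighbors)]
        seeds = danger if len(danger) else cls_idx
        nn_min = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X[cls_idx])
        pick = rng.choice(len(seeds), size=n_new, replace=True)
        for i in pick:
            xi = X[seeds[i]]
            _, nb = nn_min.kneighbors(xi[None, :])
            cand = [j for j in nb[0] if cls_idx[j] != seeds[i]][:k_neighbors]
            xj = X[cls_idx[rng.choice(cand)]]
            u = rng.uniform()
            new_X.append(xi + u * (xj - xi))
            new_y.append(cls)
    Xa = np.vstack([X] + [np.asarray(new_X)])
    ya = np.concatenate([y, np.asarray(new_y, dtype=y.dtype)])
    flags = np.concatenate([flags, np.ones(len(new_X), dtype=bool)])
    return Xa, ya, flags


def random_undersample(
    features: np.ndarray,
    labels: np.ndarray,
    plan: MitigationPlan,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove exactly the planned per-class counts, sampled without replacement."""
    X = np.asarray(features, float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    keep = np.ones(len(y), dtype=bool)
    for cls in sorted(plan.removal):
        n_rm = plan.removal[cls]
        if n_rm == 0:
            continue
        cls_idx = np.flatnonzero(y == cls)
        if n_rm > len(cls_idx):
            raise ValueError(f"cannot remove {n_rm} rows from class {cls!r} "
                             f"of size {len(cls_idx)}")
        drop = rng.choice(cls_idx, size=n_rm, replace=False)
        keep[drop] = False
    return X[keep], y[keep]


# ---------------------------------------------------------------------------
# losses (all: mean over samples, nonnegative, zero only at the optimum)
# ---------------------------------------------------------------------------


def _check_probs(probs: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(probs, float)
    y = np.asarray(labels, int)
    if P.ndim != 2 or P.shape[1] != 3 or len(P) != len(y):
        raise ValueError("prob matrix must be (n, 3) with matching labels")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1")
    if np.any(P < -1e-9):
        raise ValueError("probabilities must be nonnegative")
    return np.clip(P, PROB_EPS, 1.0 - PROB_EPS), y


def focal_loss(probs: np.ndarray, labels: np.ndarray,
               params: FocalParams | None = None) -> float:
    """Mean over samples of -alpha_y (1 - p_y)^gamma log p_y."""
    params = params or FocalParams()
    P, y = _check_probs(probs, labels)
    p_y = P[np.arange(len(y)), y]
    alpha = np.asarray(params.alpha)[y]
    return float(np.mean(-alpha * (1.0 - p_y) ** params.gamma * np.log(p_y)))


def weighted_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                           weights: dict[str, float] | np.ndarray) -> float:
    """Mean of -w_y log p_y with per-class weights."""
    P, y = _check_probs(probs, labels)
    if isinstance(weights, dict):
        w = np.asarray([weights[c] for c in CLASSES], float)
    else:
        w = np.asarray(weights, float)
    p_y = P[np.arange(len(y)), y]
    return float(np.mean(-w[y] * np.log(p_y)))


def margin_loss(capsule_lengths: np.ndarray, labels: np.ndarray,
                params: MarginParams | None = None) -> float:
    """Capsule margin loss, averaged over samples.

    L = sum_k [ T_k max(0, m+ - ||v_k||)^2
                + lambda (1 - T_k) max(0, ||v_k|| - m-)^2 ]
    where T_k = 1 for the true class.
    """
    params = params or MarginParams()
    V = np.asarray(capsule_lengths, float)
    y = np.asarray(labels, int)
    if V.ndim != 2 or V.shape[1] != 3 or len(V) != len(y):
        raise ValueError("capsule_lengths must be (n, 3) with matching labels")
    if np.any(V < 0) or np.any(V > 1):
        raise ValueError("capsule lengths must lie in [0, 1]")
    T = np.zeros_like(V)
    T[np.arange(len(y)), y] = 1.0
    pos = np.maximum(0.0, params.m_plus - V) ** 2
    neg = np.maximum(0.0, V - params.m_minus) ** 2
    per_sample = (T * pos + params.lam * (1.0 - T) * neg).sum(axis=1)
    return float(per_sample.mean())
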