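"""Constrained 0/1 feature selection by integer programming.

Maximize the total relevance of the selected features,

    max_z  sum_j s_j z_j

subject to a computational-cost budget ``sum c_j z_j <= B``, a latency
budget ``sum r_j z_j <= R``, a cardinality cap ``sum z_j <= k``, and a
required-group quota ``sum g_j z_j >= Gmin``, with z_j in {0,1}.

Two exact routes are provided: :func:`solve_lp_selection` (branch and
bound over the LP relaxation, via HiGHS) for real use, and
:func:`enumerate_optimum`, a brute-force enumeration oracle limited to
small d, used to validate the solver. This selector and the coati
search are independent; they are not composed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import LinearConstraint, milp

from .encoding import BinaryMask, FeatureMatrix

__all__ = [
    "LPInstance",
    "LPSolution",
    "check_feasibility",
    "enumerate_optimum",
    "solve_lp_selection",
    "relevance_scores",
]

_ENUM_MAX_D = 20


@dataclass(frozen=True)
class LPInstance:
    """Scores, costs, latencies, group flags and budgets for one instance.

    scores : per-feature relevance s_j in [0, 1]
    costs, latencies : nonnegative per-feature budget contributions
        (default 1 each when a caller supplies none)
    group_flags : {0,1} membership in the required group
    B, R : cost and latency budgets; k : max selected; Gmin : min from group
    """

    scores: tuple
    costs: tuple
    latencies: tuple
    group_flags: tuple
    B: float
    R: float
    k: int
    Gmin: int

    def __post_init__(self):
        s = tuple(float(v) for v in self.scores)
        c = tuple(float(v) for v in self.costs)
        r = tuple(float(v) for v in self.latencies)
        g = tuple(int(v) for v in self.group_flags)
        d = len(s)
        if not (len(c) == len(r) == len(g) == d):
            raise ValueError("scores, costs, latencies, group_flags must share length")
        if any(v < 0 or v > 1 for v in s):
            raise ValueError("relevance scores must lie in [0, 1]")
        if any(v < 0 for v in c) or any(v < 0 for v in r):
            raise ValueError("costs and latencies must be nonnegative")
        if any(v not in (0, 1) for v in g):
            raise ValueError("group flags must be 0 or 1")
        if not (0 <= self.Gmin <= self.k <= d):
            raise ValueError("require 0 <= Gmin <= k <= d")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "costs", c)
        object.__setattr__(self, "latencies", r)
        object.__setattr__(self, "group_flags", g)

    @property
    def d(self) -> int:
        return len(self.scores)

    @classmethod
    def simple(cls, scores, B=None, R=None, k=None, Gmin=0,
               costs=None, latencies=None, group_flags=None) -> "LPInstance":
        """Convenience constructor: unit costs/latencies, non-binding
        budgets unless given."""
        d = len(scores)
        costs = costs if costs is not None else (1.0,) * d
        latencies = latencies if latencies is not None else (1.0,) * d
        group_flags = group_flags if group_flags is not None else (0,) * d
        B = B if B is not None else float(sum(costs))
        R = R if R is not None else float(sum(latencies))
        k = k if k is not None else d
        return cls(tuple(scores), tuple(costs), tuple(latencies),
                   tuple(group_flags), float(B), float(R), int(k), int(Gmin))


@dataclass(frozen=True)
class LPSolution:
    mask: BinaryMask
    objective: float
    feasible: bool
    status: str  # "optimal" | "infeasible"


def check_feasibility(mask: BinaryMask, inst: LPInstance) -> bool:
    """True iff the mask satisfies all four budget/quota constraints."""
    if mask.d != inst.d:
        raise ValueError("mask length does not match instance dimension")
    z = np.asarray(mask.bits, dtype=float)
    return bool(
        np.dot(inst.costs, z) <= inst.B + 1e-9
        and np.dot(inst.latencies, z) <= inst.R + 1e-9
        and z.sum() <= inst.k + 1e-9
        and np.dot(inst.group_flags, z) >= inst.Gmin - 1e-9
    )


def enumerate_optimum(inst: LPInstance) -> LPSolution:
    """Exhaustive oracle: score all 2^d masks, return the feasible maximum.

    Ties are broken toward the lexicographically smallest bit string.
    Guarded at d <= 20 against exponential blow-up.
    """
    d = inst.d
    if d > _ENUM_MAX_D:
        raise ValueError(
            f"enumeration over 2^{d} masks refused (d > {_ENUM_MAX_D}); "
            "use solve_lp_selection for larger instances")
    best_bits = None
    best_obj = -np.inf
    s = np.asarray(inst.scores)
    for code in range(2 ** d):
        bits = tuple((code >> (d - 1 - j)) & 1 for j in range(d))
        mask = BinaryMask(bits)
        if not check_feasibility(mask, inst):
            continue
        obj = float(s @ np.asarray(bits))
        # iterating codes in increasing order visits bit strings in
        # lexicographic order, so a strict > keeps the smallest tie
        if obj > best_obj + 1e-12:
            best_obj = obj
            best_bits = bits
    if best_bits is None:
        return LPSolution(BinaryMask((0,) * d), 0.0, False, "infeasible")
    return LPSolution(BinaryMask(best_bits), best_obj, True, "optimal")


def solve_lp_selection(inst: LPInstance) -> LPSolution:
    """Exact 0/1 solve by branch and bound over the LP relaxation (HiGHS)."""
    d = inst.d
    c = -np.asarray(inst.scores, dtype=float)  # milp minimizes
    A = np.vstack([
        np.asarray(inst.costs, dtype=float),
        np.asarray(inst.latencies, dtype=float),
        np.ones(d),
        np.asarray(inst.group_flags, dtype=float),
    ])
    lb = [-np.inf, -np.inf, -np.inf, float(inst.Gmin)]
    ub = [float(inst.B), float(inst.R), float(inst.k), np.inf]
    res = milp(c=c,
               constraints=LinearConstraint(A, lb, ub),
               integrality=np.ones(d),
               bounds=(0, 1))
    if not res.success or res.x is None:
        return LPSolution(BinaryMask((0,) * d), 0.0, False, "infeasible")
    bits = tuple(int(round(v)) for v in res.x)
    mask = BinaryMask(bits)
    obj = float(np.dot(inst.scores, bits))
    return LPSolution(mask, obj, True, "optimal")


def relevance_scores(F: FeatureMatrix) -> np.ndarray:
    """Per-feature Fisher-style relevance in [0, 1].

    Between-class variance of the class means over pooled within-class
    variance, rescaled so the best feature scores 1. All-constant
    features score 0. The formulation in this module never pins down how
    the scores arise from data; this scorer is the bundled default, and
    scores may equally be supplied from file.
    """
    classes = np.unique(F.labels)
    if classes.size < 2:
        raise ValueError("relevance scores require at least 2 classes")
    X = F.values
    overall = X.mean(axis=0)
    between = np.zeros(F.d)
    within = np.zeros(F.d)
    for cls_label in classes:
        Xc = X[F.labels == cls_label]
        between += Xc.shape[0] * (Xc.mean(axis=0) - overall) ** 2
        within += ((Xc - Xc.mean(axis=0)) ** 2).sum(axis=0)
    # tiny ridge keeps zero-within (perfectly separating) features finite
    # while leaving all-constant features (zero between) at 0
    ridge = 1e-12 * max(float(within.max()), 1.0)
    ratio = between / (within + ridge)
    m = ratio.max()
    return ratio / m if m > 0 else ratio
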