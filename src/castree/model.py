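"""Closed-form quantities of the CRISPR-Cas9 lineage-recording model.

The generative model: a single progenitor with k unedited recording sites
(characters) grows into an ultrametric binary tree of height 1.  Each
character mutates along the tree as an irreversible Poisson process with
rate ``lam``; on mutation it adopts indel state j with probability q_j.
The collision probability q = sum_j q_j^2 is the chance two independent
edits of the same site coincide (homoplasy).  Each leaf entry is finally
masked (dropout) with probability p_d.

This module holds the experiment parameters and every closed form the
reconstruction guarantees rest on: the mutation CDF, the expected number of
shared mutations inside/outside a triplet, and the separation function
delta(d) with its interval minimum delta_star.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import TripletGeometry

__all__ = [
    "LineageParams",
    "mutation_probability",
    "delta",
    "delta_star",
    "delta_star_grid",
    "expected_ingroup_similarity",
    "expected_outgroup_similarity",
    "depth_tolerance",
]


@dataclass(frozen=True)
class LineageParams:
    """Parameters of a lineage-recording experiment.

    Parameters
    ----------
    k : int
        Number of recording sites (characters), > 0.
    lam : float
        Instantaneous Cas9 mutation rate per unit tree height, > 0.
    state_probs : array-like of float
        Indel-outcome distribution (q_1..q_m); must sum to 1.
    p_d : float
        Per-character, per-cell dropout probability, in [0, 1).
    """

    k: int
    lam: float
    state_probs: np.ndarray
    p_d: float = 0.0
    collision_q: float = field(init=False)

    def __post_init__(self):
        if self.k <= 0 or int(self.k) != self.k:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        # lam = 0 is allowed as the degenerate no-editing control; the
        # closed-form model quantities themselves require lam > 0
        if self.lam < 0:
            raise ValueError(f"lam must be nonnegative, got {self.lam}")
        if not (0.0 <= self.p_d < 1.0):
            raise ValueError(f"p_d must be in [0, 1), got {self.p_d}")
        probs = np.asarray(self.state_probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0:
            raise ValueError("state_probs must be a nonempty 1-d vector")
        if np.any(probs < 0):
            raise ValueError("state_probs must be nonnegative")
        if abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError(f"state_probs must sum to 1, got {probs.sum()}")
        object.__setattr__(self, "state_probs", probs)
        object.__setattr__(self, "collision_q", float(np.sum(probs**2)))

    @property
    def m(self) -> int:
        return self.state_probs.size

    @property
    def q_max(self) -> float:
        return float(self.state_probs.max())

    @classmethod
    def uniform(cls, k: int, lam: float, q: float = None, m: int = None,
                p_d: float = 0.0) -> "LineageParams":
        """Uniform indel distribution with m = 1/q equiprobable states."""
        if m is None:
            if q is None or not (0 < q <= 1):
                raise ValueError("provide m, or q in (0, 1]")
            m = round(1.0 / q)
            if abs(m - 1.0 / q) > 1e-6:
                raise ValueError(f"1/q = {1 / q} is not an integer state count")
        return cls(k=k, lam=lam, state_probs=np.full(m, 1.0 / m), p_d=p_d)


def mutation_probability(lam: float, t) -> float:
    """P[a character mutates within path length t] = 1 - exp(-lam * t)."""
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("path length t must be nonnegative")
    out = -np.expm1(-lam * t)
    return float(out) if out.ndim == 0 else out


def delta(d, lam: float, q: float):
    """Separation function delta(d) = 0.6(e^{-lam d}(1-q) + q e^{-lam(2-d)}).

    Lower-bounds the per-character expected ingroup/outgroup similarity gap
    per unit of lam * l_star for triplets whose LCA sits at depth d.
    """
    d = np.asarray(d, dtype=float)
    if np.any((d < -1e-12) | (d > 1 + 1e-12)):
        raise ValueError("depth d must lie in [0, 1]")
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"collision probability q must be in [0, 1], got {q}")
    out = 0.6 * (np.exp(-lam * d) * (1.0 - q) + q * np.exp(-lam * (2.0 - d)))
    return float(out) if out.ndim == 0 else out


def delta_star(d_star: float, lam: float, q: float) -> float:
    """min_{x in [0, d_star]} delta(x), in closed form.

    delta(x) = 0.6((1-q)e^{-lam x} + q e^{-2 lam} e^{lam x}) is convex in x
    with stationary point x0 = (1/(2 lam)) * ln((1-q) e^{2 lam} / q); the
    minimum over the interval is delta(clamp(x0, 0, d_star)).
    """
    if not (0.0 <= d_star <= 1.0):
        raise ValueError(f"d_star must be in [0, 1], got {d_star}")
    if q <= 0.0:
        x_min = d_star  # no homoplasy term: delta decreases monotonically
    elif q >= 1.0:
        x_min = 0.0
    else:
        x0 = (np.log((1.0 - q) / q) + 2.0 * lam) / (2.0 * lam)
        x_min = min(max(x0, 0.0), d_star)
    return float(delta(x_min, lam, q))


def delta_star_grid(d_star: float, lam: float, q: float,
                    n_grid: int = 1_000_000) -> float:
    """Dense-grid minimization of delta over [0, d_star] (test oracle)."""
    xs = np.linspace(0.0, d_star, n_grid) if d_star > 0 else np.array([0.0])
    return float(np.min(delta(xs, lam, q)))


def _check_geometry(geom: TripletGeometry):
    if geom.alpha + geom.d > 1 + 1e-9:
        raise ValueError(
            f"alpha + d = {geom.alpha + geom.d} exceeds the tree height 1"
        )


def expected_ingroup_similarity(geom: TripletGeometry,
                                params: LineageParams) -> float:
    """E[s_c(a, b)]: expected mutations shared by the ingroup pair that arose
    below the triplet LCA.

    Exact form: k e^{-lam d} ((1 - e^{-lam l'}) + e^{-lam l'}
    (1 - e^{-lam (1 - l' - d)})^2 q), where l' = geom.alpha.  The first term
    is a single shared event on the LCA->ingroup-ancestor path; the second is
    homoplasy on the two terminal paths.
    """
    _check_geometry(geom)
    lam, q, k = params.lam, params.collision_q, params.k
    d, lp = geom.d, geom.alpha
    shared = -np.expm1(-lam * lp)
    homoplasy = np.exp(-lam * lp) * (-np.expm1(-lam * (1.0 - lp - d))) ** 2 * q
    return float(k * np.exp(-lam * d) * (shared + homoplasy))


def expected_outgroup_similarity(geom: TripletGeometry,
                                 params: LineageParams) -> float:
    """E[s_a(b, c)]: expected homoplastic mutations shared with the outgroup,
    k e^{-lam d} (1 - e^{-lam (1 - d)})^2 q."""
    _check_geometry(geom)
    lam, q, k = params.lam, params.collision_q, params.k
    d = geom.d
    return float(k * np.exp(-lam * d) * (-np.expm1(-lam * (1.0 - d))) ** 2 * q)


def depth_tolerance(event_time: float, trace_time: float) -> float:
    """Depth tolerance d* for resolving events up to ``event_time`` in an
    experiment traced until ``trace_time`` (times in any common unit).

    Example: restriction events up to mouse embryonic day 6.5 in a trace
    collected at day 9 give d* = 6.5 / 9.
    """
    if not (0 < event_time <= trace_time):
        raise ValueError("need 0 < event_time <= trace_time")
    return event_time / trace_time
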