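"""Sufficient character-count bounds and admissibility conditions.

Every bound answers the question: how many recording sites k suffice for the
corresponding reconstruction guarantee to hold with probability 1 - zeta on a
height-1 tree over n sampled cells?  All logarithms are natural: the constants
(96/32 for the top-down bounds, 20/10 for the bottom-up bound) come from
exponential concentration inequalities, which are base-e; a ``log_base``
switch is provided for sensitivity analysis only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import delta_star

__all__ = [
    "BoundQuery",
    "k_condition_i",
    "k_conditions_i_ii",
    "k_missing_data",
    "theorem_topdown_k",
    "theorem3_admissible",
    "k_bottomup",
    "k_bottomup_limit",
    "bound_heatmap",
]


@dataclass(frozen=True)
class BoundQuery:
    """Inputs to the sufficient-k bounds.

    ``l`` is the minimum edge length of the ground-truth tree and ``c`` the
    max/min edge ratio bound (edges lie in [l, c*l]); ``l_star`` / ``d_star``
    are the oracle tolerances; ``beta`` defaults to lam * q * max(1, c).
    """

    n: int
    zeta: float = 0.1
    lam: float = 1.0
    collision_q: float = 0.1
    q_max: float = None
    l: float = None
    l_star: float = None
    d_star: float = 1.0
    c: float = 1.0
    p_d: float = 0.0
    beta: float = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2 samples")
        if not (0 < self.zeta < 1):
            raise ValueError("zeta must be in (0, 1)")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not (0 < self.collision_q <= 1):
            raise ValueError("collision_q must be in (0, 1]")
        if self.q_max is None:
            object.__setattr__(self, "q_max", self.collision_q)
        if not (self.collision_q <= self.q_max <= 1):
            raise ValueError("need collision_q <= q_max <= 1")
        if self.l_star is None and self.l is not None:
            object.__setattr__(self, "l_star", self.l)
        if self.c < 1:
            raise ValueError("edge-ratio bound c must be >= 1")
        if self.beta is None:
            object.__setattr__(
                self, "beta", self.lam * self.collision_q * max(1.0, self.c))


def _log_terms(n, zeta, a, b, log_base=np.e):
    return (a * np.log(n) + b * np.log(1.0 / zeta)) / np.log(log_base)


def k_condition_i(query: BoundQuery, log_base: float = np.e) -> float:
    """Sufficient k for oracle condition (i) — the true outgroup margin
    exceeds the threshold for every well-separated, shallow triplet:

    k >= (96 ln n + 32 ln 1/zeta)(l* + (1-e^{-lam}) q)
         / (0.6 lam l*^2 delta* (1 - q + q e^{-2 lam})).
    """
    if query.l_star is None or query.l_star <= 0:
        raise ValueError("k_condition_i needs a positive l_star (or l)")
    lam, q, ls = query.lam, query.collision_q, query.l_star
    ds = delta_star(query.d_star, lam, q)
    num = _log_terms(query.n, query.zeta, 96, 32, log_base) * \
        (ls + (-np.expm1(-lam)) * q)
    den = 0.6 * lam * ls**2 * ds * (1.0 - q + q * np.exp(-2.0 * lam))
    return float(num / den)


def k_conditions_i_ii(query: BoundQuery, log_base: float = np.e) -> float:
    """Sufficient k for both oracle conditions (no wrong answers and correct
    answers on separated triplets): the max of q (96 ln n + 32 ln 1/zeta) /
    (l*^2 delta*^2) and the condition-(i) bound."""
    lam, q, ls = query.lam, query.collision_q, query.l_star
    ds = delta_star(query.d_star, lam, q)
    branch_ii = _log_terms(query.n, query.zeta, 96, 32, log_base) * q / \
        (ls**2 * ds**2)
    return float(max(branch_ii, k_condition_i(query, log_base)))


def k_missing_data(query: BoundQuery, log_base: float = np.e) -> float:
    """Both-conditions bound under worst-case (heritable + stochastic)
    missing data: the condition-(ii) branch gains a (1-p_d)^5 and the
    condition-(i) branch a (1-p_d)^3 denominator."""
    pd_ = query.p_d
    if not (0 <= pd_ < 1):
        raise ValueError("p_d must be in [0, 1)")
    lam, q, ls = query.lam, query.collision_q, query.l_star
    ds = delta_star(query.d_star, lam, q)
    branch_ii = _log_terms(query.n, query.zeta, 96, 32, log_base) * q / \
        (ls**2 * ds**2 * (1.0 - pd_) ** 5)
    branch_i = k_condition_i(query, log_base) / (1.0 - pd_) ** 3
    return float(max(branch_ii, branch_i))


def theorem_topdown_k(query: BoundQuery, log_base: float = np.e) -> float:
    """Sufficient k for exact reconstruction up to depth d* by the threshold
    splitting algorithm (l* taken as the minimum edge length l)."""
    if query.l is None:
        raise ValueError("theorem_topdown_k needs the minimum edge length l")
    q2 = BoundQuery(n=query.n, zeta=query.zeta, lam=query.lam,
                    collision_q=query.collision_q, q_max=query.q_max,
                    l=query.l, l_star=query.l, d_star=query.d_star,
                    c=query.c, p_d=query.p_d)
    return k_condition_i(q2, log_base)


def theorem3_admissible(query: BoundQuery) -> dict:
    """Check the bottom-up guarantee's parameter preconditions.

    Returns a dict with ``admissible`` plus each condition's margin:
    q_max <= (3/16)(1 - e^{-lam c l}) and
    beta < 1 / (1 + C + 2 (e^{-lam l} + 2 lam c l q_max)^2), where
    C = 2 c l e^{-lam} + 4 lam c l q_max.
    """
    if query.l is None or query.l <= 0:
        raise ValueError("theorem3_admissible needs a positive minimum edge l")
    lam, l, cl = query.lam, query.l, query.c * query.l
    qmax, beta = query.q_max, query.beta
    C = 2.0 * cl * np.exp(-lam) + 4.0 * lam * cl * qmax
    qmax_cap = (3.0 / 16.0) * (-np.expm1(-lam * cl))
    beta_cap = 1.0 / (1.0 + C + 2.0 * (np.exp(-lam * l) +
                                       2.0 * lam * cl * qmax) ** 2)
    return {
        "admissible": bool(qmax <= qmax_cap and beta < beta_cap),
        "q_max": qmax, "q_max_cap": float(qmax_cap),
        "q_max_margin": float(qmax_cap - qmax),
        "beta": beta, "beta_cap": float(beta_cap),
        "beta_margin": float(beta_cap - beta),
        "C": float(C),
    }


def k_bottomup(query: BoundQuery, log_base: float = np.e) -> float:
    """Sufficient k for the greedy bottom-up algorithm (edges in [l, c*l]):

    k >= (20 ln n + 10 ln 1/zeta) /
         (lam e^{-lam l} (1 - beta(1+C)) (1 - beta(1+C) -
          2 beta (e^{-lam l} + 2 lam c l q_max)^2)).

    Raises for inadmissible queries (see :func:`theorem3_admissible`).
    """
    diag = theorem3_admissible(query)
    if not diag["admissible"]:
        raise ValueError(f"parameters violate the bottom-up guarantee "
                         f"preconditions: {diag}")
    lam, l, cl = query.lam, query.l, query.c * query.l
    qmax, beta, C = query.q_max, query.beta, diag["C"]
    g = np.exp(-lam * l) + 2.0 * lam * cl * qmax
    den = lam * np.exp(-lam * l) * (1.0 - beta * (1.0 + C)) * \
        (1.0 - beta * (1.0 + C) - 2.0 * beta * g**2)
    num = _log_terms(query.n, query.zeta, 20, 10, log_base)
    if den <= 0:
        raise ValueError("degenerate denominator; query too close to the "
                         "admissibility boundary")
    return float(num / den)


def k_bottomup_limit(query: BoundQuery, log_base: float = np.e) -> float:
    """Small-l / large-n limit of the bottom-up bound (beta < 1/3):
    k >= (20 ln n + 10 ln 1/zeta) / (lam e^{-lam l} (1 - beta)(1 - 3 beta))."""
    beta = query.beta
    if beta >= 1.0 / 3.0:
        raise ValueError(f"limit bound requires beta < 1/3, got {beta}")
    lam = query.lam
    l = query.l if query.l is not None else 0.0
    num = _log_terms(query.n, query.zeta, 20, 10, log_base)
    return float(num / (lam * np.exp(-lam * l) * (1.0 - beta) *
                        (1.0 - 3.0 * beta)))


def bound_heatmap(lams, qs, *, n: int, zeta: float = 0.1, theorem: str,
                  l: float = None, l_star: float = None, d_star: float = 1.0,
                  c: float = 1.0, p_d: float = 0.0,
                  log10: bool = True) -> pd.DataFrame:
    """Evaluate a sufficient-k bound on a (lam, q) grid.

    ``zeta = 0.1`` corresponds to a 0.9 probability of exact reconstruction.
    Returns a DataFrame (rows = lam, columns = q) of (optionally log10) k;
    inadmissible bottom-up cells are NaN, mirroring excluded heatmap regions.
    """
    funcs = {
        "topdown": theorem_topdown_k,
        "lemma2": k_conditions_i_ii,
        "lemma3": k_missing_data,
        "bottomup": k_bottomup,
    }
    if theorem not in funcs:
        raise ValueError(f"unknown theorem {theorem!r}; choose from "
                         f"{sorted(funcs)}")
    out = np.full((len(lams), len(qs)), np.nan)
    for i, lam in enumerate(lams):
        for j, q in enumerate(qs):
            query = BoundQuery(n=n, zeta=zeta, lam=lam, collision_q=q,
                               l=l, l_star=l_star, d_star=d_star, c=c, p_d=p_d)
            try:
                out[i, j] = funcs[theorem](query)
            except ValueError:
                continue  # inadmissible cell stays NaN
    if log10:
        out = np.log10(out)
    return pd.DataFrame(out, index=pd.Index(lams, name="lam"),
                        columns=pd.Index(qs, name="q"))
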