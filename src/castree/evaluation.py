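"""Tree-comparison metrics and the empirical minimum-k search harness.

The scoring unit is the leaf triplet: a reconstruction is exact (up to depth
d) when every triplet whose true LCA lies at depth <= d is resolved
identically in the inferred tree.  The minimum-k harness doubles the number
of characters until a sufficient value is found (>= 9/10 replicate successes),
binary-searches the final bin, fits a logistic regression of success on k,
and reports the first k whose fitted success probability reaches 0.9 with
pointwise delta-method confidence bands.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import norm

from .bottomup import greedy_bottomup_reconstruct
from .model import LineageParams
from .simulate import TopologyConfig, as_rng, simulate_experiment, simulate_topology
from .topdown import OracleConfig, oracle_reconstruct, threshold_split_reconstruct
from .tree import LineageTree

__all__ = [
    "TripletScore",
    "triplets_correct",
    "exact_reconstruction",
    "make_criterion",
    "sufficiency_trial",
    "MinKResult",
    "min_k_search",
    "min_k_confidence_interval",
]


@dataclass(frozen=True)
class TripletScore:
    fraction: float
    n_correct: int
    n_total: int


def _triplet_indices(n: int):
    iu = np.arange(n)
    mask = (iu[:, None, None] < iu[None, :, None]) & \
           (iu[None, :, None] < iu[None, None, :])
    return np.nonzero(mask)


def _resolve(D, ia, ib, ic):
    """Outgroup code per triplet from pairwise LCA depths: 0 = a, 1 = b,
    2 = c, -1 = unresolved (polytomy)."""
    dab, dac, dbc = D[ia, ib], D[ia, ic], D[ib, ic]
    out = np.full(ia.shape, -1, dtype=np.int8)
    out[(dbc > dab) & (dbc > dac)] = 0
    out[(dac > dab) & (dac > dbc)] = 1
    out[(dab > dac) & (dab > dbc)] = 2
    return out


def triplets_correct(true_tree: LineageTree, inferred_tree: LineageTree,
                     depth_limit: float = 1.0) -> TripletScore:
    """Fraction of leaf triplets with true LCA depth <= ``depth_limit`` that
    the inferred tree resolves identically to the truth.

    Resolution uses topology only (edge-count LCA depths), so inferred trees
    need no meaningful branch lengths; a multifurcation resolves no triplet.
    The depth gate uses the true tree's branch-length depths; d = 1 covers
    all triplets.
    """
    leaves = true_tree.leaves
    if set(leaves) != set(inferred_tree.leaves):
        raise ValueError("trees must share the same leaf set")
    D_len, D_cnt_t, _ = true_tree.lca_depth_matrices(leaves)
    _, D_cnt_i, _ = inferred_tree.lca_depth_matrices(leaves)
    ia, ib, ic = _triplet_indices(len(leaves))
    lca_depth = np.minimum(np.minimum(D_len[ia, ib], D_len[ia, ic]),
                           D_len[ib, ic])
    gate = lca_depth <= depth_limit + 1e-9
    res_t = _resolve(D_cnt_t, ia, ib, ic)
    res_i = _resolve(D_cnt_i, ia, ib, ic)
    correct = gate & (res_t == res_i) & (res_t >= 0)
    n_total = int(gate.sum())
    n_correct = int(correct.sum())
    frac = 1.0 if n_total == 0 else n_correct / n_total
    return TripletScore(fraction=frac, n_correct=n_correct, n_total=n_total)


def exact_reconstruction(true_tree: LineageTree, inferred_tree: LineageTree,
                         depth_limit: float = 1.0) -> bool:
    """True iff every triplet with true LCA depth <= ``depth_limit`` is
    resolved identically."""
    score = triplets_correct(true_tree, inferred_tree, depth_limit)
    return score.n_correct == score.n_total


def make_criterion(kind: str = "exact", depth_limit: float = 1.0,
                   min_fraction: float = 1.0):
    """Build a scoring criterion callable(true_tree, inferred_tree) -> bool.

    ``exact``: all triplets up to ``depth_limit`` correct.
    ``triplets``: fraction of such triplets correct >= ``min_fraction``.
    """
    if kind == "exact":
        return lambda t, i: exact_reconstruction(t, i, depth_limit)
    if kind == "triplets":
        return lambda t, i: (triplets_correct(t, i, depth_limit).fraction
                             >= min_fraction)
    raise ValueError(f"unknown criterion {kind!r}")


def _reconstructor(method, params: LineageParams, l_star: float,
                   d_star: float):
    if callable(method):
        return method
    if method == "threshold":
        return threshold_split_reconstruct
    if method == "bottomup":
        return greedy_bottomup_reconstruct
    if method == "oracle":
        mode = "worst_case" if params.p_d > 0 else "none"
        cfg = OracleConfig(l_star=l_star, d_star=d_star, missing_mode=mode,
                           p_d=params.p_d)
        return lambda M: oracle_reconstruct(M, cfg, params)
    raise ValueError(f"unknown method {method!r}")


def sufficiency_trial(k: int, params: LineageParams,
                      topo_cfg: TopologyConfig, method="threshold",
                      criterion=None, replicates: int = 10, rng=None,
                      l_star: float = None, d_star: float = 1.0) -> int:
    """Replicated reconstruction at a fixed character count k.

    Uniform regime: ``replicates`` mutation overlays on one complete binary
    topology.  Asynchronous regime: one overlay on each of ``replicates``
    fresh topologies.  Returns the number of replicates meeting the scoring
    criterion (default: exact reconstruction up to ``d_star``).
    """
    rng = as_rng(rng)
    params = dataclasses.replace(params, k=int(k))
    if criterion is None:
        criterion = make_criterion("exact", d_star)
    if l_star is None:
        if topo_cfg.regime == "uniform":
            l_star = 1.0 / (int(np.log2(topo_cfg.n_target)) + 1)
        else:
            l_star = topo_cfg.shift_a
    recon = _reconstructor(method, params, l_star, d_star)
    shared_tree = (simulate_topology(topo_cfg, rng)
                   if topo_cfg.regime == "uniform" else None)
    successes = 0
    for _ in range(replicates):
        true_tree, matrix = simulate_experiment(params, topo_cfg, rng,
                                                tree=shared_tree)
        inferred = recon(matrix)
        if criterion(true_tree, inferred):
            successes += 1
    return successes


@dataclass
class MinKResult:
    """Outcome of a minimum-k search."""

    ks: np.ndarray                 # tested character counts
    successes: np.ndarray          # successes out of `replicates` at each k
    replicates: int
    min_k_hat: float = None        # first k with fitted P(success) >= 0.9
    ci_low: float = None
    ci_high: float = None
    coef: np.ndarray = None        # logistic (intercept, slope)
    cov: np.ndarray = None
    censored: bool = False         # no sufficient k up to the cap
    degenerate: bool = False       # regression fell back to the bracket
    cap: int = None
    bin_ks: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.ks = np.asarray(self.ks)
        self.successes = np.asarray(self.successes)


def _fit_logistic(ks, succ, replicates, grouped=True):
    ks = np.asarray(ks, dtype=float)
    succ = np.asarray(succ, dtype=float)
    if grouped:
        endog = np.column_stack([succ, replicates - succ])
        exog = sm.add_constant(ks)
    else:
        y = np.concatenate([np.repeat([1.0, 0.0], [s, replicates - s])
                            for s in succ.astype(int)])
        x = np.repeat(ks, replicates)
        endog, exog = y, sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
            maxiter=200)
    return np.asarray(res.params), np.asarray(res.cov_params())


def min_k_confidence_interval(result: MinKResult, level: float = 0.95,
                              target: float = 0.9):
    """Pointwise delta-method bands on the fitted success curve.

    ``ci_high`` is the first integer k whose lower band reaches ``target``
    (the search cap if none does), ``ci_low`` the first whose upper band
    does.
    """
    if result.coef is None:
        return result.ci_low, result.ci_high
    b0, b1 = result.coef
    cap = int(result.cap or result.ks.max())
    grid = np.arange(1, cap + 1, dtype=float)
    eta = b0 + b1 * grid
    var = (result.cov[0, 0] + 2.0 * grid * result.cov[0, 1]
           + grid**2 * result.cov[1, 1])
    se = np.sqrt(np.maximum(var, 0.0))
    z = norm.ppf(0.5 + level / 2.0)
    lower = expit(eta - z * se)
    upper = expit(eta + z * se)
    hit_low = np.nonzero(upper >= target)[0]
    hit_high = np.nonzero(lower >= target)[0]
    ci_low = float(grid[hit_low[0]]) if hit_low.size else float(cap)
    ci_high = float(grid[hit_high[0]]) if hit_high.size else float(cap)
    return ci_low, ci_high


def min_k_search(params: LineageParams, topo_cfg: TopologyConfig,
                 method="threshold", criterion=None, cap: int = 4096,
                 seed: int = 0, replicates: int = 10,
                 success_threshold: int = 9, k_start: int = 1,
                 l_star: float = None, d_star: float = 1.0,
                 grouped: bool = True, trial=None) -> MinKResult:
    """Empirical minimum number of characters for 90% reconstruction success.

    Doubles k from ``k_start`` until a sufficient k is found (>=
    ``success_threshold`` of ``replicates`` successes) or ``cap`` is reached
    (censored), then binary-searches the bin between the sufficient k and
    half that value.  All (k, successes) pairs in the bin feed a logistic
    regression of success on k; the reported minimum k is the first integer
    whose fitted success probability reaches 0.9.

    ``trial`` may override the sufficiency trial (callable k -> successes),
    e.g. for harness tests; each k is evaluated with an rng derived from
    (seed, k) so recounts are identical.
    """
    if trial is None:
        def trial(k):
            return sufficiency_trial(
                k, params, topo_cfg, method=method, criterion=criterion,
                replicates=replicates, rng=np.random.default_rng([seed, k]),
                l_star=l_star, d_star=d_star)
    record: dict = {}

    def run(k):
        if k not in record:
            record[k] = int(trial(k))
        return record[k]

    k = int(k_start)
    sufficient = None
    while k <= cap:
        if run(k) >= success_threshold:
            sufficient = k
            break
        k *= 2
    ks_sorted = np.array(sorted(record))
    succ_sorted = np.array([record[kk] for kk in ks_sorted])
    if sufficient is None:
        return MinKResult(ks=ks_sorted, successes=succ_sorted,
                          replicates=replicates, min_k_hat=float(cap),
                          ci_low=float(cap), ci_high=float(cap),
                          censored=True, cap=cap)

    lo, hi = sufficient // 2, sufficient
    if lo >= 1:
        run(lo)
    while hi - lo > 1 and lo >= 1:
        mid = (lo + hi) // 2
        if run(mid) >= success_threshold:
            hi = mid
        else:
            lo = mid

    ks_sorted = np.array(sorted(record))
    succ_sorted = np.array([record[kk] for kk in ks_sorted])
    bin_mask = (ks_sorted >= max(sufficient // 2, 1)) & \
               (ks_sorted <= sufficient)
    bin_ks = ks_sorted[bin_mask]
    bin_succ = succ_sorted[bin_mask]
    result = MinKResult(ks=ks_sorted, successes=succ_sorted,
                        replicates=replicates, cap=cap, bin_ks=bin_ks)

    degenerate = (bin_ks.size < 2 or bin_succ.min() == bin_succ.max())
    if not degenerate:
        try:
            coef, cov = _fit_logistic(bin_ks, bin_succ, replicates, grouped)
            if not (np.isfinite(coef).all() and np.isfinite(cov).all()
                    and coef[1] > 0):
                degenerate = True
            else:
                result.coef, result.cov = coef, cov
        except Exception:
            degenerate = True
    if degenerate:
        # all-success / all-failure bin or separation too extreme to fit:
        # fall back to the final binary-search bracket midpoint
        result.degenerate = True
        result.min_k_hat = float(int(np.ceil((lo + hi) / 2.0)))
        result.ci_low, result.ci_high = float(max(lo, 1)), float(hi)
        return result

    b0, b1 = result.coef
    crossing = (logit(0.9) - b0) / b1
    result.min_k_hat = float(max(1, int(np.ceil(crossing - 1e-9))))
    result.ci_low, result.ci_high = min_k_confidence_interval(result)
    return result
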