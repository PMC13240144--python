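"""Two-state continuous-time Markov model for a binary trait.

The trait takes states 0 (absent) and 1 (present) and evolves along the
phylogeny under an "all rates different" (ARD) Mk model with gain rate
``a = q01`` (absent -> present) and loss rate ``b = q10``, both per unit
branch length.  With ``s = a + b`` the transition kernel has the closed form

    P00(t) = (b + a e^{-st}) / s        P01(t) = 1 - P00(t)
    P11(t) = (a + b e^{-st}) / s        P10(t) = 1 - P11(t)

and stationary distribution (b, a)/s.  Likelihoods are computed by
post-order pruning with per-node rescaling; tips enter through probability
vectors ("tip priors") which are degenerate (0/1) for hard presence/absence
calls or equal to the record state frequencies when intraspecific variation
is carried into the analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy import optimize

from .treeio import Phylogeny, normalize_label

log = logging.getLogger(__name__)

ABSENT, PRESENT = 0, 1
_LOG_RATE_LO = -14.0
_MAX_CHANGES_PER_HEIGHT = 200.0  # upper rate box: soft tip data otherwise
                                 # push the fit onto the infinite-rate ridge


def _log_rate_bounds(height: float) -> tuple[float, float]:
    return (_LOG_RATE_LO,
            float(np.log(_MAX_CHANGES_PER_HEIGHT / max(height, 1e-12))))


class CTMCError(ValueError):
    pass


@dataclass(frozen=True)
class RateMatrix2:
    """ARD rate matrix for a binary trait.

    ``q_gain`` is the 0->1 (absent to present) rate, ``q_loss`` the 1->0
    rate, both per unit branch length of the tree they are fitted on.
    """

    q_gain: float
    q_loss: float

    def __post_init__(self) -> None:
        if self.q_gain < 0 or self.q_loss < 0:
            raise CTMCError("rates must be nonnegative")

    @property
    def total(self) -> float:
        return self.q_gain + self.q_loss

    def stationary(self) -> np.ndarray:
        """Stationary distribution over (absent, present)."""
        s = self.total
        if s <= 0:
            raise CTMCError("stationary distribution undefined for Q = 0")
        return np.array([self.q_loss, self.q_gain]) / s

    def matrix(self) -> np.ndarray:
        return np.array([[-self.q_gain, self.q_gain],
                         [self.q_loss, -self.q_loss]])


def transition_matrix(Q: RateMatrix2, t: float) -> np.ndarray:
    """Closed-form ``expm(Q t)`` for the 2-state chain; identity at s = 0."""
    if t < 0:
        raise CTMCError("negative branch length")
    a, b = Q.q_gain, Q.q_loss
    s = a + b
    if s == 0.0 or t == 0.0:
        return np.eye(2)
    e = np.exp(-s * t)
    p00 = (b + a * e) / s
    p11 = (a + b * e) / s
    return np.array([[p00, 1.0 - p00], [1.0 - p11, p11]])


# ---------------------------------------------------------------------------
# Tip priors
# ---------------------------------------------------------------------------

def tip_prior_matrix(tree: Phylogeny,
                     tip_priors: Mapping[str, Sequence[float]] | np.ndarray
                     ) -> np.ndarray:
    """Align tip priors to tip order; validate the simplex constraint.

    ``tip_priors`` maps species name (normalised-label matching) to a
    2-vector ``(P(absent), P(present))``, or is already an ``(n_tips, 2)``
    array in tip order.
    """
    if isinstance(tip_priors, np.ndarray):
        P = np.asarray(tip_priors, dtype=float)
        if P.shape != (tree.n_tips, 2):
            raise CTMCError(f"tip prior array must be ({tree.n_tips}, 2)")
    else:
        norm = {normalize_label(k): np.asarray(v, dtype=float)
                for k, v in tip_priors.items()}
        P = np.empty((tree.n_tips, 2))
        missing = []
        for i, lb in enumerate(tree.tip_labels):
            v = norm.get(normalize_label(lb))
            if v is None:
                missing.append(lb)
            else:
                P[i] = v
        if missing:
            raise CTMCError(f"tips missing a prior: {missing}")
    if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise CTMCError("tip priors must be probability vectors over "
                        "(absent, present)")
    return P


def presence_priors(presence: Mapping[str, bool]) -> dict[str, np.ndarray]:
    """Degenerate tip priors from species-level presence calls."""
    return {sp: np.array([0.0, 1.0]) if bool(p) else np.array([1.0, 0.0])
            for sp, p in presence.items()}


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

@njit(cache=True)
def _prune_kernel(postorder, left, right, blen, tipP, a, b):
    """Post-order partial likelihoods with per-node max rescaling.

    Returns (partials, logscale) where ``partials[v]`` has max entry 1 for
    internal nodes and ``logscale[v]`` accumulates this node's own log
    rescaling factor.
    """
    n_nodes = len(blen)
    n_tips = tipP.shape[0]
    part = np.zeros((n_nodes, 2))
    logsc = np.zeros(n_nodes)
    for i in range(n_tips):
        part[i, 0] = tipP[i, 0]
        part[i, 1] = tipP[i, 1]
    s = a + b
    for k in range(len(postorder)):
        v = postorder[k]
        acc0 = 1.0
        acc1 = 1.0
        for c in (left[v], right[v]):
            t = blen[c]
            if s == 0.0 or t == 0.0:
                l0 = part[c, 0]
                l1 = part[c, 1]
            else:
                e = np.exp(-s * t)
                p00 = (b + a * e) / s
                p11 = (a + b * e) / s
                l0 = p00 * part[c, 0] + (1.0 - p00) * part[c, 1]
                l1 = (1.0 - p11) * part[c, 0] + p11 * part[c, 1]
            acc0 *= l0
            acc1 *= l1
        m = acc0 if acc0 > acc1 else acc1
        if m <= 0.0:
            # impossible configuration below this node
            part[v, 0] = 0.0
            part[v, 1] = 0.0
            logsc[v] = -np.inf
        else:
            part[v, 0] = acc0 / m
            part[v, 1] = acc1 / m
            logsc[v] = np.log(m)
    return part, logsc


@dataclass
class ConditionalLikelihoods:
    """Scaled partial likelihoods per node plus accumulated log scalings."""

    partials: np.ndarray  # (n_nodes, 2), internal rows scaled to max 1
    logscale: np.ndarray  # per-node log rescaling factors
    tree: Phylogeny
    Q: RateMatrix2

    def root_conditional(self) -> np.ndarray:
        """Conditional scaled likelihood distribution at the root."""
        p = self.partials[self.tree.root]
        tot = p.sum()
        if tot <= 0:
            raise CTMCError("zero likelihood at root")
        return p / tot

    def total_logscale(self) -> float:
        return float(self.logscale.sum())


def conditional_likelihoods(tree: Phylogeny, tip_priors, Q: RateMatrix2
                            ) -> ConditionalLikelihoods:
    P = tip_prior_matrix(tree, tip_priors)
    part, logsc = _prune_kernel(tree.postorder, tree.left, tree.right,
                                tree.blen, P, Q.q_gain, Q.q_loss)
    return ConditionalLikelihoods(part, logsc, tree, Q)


def pruning_loglik(tree: Phylogeny, tip_priors, Q: RateMatrix2,
                   root_mode: str = "stationary") -> float:
    """Log-likelihood of tip data under the ARD model.

    ``root_mode`` selects the root state weights: ``stationary`` (default
    for fitting), ``uniform`` (0.5, 0.5), or ``conditional-scaled``
    (FitzJohn-style weights equal to the normalised root partials, as used
    when sampling root states for stochastic mapping).
    """
    cl = conditional_likelihoods(tree, tip_priors, Q)
    p = cl.partials[tree.root]
    if root_mode == "stationary":
        w = Q.stationary()
    elif root_mode == "uniform":
        w = np.array([0.5, 0.5])
    elif root_mode == "conditional-scaled":
        w = cl.root_conditional()
    else:
        raise CTMCError(f"unknown root_mode: {root_mode!r}")
    lik = float(w @ p)
    if lik <= 0 or not np.isfinite(cl.logscale.sum()):
        return -np.inf
    ll = np.log(lik) + cl.total_logscale()
    if np.isnan(ll):
        raise CTMCError("NaN log-likelihood")
    return float(ll)


# ---------------------------------------------------------------------------
# Maximum-likelihood ARD fitting
# ---------------------------------------------------------------------------

def _nll_factory(trees: list[Phylogeny], priors_list: list[np.ndarray],
                 root_mode: str):
    def nll(x):
        a, bb = np.exp(x)
        Q = RateMatrix2(a, bb)
        tot = 0.0
        for tr, P in zip(trees, priors_list):
            tot -= pruning_loglik(tr, P, Q, root_mode)
        return tot if np.isfinite(tot) else 1e12
    return nll


def _default_starts(height: float) -> list[tuple[float, float]]:
    # fixed multi-start grid in units of expected changes per tree height
    base = 1.0 / max(height, 1e-12)
    g = []
    for ra in (0.1, 1.0):
        for rb in (0.1, 1.0):
            g.append((np.log(ra * base), np.log(rb * base)))
    g.append((np.log(3.0 * base), np.log(3.0 * base)))
    return g


@dataclass
class ARDFit:
    Q: RateMatrix2
    loglik: float
    boundary: bool = False

    def __iter__(self):  # allow Q, ll = fit_ard(...)
        return iter((self.Q, self.loglik))


def fit_ard(tree_or_sample, tip_priors, root_mode: str = "stationary",
            starts: int = 5) -> ARDFit:
    """Maximum-likelihood ARD rates by box-constrained multi-start BFGS.

    Accepts a single :class:`Phylogeny` or a :class:`~avimast.treeio.TreeSample`
    (joint fit summing log-likelihoods across trees).  Optimisation runs on
    log-rates from a fixed grid of starting points, so the fit is
    deterministic.  Monomorphic data push a rate to the lower box boundary;
    this is reported via ``boundary=True`` with a warning rather than an
    error.
    """
    if hasattr(tree_or_sample, "trees"):
        trees = list(tree_or_sample.trees)
    else:
        trees = [tree_or_sample]
    priors_list = [tip_prior_matrix(tr, tip_priors) for tr in trees]
    height = max(tr.max_depth() for tr in trees)
    # monomorphic data: the likelihood ridge is degenerate (the rate out of
    # the observed state has MLE 0, the other is unidentified); return the
    # boundary solution explicitly
    all_present = all((P[:, 0] == 0).all() for P in priors_list)
    all_absent = all((P[:, 1] == 0).all() for P in priors_list)
    if all_present or all_absent:
        warnings.warn("monomorphic tip data: rate estimate at lower "
                      "boundary", stacklevel=2)
        Q = (RateMatrix2(1.0 / height, 0.0) if all_present
             else RateMatrix2(0.0, 1.0 / height))
        ll = sum(pruning_loglik(tr, P, Q, root_mode)
                 for tr, P in zip(trees, priors_list))
        return ARDFit(Q, float(ll), boundary=True)
    nll = _nll_factory(trees, priors_list, root_mode)
    lo, hi = _log_rate_bounds(height)
    best = None
    for x0 in _default_starts(height)[:max(starts, 1)]:
        res = optimize.minimize(nll, x0=np.clip(x0, lo, hi),
                                method="L-BFGS-B",
                                bounds=[(lo, hi), (lo, hi)])
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    boundary = bool(np.any(best.x <= lo + 1.0))
    if boundary:
        warnings.warn("ARD rate at lower boundary (trait effectively "
                      "monomorphic in one direction)", stacklevel=2)
    return ARDFit(RateMatrix2(float(a), float(b)), -float(best.fun), boundary)


def profile_interval(tree_or_sample, tip_priors, which: str,
                     level: float = 0.95, root_mode: str = "stationary",
                     fit: ARDFit | None = None) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one rate.

    ``which`` is ``"q_gain"`` or ``"q_loss"``.  The bound solves
    ``profile_loglik(rate) = max_loglik - chi2_{1,level}/2`` on each side of
    the MLE on the log scale, profiling out the other rate.
    """
    from scipy.stats import chi2

    if hasattr(tree_or_sample, "trees"):
        trees = list(tree_or_sample.trees)
    else:
        trees = [tree_or_sample]
    priors_list = [tip_prior_matrix(tr, tip_priors) for tr in trees]
    if fit is None:
        fit = fit_ard(tree_or_sample, tip_priors, root_mode)
    idx = {"q_gain": 0, "q_loss": 1}[which]
    other = 1 - idx
    lo, hi = _log_rate_bounds(max(tr.max_depth() for tr in trees))
    cut = fit.loglik - chi2.ppf(level, df=1) / 2.0
    mle_log = np.log([fit.Q.q_gain, fit.Q.q_loss])

    def profile_ll(xr: float) -> float:
        def nll_other(xo):
            x = np.empty(2)
            x[idx] = xr
            x[other] = xo[0]
            a, b = np.exp(x)
            tot = 0.0
            for tr, P in zip(trees, priors_list):
                tot -= pruning_loglik(tr, P, RateMatrix2(a, b), root_mode)
            return tot if np.isfinite(tot) else 1e12
        res = optimize.minimize(nll_other, x0=[mle_log[other]],
                                method="L-BFGS-B", bounds=[(lo, hi)])
        return -float(res.fun)

    def g(xr: float) -> float:
        return profile_ll(xr) - cut

    lower = np.exp(lo)
    if g(lo) < 0:
        lower = np.exp(optimize.brentq(g, lo, mle_log[idx], xtol=1e-4))
    upper = np.exp(hi)
    if g(hi) < 0:
        upper = np.exp(optimize.brentq(g, mle_log[idx], hi, xtol=1e-4))
    return float(lower), float(upper)
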