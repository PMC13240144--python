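"""Bayesian stochastic character mapping for a binary trait.

Given a fitted (or supplied) ARD rate matrix per tree, a character history
is sampled in two stages:

1. joint node states: the root state is drawn from the conditional scaled
   likelihood distribution at the root; each descendant node (tips included)
   is then drawn from its partial likelihoods combined with the transition
   probability from the sampled parent state;
2. branch paths: each branch's full state path is an endpoint-conditioned
   realisation of the 2-state chain, drawn by rejection sampling of forward
   paths with a uniformization bridge as fallback on hard branches.

Aggregating histories over a posterior sample of trees (default 10 maps per
tree) yields posterior distributions of gain/loss counts, transition rates
and root states; gains and losses are compared with a Wilcoxon matched-pairs
test over simulations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import ctmc
from .ctmc import ABSENT, PRESENT, RateMatrix2
from .treeio import Phylogeny, TreeSample

log = logging.getLogger(__name__)

REJECTION_CAP = 1000  # forward-path attempts per branch before uniformization


class SimmapError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Character histories
# ---------------------------------------------------------------------------

@dataclass
class CharacterHistory:
    """One sampled state history over a tree.

    ``paths[v]`` lists ``(time_from_parent, new_state)`` change points along
    the branch above node ``v``, strictly increasing in ``(0, blen[v])``;
    states alternate because the trait is binary.
    """

    tree: Phylogeny
    node_states: np.ndarray
    paths: dict[int, list[tuple[float, int]]]
    Q: RateMatrix2
    tree_index: int = 0
    sim_index: int = 0

    def n_gains(self) -> int:
        return sum(1 for ch in self.paths.values()
                   for _, s in ch if s == PRESENT)

    def n_losses(self) -> int:
        return sum(1 for ch in self.paths.values()
                   for _, s in ch if s == ABSENT)

    def root_state(self) -> int:
        return int(self.node_states[self.tree.root])

    def validate(self) -> None:
        """Parity and monotonicity invariants for every branch."""
        for v, ch in self.paths.items():
            t_prev = 0.0
            s = int(self.node_states[self.tree.parent[v]])
            for t, ns in ch:
                if not (t_prev < t < self.tree.blen[v] or
                        (t_prev < t and math.isclose(t, self.tree.blen[v]))):
                    raise SimmapError(f"non-increasing change point on {v}")
                if ns == s:
                    raise SimmapError(f"non-alternating state on branch {v}")
                s = ns
                t_prev = t
            if s != int(self.node_states[v]):
                raise SimmapError(f"endpoint parity violated on branch {v}")


# ---------------------------------------------------------------------------
# Node-state sampling
# ---------------------------------------------------------------------------

def sample_node_states(tree: Phylogeny, tip_priors, Q: RateMatrix2,
                       rng: np.random.Generator,
                       cl: ctmc.ConditionalLikelihoods | None = None
                       ) -> np.ndarray:
    """Joint draw of states at every node (tips included).

    The root is drawn from the normalised root partials; each child ``c`` of
    a node in state ``s`` is drawn with probability proportional to
    ``P[s, j](t_c) * partial_c[j]``.  Tips with degenerate priors are fixed.
    """
    if cl is None:
        cl = ctmc.conditional_likelihoods(tree, tip_priors, Q)
    part = cl.partials
    states = np.full(tree.n_nodes, -1, dtype=np.int64)
    root_p = cl.root_conditional()
    states[tree.root] = rng.choice(2, p=root_p)
    # preorder
    stack = [tree.root]
    while stack:
        v = stack.pop()
        if tree.left[v] < 0:
            continue
        for c in (tree.left[v], tree.right[v]):
            P = ctmc.transition_matrix(Q, float(tree.blen[c]))
            w = P[states[v]] * part[c]
            tot = w.sum()
            if tot <= 0:
                raise SimmapError(f"zero-probability configuration at node {c}")
            states[c] = rng.choice(2, p=w / tot)
            stack.append(c)
    return states


# ---------------------------------------------------------------------------
# Endpoint-conditioned branch paths
# ---------------------------------------------------------------------------

def _forward_path(state: int, t: float, a: float, b: float,
                  rng: np.random.Generator) -> tuple[int, list[tuple[float, int]]]:
    """Unconditional forward simulation on one branch."""
    rates = (a, b)  # leaving rate of state 0 is a, of state 1 is b
    ch: list[tuple[float, int]] = []
    x = 0.0
    s = state
    while True:
        r = rates[s]
        if r <= 0:
            break
        x += rng.exponential(1.0 / r)
        if x >= t:
            break
        s = 1 - s
        ch.append((x, s))
    return s, ch


def _uniformization_path(s0: int, s1: int, t: float, Q: RateMatrix2,
                         rng: np.random.Generator) -> list[tuple[float, int]]:
    """Exact endpoint-conditioned draw via the uniformization bridge."""
    a, b = Q.q_gain, Q.q_loss
    omega = max(a, b)
    if omega <= 0:
        if s0 != s1:
            raise SimmapError("impossible path: zero rates, unequal endpoints")
        return []
    R = np.eye(2) + Q.matrix() / omega
    P_t = ctmc.transition_matrix(Q, t)
    p_ab = P_t[s0, s1]
    if p_ab <= 0:
        raise SimmapError("impossible endpoint pair for this Q and t")
    # sample the number of uniformized jumps n | endpoints
    u = rng.uniform()
    acc = 0.0
    Rn = np.eye(2)
    pois = math.exp(-omega * t)
    n = 0
    # sequential search; n is a.s. finite
    while True:
        term = pois * Rn[s0, s1] / p_ab
        acc += term
        if u <= acc or n > 100000:
            break
        n += 1
        pois *= omega * t / n
        Rn = Rn @ R
    if n == 0:
        return []
    times = np.sort(rng.uniform(0.0, t, size=n))
    # bridge states at the jump epochs
    # precompute powers of R up to n
    Rpow = [np.eye(2)]
    for _ in range(n):
        Rpow.append(Rpow[-1] @ R)
    states = np.empty(n + 1, dtype=np.int64)
    states[0] = s0
    for k in range(1, n + 1):
        w = np.array([R[states[k - 1], j] * Rpow[n - k][j, s1]
                      for j in range(2)])
        tot = w.sum()
        states[k] = rng.choice(2, p=w / tot)
    if states[n] != s1:  # numerically impossible, guard anyway
        raise SimmapError("uniformization bridge failed to hit endpoint")
    ch = []
    cur = s0
    for k in range(1, n + 1):
        if states[k] != cur:  # drop virtual (self) jumps
            cur = int(states[k])
            ch.append((float(times[k - 1]), cur))
    return ch


def sample_branch_path(state_parent: int, state_child: int, t: float,
                       Q: RateMatrix2, rng: np.random.Generator
                       ) -> list[tuple[float, int]]:
    """Endpoint-conditioned path on a single branch.

    Rejection-samples forward paths conditioned on the child state, falling
    back to the uniformization bridge after ``REJECTION_CAP`` rejected
    attempts (long branches / unlikely endpoint pairs).
    """
    if t < 0:
        raise SimmapError("negative branch length")
    if t == 0:
        if state_parent != state_child:
            raise SimmapError("impossible path: t = 0 with unequal endpoints")
        return []
    a, b = Q.q_gain, Q.q_loss
    if a + b == 0:
        if state_parent != state_child:
            raise SimmapError("impossible path: Q = 0 with unequal endpoints")
        return []
    for _ in range(REJECTION_CAP):
        end, ch = _forward_path(state_parent, t, a, b, rng)
        if end == state_child:
            return ch
    return _uniformization_path(state_parent, state_child, t, Q, rng)


def sample_history(tree: Phylogeny, tip_priors, Q: RateMatrix2,
                   rng: np.random.Generator,
                   cl: ctmc.ConditionalLikelihoods | None = None,
                   tree_index: int = 0, sim_index: int = 0) -> CharacterHistory:
    """One full stochastic map: node states plus per-branch paths."""
    states = sample_node_states(tree, tip_priors, Q, rng, cl=cl)
    paths: dict[int, list[tuple[float, int]]] = {}
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        paths[v] = sample_branch_path(int(states[tree.parent[v]]),
                                      int(states[v]), float(tree.blen[v]),
                                      Q, rng)
    return CharacterHistory(tree, states, paths, Q, tree_index, sim_index)


# ---------------------------------------------------------------------------
# Mapping over a tree sample
# ---------------------------------------------------------------------------

@dataclass
class MappingSummary:
    """Per-simulation table plus aggregate posterior summaries.

    ``table`` has one row per simulation with columns ``tree_index``,
    ``sim_index``, ``n_gain``, ``n_loss``, ``q_gain``, ``q_loss``,
    ``root_state``.
    """

    table: pd.DataFrame
    n_trees: int
    n_per_tree: int

    @property
    def n_simulations(self) -> int:
        return len(self.table)

    def root_state_probs(self) -> dict[str, float]:
        p1 = float((self.table["root_state"] == PRESENT).mean())
        return {"absent": 1.0 - p1, "present": p1}

    def count_differences(self) -> np.ndarray:
        return (self.table["n_gain"] - self.table["n_loss"]).to_numpy(float)

    def rate_differences(self) -> np.ndarray:
        return (self.table["q_gain"] - self.table["q_loss"]).to_numpy(float)

    def to_json_dict(self) -> dict:
        return {
            "n_simulations": int(self.n_simulations),
            "n_trees": int(self.n_trees),
            "n_per_tree": int(self.n_per_tree),
            "root_state_probs": self.root_state_probs(),
            "mean_n_gain": float(self.table["n_gain"].mean()),
            "mean_n_loss": float(self.table["n_loss"].mean()),
            "mean_q_gain": float(self.table["q_gain"].mean()),
            "mean_q_loss": float(self.table["q_loss"].mean()),
        }


def map_over_sample(sample: TreeSample, tip_priors, n_per_tree: int = 10,
                    seed: int = 0, Q: RateMatrix2 | None = None,
                    rates: Sequence[RateMatrix2] | None = None,
                    keep_histories: bool = False) -> MappingSummary:
    """Stochastic mapping across a tree sample.

    Rates default to a per-tree maximum-likelihood ARD fit (empirical
    Bayes); pass ``Q`` for a single shared matrix or ``rates`` (one per
    tree) to reuse fits.  Substreams per (tree, simulation) derive
    deterministically from ``seed``, so the run is fully reproducible.
    """
    ss = np.random.SeedSequence(seed)
    tree_seeds = ss.spawn(len(sample.trees))
    rows = []
    histories: list[CharacterHistory] = []
    for k, tree in enumerate(sample.trees):
        if rates is not None:
            Qk = rates[k]
        elif Q is not None:
            Qk = Q
        else:
            Qk = ctmc.fit_ard(tree, tip_priors).Q
        cl = ctmc.conditional_likelihoods(tree, tip_priors, Qk)
        sim_seeds = tree_seeds[k].spawn(n_per_tree)
        for j in range(n_per_tree):
            rng = np.random.default_rng(sim_seeds[j])
            h = sample_history(tree, tip_priors, Qk, rng, cl=cl,
                               tree_index=k, sim_index=j)
            rows.append((k, j, h.n_gains(), h.n_losses(),
                         Qk.q_gain, Qk.q_loss, h.root_state()))
            if keep_histories:
                histories.append(h)
    table = pd.DataFrame(rows, columns=["tree_index", "sim_index", "n_gain",
                                        "n_loss", "q_gain", "q_loss",
                                        "root_state"])
    summary = MappingSummary(table, n_trees=len(sample.trees),
                             n_per_tree=n_per_tree)
    if keep_histories:
        summary.histories = histories  # type: ignore[attr-defined]
    return summary


# ---------------------------------------------------------------------------
# Gains vs losses
# ---------------------------------------------------------------------------

@dataclass
class PairedTestResult:
    statistic: float
    p_value: float
    n_nonzero: int
    note: str = ""


def _wilcoxon(diffs: np.ndarray) -> PairedTestResult:
    d = np.asarray(diffs, dtype=float)
    nz = d[d != 0]
    note = ""
    if nz.size == 0:
        return PairedTestResult(0.0, 1.0, 0, "all paired differences zero")
    if d.size != nz.size:
        note = f"{d.size - nz.size} zero differences dropped"
    tied = len(np.unique(np.abs(nz))) < nz.size
    if nz.size <= 25 and not tied:
        res = stats.wilcoxon(nz, alternative="two-sided", method="exact",
                             zero_method="wilcox")
    else:
        res = stats.wilcoxon(nz, alternative="two-sided", method="approx",
                             correction=True, zero_method="wilcox")
    return PairedTestResult(float(res.statistic), float(res.pvalue),
                            int(nz.size), note)


def compare_gains_losses(summary: MappingSummary) -> dict[str, PairedTestResult]:
    """Wilcoxon matched-pairs tests of gains vs losses.

    Pairs are (gain, loss) within each simulation; both the event-count and
    the transition-rate comparisons are reported (signed-rank on the paired
    differences; exact null for <= 25 untied nonzero differences, normal
    approximation with continuity and tie correction otherwise; zero
    differences dropped).
    """
    if summary.n_simulations < 1:
        raise SimmapError("no simulations to compare")
    return {
        "counts": _wilcoxon(summary.count_differences()),
        "rates": _wilcoxon(summary.rate_differences()),
    }
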