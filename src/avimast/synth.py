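"""Synthetic trees, traits and survey-style record tables.

Stands in for the study data (a multi-record behavioural survey over ~120
bird species with a posterior sample of ultrametric phylogenies) so that
every stage of the analysis is testable offline:

* :func:`simulate_tree` -- birth-death trees conditioned on a tip count,
  rescaled to unit height;
* :func:`simulate_trait` -- forward simulation of the binary trait under a
  2-state ARD chain, returning the true character history so mapping
  accuracy is measurable;
* :func:`simulate_records` -- a survey observation process: an
  overdispersed number of records per species, categorical covariates,
  clade-conserved mating-system flags, and record responses from the same
  latent logistic model the pGLMM fits (known intercept, effect sizes and
  variance components, returned as a truth table).

Defaults mirror the study conditions: 120 species, about two records per
species (200+ records in total), an even sex split, mostly adult and mostly
captive records, no poor-condition records, and a strongly clade-conserved
trait (large phylogenetic variance relative to residual).

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .ctmc import ABSENT, PRESENT, RateMatrix2
from .dataset import ObservationRecord
from .treeio import Phylogeny, TreeSample, phylo_correlation

log = logging.getLogger(__name__)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SynthConfig:
    """Truth and sampling-design knobs for the synthetic study."""

    n_species: int = 120
    birth_rate: float = 1.0
    death_rate: float = 0.0
    # trait evolution on the unit-height tree: losses outpace gains
    q_gain: float = 0.8
    q_loss: float = 1.6
    # latent logistic truth
    intercept: float = 0.5
    beta: dict = field(default_factory=lambda: {
        "sex:male": 2.0,
        "origin:wild": 2.0,
        "social_monogamy:y": -2.0,
        "long_term_pair_bond:y": -2.0,
        "multiple_mates:y": 2.0,
        "rearing:hand": -2.0,
    })
    # the study-like regime: phylogenetic variance dominating the residual
    # (signal near 1), giving a trait fixed or nearly so within clades
    v_phylo: float = 100.0
    v_resid: float = 1.0
    # records per species: 1 + NegBin(mean-1, dispersion)
    records_per_species_mean: float = 2.0
    records_dispersion: float = 1.0
    # covariate level frequencies
    sex_freqs: dict = field(default_factory=lambda: {
        "male": 0.45, "female": 0.45, "unknown": 0.10})
    age_freqs: dict = field(default_factory=lambda: {
        "adult": 0.45, "juvenile": 0.10, "unknown": 0.45})
    origin_freqs: dict = field(default_factory=lambda: {
        "captive": 0.70, "wild": 0.30})
    social_env_freqs: dict = field(default_factory=lambda: {
        "mixed-species": 0.20, "solitary": 0.25, "opposite-sex": 0.25,
        "same-sex": 0.15, "unknown": 0.15})
    rearing_freqs: dict = field(default_factory=lambda: {
        "parent": 0.55, "hand": 0.30, "unknown": 0.15})
    condition_freqs: dict = field(default_factory=lambda: {
        "good": 0.60, "poor": 0.0, "unknown": 0.40})
    source_freqs: dict = field(default_factory=lambda: {
        "literature": 0.25, "expert": 0.45, "citizen": 0.30})
    flag_prevalence: dict = field(default_factory=lambda: {
        "social_monogamy": 0.6, "long_term_pair_bond": 0.45,
        "lekking": 0.1, "multiple_mates": 0.35,
        "cooperative_breeding": 0.1})
    clade_size: int = 10   # subtree size for clade-wise flag assignment
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.death_rate >= self.birth_rate:
            raise ValueError("death rate must be below birth rate")
        if min(self.q_gain, self.q_loss) < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def Q(self) -> RateMatrix2:
        return RateMatrix2(self.q_gain, self.q_loss)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_tree(config: SynthConfig | None = None, *,
                  n_species: int | None = None, seed: int | None = None
                  ) -> Phylogeny:
    """Ultrametric birth-death tree conditioned on the tip count, unit
    height, tips labelled ``sp0001 ...``."""
    config = config or SynthConfig()
    n = n_species if n_species is not None else config.n_species
    sd = config.seed if seed is None else seed
    dt = treesim.birth_death_tree(
        birth_rate=config.birth_rate, death_rate=config.death_rate,
        num_extant_tips=n, rng=random.Random(sd))
    # the simulation stops exactly at the n-th birth, leaving a zero-length
    # cherry; extend every tip branch by the (memoryless) waiting time to
    # the next event so the final interval is properly represented
    w = np.random.default_rng(sd).exponential(
        1.0 / (n * config.birth_rate))
    for i, leaf in enumerate(dt.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:04d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + w
    tree = Phylogeny.from_dendropy(dt)
    h = tree.max_depth()
    if h > 0:
        tree = tree.scaled(1.0 / h)
    return tree


def _rebuild_postorder(tree: Phylogeny) -> None:
    order = []
    stack = [(tree.root, False)]
    while stack:
        v, done = stack.pop()
        if tree.left[v] < 0:
            continue
        if done:
            order.append(v)
        else:
            stack.append((v, True))
            stack.append((tree.left[v], False))
            stack.append((tree.right[v], False))
    tree.postorder = np.array(order, dtype=np.int64)


def _perturb_tree(base: Phylogeny, rng: np.random.Generator,
                  age_jitter: float, n_nni: int) -> Phylogeny:
    """Posterior-style perturbation: ultrametric-preserving NNI moves plus
    lognormal node-age jitter, rescaled to unit height."""
    t = Phylogeny(list(base.tip_labels), base.parent.copy(),
                  base.blen.copy(), base.left.copy(), base.right.copy(),
                  base.postorder.copy(), base.root)
    # NNI: swap a node's child with its sibling where node ages permit
    moves = 0
    for _ in range(50):
        if moves >= n_nni:
            break
        d = t.depths()
        internals = [v for v in range(t.n_nodes)
                     if t.left[v] >= 0 and v != t.root]
        v = int(rng.choice(internals))
        p = int(t.parent[v])
        s = int(t.left[p] if t.right[p] == v else t.right[p])
        c = int(t.left[v] if rng.uniform() < 0.5 else t.right[v])
        if d[s] <= d[v]:  # s cannot reattach below v
            continue
        if t.left[v] == c:
            t.left[v] = s
        else:
            t.right[v] = s
        if t.left[p] == s:
            t.left[p] = c
        else:
            t.right[p] = c
        t.parent[s] = v
        t.parent[c] = p
        t.blen[s] = d[s] - d[v]
        t.blen[c] = d[c] - d[p]
        moves += 1
    _rebuild_postorder(t)
    # node-age jitter: scale internal edges, re-close tips to a common height
    internal_mask = t.left >= 0
    jit = np.exp(rng.normal(0.0, age_jitter, size=t.n_nodes))
    t.blen = np.where(internal_mask, t.blen * jit, t.blen)
    d = t.depths()
    H = max(float(d[internal_mask].max()) * 1.02, 1e-6)
    for i in range(t.n_tips):
        t.blen[i] = H - d[t.parent[i]]
    h = t.max_depth()
    return t.scaled(1.0 / h)


def simulate_tree_sample(config: SynthConfig | None = None, *,
                         n_trees: int = 20, seed: int | None = None,
                         age_jitter: float = 0.1, n_nni: int = 2
                         ) -> TreeSample:
    """A synthetic posterior sample of phylogenies.

    The members are correlated perturbations of one base tree (a few
    ultrametric-preserving nearest-neighbour interchanges plus lognormal
    node-age jitter), mimicking a posterior sample's topological and dating
    uncertainty around a common truth; two halves are tagged as coming from
    two backbones."""
    config = config or SynthConfig()
    sd = config.seed if seed is None else seed
    base = simulate_tree(config, seed=sd)
    rng = np.random.default_rng(sd + 977)
    trees = [base] + [_perturb_tree(base, rng, age_jitter, n_nni)
                      for _ in range(n_trees - 1)]
    tags = ["backboneA" if k < n_trees / 2 else "backboneB"
            for k in range(n_trees)]
    return TreeSample(trees, tags)


# ---------------------------------------------------------------------------
# Trait evolution
# ---------------------------------------------------------------------------

def simulate_trait(tree: Phylogeny, Q: RateMatrix2, seed: int = 0,
                   root_state: int | None = None
                   ) -> tuple[dict[str, int], "TrueHistory"]:
    """Forward 2-state CTMC on the tree from a stationary root draw.

    ``root_state`` conditions the root instead of drawing it from the
    stationary distribution (e.g. to emulate an ancestrally-present trait
    eroded by losses).  Returns tip states keyed by label and the true
    history (node states, per-branch change points, gain/loss counts).
    """
    rng = np.random.default_rng(seed)
    states = np.full(tree.n_nodes, -1, dtype=np.int64)
    if root_state is not None:
        states[tree.root] = int(root_state)
    elif Q.total > 0:
        states[tree.root] = rng.choice(2, p=Q.stationary())
    else:
        states[tree.root] = rng.integers(2)
    paths: dict[int, list[tuple[float, int]]] = {}
    rates = (Q.q_gain, Q.q_loss)
    stack = [tree.root]
    while stack:
        v = stack.pop()
        if tree.left[v] >= 0:
            stack.append(tree.left[v])
            stack.append(tree.right[v])
        if v == tree.root:
            continue
        s = int(states[tree.parent[v]])
        t = float(tree.blen[v])
        ch: list[tuple[float, int]] = []
        x = 0.0
        while True:
            r = rates[s]
            if r <= 0:
                break
            x += rng.exponential(1.0 / r)
            if x >= t:
                break
            s = 1 - s
            ch.append((x, s))
        states[v] = s
        paths[v] = ch
    tips = {lb: int(states[i]) for i, lb in enumerate(tree.tip_labels)}
    return tips, TrueHistory(states, paths)


@dataclass
class TrueHistory:
    node_states: np.ndarray
    paths: dict[int, list[tuple[float, int]]]

    def n_gains(self) -> int:
        return sum(1 for ch in self.paths.values()
                   for _, s in ch if s == PRESENT)

    def n_losses(self) -> int:
        return sum(1 for ch in self.paths.values()
                   for _, s in ch if s == ABSENT)


# ---------------------------------------------------------------------------
# Survey records
# ---------------------------------------------------------------------------

def _draw_level(rng, freqs: dict) -> str:
    levels = list(freqs)
    p = np.array([freqs[l] for l in levels], dtype=float)
    p = p / p.sum()
    return str(rng.choice(levels, p=p))


def _clade_partition(tree: Phylogeny, max_size: int) -> list[np.ndarray]:
    """Partition tips into maximal subtrees of at most ``max_size`` tips."""
    sizes = np.ones(tree.n_nodes, dtype=np.int64)
    for v in tree.postorder:
        sizes[v] = sizes[tree.left[v]] + sizes[tree.right[v]]
    clades: list[np.ndarray] = []

    def collect(v: int) -> None:
        if sizes[v] <= max_size or tree.left[v] < 0:
            tips = []
            stack = [v]
            while stack:
                u = stack.pop()
                if tree.left[u] < 0:
                    tips.append(u)
                else:
                    stack.append(tree.left[u])
                    stack.append(tree.right[u])
            clades.append(np.array(sorted(tips)))
        else:
            collect(tree.left[v])
            collect(tree.right[v])

    collect(tree.root)
    return clades


def simulate_records(tree: Phylogeny, config: SynthConfig | None = None,
                     seed: int | None = None
                     ) -> tuple[list[ObservationRecord], dict]:
    """Survey observation process over the tree's species.

    Per species: a record count from a shifted negative binomial (min 1);
    per record: covariates from the configured level frequencies, with
    mating-system flags drawn once per clade (phylogenetically conserved,
    like real mating systems) and rearing only set for captive records.
    Record responses come from the latent logistic model with species
    random effects ``u ~ N(0, v_phylo * A)`` and iid residuals.

    Returns the records and a truth table (betas, variance components, the
    species random effects and latent presence probabilities).
    """
    config = config or SynthConfig()
    sd = config.seed if seed is None else seed
    rng = np.random.default_rng(sd)
    n = tree.n_tips
    labels = tree.tip_labels

    # clade-conserved species flags
    clades = _clade_partition(tree, config.clade_size)
    flag_vals = {c: np.empty(n, dtype=object) for c in config.flag_prevalence}
    for tips in clades:
        for c, prev in config.flag_prevalence.items():
            v = "y" if rng.uniform() < prev else "n"
            flag_vals[c][tips] = v
    # keep pair-bond consistent with monogamy
    if "long_term_pair_bond" in flag_vals and "social_monogamy" in flag_vals:
        mono = flag_vals["social_monogamy"]
        ltpb = flag_vals["long_term_pair_bond"]
        ltpb[mono == "n"] = "n"

    # species random effects
    A = phylo_correlation(tree).to_numpy(float)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    u = np.sqrt(config.v_phylo) * (L @ rng.standard_normal(n))

    # record counts: 1 + NB(mean-1, dispersion)
    mu = max(config.records_per_species_mean - 1.0, 0.0)
    k = max(config.records_dispersion, 1e-6)
    if mu > 0:
        p_nb = k / (k + mu)
        extra = rng.negative_binomial(k, p_nb, size=n)
    else:
        extra = np.zeros(n, dtype=int)
    counts = 1 + extra

    records: list[ObservationRecord] = []
    beta = dict(config.beta)
    for i in range(n):
        for _ in range(int(counts[i])):
            sex = _draw_level(rng, config.sex_freqs)
            age = _draw_level(rng, config.age_freqs)
            origin = _draw_level(rng, config.origin_freqs)
            social_env = _draw_level(rng, config.social_env_freqs)
            rearing = (_draw_level(rng, config.rearing_freqs)
                       if origin == "captive" else "unknown")
            condition = _draw_level(rng, config.condition_freqs)
            source = _draw_level(rng, config.source_freqs)
            eta = config.intercept + u[i]
            eta += beta.get(f"sex:{sex}", 0.0)
            eta += beta.get(f"age:{age}", 0.0)
            eta += beta.get(f"origin:{origin}", 0.0)
            eta += beta.get(f"social_env:{social_env}", 0.0)
            eta += beta.get(f"rearing:{rearing}", 0.0)
            for c in config.flag_prevalence:
                eta += beta.get(f"{c}:{flag_vals[c][i]}", 0.0)
            eta += rng.normal(0.0, np.sqrt(config.v_resid))
            yes = rng.uniform() < _logistic(eta)
            records.append(ObservationRecord(
                species=labels[i],
                masturbation="yes" if yes else "no",
                sex=sex, age=age, origin=origin, social_env=social_env,
                rearing=rearing, condition=condition,
                n_observed=int(1 + rng.poisson(0.5)),
                source=source,
                flags={c: flag_vals[c][i] for c in config.flag_prevalence}))

    truth = {
        "seed": int(sd),
        "intercept": config.intercept,
        "beta": beta,
        "v_phylo": config.v_phylo,
        "v_resid": config.v_resid,
        "u": {labels[i]: float(u[i]) for i in range(n)},
        "records_per_species": {labels[i]: int(counts[i]) for i in range(n)},
    }
    return records, truth


def write_study(outdir, config: SynthConfig | None = None, *,
                n_trees: int = 20, seed: int | None = None) -> dict:
    """Write a full synthetic study to ``outdir``: tree sample (Newick),
    record CSV and truth JSON.  Returns the file paths."""
    import pathlib

    from .dataset import write_records

    config = config or SynthConfig()
    sd = config.seed if seed is None else seed
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample = simulate_tree_sample(config, n_trees=n_trees, seed=sd)
    tree = sample.trees[0]
    records, truth = simulate_records(tree, config, seed=sd + 1)
    trees_path = outdir / "trees.nwk"
    sample.write(trees_path)
    rec_path = outdir / "records.csv"
    write_records(records, rec_path)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"trees": str(trees_path), "records": str(rec_path),
            "truth": str(truth_path)}
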