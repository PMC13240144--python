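"""Bayesian binary phylogenetic mixed model (pGLMM) on record-level data.

Model (latent-threshold, logistic link).  Each observation record ``i`` of
species ``s(i)`` has a latent score

    l_i = mu + x_i' beta + u_{s(i)} + e_i,
    u ~ N(0, V_phylo * A),   e_i ~ N(0, V_resid),
    P(response_i = yes) = logistic(l_i),

where ``A`` is the phylogenetic correlation matrix of the species on the
tree (see :func:`avimast.treeio.phylo_correlation`).  Priors: inverse-Wishart
(scalar: inverse-gamma) with scale ``V`` and shape ``nu`` on both variance
components, and a diffuse zero-mean normal on fixed effects.

Sampling uses Polya-Gamma data augmentation (Polson, Scott & Windle 2013):
conditional on auxiliary ``omega_i ~ PG(1, l_i)`` every update is conjugate
Gaussian / inverse-gamma, giving an exact MCMC scheme with good mixing for
binary responses.  The heavy loops are numba-compiled.

Phylogenetic signal is reported as the ratio of the posterior mean
phylogenetic variance to the sum of posterior mean phylogenetic and
residual variances (a ratio of means, not a mean of ratios).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .treeio import Phylogeny, normalize_label, phylo_correlation

log = logging.getLogger(__name__)

#: Explanatory variables the analysis supports, one per model.
PREDICTORS = ("age", "sex", "origin", "social_monogamy",
              "long_term_pair_bond", "lekking", "multiple_mates",
              "social_env", "rearing")

_UNKNOWN = {"unknown", "", "na", "nan", "none"}


class PGLMMError(ValueError):
    pass


class InadequateModelError(PGLMMError):
    """Chain failed diagnostics after the maximum number of escalations."""


# ---------------------------------------------------------------------------
# Specs and settings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """At most one explanatory variable; ``None`` gives the null
    (signal-estimation) model."""

    fixed_effect: str | None = None
    response: str = "masturbation"

    def __post_init__(self) -> None:
        if self.fixed_effect is not None and not isinstance(self.fixed_effect, str):
            raise PGLMMError("fixed_effect must be a column name or None")


@dataclass(frozen=True)
class PriorSpec:
    """Inverse-Wishart (scalar inverse-gamma) variance priors and a diffuse
    normal fixed-effect prior."""

    V: float = 1.0
    nu: float = 0.002
    beta_variance: float = 1e10

    def __post_init__(self) -> None:
        if self.V <= 0 or self.nu <= 0 or self.beta_variance <= 0:
            raise PGLMMError("prior scales must be positive")


@dataclass(frozen=True)
class ChainSettings:
    """MCMC length policy.

    Defaults are the full study profile (11e6 iterations, 1e6 burn-in,
    thinning 1e4, posterior of 1000); :meth:`desk` gives the reduced profile
    used for routine runs and tests.
    """

    iterations: int = 11_000_000
    burn_in: int = 1_000_000
    thin: int = 10_000
    target_posterior: int = 1000
    ess_floor: float = 200.0
    escalation_factor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.iterations, self.burn_in, self.thin,
               self.target_posterior) <= 0:
            raise PGLMMError("all chain settings must be positive")
        if (self.iterations - self.burn_in) // self.thin != self.target_posterior:
            raise PGLMMError("(iterations - burn_in)/thin must equal the "
                             "target posterior size")

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "ChainSettings":
        return cls(iterations=110_000, burn_in=10_000, thin=100,
                   seed=seed, **kw)

    @classmethod
    def quick(cls, seed: int = 0, **kw) -> "ChainSettings":
        """Small profile for simulation studies (posterior still 1000)."""
        return cls(iterations=11_000, burn_in=1_000, thin=10, seed=seed, **kw)

    def escalated(self) -> "ChainSettings":
        f = self.escalation_factor
        return replace(self, iterations=self.iterations * f,
                       burn_in=self.burn_in * f, thin=self.thin * f)


# ---------------------------------------------------------------------------
# Polya-Gamma sampler (Devroye's alternating-series method for PG(1, z))
# ---------------------------------------------------------------------------

_T = 0.64  # series crossover point


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _a_coef(n, x):
    nph = n + 0.5
    if x <= _T:
        return (math.pi * nph * (2.0 / (math.pi * x)) ** 1.5
                * math.exp(-2.0 * nph * nph / x))
    return math.pi * nph * math.exp(-nph * nph * math.pi * math.pi * x / 2.0)


@njit(cache=True)
def _rtigauss(z):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _T]."""
    t = _T
    if z < 1.0 / t:  # mu > t: one-over-chi-square style rejection
        while True:
            while True:
                ee = np.random.exponential(1.0)
                ep = np.random.exponential(1.0)
                if ee * ee <= 2.0 * ep / t:
                    break
            x = t / ((1.0 + t * ee) ** 2)
            if np.random.uniform(0.0, 1.0) <= math.exp(-z * z * x / 2.0):
                return x
    mu = 1.0 / z
    while True:
        v = np.random.normal(0.0, 1.0)
        y = v * v
        x = mu + 0.5 * mu * mu * y - 0.5 * mu * math.sqrt(
            4.0 * mu * y + (mu * y) ** 2)
        if np.random.uniform(0.0, 1.0) > mu / (mu + x):
            x = mu * mu / x
        if 0.0 < x <= t:
            return x


@njit(cache=True)
def _rpg1(zin):
    """One draw from PG(1, zin)."""
    z = abs(zin) * 0.5
    t = _T
    K = math.pi * math.pi / 8.0 + z * z / 2.0
    p = (math.pi / (2.0 * K)) * math.exp(-K * t)
    # q = 2 exp(-z) * IG(1/z,1)-cdf at t, written overflow-safely
    sq = math.sqrt(t)
    term1 = math.exp(-z) * _norm_cdf((t * z - 1.0) / sq)
    term2 = math.exp(z) * _norm_cdf(-(t * z + 1.0) / sq)
    q = 2.0 * (term1 + term2)
    while True:
        if p + q <= 0.0 or np.random.uniform(0.0, 1.0) >= p / (p + q):
            x = _rtigauss(z)
        else:
            x = t + np.random.exponential(1.0) / K
        s = _a_coef(0, x)
        y = np.random.uniform(0.0, 1.0) * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accept:
            return x / 4.0


@njit(cache=True)
def polya_gamma_draws(z, n, seed):
    """``n`` iid PG(1, z) draws (testing / diagnostics helper)."""
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _rpg1(z)
    return out


# ---------------------------------------------------------------------------
# Gibbs kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _chol_solve_inplace(L, b, x):
    """Solve (L L') x = b given lower-triangular L."""
    d = L.shape[0]
    # forward: L w = b (reuse x as w)
    for i in range(d):
        acc = b[i]
        for j in range(i):
            acc -= L[i, j] * x[j]
        x[i] = acc / L[i, i]
    # backward: L' y = w
    for i in range(d - 1, -1, -1):
        acc = x[i]
        for j in range(i + 1, d):
            acc -= L[j, i] * x[j]
        x[i] = acc / L[i, i]


@njit(cache=True)
def _upper_solve(L, z, x):
    """Solve L' x = z for lower-triangular L."""
    d = L.shape[0]
    for i in range(d - 1, -1, -1):
        acc = z[i]
        for j in range(i + 1, d):
            acc -= L[j, i] * x[j]
        x[i] = acc / L[i, i]


@njit(cache=True)
def _gibbs(y, X, sp, Ainv, nu, V0, beta_prec, fix_resid, fix_phylo,
           n_iter, burn, thin, seed):
    """Polya-Gamma Gibbs sampler.

    Blocks: omega (PG), joint (beta, u) Gaussian, e element-wise Gaussian,
    then inverse-gamma draws for V_phylo and (unless fixed) V_resid.
    Returns thinned samples of (beta..., V_phylo, V_resid).
    """
    np.random.seed(seed)
    N, p = X.shape
    S = Ainv.shape[0]
    d = p + S
    theta = np.zeros(d)          # (beta, u)
    e = np.zeros(N)
    Vp = fix_phylo if fix_phylo > 0.0 else 1.0
    Vr = fix_resid if fix_resid > 0.0 else 1.0
    kappa = y - 0.5
    omega = np.empty(N)
    P = np.empty((d, d))
    bvec = np.empty(d)
    m = np.empty(d)
    v = np.empty(d)
    zdraw = np.empty(d)
    n_out = (n_iter - burn) // thin
    out = np.empty((n_out, p + 2))
    kout = 0
    for it in range(n_iter):
        # --- omega | theta, e
        for i in range(N):
            eta = e[i] + theta[p + sp[i]]
            for j in range(p):
                eta += X[i, j] * theta[j]
            omega[i] = _rpg1(eta)
        # --- (beta, u) | omega, e  (upper triangle accumulation)
        for r in range(d):
            bvec[r] = 0.0
            for c in range(d):
                P[r, c] = 0.0
        for i in range(N):
            w = omega[i]
            ks = kappa[i] - w * e[i]
            si = p + sp[i]
            for j in range(p):
                xj = X[i, j]
                bvec[j] += ks * xj
                for l in range(j, p):
                    P[j, l] += w * xj * X[i, l]
                P[j, si] += w * xj
            P[si, si] += w
            bvec[si] += ks
        for j in range(p):
            P[j, j] += beta_prec
        for r in range(S):
            for c in range(r, S):
                P[p + r, p + c] += Ainv[r, c] / Vp
        for r in range(d):
            for c in range(r):
                P[r, c] = P[c, r]
        ridge = 0.0
        for r in range(d):
            ridge += P[r, r]
        ridge = 1e-12 * ridge / d
        for r in range(d):
            P[r, r] += ridge
        L = np.linalg.cholesky(P)
        _chol_solve_inplace(L, bvec, m)
        for r in range(d):
            zdraw[r] = np.random.normal(0.0, 1.0)
        _upper_solve(L, zdraw, v)
        for r in range(d):
            theta[r] = m[r] + v[r]
        # --- e | omega, theta
        for i in range(N):
            mi = theta[p + sp[i]]
            for j in range(p):
                mi += X[i, j] * theta[j]
            prec = omega[i] + 1.0 / Vr
            mean = (kappa[i] - omega[i] * mi) / prec
            e[i] = mean + np.random.normal(0.0, 1.0) / math.sqrt(prec)
        # --- V_phylo | u
        if fix_phylo <= 0.0:
            quad = 0.0
            for r in range(S):
                acc = 0.0
                for c in range(S):
                    acc += Ainv[r, c] * theta[p + c]
                quad += theta[p + r] * acc
            shape = 0.5 * (nu + S)
            scale = 0.5 * (nu * V0 + quad)
            Vp = scale / np.random.gamma(shape, 1.0)
            # numerical guards only; hit in regimes where the latent scale
            # is unidentified anyway
            if Vp < 1e-10:
                Vp = 1e-10
            elif Vp > 1e12:
                Vp = 1e12
        # --- V_resid | e
        if fix_resid <= 0.0:
            sse = 0.0
            for i in range(N):
                sse += e[i] * e[i]
            shape_r = 0.5 * (nu + N)
            scale_r = 0.5 * (nu * V0 + sse)
            Vr = scale_r / np.random.gamma(shape_r, 1.0)
            if Vr < 1e-10:
                Vr = 1e-10
            elif Vr > 1e12:
                Vr = 1e12
        # --- record
        if it >= burn and (it - burn) % thin == 0 and kout < n_out:
            for j in range(p):
                out[kout, j] = theta[j]
            out[kout, p] = Vp
            out[kout, p + 1] = Vr
            kout += 1
    return out


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

def _is_unknown(v) -> bool:
    return pd.isna(v) or str(v).strip().lower() in _UNKNOWN


def _response_vector(col: pd.Series) -> np.ndarray:
    vals = col.map(lambda v: 1.0 if str(v).strip().lower() in
                   {"yes", "y", "1", "true"} else
                   (0.0 if str(v).strip().lower() in {"no", "n", "0", "false"}
                    else np.nan))
    if vals.isna().any():
        raise PGLMMError("response contains values other than yes/no")
    return vals.to_numpy(float)


@dataclass
class DesignInfo:
    X: np.ndarray
    y: np.ndarray
    species_index: np.ndarray
    species: list[str]
    param_names: list[str]
    reference_level: str | None
    n_dropped_unknown: int
    separation_warning: bool


def build_design(data: pd.DataFrame, spec: ModelSpec) -> DesignInfo:
    """Design matrix with treatment coding.

    Records whose value for the model's factor is unknown/missing are
    excluded from that model (they remain available to other models); the
    most frequent level is the reference; levels with zero records simply do
    not appear.
    """
    df = data.copy()
    if spec.response not in df.columns:
        raise PGLMMError(f"response column {spec.response!r} missing")
    ref = None
    names = ["(Intercept)"]
    dropped = 0
    if spec.fixed_effect is not None:
        fe = spec.fixed_effect
        if fe not in df.columns:
            raise PGLMMError(f"unknown factor: {fe!r}")
        keep = ~df[fe].map(_is_unknown)
        dropped = int((~keep).sum())
        df = df.loc[keep]
        if df.empty:
            raise PGLMMError(f"no records with a known level of {fe!r}")
        levels = df[fe].astype(str).str.strip().str.lower()
        counts = levels.value_counts()
        if len(counts) < 2:
            raise PGLMMError(
                f"factor {fe!r} has a single observed level "
                f"({counts.index[0]!r}); model cannot be run")
        ref = str(counts.index[0])
        other = [lv for lv in counts.index if lv != ref]
        cols = [np.ones(len(df))]
        for lv in other:
            cols.append((levels == lv).to_numpy(float))
            names.append(f"{fe}:{lv}")
        X = np.column_stack(cols)
    else:
        X = np.ones((len(df), 1))

    y = _response_vector(df[spec.response])
    species = sorted({normalize_label(s) for s in df["species"]})
    sp_map = {s: i for i, s in enumerate(species)}
    sp_idx = df["species"].map(
        lambda s: sp_map[normalize_label(s)]).to_numpy(np.int64)

    separation = False
    for j in range(1, X.shape[1]):
        for val in (0.0, 1.0):
            sub = y[X[:, j] == val]
            if sub.size and (sub.min() == sub.max()):
                separation = True
    return DesignInfo(X, y, sp_idx, species, names, ref, dropped, separation)


def _phylo_precision(tree: Phylogeny, species: Sequence[str]) -> np.ndarray:
    A = phylo_correlation(tree)
    idx = {normalize_label(lb): lb for lb in A.index}
    missing = [s for s in species if s not in idx]
    if missing:
        raise PGLMMError(f"species not in tree: {missing}")
    order = [idx[s] for s in species]
    Asub = A.loc[order, order].to_numpy(float)
    # a small ridge keeps the inverse well conditioned when terminal
    # branches are very short (near-duplicate rows)
    for jitter in (1e-8, 1e-6):
        try:
            np.linalg.cholesky(Asub + jitter * np.eye(len(Asub)))
            return np.linalg.inv(Asub + jitter * np.eye(len(Asub)))
        except np.linalg.LinAlgError:
            continue
    raise PGLMMError("phylogenetic correlation matrix is not positive "
                     "definite even after jitter")


@dataclass
class PosteriorChain:
    """Thinned posterior samples of a single model."""

    samples: pd.DataFrame            # one column per parameter
    spec: ModelSpec
    settings: ChainSettings
    n_records: int
    n_species: int
    reference_level: str | None = None
    n_dropped_unknown: int = 0
    separation_warning: bool = False

    @property
    def fixed_effect_names(self) -> list[str]:
        return [c for c in self.samples.columns
                if c not in ("V_phylo", "V_resid")]


def run_chain(data: pd.DataFrame, tree: Phylogeny, spec: ModelSpec,
              priors: PriorSpec | None = None,
              settings: ChainSettings | None = None,
              fix_residual: float | None = None,
              fix_phylo: float | None = None) -> PosteriorChain:
    """Run the pGLMM MCMC and return thinned posterior samples.

    ``fix_residual`` pins the residual variance (recommended for synthetic
    benchmarking, where the free residual variance of a binary model is
    weakly identified); by default it is sampled under the stated prior.
    ``fix_phylo`` likewise pins the phylogenetic variance (benchmarking
    only).
    """
    priors = priors or PriorSpec()
    settings = settings or ChainSettings.desk()
    design = build_design(data, spec)
    if design.separation_warning:
        warnings.warn("complete separation detected: latent-scale estimates "
                      "may be extreme", stacklevel=2)
    Ainv = _phylo_precision(tree, design.species)
    out = _gibbs(design.y, np.ascontiguousarray(design.X),
                 design.species_index, np.ascontiguousarray(Ainv),
                 float(priors.nu), float(priors.V),
                 1.0 / float(priors.beta_variance),
                 -1.0 if fix_residual is None else float(fix_residual),
                 -1.0 if fix_phylo is None else float(fix_phylo),
                 int(settings.iterations), int(settings.burn_in),
                 int(settings.thin), int(settings.seed) % (2 ** 31))
    cols = design.param_names + ["V_phylo", "V_resid"]
    samples = pd.DataFrame(out, columns=cols)
    return PosteriorChain(samples, spec, settings, len(design.y),
                          len(design.species), design.reference_level,
                          design.n_dropped_unknown,
                          design.separation_warning)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def pmcmc(samples: np.ndarray | pd.Series) -> float:
    """Twice the smaller of P(parameter <= 0) and P(parameter >= 0)."""
    s = np.asarray(samples, dtype=float)
    if s.size < 2:
        raise PGLMMError("need at least 2 samples")
    lo = float((s <= 0).mean())
    hi = float((s >= 0).mean())
    return min(2.0 * min(lo, hi), 1.0)


def format_pmcmc(samples: np.ndarray | pd.Series) -> str:
    """Printed form; no sample crossing zero reports the resolution floor
    (``"< 0.001"`` for a posterior of 1000)."""
    s = np.asarray(samples, dtype=float)
    p = pmcmc(s)
    if min((s <= 0).sum(), (s >= 0).sum()) == 0:
        return f"< {1.0 / s.size:g}"
    return f"{p:g}"


def hpd(samples: np.ndarray | pd.Series, mass: float = 0.95
        ) -> tuple[float, float]:
    """Shortest interval containing ``ceil(mass * n)`` sorted samples.

    Ties in width resolve to the smallest lower bound.
    """
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    if n < math.ceil(1.0 / (1.0 - mass)):
        raise PGLMMError("too few samples for this mass")
    m = math.ceil(mass * n)
    widths = s[m - 1:] - s[: n - m + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m - 1])


def phylo_signal(v_phylo: np.ndarray | pd.Series,
                 v_resid: np.ndarray | pd.Series) -> float:
    """mean(V_phylo) / (mean(V_phylo) + mean(V_resid)), a ratio of means."""
    mp = float(np.mean(v_phylo))
    mr = float(np.mean(v_resid))
    if mp < 0 or mr < 0:
        raise PGLMMError("variance samples must be nonnegative")
    if mp + mr == 0:
        raise PGLMMError("signal undefined: both variance means are zero")
    return mp / (mp + mr)


@dataclass
class PosteriorSummary:
    """Per-parameter posterior table plus model-level quantities."""

    table: pd.DataFrame  # index: parameter; cols: mean, hpd_lower, hpd_upper, pmcmc, pmcmc_str, ess
    signal: float | None = None
    status: str = "ok"

    def to_json_dict(self) -> dict:
        d = {"parameters": {
            name: {k: (row[k] if isinstance(row[k], str) else float(row[k]))
                   for k in row.index}
            for name, row in self.table.iterrows()},
            "status": self.status}
        if self.signal is not None:
            d["phylogenetic_signal"] = float(self.signal)
        return d


def summarize(chain: PosteriorChain, include_signal: bool | None = None
              ) -> PosteriorSummary:
    from . import mcdiag

    rows = {}
    for col in chain.samples.columns:
        s = chain.samples[col].to_numpy(float)
        lo, hi = hpd(s)
        rows[col] = {
            "mean": float(s.mean()),
            "hpd_lower": lo,
            "hpd_upper": hi,
            "pmcmc": pmcmc(s),
            "pmcmc_str": format_pmcmc(s),
            "ess": mcdiag.ess(s),
        }
    table = pd.DataFrame(rows).T
    if include_signal is None:
        include_signal = chain.spec.fixed_effect is None
    sig = None
    if include_signal:
        sig = phylo_signal(chain.samples["V_phylo"], chain.samples["V_resid"])
    return PosteriorSummary(table, signal=sig)


# ---------------------------------------------------------------------------
# Escalation policy
# ---------------------------------------------------------------------------

MAX_ESCALATIONS = 2


def escalate_if_needed(summary: PosteriorSummary, settings: ChainSettings
                       ) -> ChainSettings:
    """Scale chain length, burn-in and thinning by the escalation factor
    when any parameter's ESS falls below the floor; otherwise unchanged."""
    ess_vals = summary.table["ess"].astype(float)
    if (ess_vals < settings.ess_floor).any():
        return settings.escalated()
    return settings


def fit_model(data: pd.DataFrame, tree: Phylogeny, spec: ModelSpec,
              priors: PriorSpec | None = None,
              settings: ChainSettings | None = None,
              fix_residual: float | None = None,
              max_escalations: int = MAX_ESCALATIONS
              ) -> tuple[PosteriorChain, PosteriorSummary]:
    """Run a model under the escalation policy.

    Re-runs with a 10-fold longer chain whenever any ESS is below the floor,
    at most ``max_escalations`` times (default :data:`MAX_ESCALATIONS`); a
    chain still failing its diagnostics afterwards is returned with status
    ``"inadequate"`` (never silently dropped).
    """
    from . import mcdiag

    settings = settings or ChainSettings.desk()
    chain = run_chain(data, tree, spec, priors, settings, fix_residual)
    summary = summarize(chain)
    for _ in range(max_escalations):
        new = escalate_if_needed(summary, settings)
        if new is settings:
            break
        log.warning("low ESS: escalating chain x%d", settings.escalation_factor)
        settings = new
        chain = run_chain(data, tree, spec, priors, settings, fix_residual)
        summary = summarize(chain)
    diag = mcdiag.diagnose(chain.samples, ess_floor=settings.ess_floor)
    if not diag.passed:
        summary.status = "inadequate"
    return chain, summary
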