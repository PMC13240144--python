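"""MCMC convergence diagnostics for single thinned chains.

These power the chain-length escalation policy and the model-adequacy gate
of the pipeline: effective sample size by initial-positive-sequence
autocorrelation summation, lag autocorrelation, a Geweke window z score
with batch-means spectral variances, and Heidelberger & Welch's iterative
Cramer-von-Mises stationarity test.  All statistics are invariant under
affine transformation of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DiagnosticsError(ValueError):
    pass


def _autocorrelations(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = x.size
    xc = x - x.mean()
    var = float(xc @ xc) / n
    if var == 0:
        return np.zeros(max_lag + 1)
    # FFT autocovariance
    m = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[: max_lag + 1].real / n
    return acov / acov[0]


def autocorr(samples, lag: int) -> float:
    """Sample autocorrelation of the chain at the given lag."""
    x = np.asarray(samples, dtype=float)
    if lag >= x.size / 2:
        raise DiagnosticsError("lag must be < n/2")
    return float(_autocorrelations(x, lag)[lag])


def ess(samples) -> float:
    """Effective sample size via initial-positive-sequence summation.

    ``tau = 1 + 2 * sum(rho_k)`` over leading lags while the autocorrelation
    stays positive; ESS = n / tau, capped at n.  A constant chain has no
    autocorrelation information and is reported as n (see
    :func:`diagnose` for the zero-variance flag).
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise DiagnosticsError("need at least 10 samples")
    if np.ptp(x) == 0:
        return float(n)
    rho = _autocorrelations(x, max_lag=min(n - 2, n // 2))
    tau = 1.0
    for k in range(1, rho.size):
        if rho[k] <= 0:
            break
        tau += 2.0 * rho[k]
    return float(min(n, n / tau))


def _batch_means_var(x: np.ndarray, n_batches: int = 10) -> float:
    """Spectral variance estimate (variance of the sample mean times n)."""
    n = x.size
    b = max(n // n_batches, 1)
    k = n // b
    means = x[: k * b].reshape(k, b).mean(axis=1)
    if k < 2:
        return float(x.var(ddof=1)) if n > 1 else 0.0
    return float(means.var(ddof=1) * b)


def geweke(samples, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke z score comparing the first and last window means.

    Variances of the window means come from batch-means spectral estimates
    (10 batches).  ``|z| > 2`` flags nonstationarity.  Constant chains
    return 0.
    """
    x = np.asarray(samples, dtype=float)
    if first + last > 1.0 or first <= 0 or last <= 0:
        raise DiagnosticsError("window fractions must be disjoint")
    n = x.size
    a = x[: int(first * n)]
    b = x[int((1.0 - last) * n):]
    if np.ptp(x) == 0:
        return 0.0
    va = _batch_means_var(a) / a.size
    vb = _batch_means_var(b) / b.size
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


_CVM_CRIT_05 = 0.461  # Cramer-von-Mises critical value, alpha = 0.05


@dataclass
class HWResult:
    passed: bool
    stationary_fraction: float
    start_fraction: float


def heidelberger_welch(samples) -> HWResult:
    """Heidelberger & Welch stationarity test.

    Iteratively discards leading 10% increments of the chain and applies the
    Cramer-von-Mises test to the Brownian bridge of the standardised
    cumulative sums; the chain passes when some retained suffix of at least
    half the chain is stationary at alpha = 0.05.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 50:
        raise DiagnosticsError("need at least 50 samples")
    if np.ptp(x) == 0:
        return HWResult(True, 1.0, 0.0)
    s2_full = _batch_means_var(x[n // 2:])
    for start in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        seg = x[int(start * n):]
        m = seg.size
        s2 = s2_full if s2_full > 0 else _batch_means_var(seg)
        if s2 <= 0:
            return HWResult(True, 1.0 - start, start)
        cs = np.cumsum(seg)
        k = np.arange(1, m + 1)
        bridge = (cs - k * seg.mean()) / np.sqrt(m * s2)
        cvm = float((bridge ** 2).mean())
        if cvm < _CVM_CRIT_05:
            return HWResult(True, 1.0 - start, start)
    return HWResult(False, 0.0, 0.5)


@dataclass
class ChainDiagnostics:
    """Per-parameter diagnostics and chain-level verdict.

    A chain passes when every parameter has ESS at or above the floor and
    passes the stationarity test; autocorrelation above 0.1 at lag 10 is a
    warning only (recorded in ``warnings``), not a failure.
    """

    table: pd.DataFrame
    passed: bool
    warnings: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "passed": bool(self.passed),
            "warnings": list(self.warnings),
            "parameters": {str(k): {c: (bool(v) if isinstance(v, (bool, np.bool_))
                                        else float(v))
                                    for c, v in row.items()}
                           for k, row in self.table.iterrows()},
        }


def diagnose(samples: pd.DataFrame, ess_floor: float = 200.0,
             autocorr_lag: int = 10, autocorr_warn: float = 0.1
             ) -> ChainDiagnostics:
    """Full diagnostics table for a posterior sample DataFrame."""
    rows = {}
    warns: list[str] = []
    ok = True
    for col in samples.columns:
        x = samples[col].to_numpy(float)
        zero_var = np.ptp(x) == 0
        e = ess(x)
        ac = 0.0 if zero_var else autocorr(x, autocorr_lag)
        z = geweke(x)
        hw = heidelberger_welch(x)
        rows[col] = {
            "ess": e,
            "autocorr_lag10": ac,
            "geweke_z": z,
            "hw_passed": hw.passed,
            "hw_stationary_fraction": hw.stationary_fraction,
            "zero_variance": zero_var,
        }
        if not zero_var:
            if e < ess_floor or not hw.passed:
                ok = False
        if abs(ac) > autocorr_warn:
            warns.append(f"{col}: autocorrelation {ac:.3f} at lag "
                         f"{autocorr_lag} exceeds {autocorr_warn}")
    return ChainDiagnostics(pd.DataFrame(rows).T, ok, warns)
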