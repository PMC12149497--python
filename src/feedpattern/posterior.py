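"""Posterior summaries and MCMC convergence diagnostics.

Summaries report the posterior mean, posterior SD and the 90% highest
posterior density (HPD) interval — the shortest interval holding the stated
probability mass. Derived quantities (heritability, genetic correlation)
are computed per retained sample and then summarised, so their uncertainty
propagates exactly.

Diagnostics follow the classical single- and multi-chain batteries: the
Geweke first-vs-last window z score, the Heidelberger–Welch stationarity
test (Cramér–von Mises statistic on the standardised cumulative-sum bridge,
iteratively discarding the front of the chain), and the Gelman–Rubin
potential scale reduction factor across independent chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gibbs import GibbsChain

__all__ = [
    "hpd_interval",
    "summarize",
    "geweke_z",
    "heidelberger_welch",
    "gelman_rubin",
    "diagnostics",
    "DiagnosticsReport",
]


def hpd_interval(samples: np.ndarray, credibility: float = 0.90) -> tuple[float, float]:
    """Shortest interval containing ``credibility`` mass of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("HPD interval needs at least 2 samples")
    k = max(1, int(np.ceil(credibility * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def _scalar_series(chain: GibbsChain) -> dict[str, np.ndarray]:
    out = {}
    for name, arr in chain.samples.items():
        if arr.ndim == 1:
            out[name] = arr
        elif name in {"G0", "R0"}:
            prefix = "g" if name == "G0" else "r"
            out[f"{prefix}11"] = arr[:, 0, 0]
            out[f"{prefix}22"] = arr[:, 1, 1]
            out[f"{prefix}12"] = arr[:, 0, 1]
    return out


def summarize(chain: GibbsChain | dict | np.ndarray, credibility: float = 0.90) -> pd.DataFrame:
    """Posterior mean, SD and HPD interval for every scalar chain quantity.

    Accepts a :class:`~feedpattern.gibbs.GibbsChain` (matrix-valued samples
    are unpacked into their distinct elements), a dict of sample arrays, or a
    single array. Requires at least 100 retained samples.
    """
    if isinstance(chain, GibbsChain):
        series = _scalar_series(chain)
    elif isinstance(chain, dict):
        series = {k: np.asarray(v, dtype=float) for k, v in chain.items()}
    else:
        series = {"parameter": np.asarray(chain, dtype=float)}
    rows = []
    for name, x in series.items():
        if x.shape[0] < 100:
            raise ValueError(f"{name}: need >= 100 retained samples, got {x.shape[0]}")
        lo, hi = hpd_interval(x, credibility)
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)),
                "hpd_low": lo,
                "hpd_high": hi,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# spectral variance estimate shared by Geweke and Heidelberger-Welch


def _spectral0(x: np.ndarray) -> float:
    """Spectral density of the chain at frequency zero (variance of the mean
    times n), via a Bartlett-windowed autocovariance sum with bandwidth
    ~ n^(1/3)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    xc = x - x.mean()
    lag_max = min(n - 1, max(1, int(np.ceil(n ** (1 / 3) * 2))))
    acov = np.correlate(xc, xc, mode="full")[n - 1 : n + lag_max] / n
    w = 1.0 - np.arange(1, lag_max + 1) / (lag_max + 1)
    s0 = acov[0] + 2.0 * np.sum(w * acov[1:])
    return float(max(s0, 1e-300))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z score.

    Compares the mean of the first ``first`` fraction of the chain with the
    mean of the last ``last`` fraction, standardised by spectral-density
    estimates of each window's variance of the mean. |z| > ~2-3 flags a
    drifting chain.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    na, nb = int(first * n), int(last * n)
    if na < 10 or nb < 10:
        raise ValueError("chain too short for the Geweke windows")
    a, b = x[:na], x[n - nb :]
    var = _spectral0(a) / na + _spectral0(b) / nb
    return float((a.mean() - b.mean()) / np.sqrt(var))


_CVM_CRIT_5PCT = 0.461  # 5% critical value of the Cramer-von Mises distribution


def heidelberger_welch(x: np.ndarray, alpha_crit: float = _CVM_CRIT_5PCT) -> dict:
    """Heidelberger–Welch stationarity test.

    Computes the Cramér–von Mises statistic of the standardised Brownian
    bridge of chain cumulative sums; while the test rejects, the first 10%
    of the chain is discarded, up to half the chain. Returns pass/fail, the
    retained start index and the final statistic.
    """
    x = np.asarray(x, dtype=float)
    n0 = x.shape[0]
    if n0 < 100:
        raise ValueError("chain too short for the stationarity test")
    start = 0
    while True:
        y = x[start:]
        n = y.shape[0]
        s0 = _spectral0(y)
        csum = np.cumsum(y - y.mean())
        t = np.arange(1, n + 1) / n
        bridge = csum / np.sqrt(n * s0)
        cvm = float(np.sum((bridge - t * bridge[-1]) ** 2) / n)
        if cvm <= alpha_crit:
            return {"stationary": True, "start": start, "cvm": cvm}
        nxt = start + int(0.1 * n0)
        if nxt >= n0 // 2:  # would leave less than half: reject stationarity
            return {"stationary": False, "start": start, "cvm": cvm}
        start = nxt


def gelman_rubin(chains: list[np.ndarray]) -> float:
    """Potential scale reduction factor R-hat from >= 2 chains.

    Classical between/within variance ratio; values near 1 indicate the
    chains have mixed into the same distribution.
    """
    if len(chains) < 2:
        raise ValueError("R-hat needs at least two chains")
    arrs = [np.asarray(c, dtype=float) for c in chains]
    n = min(a.shape[0] for a in arrs)
    arrs = np.stack([a[:n] for a in arrs])  # (m, n)
    m = arrs.shape[0]
    means = arrs.mean(axis=1)
    w = arrs.var(axis=1, ddof=1).mean()
    grand = means.mean()
    b = n * np.sum((means - grand) ** 2) / (m - 1)
    var_plus = (n - 1) / n * w + b / n
    if w == 0:
        return 1.0
    # sampling noise can push the ratio below 1; clip so identical chains give 1
    return float(max(1.0, np.sqrt(var_plus / w)))


@dataclass
class DiagnosticsReport:
    """Per-parameter convergence summary for one or more chains."""

    geweke: dict[str, float]
    heidelberger: dict[str, dict]
    rhat: dict[str, float] | None

    def all_ok(self, z_limit: float = 3.0, rhat_limit: float = 1.1) -> bool:
        ok = all(abs(z) < z_limit for z in self.geweke.values())
        ok &= all(h["stationary"] for h in self.heidelberger.values())
        if self.rhat is not None:
            ok &= all(r < rhat_limit for r in self.rhat.values())
        return ok


def diagnostics(chains: GibbsChain | list[GibbsChain]) -> DiagnosticsReport:
    """Run the Geweke, Heidelberger–Welch and (given >= 2 chains) Gelman–Rubin
    diagnostics on every scalar quantity of the chain(s)."""
    if isinstance(chains, GibbsChain):
        chains = [chains]
    series = [_scalar_series(c) for c in chains]
    names = series[0].keys()
    gw = {k: geweke_z(series[0][k]) for k in names}
    hw = {k: heidelberger_welch(series[0][k]) for k in names}
    rhat = None
    if len(chains) >= 2:
        rhat = {k: gelman_rubin([s[k] for s in series]) for k in names}
    return DiagnosticsReport(geweke=gw, heidelberger=hw, rhat=rhat)
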