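"""MCMC convergence diagnostics: PSRF, multivariate PSRF, half-width test.

The potential scale reduction factor (PSRF) compares between- and
within-chain variance; values near 1 indicate the chains are sampling the
same distribution (the study protocol flags convergence when PSRF < 1.2).
The multivariate version bounds the PSRF over all linear combinations of a
parameter block.  The Heidelberger–Welch half-width test checks chain-mean
stationarity (Cramér–von Mises on a standardized Brownian bridge) and then
whether the chain is long enough for the mean's confidence half-width to
be small relative to the mean.
"""

from __future__ import annotations

import numpy as np

# asymptotic Cramer-von Mises critical values
_CVM_CRIT = {0.10: 0.347, 0.05: 0.461, 0.025: 0.581, 0.01: 0.743}


def _chain_matrix(draws, parameter=None):
    """Extract an (iterations, chains) matrix from ChainDraws or an array."""
    if hasattr(draws, "draws"):
        if parameter is None:
            raise ValueError("parameter name required for ChainDraws input")
        name, *rest = parameter if isinstance(parameter, tuple) else (parameter,)
        arr = draws.draws[name]
        if arr.ndim == 3:
            idx = rest[0] if rest else 0
            arr = arr[:, :, idx]
        return arr
    arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected an (iterations, chains) array")
    return arr


def psrf(draws, parameter=None) -> float:
    """Univariate potential scale reduction factor.

    R-hat = sqrt(V-hat / W) with V-hat = (n-1)/n W + B/n, where W is the
    mean within-chain variance and B/n the variance of the chain means.
    Requires at least two chains of equal length.
    """
    x = _chain_matrix(draws, parameter)
    n, m = x.shape
    if m < 2:
        raise ValueError("PSRF requires at least 2 chains")
    W = x.var(axis=0, ddof=1).mean()
    B_over_n = x.mean(axis=0).var(ddof=1)
    if W == 0.0:
        return 1.0
    v_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(v_hat / W))


def mpsrf(draws, parameters=None) -> float:
    """Multivariate PSRF (largest-eigenvalue bound over a parameter block).

    R_p = sqrt((n-1)/n + (m+1)/m * lambda_1), lambda_1 the top eigenvalue
    of W^{-1} B/n for within/between covariance matrices W, B/n.
    """
    if hasattr(draws, "draws"):
        names = parameters or draws.parameter_names()
        cols = []
        for name in names:
            arr = draws.draws[name]
            if arr.ndim == 3:
                cols.append(arr.reshape(arr.shape[0], arr.shape[1], -1))
            else:
                cols.append(arr[:, :, None])
        x = np.concatenate(cols, axis=2)  # (n, m, p)
    else:
        x = np.asarray(draws, dtype=float)
        if x.ndim != 3:
            raise ValueError("expected an (iterations, chains, params) array")
    n, m, p = x.shape
    if m < 2:
        raise ValueError("MPSRF requires at least 2 chains")
    chain_means = x.mean(axis=0)  # (m, p)
    W = np.zeros((p, p))
    for c in range(m):
        d = x[:, c, :] - chain_means[c]
        W += d.T @ d / (n - 1)
    W /= m
    gm = chain_means.mean(axis=0)
    d = chain_means - gm
    B_over_n = d.T @ d / (m - 1)
    # eigenvalues of W^{-1} B/n via a solve; symmetrize for stability
    lam = np.linalg.eigvals(np.linalg.solve(W + 1e-12 * np.eye(p), B_over_n))
    lam1 = float(np.max(lam.real))
    return float(np.sqrt((n - 1) / n + (m + 1) / m * lam1))


def _spectral0(x: np.ndarray, max_order: int = 10) -> float:
    """Spectral density of a chain at frequency zero via an AR fit.

    Yule–Walker AR(p) with the order chosen by AIC; s(0) =
    sigma^2 / (1 - sum(phi))^2.  Returns 0 for a constant chain.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    c0 = float(xc @ xc) / n
    if c0 == 0.0:
        return 0.0
    max_order = int(min(max_order, n // 10))
    acov = np.array([float(xc[: n - k] @ xc[k:]) / n for k in range(max_order + 1)])
    best = (n * np.log(c0), c0)  # AIC, s(0) for order 0
    for p in range(1, max_order + 1):
        R = np.array([[acov[abs(i - j)] for j in range(p)] for i in range(p)])
        try:
            phi = np.linalg.solve(R, acov[1 : p + 1])
        except np.linalg.LinAlgError:
            continue
        sigma2 = acov[0] - phi @ acov[1 : p + 1]
        if sigma2 <= 0:
            continue
        aic = n * np.log(sigma2) + 2 * p
        denom = (1.0 - phi.sum()) ** 2
        if denom <= 1e-12:
            continue
        if aic < best[0]:
            best = (aic, sigma2 / denom)
    return max(best[1], 0.0)


def halfwidth_test(chain, alpha: float = 0.05, eps: float = 0.1) -> bool:
    """Heidelberger–Welch stationarity + half-width test for one chain.

    Stationarity: a Cramér–von Mises statistic on the standardized
    cumulative-sum bridge, applied to the full chain and then with the
    first 10%, ..., 50% discarded until a portion passes.  Half-width: on
    the passing portion, the (1-alpha) normal CI half-width of the mean,
    using the spectral variance estimate, must be below ``eps * |mean|``.
    A constant chain passes trivially.
    """
    x = np.asarray(chain, dtype=float)
    n0 = len(x)
    if n0 < 100:
        raise ValueError("half-width test requires a chain of length >= 100")
    if np.ptp(x) == 0.0:
        return True
    crit = _CVM_CRIT.get(round(alpha, 3), 0.461)

    kept = None
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        y = x[int(frac * n0):]
        n = len(y)
        s0 = _spectral0(y)
        if s0 <= 0:
            kept = y
            break
        mu = y.mean()
        csum = np.cumsum(y - mu)
        bridge = csum / np.sqrt(n * s0)
        cvm = float(np.sum(bridge**2) / n)
        if cvm < crit:
            kept = y
            break
    if kept is None:
        return False

    s0 = _spectral0(kept)
    if s0 == 0.0:
        return True
    from scipy.stats import norm as _norm

    half = _norm.ppf(1.0 - alpha / 2.0) * np.sqrt(s0 / len(kept))
    mean = kept.mean()
    if mean == 0.0:
        return False
    return bool(half / abs(mean) < eps)
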