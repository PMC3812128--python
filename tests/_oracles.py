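"""Independent brute-force oracles used by the test suite.

The state-space oracle never touches the package's Kalman recursions: it
builds the exact joint Gaussian distribution of the stacked latent states
over all time points and conditions on the observed yields in a single
multivariate-normal conditioning step.  Feasible only for short series
(d·M ≲ 30), which is exactly what makes it an oracle.
"""

from __future__ import annotations

import numpy as np

from yieldtrends.state_space import DlmSpec


def _solve_ld(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gaussian elimination with partial pivoting in extended precision.

    LAPACK only runs in double, where the near-diffuse prior (1e7 on the
    covariance diagonal) costs ~9 digits through the conditioning step;
    longdouble keeps the oracle trustworthy at 1e-8 absolute.
    """
    a = np.array(a, dtype=np.longdouble)
    b = np.array(b, dtype=np.longdouble)
    n = a.shape[0]
    vec = b.ndim == 1
    if vec:
        b = b[:, None]
    for col in range(n):
        piv = col + int(np.argmax(np.abs(a[col:, col])))
        if piv != col:
            a[[col, piv]] = a[[piv, col]]
            b[[col, piv]] = b[[piv, col]]
        factors = a[col + 1:, col] / a[col, col]
        a[col + 1:] -= factors[:, None] * a[col]
        b[col + 1:] -= factors[:, None] * b[col]
    x = np.zeros_like(b)
    for row in range(n - 1, -1, -1):
        x[row] = (b[row] - a[row, row + 1:] @ x[row + 1:]) / a[row, row]
    return x[:, 0] if vec else x


def _logdet_ld(a: np.ndarray) -> float:
    """log|A| of a positive-definite matrix via longdouble elimination."""
    a = np.array(a, dtype=np.longdouble)
    n = a.shape[0]
    logdet = np.longdouble(0.0)
    for col in range(n):
        piv = col + int(np.argmax(np.abs(a[col:, col])))
        if piv != col:
            a[[col, piv]] = a[[piv, col]]  # symmetric PD: pivot sign flips cancel in |det|
        logdet += np.log(np.abs(a[col, col]))
        factors = a[col + 1:, col] / a[col, col]
        a[col + 1:] -= factors[:, None] * a[col]
    return float(logdet)


def _system_matrices(spec: DlmSpec):
    d = spec.dim
    F = np.eye(d)
    if d == 2:
        F[0, 1] = 1.0
    Q = np.zeros((d, d))
    Q[0, 0] = spec.var_level
    if d == 2:
        Q[1, 1] = spec.var_slope
    return F, Q


def joint_state_moments(spec: DlmSpec, m: int):
    """Mean and covariance of the stacked states (x_1, ..., x_m).

    x_t = F x_{t-1} + w_t with x_0 ~ N(init_mean·1, init_var·I).
    """
    d = spec.dim
    F, Q = _system_matrices(spec)
    F = F.astype(np.longdouble)
    Q = Q.astype(np.longdouble)
    powers = [np.linalg.matrix_power(F, j) for j in range(m + 1)]
    mu = np.concatenate(
        [powers[t] @ np.full(d, spec.init_mean, dtype=np.longdouble) for t in range(1, m + 1)]
    )
    C0 = np.eye(d, dtype=np.longdouble) * spec.init_var
    cov = np.zeros((d * m, d * m), dtype=np.longdouble)
    for s in range(1, m + 1):
        for t in range(1, m + 1):
            block = powers[s] @ C0 @ powers[t].T
            for j in range(1, min(s, t) + 1):
                block += powers[s - j] @ Q @ powers[t - j].T
            cov[(s - 1) * d:s * d, (t - 1) * d:t * d] = block
    return mu, cov


def conditional_state_moments(spec: DlmSpec, y: np.ndarray, upto: int | None = None):
    """Posterior mean/cov of all states given the observed yields.

    ``y`` may contain NaN (missing years).  ``upto`` restricts conditioning
    to observations at times ≤ upto (1-based), giving filtered instead of
    smoothed moments.  Returns (mean (m, d), cov (m, d, m, d)).
    """
    y = np.asarray(y, dtype=float)
    m = y.size
    d = spec.dim
    mu, cov = joint_state_moments(spec, m)
    limit = m if upto is None else upto
    obs_idx = [t for t in range(limit) if np.isfinite(y[t])]
    if obs_idx:
        sel = np.zeros((len(obs_idx), d * m), dtype=np.longdouble)
        for r, t in enumerate(obs_idx):
            sel[r, t * d] = 1.0  # observation loads on the level component
        syy = sel @ cov @ sel.T + np.eye(len(obs_idx), dtype=np.longdouble) * spec.var_obs
        sxy = cov @ sel.T
        resid = np.asarray(y, dtype=np.longdouble)[obs_idx] - sel @ mu
        mean = mu + sxy @ _solve_ld(syy, resid)
        post = cov - sxy @ _solve_ld(syy, sxy.T)
    else:
        mean, post = mu, cov
    return (mean.astype(float).reshape(m, d),
            post.astype(float).reshape(m, d, m, d))


def oracle_filtered(spec: DlmSpec, y: np.ndarray):
    """Filtered moments at every time: condition only on y_1..y_t."""
    m = np.asarray(y).size
    d = spec.dim
    means = np.empty((m, d))
    covs = np.empty((m, d, d))
    for t in range(1, m + 1):
        mean, post = conditional_state_moments(spec, y, upto=t)
        means[t - 1] = mean[t - 1]
        covs[t - 1] = post[t - 1, :, t - 1, :]
    return means, covs


def oracle_smoothed(spec: DlmSpec, y: np.ndarray):
    """Smoothed moments: condition every state on the full series."""
    mean, post = conditional_state_moments(spec, y)
    m = mean.shape[0]
    covs = np.array([post[t, :, t, :] for t in range(m)])
    return mean, covs


def oracle_conditional_loglik(spec: DlmSpec, y: np.ndarray) -> float:
    """Log density of the last (n_obs − d) observations given the first d.

    Equals the diffuse-corrected prediction-error-decomposition likelihood:
    log p(y_{d+1:M} | y_{1:d}) = log p(y_{1:M}) − log p(y_{1:d}).
    """
    y = np.asarray(y, dtype=float)
    m = y.size
    d = spec.dim
    mu, cov = joint_state_moments(spec, m)
    obs_idx = [t for t in range(m) if np.isfinite(y[t])]
    sel = np.zeros((len(obs_idx), spec.dim * m), dtype=np.longdouble)
    for r, t in enumerate(obs_idx):
        sel[r, t * spec.dim] = 1.0
    syy = sel @ cov @ sel.T + np.eye(len(obs_idx), dtype=np.longdouble) * spec.var_obs
    my = sel @ mu
    yo = np.asarray(y, dtype=np.longdouble)[obs_idx]

    def logpdf(values, mean, sigma):
        n = values.size
        diff = values - mean
        return float(
            -0.5 * (n * np.log(2 * np.pi) + _logdet_ld(sigma) + diff @ _solve_ld(sigma, diff))
        )

    full = logpdf(yo, my, syy)
    head = logpdf(yo[:d], my[:d], syy[:d, :d])
    return float(full - head)


def plateau_grid_rss(t: np.ndarray, y: np.ndarray, breaks: np.ndarray):
    """Profiled RSS of the broken-line model over a dense break grid.

    At each candidate break the conditionally linear parameters are solved
    exactly by OLS on the basis (1, min(T − T*, 0)).
    """
    out = []
    for tb in breaks:
        x = np.minimum(t - tb, 0.0)
        X = np.column_stack([np.ones_like(x), x])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        out.append((float(r @ r), float(coef[0]), float(coef[1]), float(tb)))
    return out
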