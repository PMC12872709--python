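"""Independent reference implementations used only to check the package.

Everything here is deliberately written from the mathematical definition
(dense matrices, O(m^2) loops, fine-grid quadrature) and shares no code
with the implementation under test.
"""

import numpy as np
import pandas as pd


def dense_reml_negloglik(log_sd, y, X, components, residual_groups):
    """-2 restricted log-likelihood, building V entry by entry.

    V = sum_k sd_k^2 Z_k Z_k' + diag(sd_group^2), then the textbook REML
    expression log|V| + log|X'V^-1 X| + r'V^-1 r + (n-p) log 2pi with r
    the GLS residual.
    """
    log_sd = np.asarray(log_sd, dtype=float)
    K = len(components)
    n, p = X.shape
    V = np.zeros((n, n))
    for k, (_, Z) in enumerate(components):
        V += np.exp(log_sd[k]) ** 2 * (Z @ Z.T)
    codes = pd.factorize(pd.Series(residual_groups), sort=True)[0]
    V += np.diag(np.exp(log_sd[K:])[codes] ** 2)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    return ldV + ldX + float(r @ Vi @ r) + (n - p) * np.log(2.0 * np.pi)


def bh_stepup_bruteforce(p):
    """BH q-values straight from the step-up definition, O(m^2):
    q_i = min over j with p_j >= p_i of p_j * m / rank(p_j), capped at 1,
    where rank(p_j) counts values <= p_j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    q = np.empty(m)
    for i in range(m):
        candidates = [pj * m / np.sum(p <= pj) for pj in p if pj >= p[i]]
        q[i] = min(1.0, min(candidates))
    return q


def anova_oneway_reml(y, groups):
    """Closed-form REML for the balanced one-way random-intercept model:
    sigma_e^2 = MSE, sigma_b^2 = (MSB - MSE) / n_per_group."""
    y = np.asarray(y, dtype=float)
    codes = pd.factorize(pd.Series(groups), sort=True)[0]
    k = codes.max() + 1
    n_per = np.bincount(codes)
    assert len(set(n_per)) == 1, "oracle requires a balanced design"
    n = n_per[0]
    means = np.array([y[codes == g].mean() for g in range(k)])
    mse = sum(((y[codes == g] - means[g]) ** 2).sum() for g in range(k)) / (k * (n - 1))
    msb = n * ((means - means.mean()) ** 2).sum() / (k - 1)
    return {"sigma_e2": mse, "sigma_b2": (msb - mse) / n}


def curve_crossing_oracle(curve, level, bracket):
    """Root of curve(t) = level on a bracket, by scipy's brentq."""
    from scipy.optimize import brentq
    return brentq(lambda t: curve(t) - level, *bracket, xtol=1e-10)


def curve_argmax_oracle(curve, lo=1.0, hi=365.0):
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(lambda t: -curve(t), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def fine_quadrature(curve, a, b, per_day=10):
    """Trapezoid of |curve| on a grid ``per_day`` times finer than daily."""
    t = np.linspace(a, b, max(int((b - a) * per_day), 2) + 1)
    return float(np.trapezoid(np.abs(curve(t)), t))


def exact_corr_pair(rng, n, r):
    """Two length-n series whose sample Pearson correlation is exactly r."""
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    e = e - e.mean()
    e = e - x * (x @ e) / (x @ x)       # orthogonalize against x
    e = e / e.std(ddof=1)
    y = r * x + np.sqrt(1.0 - r ** 2) * e
    return x, y


def gompertz_recursion(alpha, theta, x0, n_steps, beta=0.0, cov=None):
    """Deterministic forward iteration of the Gompertz recursion."""
    x = [float(x0)]
    for t in range(1, n_steps):
        forcing = beta * cov[t - 1] if cov is not None else 0.0
        x.append(alpha + theta * x[-1] + forcing)
    return np.array(x)
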