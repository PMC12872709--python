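"""Hierarchical discrete Gompertz population-growth model.

The model for log population density x of one species is

    x_{t,i} = alpha + stratum_i + year_t + theta_i * x_{t-1,i}
              + beta_1 * covariate_{t-1,i} [+ beta_lat * covariate_{t-1,i} * lat_i]
              + eps_{t,i}

    stratum_i ~ N(0, sigma_stratum^2)        (crossed random intercepts)
    year_t    ~ N(0, sigma_year^2)
    theta_i   ~ N(theta, sigma_theta^2)      (random density-dependence slope)
    eps_{t,i} ~ N(0, sigma_i^2)              (residual SD differs by stratum)

with latitude coded as lat_i - min(lat_i), so the covariate main effect
is the effect at the southernmost stratum and a positive interaction
means the effect grows with latitude.  Variance parameters are estimated
by restricted maximum likelihood (REML) on the log-SD scale; fixed
effects are recovered by GLS at the optimum and tested with z-based Wald
statistics.

The REML engine (:class:`MixedREML`) is generic: any set of scalar-variance
random-effect blocks plus grouped heteroscedastic residuals.  It evaluates
the restricted likelihood through a low-rank (Woodbury) factorization of
the marginal covariance V = R + Z D Z', with an analytic gradient, so a
fit costs O(n q^2) per evaluation instead of O(n^3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize
from scipy.stats import norm

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))

#: fitted SDs below this are reported as exact zeros (boundary estimates)
BOUNDARY_SD = 1e-4


# ---------------------------------------------------------------------------
# generic REML engine
# ---------------------------------------------------------------------------

@dataclass
class MixedREMLFit:
    """Estimates from one restricted-likelihood optimization."""

    params: np.ndarray            # fixed effects (GLS at the optimum)
    cov_params: np.ndarray        # (X' V^-1 X)^-1
    exog_names: list[str]
    sd_components: dict[str, float]
    sd_resid: pd.Series           # per residual group
    boundary: dict[str, bool]
    llf: float                    # restricted log-likelihood
    converged: bool
    n_obs: int
    message: str = ""
    log_sd: np.ndarray | None = None


class MixedREML:
    """REML for a Gaussian mixed model with scalar-variance random blocks.

    Parameters
    ----------
    y, X : arrays
        Response (n,) and fixed-effect design (n, p).
    components : sequence of (name, Z)
        Random-effect blocks; each Z is (n, q_k) and its q_k columns share
        one variance.
    residual_groups : array-like
        Length-n labels; each group gets its own residual variance.
    """

    def __init__(self, y, X, components, residual_groups, exog_names=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(self.p)])
        self.comp_names = [name for name, _ in components]
        zs = [np.asarray(Z, dtype=float) for _, Z in components]
        self.q_k = [Z.shape[1] for Z in zs]
        self.Z = np.hstack(zs) if zs else np.empty((self.n, 0))
        self.q = self.Z.shape[1]
        self.comp_index = np.repeat(np.arange(len(zs)), self.q_k)

        groups = pd.Series(np.asarray(residual_groups))
        codes, labels = pd.factorize(groups, sort=True)
        self.gcodes = codes
        self.group_labels = list(labels)
        self.m = len(labels)
        self.n_g = np.bincount(codes, minlength=self.m).astype(float)

        # per-group Gram matrices of M = [Z X y]; the weighted sum over
        # groups gives every V^-1-free cross-product the likelihood needs
        M = np.hstack([self.Z, self.X, self.y[:, None]])
        dim = M.shape[1]
        self._C = np.zeros((self.m, dim, dim))
        for g in range(self.m):
            Mg = M[codes == g]
            self._C[g] = Mg.T @ Mg

    @property
    def n_params(self) -> int:
        return len(self.comp_names) + self.m

    # -- likelihood ---------------------------------------------------------

    def _core(self, gamma, want_grad):
        K = len(self.comp_names)
        q, p, n = self.q, self.p, self.n
        sd_c = np.exp(gamma[:K])
        sd_r = np.exp(gamma[K:])
        rinv = 1.0 / sd_r ** 2
        A = np.tensordot(rinv, self._C, axes=1)
        Azz, Azx, Azy = A[:q, :q], A[:q, q:q + p], A[:q, -1]
        Axx, Axy, Ayy = A[q:q + p, q:q + p], A[q:q + p, -1], A[-1, -1]

        d = sd_c[self.comp_index] ** 2 if q else np.empty(0)
        sq = np.sqrt(d)
        W = np.eye(q) + sq[:, None] * Azz * sq[None, :]
        Lw = np.linalg.cholesky(W)
        Uzx = solve_triangular(Lw, sq[:, None] * Azx, lower=True) if q else Azx
        Uzy = (solve_triangular(Lw, (sq * Azy)[:, None], lower=True).ravel()
               if q else Azy)
        XtViX = Axx - (Uzx.T @ Uzx if q else 0.0)
        XtViy = Axy - (Uzx.T @ Uzy if q else 0.0)
        ytViy = Ayy - (Uzy @ Uzy if q else 0.0)

        Lx = np.linalg.cholesky(XtViX)
        beta = solve_triangular(
            Lx.T, solve_triangular(Lx, XtViy, lower=True), lower=False)
        quad = ytViy - XtViy @ beta
        logdetV = 2.0 * np.sum(np.log(np.diag(Lw))) + np.sum(
            self.n_g * np.log(sd_r ** 2))
        logdetXtViX = 2.0 * np.sum(np.log(np.diag(Lx)))
        f = logdetV + logdetXtViX + quad + (n - p) * _LOG2PI

        out = {"f": f, "beta": beta, "XtViX": XtViX, "Lx": Lx}
        if not want_grad:
            return out

        rvec = self.y - self.X @ beta
        rinv_row = rinv[self.gcodes]
        # u = V^-1 r via Woodbury; P y = V^-1 r because X' V^-1 r = 0
        ZtRr = Azy - Azx @ beta
        if q:
            t1 = solve_triangular(Lw, sq * ZtRr, lower=True)
            t2 = solve_triangular(Lw.T, t1, lower=False)
            u = rinv_row * (rvec - self.Z @ (sq * t2))
        else:
            u = rinv_row * rvec

        grad = np.empty(self.n_params)
        if q:
            ZtVir = self.Z.T @ u
            Uzz = solve_triangular(Lw, sq[:, None] * Azz, lower=True)
            ZtViZ = Azz - Uzz.T @ Uzz
            ZtViX = Azx - Uzz.T @ Uzx
            Kx = solve_triangular(Lx, ZtViX.T, lower=True)
            diag_ZPZ = np.diag(ZtViZ) - np.sum(Kx ** 2, axis=0)
            for k in range(K):
                cols = self.comp_index == k
                grad[k] = 2.0 * sd_c[k] ** 2 * (
                    diag_ZPZ[cols].sum() - np.sum(ZtVir[cols] ** 2))

        # diag of P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1, per residual group
        if q:
            S = rinv_row[:, None] * (self.Z * sq[None, :])
            Tm = solve_triangular(Lw, S.T, lower=True)
            diagVinv = rinv_row - np.sum(Tm ** 2, axis=0)
            w2 = solve_triangular(
                Lw.T, solve_triangular(Lw, sq[:, None] * Azx, lower=True),
                lower=False)
            F = rinv_row[:, None] * self.X - S @ w2
        else:
            diagVinv = rinv_row
            F = rinv_row[:, None] * self.X
        G = solve_triangular(Lx, F.T, lower=True)
        diagP = diagVinv - np.sum(G ** 2, axis=0)
        trP_g = np.bincount(self.gcodes, weights=diagP, minlength=self.m)
        uu_g = np.bincount(self.gcodes, weights=u ** 2, minlength=self.m)
        grad[K:] = 2.0 * sd_r ** 2 * (trP_g - uu_g)
        out["grad"] = grad
        return out

    def negloglik(self, log_sd) -> float:
        """-2 x restricted log-likelihood at the given log-SD parameters.

        ``log_sd`` stacks the component log-SDs (in construction order)
        followed by the per-group residual log-SDs.
        """
        log_sd = np.asarray(log_sd, dtype=float)
        if log_sd.size != self.n_params:
            raise ValueError(
                f"expected {self.n_params} log-SD parameters, got {log_sd.size}")
        try:
            return float(self._core(log_sd, want_grad=False)["f"])
        except np.linalg.LinAlgError as exc:
            cond = np.linalg.cond(self.X)
            raise np.linalg.LinAlgError(
                f"marginal covariance numerically singular at log_sd={log_sd} "
                f"(design condition estimate {cond:.3e})") from exc

    def _obj_grad(self, gamma):
        try:
            out = self._core(gamma, want_grad=True)
            return out["f"], out["grad"]
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(gamma)

    def _starts(self):
        beta0, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        s0 = float(np.std(self.y - self.X @ beta0, ddof=min(self.p, self.n - 1)))
        s0 = max(s0, 1e-3)
        K = len(self.comp_names)
        starts = []
        for comp_scale, resid_scale in ((0.5, 1.0), (0.1, 1.0), (1.0, 0.5)):
            g = np.concatenate([
                np.full(K, np.log(comp_scale * s0)),
                np.full(self.m, np.log(resid_scale * s0)),
            ])
            starts.append(g)
        return starts

    def fit(self, n_starts: int = 3, gtol: float = 1e-8,
            bounds_log_sd: tuple[float, float] = (-10.0, 4.0)) -> MixedREMLFit:
        """Optimize the restricted likelihood from multiple starts."""
        lo, hi = bounds_log_sd
        bounds = [(lo, hi)] * self.n_params
        sols = []
        for g0 in self._starts()[:n_starts]:
            g0 = np.clip(g0, lo + 1e-6, hi - 1e-6)
            sols.append(minimize(
                self._obj_grad, g0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol}))
        # prefer the best successful start unless a failed one found a
        # meaningfully lower objective
        def _kkt_ok(sol):
            # projected gradient: at an active bound only the infeasible
            # descent direction counts against convergence
            pg = sol.jac.copy()
            pg[(sol.x <= lo + 1e-6) & (pg > 0)] = 0.0
            pg[(sol.x >= hi - 1e-6) & (pg < 0)] = 0.0
            return np.max(np.abs(pg)) < 1e-3

        best_all = min(sols, key=lambda s: s.fun)
        ok = [s for s in sols if s.success or _kkt_ok(s)]
        if ok and min(ok, key=lambda s: s.fun).fun <= best_all.fun + 1e-4:
            best = min(ok, key=lambda s: s.fun)
        else:
            best = best_all
        best_converged = best.success or _kkt_ok(best)
        out = self._core(best.x, want_grad=False)
        K = len(self.comp_names)
        sd_c = np.exp(best.x[:K])
        sd_r = np.exp(best.x[K:])
        boundary = {}
        sd_components = {}
        for k, name in enumerate(self.comp_names):
            at_floor = sd_c[k] < BOUNDARY_SD
            sd_components[name] = 0.0 if at_floor else float(sd_c[k])
            boundary[name] = bool(at_floor)
        Lx = out["Lx"]
        inv_half = solve_triangular(Lx, np.eye(self.p), lower=True)
        cov = inv_half.T @ inv_half
        return MixedREMLFit(
            params=out["beta"], cov_params=cov, exog_names=self.exog_names,
            sd_components=sd_components,
            sd_resid=pd.Series(sd_r, index=self.group_labels, name="sd_resid"),
            boundary=boundary, llf=-0.5 * float(out["f"]),
            converged=bool(best_converged), n_obs=self.n,
            message=str(best.message), log_sd=best.x.copy())


# ---------------------------------------------------------------------------
# Gompertz model specifics
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Which growing-season covariate enters the model, and how.

    A length-of-season model always carries SOS as an extra (nuisance)
    covariate, reflecting LOS = EOS - SOS.
    """

    covariate: str
    include_latitude_interaction: bool = True
    extra_covariates: tuple[str, ...] = ()

    def __post_init__(self):
        self.extra_covariates = tuple(self.extra_covariates)
        if self.covariate == "los" and "sos" not in self.extra_covariates:
            self.extra_covariates = self.extra_covariates + ("sos",)


@dataclass
class DesignBundle:
    """Response, fixed-effect design and random-effect structure for Eq-style
    Gompertz fitting; rows exist only where both x_t and x_{t-1} do."""

    y: np.ndarray
    X: np.ndarray
    exog_names: list[str]
    x_lag: np.ndarray
    stratum_codes: np.ndarray
    year_codes: np.ndarray
    stratum_labels: list
    year_labels: list
    lat_std: np.ndarray           # per-stratum, lat - min(lat)
    keys: pd.DataFrame            # stratum_id, year per row
    spec: ModelSpec | None = None

    @property
    def n_obs(self) -> int:
        return self.y.size


def log_density_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Attach x = log(abundance / area), dropping zero-abundance records.

    Zero (or negative) abundance has no log density; those stratum-years
    are removed from both response and lag positions, and the count is
    logged.
    """
    df = panel.copy()
    bad = df["abundance"] <= 0
    if bad.any():
        logger.info("dropping %d zero-abundance stratum-years", int(bad.sum()))
        df = df[~bad].copy()
    df["x"] = np.log(df["abundance"] / df["area"])
    return df


def _covariate_lookup(covariates, name):
    pan = covariates[name]
    data = getattr(pan, "data", pan)
    if hasattr(pan, "standardized") and not pan.standardized:
        logger.warning("covariate %r is not standardized", name)
    return {(r.stratum_id, r.year): r.value for r in data.itertuples()}


def build_design(panel: pd.DataFrame, spec: ModelSpec,
                 covariates: Mapping[str, object]) -> DesignBundle:
    """Assemble the lag-1 design for one species and one covariate choice.

    ``panel`` needs columns stratum_id, year, x, latitude.  Covariates
    enter with lag 1; a row for (i, t) exists only when x_{t,i}, x_{t-1,i}
    and every needed covariate_{t-1,i} are available.
    """
    needed = [spec.covariate, *spec.extra_covariates]
    lookups = {name: _covariate_lookup(covariates, name) for name in needed}

    panel = panel.dropna(subset=["x"])
    lat_by_stratum = panel.groupby("stratum_id")["latitude"].first()
    lat0 = lat_by_stratum.min()
    x_map = {(r.stratum_id, r.year): r.x for r in panel.itertuples()}

    missing_cov = []
    rows = []
    for r in panel.itertuples():
        prev = (r.stratum_id, r.year - 1)
        if prev not in x_map:
            continue
        vals = {}
        ok = True
        for name in needed:
            if prev not in lookups[name]:
                missing_cov.append((name,) + prev)
                ok = False
            else:
                vals[name] = lookups[name][prev]
        if ok:
            rows.append((r.stratum_id, r.year, r.x, x_map[prev], vals))
    if missing_cov:
        raise ValueError(
            f"covariate values missing for lagged stratum-years: "
            f"{missing_cov[:10]}{'...' if len(missing_cov) > 10 else ''}")
    if not rows:
        raise ValueError("no usable response rows after lag construction")

    keys = pd.DataFrame({"stratum_id": [r[0] for r in rows],
                         "year": [r[1] for r in rows]})
    y = np.array([r[2] for r in rows])
    x_lag = np.array([r[3] for r in rows])
    scodes, slabels = pd.factorize(keys["stratum_id"], sort=True)
    ycodes, ylabels = pd.factorize(keys["year"], sort=True)
    lat_std = (lat_by_stratum.reindex(slabels) - lat0).to_numpy()

    cols = [np.ones(len(rows)), x_lag,
            np.array([r[4][spec.covariate] for r in rows])]
    names = ["const", "x_lag", spec.covariate]
    if spec.include_latitude_interaction:
        cols.append(cols[2] * lat_std[scodes])
        names.append(f"{spec.covariate}:lat")
    for name in spec.extra_covariates:
        cols.append(np.array([r[4][name] for r in rows]))
        names.append(name)
    X = np.column_stack(cols)
    return DesignBundle(y=y, X=X, exog_names=names, x_lag=x_lag,
                        stratum_codes=scodes, year_codes=ycodes,
                        stratum_labels=list(slabels), year_labels=list(ylabels),
                        lat_std=lat_std, keys=keys, spec=spec)


def _onehot(codes, k):
    Z = np.zeros((codes.size, k))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


@dataclass
class WaldTest:
    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float


class GompertzModel:
    """Hierarchical Gompertz growth model for one species panel.

    Build from a :class:`DesignBundle` (or via :meth:`from_panel`), call
    :meth:`fit` for a :class:`GompertzResults`.
    """

    def __init__(self, design: DesignBundle):
        self.design = design
        m = len(design.stratum_labels)
        T = len(design.year_labels)
        Zs = _onehot(design.stratum_codes, m)
        Zy = _onehot(design.year_codes, T)
        Zt = Zs * design.x_lag[:, None]
        self._engine = MixedREML(
            design.y, design.X,
            components=[("stratum", Zs), ("year", Zy), ("theta", Zt)],
            residual_groups=np.asarray(design.stratum_labels)[design.stratum_codes],
            exog_names=design.exog_names)

    @classmethod
    def from_panel(cls, panel: pd.DataFrame, covariates: Mapping[str, object],
                   spec: ModelSpec | str) -> "GompertzModel":
        if isinstance(spec, str):
            spec = ModelSpec(covariate=spec)
        return cls(build_design(panel, spec, covariates))

    def reml_negloglik(self, log_sd) -> float:
        """-2 x restricted log-likelihood; parameters are
        [log sd_stratum, log sd_year, log sd_theta, log sd_1..sd_m]."""
        return self._engine.negloglik(log_sd)

    def fit(self, n_starts: int = 3, gtol: float = 1e-8) -> "GompertzResults":
        fit = self._engine.fit(n_starts=n_starts, gtol=gtol)
        return GompertzResults(self, fit)


class GompertzResults:
    """Estimates, uncertainties and Wald inference for a fitted model."""

    def __init__(self, model: GompertzModel, fit: MixedREMLFit):
        self.model = model
        self._fit = fit
        self.params = pd.Series(fit.params, index=fit.exog_names, name="estimate")
        self.bse = pd.Series(np.sqrt(np.diag(fit.cov_params)),
                             index=fit.exog_names, name="se")
        self.llf = fit.llf
        self.converged = fit.converged
        self.n_obs = fit.n_obs

    # -- statsmodels-flavoured accessors ------------------------------------

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self._fit.cov_params, index=self.params.index,
                            columns=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * norm.sf(np.abs(self.zvalues)),
                         index=self.params.index, name="p")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        zq = norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame({"lower": self.params - zq * self.bse,
                             "upper": self.params + zq * self.bse})

    @property
    def alpha_hat(self) -> float:
        return float(self.params["const"])

    @property
    def theta_hat(self) -> float:
        return float(self.params["x_lag"])

    @property
    def varcomps(self) -> dict:
        f = self._fit
        return {"sigma_stratum": f.sd_components.get("stratum"),
                "sigma_year": f.sd_components.get("year"),
                "sigma_theta": f.sd_components.get("theta"),
                "sigma_resid": f.sd_resid,
                "boundary": dict(f.boundary)}

    def wald_test(self, term: str, alpha: float = 0.05) -> WaldTest:
        """z-based Wald test for one fixed-effect term."""
        if not self.converged:
            raise ValueError("refusing inference on a non-converged fit")
        if term not in self.params.index:
            raise KeyError(f"term {term!r} not in design "
                           f"(have {list(self.params.index)})")
        est, se = float(self.params[term]), float(self.bse[term])
        z = est / se
        zq = norm.ppf(1.0 - alpha / 2.0)
        return WaldTest(term=term, estimate=est, se=se,
                        ci_low=est - zq * se, ci_high=est + zq * se,
                        z=z, p=float(2.0 * norm.sf(abs(z))))

    def to_dict(self) -> dict:
        vc = self.varcomps
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "sigma_stratum": vc["sigma_stratum"],
            "sigma_year": vc["sigma_year"],
            "sigma_theta": vc["sigma_theta"],
            "sigma_resid": vc["sigma_resid"].to_dict(),
            "boundary": vc["boundary"],
            "llf": self.llf,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Hierarchical Gompertz growth model (REML)",
            "=" * 64,
            f"Observations: {self.n_obs}   Strata: {len(self.model.design.stratum_labels)}"
            f"   Years: {len(self.model.design.year_labels)}",
            f"Restricted log-likelihood: {self.llf:.4f}   "
            f"Converged: {self.converged}",
            "-" * 64,
            f"{'term':<16}{'coef':>10}{'se':>10}{'z':>8}{'P>|z|':>9}"
            f"{'[0.025':>10}{'0.975]':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<16}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.zvalues[name]:>8.2f}{self.pvalues[name]:>9.3f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}")
        vc = self.varcomps
        lines += ["-" * 64,
                  f"sigma_stratum {vc['sigma_stratum']:.4f}   "
                  f"sigma_year {vc['sigma_year']:.4f}   "
                  f"sigma_theta {vc['sigma_theta']:.4f}",
                  "sigma_resid by stratum: "
                  + ", ".join(f"{k}={v:.4f}" for k, v in vc["sigma_resid"].items())]
        return "\n".join(lines)


# -- functional wrappers mirroring the pipeline surface ----------------------

def reml_negloglik(log_sd, design: DesignBundle) -> float:
    """-2 x restricted log-likelihood of the Gompertz design at ``log_sd``."""
    return GompertzModel(design).reml_negloglik(log_sd)


def fit_model(design: DesignBundle, n_starts: int = 3,
              gtol: float = 1e-8) -> GompertzResults:
    return GompertzModel(design).fit(n_starts=n_starts, gtol=gtol)


def wald_inference(results: GompertzResults, term: str) -> WaldTest:
    return results.wald_test(term)
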