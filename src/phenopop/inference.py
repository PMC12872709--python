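"""Species x covariate test battery with FDR control.

For every species and every growing-season covariate (SOS, DOP, LOS,
productivity) one Gompertz model is fitted with the covariate main
effect and its interaction with latitude; LOS models additionally carry
SOS as a nuisance covariate.  Each model contributes two hypothesis
tests (main + interaction) to a single Benjamini-Hochberg pool — with 8
species and 4 covariates that pool holds 64 tests.  A covariate effect
is called supported when any of its terms has BH q < 0.05, and it is
interpreted relative to latitude when the interaction's unadjusted
p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gompertz import GompertzModel, ModelSpec

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sos", "dop", "los", "productivity")


def filter_strata(panel: pd.DataFrame, min_recorded: int = 5) -> pd.DataFrame:
    """Drop species-strata where the species was recorded in too few years.

    A stratum is retained for a species only if abundance > 0 in strictly
    more than ``min_recorded`` years of its series — such sparse strata
    are likely peripheral to the species' core breeding range.  Works on
    a single-species panel or a multi-species panel with a ``species``
    column.
    """
    keys = ["species", "stratum_id"] if "species" in panel.columns else ["stratum_id"]
    recorded = (panel.assign(rec=panel["abundance"] > 0)
                .groupby(keys)["rec"].sum())
    keep = recorded[recorded > min_recorded].index
    before = panel.groupby(keys).ngroups
    if len(keys) == 1:
        out = panel[panel["stratum_id"].isin(keep)]
    else:
        idx = pd.MultiIndex.from_frame(panel[keys])
        out = panel[idx.isin(keep)]
    logger.info("stratum filter: %d of %d species-strata retained "
                "(recorded in > %d years)", len(keep), before, min_recorded)
    if out.empty:
        logger.warning("stratum filter removed every record")
    return out.reset_index(drop=True)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up q-values: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.

    Input order is preserved in the output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class BatteryConfig:
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    q_threshold: float = 0.05
    interaction_gate: float = 0.05
    min_recorded: int = 5
    n_starts: int = 3


def run_battery(panels: dict[str, pd.DataFrame],
                covariate_panels: dict[str, object],
                config: BatteryConfig | None = None,
                apply_filter: bool = True):
    """Fit the full species x covariate battery and BH-adjust its p-values.

    Parameters
    ----------
    panels : mapping species -> stratum-year panel (with x, latitude)
    covariate_panels : mapping covariate name -> standardized panel

    Returns
    -------
    results : DataFrame, one row per hypothesis test (main and
        latitude-interaction terms only; the SOS nuisance term inside LOS
        models is a control, not a hypothesis)
    metadata : dict with the BH pool size actually used and an audit of
        non-converged fits
    """
    config = config or BatteryConfig()
    rows, audit = [], []
    for species, panel in panels.items():
        if apply_filter:
            panel = filter_strata(panel, min_recorded=config.min_recorded)
        for cov in config.covariates:
            spec = ModelSpec(covariate=cov, include_latitude_interaction=True)
            try:
                res = GompertzModel.from_panel(panel, covariate_panels, spec).fit(
                    n_starts=config.n_starts)
            except (ValueError, np.linalg.LinAlgError) as exc:
                audit.append({"species": species, "covariate": cov,
                              "reason": str(exc)})
                continue
            if not res.converged:
                audit.append({"species": species, "covariate": cov,
                              "reason": "non-converged fit"})
                continue
            for term_kind, term in (("main", cov), ("latitude-interaction",
                                                    f"{cov}:lat")):
                w = res.wald_test(term)
                rows.append({"species": species, "covariate": cov,
                             "term": term_kind, "estimate": w.estimate,
                             "se": w.se, "ci_low": w.ci_low,
                             "ci_high": w.ci_high, "p_unadjusted": w.p})
    results = pd.DataFrame(rows)
    if len(results):
        results["q_bh"] = benjamini_hochberg(results["p_unadjusted"].to_numpy())
        results["supported"] = results["q_bh"] < config.q_threshold
        inter = results["term"] == "latitude-interaction"
        results["interaction_interpreted"] = inter & (
            results["p_unadjusted"] < config.interaction_gate)
    metadata = {"n_tests": int(len(results)),
                "q_threshold": config.q_threshold,
                "interaction_gate": config.interaction_gate,
                "n_excluded_fits": len(audit),
                "excluded_fits": audit}
    if audit:
        logger.warning("%d fits excluded from the BH pool", len(audit))
    return results, metadata


def decision_table(results: pd.DataFrame,
                   q_threshold: float = 0.05,
                   interaction_gate: float = 0.05) -> pd.DataFrame:
    """Per species x covariate outcome from the battery results.

    An effect is supported when any associated term has q below the
    threshold; it is reported relative to latitude when the interaction's
    unadjusted p is below the gate; otherwise the main term is read at
    the southernmost (baseline) latitude.
    """
    rows = []
    for (species, cov), grp in results.groupby(["species", "covariate"],
                                               sort=True):
        main = grp[grp["term"] == "main"]
        inter = grp[grp["term"] == "latitude-interaction"]
        if main.empty or inter.empty:
            rows.append({"species": species, "covariate": cov,
                         "supported": False, "latitude_dependent": False,
                         "conclusion": "not evaluable"})
            continue
        main, inter = main.iloc[0], inter.iloc[0]
        supported = bool((grp["q_bh"] < q_threshold).any())
        lat_dep = bool(inter["p_unadjusted"] < interaction_gate)
        if not supported:
            concl = "no effect detected"
        elif lat_dep:
            direction = "increases" if inter["estimate"] > 0 else "decreases"
            concl = (f"effect varies with latitude ({direction} northward; "
                     f"baseline {'+' if main['estimate'] > 0 else '-'})")
        else:
            concl = ("positive effect at baseline latitude"
                     if main["estimate"] > 0
                     else "negative effect at baseline latitude")
        rows.append({"species": species, "covariate": cov,
                     "supported": supported, "latitude_dependent": lat_dep,
                     "main_estimate": float(main["estimate"]),
                     "main_q": float(main["q_bh"]),
                     "interaction_estimate": float(inter["estimate"]),
                     "interaction_p": float(inter["p_unadjusted"]),
                     "conclusion": concl})
    return pd.DataFrame(rows)
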