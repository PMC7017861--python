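"""Derived annual state distributions and covariate-response predictions.

From a fitted model, the distribution over the three states in year t is
propagated per site as pi_1 = phi0 and pi_{t+1} = pi_t Phi_t (each site using
its own covariates), then averaged over sites.  Standard errors come from the
delta method through the full coefficient covariance (central finite
differences of the derived series in the coefficients); a parametric
bootstrap over the coefficient sampling distribution is available as a
cross-check.  Confidence intervals for probabilities are normal on the logit
scale and back-transformed, so they always lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data_io import StudyData
from .fit_select import FitResult
from .likelihood import realize

_STATE_NAMES = ("p_dry", "p_wet_unoccupied", "p_breeding")


@dataclass
class DerivedSeries:
    """Per-year site-averaged state distribution with uncertainty."""

    years: np.ndarray                # (T,)
    estimates: np.ndarray            # (T, 3), rows sum to 1
    ses: np.ndarray                  # (T, 3)
    ci_low: np.ndarray               # (T, 3)
    ci_high: np.ndarray              # (T, 3)
    reliable_ses: bool = True

    @property
    def cvs(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.estimates > 0, self.ses / self.estimates, np.nan)

    def to_frame(self) -> pd.DataFrame:
        cols = {"year": self.years}
        for s, name in enumerate(_STATE_NAMES):
            cols[name] = self.estimates[:, s]
            cols[f"{name}_se"] = self.ses[:, s]
            cols[f"{name}_lo"] = self.ci_low[:, s]
            cols[f"{name}_hi"] = self.ci_high[:, s]
        return pd.DataFrame(cols)


def _logit_ci(est, se, level=1.959963984540054):
    """Normal CI on the logit scale, back-transformed; degenerate at 0/1."""
    est = np.clip(est, 1e-12, 1 - 1e-12)
    se_logit = se / (est * (1 - est))
    lo = expit(logit(est) - level * se_logit)
    hi = expit(logit(est) + level * se_logit)
    return lo, hi


def state_distribution_series(beta, design, representative: bool = False) -> np.ndarray:
    """(T, 3) site-averaged state distribution under coefficients ``beta``.

    With ``representative=True`` the recursion is run at the site-averaged
    transition probabilities (one representative site) instead of averaging
    the per-site series.
    """
    params = realize(beta, design)
    n, Tm1 = params.psi.shape[0], params.psi.shape[1]
    psi, r = params.psi, params.r
    if representative:
        psi, r = psi.mean(axis=0, keepdims=True), r.mean(axis=0, keepdims=True)
        n = 1
    pi = np.empty((n, Tm1 + 1, 3))
    pi[:, 0] = params.phi0[None, :]
    for t in range(Tm1):
        p, q = psi[:, t], r[:, t]
        # pi_{t+1}[j] = sum_m pi_t[m] * Phi_t[m, j]
        pi[:, t + 1, 0] = np.sum(pi[:, t] * (1 - p), axis=1)
        pi[:, t + 1, 1] = np.sum(pi[:, t] * p * (1 - q), axis=1)
        pi[:, t + 1, 2] = np.sum(pi[:, t] * p * q, axis=1)
    return pi.mean(axis=0)


def _series_jacobian(fit: FitResult, representative: bool, step: float = 1e-5):
    beta = fit.beta_hat
    k = beta.size
    base_shape = None
    jac = None
    for i in range(k):
        e = np.zeros(k)
        e[i] = step * max(1.0, abs(beta[i]))
        hi = state_distribution_series(beta + e, fit.design, representative)
        lo = state_distribution_series(beta - e, fit.design, representative)
        d = (hi - lo) / (2 * e[i])
        if jac is None:
            base_shape = d.shape
            jac = np.empty((k,) + base_shape)
        jac[i] = d
    return jac.reshape(k, -1), base_shape


def annual_state_distribution(fit: FitResult, data: StudyData | None = None,
                              representative: bool = False) -> DerivedSeries:
    """Derived per-year distribution [Pr(m=0), Pr(m=1), Pr(m=2)] with SEs.

    ``data`` is only used for the year labels; the covariates are already
    baked into the fit's design tensors.
    """
    est = state_distribution_series(fit.beta_hat, fit.design, representative)
    jac, shape = _series_jacobian(fit, representative)
    var = np.einsum("kf,kl,lf->f", jac, fit.vcov, jac).reshape(shape)
    ses = np.sqrt(np.clip(var, 0, None))
    lo, hi = _logit_ci(est, ses)
    years = (data.years if data is not None
             else np.arange(1, est.shape[0] + 1))
    return DerivedSeries(years=np.asarray(years), estimates=est, ses=ses,
                         ci_low=lo, ci_high=hi,
                         reliable_ses=not fit.on_boundary)


def bootstrap_state_distribution(fit: FitResult, n_draws: int = 500,
                                 seed: int = 0, representative: bool = False):
    """Parametric-bootstrap SEs for the derived series (delta-method check)."""
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.beta_hat, fit.vcov, size=n_draws,
                                    method="svd")
    series = np.stack([state_distribution_series(b, fit.design, representative)
                       for b in draws])
    return series.std(axis=0, ddof=1)


def proportion_dry_series(fit: FitResult, data: StudyData | None = None,
                          representative: bool = False) -> pd.DataFrame:
    """Per-year derived probability that a wetland is dry (m = 0), with CIs."""
    s = annual_state_distribution(fit, data, representative)
    return pd.DataFrame({"year": s.years, "p_dry": s.estimates[:, 0],
                         "se": s.ses[:, 0], "lo": s.ci_low[:, 0],
                         "hi": s.ci_high[:, 0]})


def breeding_occupancy_series(fit: FitResult, data: StudyData | None = None,
                              representative: bool = False) -> pd.DataFrame:
    """Per-year unconditional breeding occupancy Pr(m = 2) with CIs and CVs."""
    s = annual_state_distribution(fit, data, representative)
    return pd.DataFrame({"year": s.years, "p_breeding": s.estimates[:, 2],
                         "se": s.ses[:, 2], "lo": s.ci_low[:, 2],
                         "hi": s.ci_high[:, 2], "cv": s.cvs[:, 2]})


def predict_transition_probability(fit: FitResult, component: str, state: int = 0,
                                   covariate_values: dict | None = None,
                                   year: int | None = None):
    """Real-scale prediction for psi^m, R^m or delta at given covariate values.

    ``covariate_values`` maps covariate tokens of the fitted component to raw
    (unstandardized) values; every covariate in the component must be given.
    ``year`` selects the year/interval intercept (1-based; required when the
    component has a year term).  Returns ``(probability, (ci_low, ci_high))``.
    The CI is normal on the logit scale, back-transformed.
    """
    comp_name = {"psi": "psi", "R": "r", "delta": "delta"}.get(component)
    if comp_name is None:
        raise ValueError(f"component must be psi, R or delta, got {component!r}")
    spec = getattr(fit.structure, comp_name)
    covariate_values = dict(covariate_values or {})

    if spec.year_term and year is None:
        raise ValueError("year required: component has a year term")

    def standardized_product(token: str) -> float:
        z = 1.0
        for f in token.split("*"):
            if f not in covariate_values:
                raise ValueError(f"missing covariate value for {f!r}")
            z *= float(fit.design.standardize_value(spec.component, f,
                                                    covariate_values[f]))
        return z

    # build the row of the design for this query by coefficient label
    wanted = {}
    if spec.component == "delta":
        wanted[f"delta:int[year{year}]" if spec.year_term else "delta:int"] = 1.0
        for token in spec.covariates:
            wanted[f"delta:{token}"] = standardized_product(token)
    else:
        group = next(g for g in spec.groups if state in g)
        gtag = "m" + "".join(str(s) for s in group)
        if spec.year_term:
            wanted[f"{spec.component}:int[{gtag},i{year}]"] = 1.0
        else:
            wanted[f"{spec.component}:int[{gtag}]"] = 1.0
        for token in spec.covariates:
            wanted[f"{spec.component}:{token}[{gtag}]"] = standardized_product(token)

    label_index = {lab: j for j, lab in enumerate(fit.design.labels)}
    x = np.zeros(fit.k)
    for lab, val in wanted.items():
        x[label_index[lab]] = val

    eta = float(x @ fit.beta_hat)
    var_eta = float(x @ fit.vcov @ x)
    se_eta = np.sqrt(max(var_eta, 0.0))
    p = float(expit(eta))
    lo = float(expit(eta - 1.959963984540054 * se_eta))
    hi = float(expit(eta + 1.959963984540054 * se_eta))
    return p, (lo, hi)
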