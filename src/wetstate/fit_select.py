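"""Maximum-likelihood fitting, AICc model selection and model averaging.

Fitting uses L-BFGS-B on the logit-scale coefficients with the analytic
gradient of the forward-algorithm log-likelihood, restarted from several
jittered initializations.  The coefficient covariance is the inverse of the
numerical Hessian (Jacobian of the analytic gradient).  Model selection uses
AICc with the small-sample correction 2K(K+1)/(n_eff − K − 1), where the
effective sample size defaults to the number of completed site visits
(site-years with at least one survey).  When the top-ranked model holds an
Akaike weight ≤ 0.90, inference is model averaged with unconditional
standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_fprime

from .data_io import StudyData
from .likelihood import DetectionCounts, loglik_and_grad
from .model_spec import (DesignMatrices, ModelStructure, build_design_matrices,
                         count_parameters, parse_model_structure)

BOUNDARY_LOGIT = 10.0
AVERAGING_WEIGHT_THRESHOLD = 0.90


@dataclass
class FitResult:
    """MLE of one model structure on one dataset."""

    structure: ModelStructure
    design: DesignMatrices
    beta_hat: np.ndarray
    deviance: float
    k: int
    aicc: float
    vcov: np.ndarray
    converged: bool
    n_eff: int
    boundary_flags: np.ndarray            # bool per coefficient, |logit| > 10
    n_starts_used: int = 1

    @property
    def name(self) -> str:
        return self.structure.name

    @property
    def se(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.vcov))

    @property
    def on_boundary(self) -> bool:
        return bool(self.boundary_flags.any())

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.design.labels,
                             "estimate": self.beta_hat, "se": self.se,
                             "boundary": self.boundary_flags})


def compute_aicc(deviance: float, k: int, n_eff: int) -> float:
    """AICc = deviance + 2K + 2K(K+1)/(n_eff − K − 1)."""
    if n_eff <= k + 1:
        raise ValueError(f"AICc correction undefined: n_eff={n_eff} <= K+1={k + 1}")
    return deviance + 2 * k + 2 * k * (k + 1) / (n_eff - k - 1)


def default_n_eff(data: StudyData) -> int:
    return data.n_site_visits


def fit_model(structure, data: StudyData, n_starts: int = 5, seed: int = 0,
              tol: float = 1e-8, n_eff: int | None = None,
              compute_vcov: bool = True, start: np.ndarray | None = None) -> FitResult:
    """Maximize the likelihood of ``structure`` on ``data``.

    ``structure`` may be a :class:`ModelStructure` or a canonical string.
    ``n_starts`` jittered initializations guard against local optima; the best
    optimum is retained.  Coefficients with |logit| > 10 are flagged as
    boundary estimates (their SEs are unreliable).
    """
    if isinstance(structure, str):
        structure = parse_model_structure(structure)
    design = build_design_matrices(structure, data)
    counts = DetectionCounts.from_obs(data.obs)
    k = design.n_params

    def objective(beta):
        ll, grad = loglik_and_grad(beta, design, counts)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(beta)
        return -ll, -grad

    rng = np.random.default_rng(seed)
    base = np.zeros(k) if start is None else np.asarray(start, dtype=float)
    best = None
    any_converged = False
    for s in range(max(1, n_starts)):
        x0 = base if s == 0 else base + rng.normal(0, 0.5, size=k)
        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": tol, "gtol": 1e-6,
                                "maxcor": 25})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        any_converged = any_converged or bool(res.success)

    beta_hat = best.x
    deviance = 2.0 * best.fun
    boundary = np.abs(beta_hat) > BOUNDARY_LOGIT
    n_eff = default_n_eff(data) if n_eff is None else int(n_eff)

    if compute_vcov:
        grad_fn = lambda b: loglik_and_grad(b, design, counts)[1]
        hess = -approx_fprime(beta_hat, grad_fn, centered=True)
        hess = 0.5 * (hess + hess.T)
        try:
            vcov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(hess)
        if np.any(np.diag(vcov) < 0):
            vcov = np.linalg.pinv(hess)
    else:
        vcov = np.full((k, k), np.nan)

    return FitResult(structure=structure, design=design, beta_hat=beta_hat,
                     deviance=float(deviance), k=k,
                     aicc=compute_aicc(float(deviance), k, n_eff),
                     vcov=vcov, converged=any_converged, n_eff=n_eff,
                     boundary_flags=boundary, n_starts_used=max(1, n_starts))


def akaike_weights(delta_aicc) -> np.ndarray:
    """Normalized exp(−ΔAICc/2) over a model set."""
    delta = np.asarray(delta_aicc, dtype=float)
    w = np.exp(-0.5 * (delta - delta.min()))
    return w / w.sum()


def round_weights_to_sum(weights, decimals: int = 2) -> np.ndarray:
    """Round a weight column so the printed values sum to 1 (largest remainder).

    This is the convention used in published model-selection tables: floor
    every weight at the printed precision, then distribute the remaining
    units to the largest remainders.
    """
    w = np.asarray(weights, dtype=float)
    scale = 10 ** decimals
    floors = np.floor(w * scale)
    short = int(round(scale - floors.sum()))
    remainders = w * scale - floors
    order = np.argsort(-remainders)
    out = floors.copy()
    for i in range(max(0, short)):
        out[order[i]] += 1
    return out / scale


@dataclass
class ModelSelectionTable:
    """AICc ranking of a model set, in the standard table layout."""

    frame: pd.DataFrame        # Model, AICc, dAICc, weight, K, Deviance

    @classmethod
    def from_fits(cls, fits) -> "ModelSelectionTable":
        n_effs = {f.n_eff for f in fits}
        if len(n_effs) != 1:
            raise ValueError(f"fits use different n_eff values: {sorted(n_effs)}")
        rows = pd.DataFrame({
            "Model": [f.name for f in fits],
            "AICc": [f.aicc for f in fits],
            "K": [f.k for f in fits],
            "Deviance": [f.deviance for f in fits],
        })
        rows = rows.sort_values(["AICc", "K", "Model"], kind="mergesort").reset_index(drop=True)
        rows["dAICc"] = rows["AICc"] - rows["AICc"].iloc[0]
        rows["weight"] = akaike_weights(rows["dAICc"].to_numpy())
        return cls(rows[["Model", "AICc", "dAICc", "weight", "K", "Deviance"]])

    @property
    def top_model(self) -> str:
        return self.frame["Model"].iloc[0]

    @property
    def top_weight(self) -> float:
        return float(self.frame["weight"].iloc[0])

    @property
    def averaging_triggered(self) -> bool:
        """True when no single model has substantial support (top w ≤ 0.90)."""
        return self.top_weight <= AVERAGING_WEIGHT_THRESHOLD

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["weight"] = round_weights_to_sum(out["weight"].to_numpy())
        out.to_csv(path, index=False, float_format="%.2f")


def rank_models(fits) -> ModelSelectionTable:
    """Rank fitted models by AICc (ties broken by smaller K, then name)."""
    return ModelSelectionTable.from_fits(list(fits))


def model_average(fits, target, include_nonconverged: bool = False):
    """Model-averaged real-scale estimate with its unconditional SE.

    ``target(fit) -> (estimate, variance)`` must be computable under every
    fit.  Non-converged fits are excluded (with renormalized weights) unless
    requested.  Returns ``(theta_bar, unconditional_se, used_fits)``.
    """
    fits = list(fits)
    used = [f for f in fits if f.converged or include_nonconverged]
    if not used:
        raise ValueError("no converged fits to average")
    aiccs = np.array([f.aicc for f in used])
    w = akaike_weights(aiccs - aiccs.min())
    ests, variances = zip(*(target(f) for f in used))
    ests = np.asarray(ests, dtype=float)
    variances = np.asarray(variances, dtype=float)
    theta_bar = float(np.sum(w * ests))
    se = float(math.sqrt(np.sum(w * (variances + (ests - theta_bar) ** 2))))
    return theta_bar, se, used


@dataclass
class StepwiseResult:
    stage_tables: dict = field(default_factory=dict)   # stage -> ModelSelectionTable
    stage_fits: dict = field(default_factory=dict)     # stage -> {name: FitResult}
    final_structure: ModelStructure | None = None

    @property
    def final_fit(self) -> FitResult:
        table = self.stage_tables["breeding"]
        return self.stage_fits["breeding"][table.top_model]


def _compose(psi: str, r: str, delta: str) -> str:
    return f"{psi} {r} {delta}"


def stepwise_workflow(data: StudyData, detection_candidates, wetland_candidates,
                      breeding_candidates, base_psi: str = "psi[m](t)",
                      base_r: str = "R[m](t)", **fit_options) -> StepwiseResult:
    """The multistep model-building workflow.

    Stage 1 selects the detection structure while wetland and breeding
    transitions are state- and year-specific; stage 2 selects the wetland
    (psi) structure holding the best detection model; stage 3 selects the
    breeding (R) structure holding the best detection and wetland models.
    Candidates are component strings, e.g. ``"delta(Vegave+t)"`` or
    ``"psi[1=2](t)"``.
    """
    for name, cands in (("detection", detection_candidates),
                        ("wetland", wetland_candidates),
                        ("breeding", breeding_candidates)):
        if not cands:
            raise ValueError(f"empty {name} candidate list")

    result = StepwiseResult()

    def run_stage(stage, structures):
        fits = {}
        for s in structures:
            fits[s] = fit_model(s, data, **fit_options)
        converged = [f for f in fits.values() if f.converged]
        if not converged:
            raise RuntimeError(f"no candidate converged in stage {stage!r}")
        table = rank_models(list(fits.values()))
        result.stage_tables[stage] = table
        result.stage_fits[stage] = {f.name: f for f in fits.values()}
        return table.top_model

    top = run_stage("detection", [_compose(base_psi, base_r, d)
                                  for d in detection_candidates])
    best_delta = parse_model_structure(top).delta.canonical()

    top = run_stage("wetland", [_compose(p, base_r, best_delta)
                                for p in wetland_candidates])
    best_psi = parse_model_structure(top).psi.canonical()

    top = run_stage("breeding", [_compose(best_psi, r, best_delta)
                                 for r in breeding_candidates])
    result.final_structure = parse_model_structure(top)
    return result
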