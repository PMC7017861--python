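"""Marginal likelihood of detection histories under the three-state HMM.

The latent state of a site in a year is m ∈ {0 dry, 1 wet without breeding,
2 wet with breeding}.  The initial distribution is
phi0 = [(1−psi), psi(1−R), psi·R]; the transition matrix row for prior state m
is [1−psi^m, psi^m(1−R^m), psi^m·R^m].  Detection: water is detected
perfectly, and each of the S replicate surveys at a wet, breeding site detects
breeding evidence independently with probability delta, so a year's
observation likelihood given the true state is

    state 0: 1 if every completed survey recorded 0, else 0
    state 1: 1 if every completed survey recorded 1, else 0
    state 2: 0 if any survey recorded 0, else delta^{#2s} (1−delta)^{#1s}

A year with no completed surveys contributes [1, 1, 1] (marginalized through;
the transition probabilities of unvisited sites are assumed to equal those of
visited ones).  The site likelihood is the usual forward recursion
alpha_1 = phi0 ∘ D_1, alpha_{t+1} = (alpha_t Phi_t) ∘ D_{t+1}, L = Σ alpha_T,
computed with per-step rescaling.  The gradient is analytic, via the
forward–backward decomposition dL/dPhi_t[i,j] = alpha_t[i] D_{t+1}[j]
beta_{t+1}[j], chained through the logit links.  A 3^T path-enumeration oracle
is provided for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.special import expit

from .data_io import MISSING, StudyData
from .model_spec import DesignMatrices

_PROB_EPS = 1e-12


def initial_state_vector(psi: float, r: float) -> np.ndarray:
    """Initial distribution [(1−psi), psi(1−R), psi·R] over the three states."""
    if not (0 <= psi <= 1 and 0 <= r <= 1):
        raise ValueError("psi and r must lie in [0, 1]")
    return np.array([1 - psi, psi * (1 - r), psi * r])


def transition_matrix(psi_m, r_m) -> np.ndarray:
    """Row-stochastic 3×3 transition matrix from per-prior-state psi^m, R^m."""
    psi_m = np.asarray(psi_m, dtype=float)
    r_m = np.asarray(r_m, dtype=float)
    if psi_m.shape != (3,) or r_m.shape != (3,):
        raise ValueError("expected three psi^m and three R^m values")
    if np.any((psi_m < 0) | (psi_m > 1) | (r_m < 0) | (r_m > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.stack([1 - psi_m, psi_m * (1 - r_m), psi_m * r_m], axis=1)


def year_detection_vector(obs, delta: float) -> np.ndarray:
    """P(observed S-tuple | true state) for one site-year."""
    if not 0 <= delta <= 1:
        raise ValueError("delta must lie in [0, 1]")
    obs = [o for o in obs if o != MISSING and o is not None]
    if not obs:
        return np.ones(3)
    n0 = sum(o == 0 for o in obs)
    n1 = sum(o == 1 for o in obs)
    n2 = sum(o == 2 for o in obs)
    d0 = 1.0 if (n1 == 0 and n2 == 0) else 0.0
    d1 = 1.0 if (n0 == 0 and n2 == 0) else 0.0
    d2 = 0.0 if n0 > 0 else float(delta ** n2 * (1 - delta) ** n1)
    return np.array([d0, d1, d2])


def site_log_likelihood(phi0, transitions, deltas, obs) -> float:
    """Forward-recursion log-likelihood for a single site.

    ``transitions`` is (T−1, 3, 3), ``deltas`` is (T,), ``obs`` is (T, S)
    with MISSING = −1.
    """
    obs = np.asarray(obs)
    T = obs.shape[0]
    alpha = np.asarray(phi0, dtype=float) * year_detection_vector(obs[0], deltas[0])
    log_l = 0.0
    for t in range(1, T):
        c = alpha.sum()
        if c <= 0:
            return -np.inf
        log_l += np.log(c)
        alpha = (alpha / c) @ np.asarray(transitions[t - 1], dtype=float)
        alpha = alpha * year_detection_vector(obs[t], deltas[t])
    c = alpha.sum()
    return -np.inf if c <= 0 else log_l + float(np.log(c))


def brute_force_site_likelihood(phi0, transitions, deltas, obs) -> float:
    """Exact site likelihood by summing over all 3^T latent state paths.

    Testing oracle only; refuses T > 8.
    """
    obs = np.asarray(obs)
    T = obs.shape[0]
    if T > 8:
        raise ValueError("path enumeration limited to T <= 8")
    D = np.stack([year_detection_vector(obs[t], deltas[t]) for t in range(T)])
    total = 0.0
    for path in product(range(3), repeat=T):
        p = phi0[path[0]] * D[0, path[0]]
        for t in range(1, T):
            p *= transitions[t - 1][path[t - 1], path[t]] * D[t, path[t]]
        total += p
    return float(total)


# ---------------------------------------------------------------------------
# vectorized evaluation over all sites, used for fitting


@dataclass
class ParameterSet:
    """Realized probabilities for every site implied by a coefficient vector."""

    beta: np.ndarray
    psi0: float                      # initial P(wet)
    r0: float                        # initial P(breeding | wet)
    psi: np.ndarray                  # (n_sites, T-1, 3)
    r: np.ndarray                    # (n_sites, T-1, 3)
    delta: np.ndarray                # (n_sites, T)

    @property
    def phi0(self) -> np.ndarray:
        return initial_state_vector(self.psi0, self.r0)

    def transitions(self, site: int) -> np.ndarray:
        return np.stack([transition_matrix(self.psi[site, t], self.r[site, t])
                         for t in range(self.psi.shape[1])])


def realize(beta, design: DesignMatrices) -> ParameterSet:
    """Map link-scale coefficients to per-site realized probabilities."""
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise FloatingPointError("non-finite coefficient")
    init, b_psi, b_r, b_delta = design.split(beta)
    psi = expit(design.x_psi @ b_psi)
    r = expit(design.x_r @ b_r)
    delta = expit(design.x_delta @ b_delta)
    return ParameterSet(beta=beta, psi0=float(expit(init[0])),
                        r0=float(expit(init[1])), psi=psi, r=r, delta=delta)


@dataclass
class DetectionCounts:
    """Per site-year survey tallies (n0, n1, n2) driving the D vectors."""

    n0: np.ndarray
    n1: np.ndarray
    n2: np.ndarray

    @classmethod
    def from_obs(cls, obs: np.ndarray) -> "DetectionCounts":
        return cls(n0=(obs == 0).sum(axis=2), n1=(obs == 1).sum(axis=2),
                   n2=(obs == 2).sum(axis=2))

    @property
    def all_missing(self) -> np.ndarray:
        return (self.n0 + self.n1 + self.n2) == 0


def _detection_vectors(counts: DetectionCounts, delta: np.ndarray):
    """D (n, T, 3) and dD2/ddelta (n, T) for clipped delta in (0, 1)."""
    n0, n1, n2 = counts.n0, counts.n1, counts.n2
    missing = counts.all_missing
    d = np.clip(delta, _PROB_EPS, 1 - _PROB_EPS)
    D0 = np.where(missing, 1.0, ((n1 == 0) & (n2 == 0)).astype(float))
    D1 = np.where(missing, 1.0, ((n0 == 0) & (n2 == 0)).astype(float))
    pow2 = d ** n2 * (1 - d) ** n1
    D2 = np.where(missing, 1.0, np.where(n0 > 0, 0.0, pow2))
    grad_active = (~missing) & (n0 == 0)
    # derivative of delta^n2 (1-delta)^n1, safe at n=0 exponents
    dD2 = np.where(grad_active,
                   n2 * d ** np.maximum(n2 - 1, 0) * (1 - d) ** n1
                   - n1 * d ** n2 * (1 - d) ** np.maximum(n1 - 1, 0),
                   0.0)
    return np.stack([D0, D1, D2], axis=-1), dD2


def loglik_and_grad(beta, design: DesignMatrices, counts: DetectionCounts):
    """Total log-likelihood over sites and its gradient w.r.t. beta.

    Forward pass with per-step rescaling (c_t) gives log L = Σ_t log c_t per
    site; a matching scaled backward pass gives the smoothing quantities from
    which the derivatives with respect to every realized probability follow,
    and the chain rule through logit links and design tensors yields the
    coefficient gradient.
    """
    params = realize(beta, design)
    psi, r, delta = params.psi, params.r, params.delta
    n, Tm1 = psi.shape[0], psi.shape[1]
    T = Tm1 + 1
    D, dD2 = _detection_vectors(counts, delta)

    # per-site transition tensor (n, T-1, 3, 3)
    Phi = np.empty((n, Tm1, 3, 3))
    Phi[..., 0] = 1 - psi
    Phi[..., 1] = psi * (1 - r)
    Phi[..., 2] = psi * r

    phi0 = params.phi0
    alpha_hat = np.empty((n, T, 3))
    pred = np.empty((n, T, 3))          # predictive distribution before D
    c = np.empty((n, T))
    pred[:, 0] = phi0[None, :]
    a = pred[:, 0] * D[:, 0]
    c[:, 0] = a.sum(axis=1)
    if np.any(c[:, 0] <= 0):
        return -np.inf, np.zeros_like(np.asarray(beta, dtype=float))
    alpha_hat[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        pred[:, t] = np.einsum("ni,nij->nj", alpha_hat[:, t - 1], Phi[:, t - 1])
        a = pred[:, t] * D[:, t]
        c[:, t] = a.sum(axis=1)
        if np.any(c[:, t] <= 0):
            return -np.inf, np.zeros_like(np.asarray(beta, dtype=float))
        alpha_hat[:, t] = a / c[:, t, None]
    loglik = float(np.log(c).sum())

    # scaled backward pass: b_hat[T-1] = 1;
    # b_hat[t] = Phi_t (D_{t+1} ∘ b_hat[t+1]) / c_{t+1}
    b_hat = np.empty((n, T, 3))
    b_hat[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        w = D[:, t + 1] * b_hat[:, t + 1] / c[:, t + 1, None]
        b_hat[:, t] = np.einsum("nij,nj->ni", Phi[:, t], w)

    # d logL / d Phi_t[i,j] = alpha_hat_t[i] * D_{t+1}[j] * b_hat_{t+1}[j] / c_{t+1}
    w_next = D[:, 1:] * b_hat[:, 1:] / c[:, 1:, None]           # (n, T-1, 3)
    G = alpha_hat[:, :-1, :, None] * w_next[:, :, None, :]      # (n, T-1, 3, 3)

    # chain to psi^m, R^m:  row m of Phi = [1-psi, psi(1-r), psi r]
    d_psi = -G[..., 0] + (1 - r) * G[..., 1] + r * G[..., 2]    # (n, T-1, 3)
    d_r = psi * (G[..., 2] - G[..., 1])

    # d logL / d D_t[j] = pred_t[j] * b_hat_t[j] / c_t ; only state 2 varies
    d_delta = pred[..., 2] * b_hat[..., 2] / c * dD2            # (n, T)

    # chain through logits and design tensors
    g_psi_eta = d_psi * psi * (1 - psi)
    g_r_eta = d_r * r * (1 - r)
    g_delta_eta = d_delta * delta * (1 - delta)
    grad_psi = np.einsum("ntm,ntmc->c", g_psi_eta, design.x_psi)
    grad_r = np.einsum("ntm,ntmc->c", g_r_eta, design.x_r)
    grad_delta = np.einsum("nt,ntc->c", g_delta_eta, design.x_delta)

    # initial distribution: dL/dphi0[i] = D_0[i] b_hat_0[i] / c_0
    d_phi0 = (D[:, 0] * b_hat[:, 0] / c[:, 0, None]).sum(axis=0)
    psi0, r0 = params.psi0, params.r0
    d_psi0 = -d_phi0[0] + (1 - r0) * d_phi0[1] + r0 * d_phi0[2]
    d_r0 = psi0 * (d_phi0[2] - d_phi0[1])
    g_init = np.array([d_psi0 * psi0 * (1 - psi0), d_r0 * r0 * (1 - r0)])

    grad = np.concatenate([g_init, grad_psi, grad_r, grad_delta])
    return loglik, grad


def total_log_likelihood(beta, design: DesignMatrices, counts: DetectionCounts) -> float:
    return loglik_and_grad(beta, design, counts)[0]


def total_deviance(beta, design: DesignMatrices, data: StudyData) -> float:
    """−2 × total log-likelihood over the sites of ``data``."""
    counts = DetectionCounts.from_obs(data.obs)
    return -2.0 * total_log_likelihood(beta, design, counts)
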