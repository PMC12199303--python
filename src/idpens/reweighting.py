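"""Maximum-entropy ensemble reweighting against experimental observables.

Frame weights take the Gibbs form w_i proportional to w0_i * exp(-sum_j
lambda_j s_ij); the multipliers lambda are found by minimizing the convex
dual

    Gamma(lambda) = ln Z(lambda) + sum_j lambda_j m_j
                    + (theta / 2) sum_j sigma_j^2 lambda_j^2,

where m_j are the experimental targets, sigma_j their uncertainties, and
theta sets the confidence in the prior: theta -> 0 enforces the restraints
exactly, large theta leaves the prior untouched.  The stationarity
condition is <s_j>_w = m_j + theta sigma_j^2 lambda_j (restraints satisfied
within a Gaussian slack).

The effective retained-sample fraction is monitored with the Kish ratio
(sum w)^2 / (n sum w^2); theta can be tuned by bisection so the solution
matches a target Kish ratio (e.g. 0.101, i.e. ~10% of frames effectively
retained).  Cross-validation follows the restrain-one-class, hold-out-the-
rest pattern: fit on the restrained observable subset, report RMSE on the
held-out subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .io import ObservableTable


@dataclass
class ReweightConfig:
    """Solver configuration.

    ``restrained`` / ``held_out`` are disjoint observable column index
    lists; ``theta`` is the confidence parameter (mutually exclusive with
    ``target_kish``, which triggers bisection tuning).
    """
    restrained: np.ndarray | None = None
    held_out: np.ndarray | None = None
    theta: float | None = 1.0
    target_kish: float | None = None
    gradient_tol: float = 1e-9
    max_iter: int = 2000

    def __post_init__(self):
        if self.restrained is not None and self.held_out is not None:
            if set(np.asarray(self.restrained).tolist()) & set(
                    np.asarray(self.held_out).tolist()):
                raise ValueError("restrained and held-out subsets overlap")
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.target_kish is not None and not 0 < self.target_kish <= 1:
            raise ValueError("target Kish ratio must lie in (0, 1]")


@dataclass
class ReweightResult:
    weights: np.ndarray
    lambdas: np.ndarray
    theta: float
    kish: float
    residuals: np.ndarray            # restrained-set weighted-mean - target
    fit_rmse: float
    cross_validation_rmse: float | None
    converged: bool
    gradient_norm: float
    restrained: np.ndarray = field(repr=False, default=None)
    held_out: np.ndarray = field(repr=False, default=None)


def kish_ratio(weights: np.ndarray) -> float:
    """Effective sample fraction (sum w)^2 / (n sum w^2) in (0, 1]."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    w = w / total
    return float(1.0 / (w.shape[0] * (w ** 2).sum()))


def _gibbs_weights(lambdas: np.ndarray, s: np.ndarray,
                   log_prior: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalized weights and ln Z for multipliers *lambdas*."""
    logw = log_prior - s @ lambdas
    shift = logw.max()
    w = np.exp(logw - shift)
    Z = w.sum()
    return w / Z, float(np.log(Z) + shift)


def observable_rmse(observables: ObservableTable, weights: np.ndarray,
                    subset: np.ndarray | None = None) -> float:
    """RMSE between weighted ensemble-mean observables and targets."""
    if subset is None:
        subset = np.arange(observables.values.shape[1])
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("empty observable subset")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    pred = w @ observables.values[:, subset]
    return float(np.sqrt(((pred - observables.targets[subset]) ** 2).mean()))


def maxent_fit(observables: ObservableTable,
               prior_weights: np.ndarray | None = None,
               config: ReweightConfig | None = None) -> ReweightResult:
    """Solve the maximum-entropy dual for the restrained observable subset."""
    cfg = config or ReweightConfig()
    n_frames, n_obs = observables.values.shape
    restrained = (np.asarray(cfg.restrained) if cfg.restrained is not None
                  else np.arange(n_obs))
    held_out = (np.asarray(cfg.held_out) if cfg.held_out is not None
                else None)
    theta = cfg.theta if cfg.theta is not None else 1.0

    s = observables.values[:, restrained]
    m = observables.targets[restrained]
    sig2 = observables.uncertainties[restrained] ** 2
    if prior_weights is None:
        prior_weights = np.full(n_frames, 1.0 / n_frames)
    w0 = np.asarray(prior_weights, dtype=float)
    w0 = w0 / w0.sum()
    log_prior = np.log(np.clip(w0, 1e-300, None))

    def dual(lam):
        _, lnZ = _gibbs_weights(lam, s, log_prior)
        return lnZ + lam @ m + 0.5 * theta * (sig2 * lam ** 2).sum()

    def grad(lam):
        w, _ = _gibbs_weights(lam, s, log_prior)
        return m - w @ s + theta * sig2 * lam

    res = minimize(dual, np.zeros(restrained.size), jac=grad,
                   method="L-BFGS-B",
                   options={"maxiter": cfg.max_iter, "gtol": cfg.gradient_tol,
                            "ftol": 1e-15})
    lam = res.x
    w, _ = _gibbs_weights(lam, s, log_prior)
    gnorm = float(np.linalg.norm(grad(lam)))
    residuals = w @ s - m
    cv = (observable_rmse(observables, w, held_out)
          if held_out is not None and held_out.size else None)
    return ReweightResult(
        weights=w, lambdas=lam, theta=theta, kish=kish_ratio(w),
        residuals=residuals,
        fit_rmse=float(np.sqrt((residuals ** 2).mean())),
        cross_validation_rmse=cv,
        converged=bool(res.success or gnorm < 1e-5),
        gradient_norm=gnorm, restrained=restrained, held_out=held_out)


def tune_theta(observables: ObservableTable,
               prior_weights: np.ndarray | None = None,
               target_kish: float = 0.101,
               config: ReweightConfig | None = None,
               kish_tol: float = 0.005,
               log_theta_bounds: tuple[float, float] = (-8.0, 8.0),
               max_iter: int = 60) -> tuple[float, ReweightResult]:
    """Bisection on log(theta) until the solution's Kish ratio matches
    *target_kish* within *kish_tol* (Kish is monotone increasing in theta)."""
    if not 0.0 < target_kish < 1.0:
        raise ValueError("target Kish must lie in (0, 1)")
    base = config or ReweightConfig()

    def solve(log_theta):
        cfg = ReweightConfig(restrained=base.restrained,
                             held_out=base.held_out,
                             theta=float(np.exp(log_theta)),
                             gradient_tol=base.gradient_tol,
                             max_iter=base.max_iter)
        return maxent_fit(observables, prior_weights, cfg)

    lo, hi = log_theta_bounds
    res_lo, res_hi = solve(lo), solve(hi)
    if res_hi.kish < target_kish - kish_tol:
        raise RuntimeError(
            f"target Kish {target_kish} above reachable range "
            f"(max {res_hi.kish:.4f} at theta={np.exp(hi):.3g})")
    if res_lo.kish > target_kish + kish_tol:
        raise RuntimeError(
            f"target Kish {target_kish} below reachable range "
            f"(min {res_lo.kish:.4f} at theta={np.exp(lo):.3g})")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        res = solve(mid)
        if abs(res.kish - target_kish) < kish_tol:
            return res.theta, res
        if res.kish > target_kish:
            hi = mid
        else:
            lo = mid
    raise RuntimeError("theta bisection did not converge; achieved Kish "
                       f"{res.kish:.4f} vs target {target_kish}")
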