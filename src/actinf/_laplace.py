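"""Variational Laplace: Newton ascent on a free-energy objective with
numerically estimated curvature.

Shared by first-level (subject) inversion and second-level (group) inversion.
The objective is the log-joint ``log p(y | theta) + log N(theta; pE, pC)``;
at the optimum the posterior is approximated as Gaussian with covariance
equal to the inverse negative Hessian (ridge-regularized to positive
definite), and the free energy receives the usual Laplace volume correction
``(d/2) log 2 pi + (1/2) log det Cp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LaplaceResult", "variational_laplace", "gaussian_log_density"]

FD_STEP = 1e-3


class CurvatureError(RuntimeError):
    """The negative Hessian could not be regularized to positive definite."""


def gaussian_log_density(x, mean, cov) -> float:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    d = x - mean
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise CurvatureError("covariance is not positive definite")
    return float(
        -0.5 * (len(x) * np.log(2 * np.pi) + logdet + d @ np.linalg.solve(cov, d))
    )


@dataclass
class LaplaceResult:
    Ep: np.ndarray
    Cp: np.ndarray
    F: float
    trajectory: list = field(default_factory=list)
    converged: bool = False
    n_iterations: int = 0


def _grad_hess(f, x, fx, step):
    """Central-difference gradient and symmetrized Hessian."""
    d = len(x)
    g = np.zeros(d)
    H = np.zeros((d, d))
    fp = np.zeros(d)
    fm = np.zeros(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = step
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        g[i] = (fp[i] - fm[i]) / (2 * step)
        H[i, i] = (fp[i] - 2 * fx + fm[i]) / step**2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = step
            ej[j] = step
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * step**2)
    return g, H


def _regularize_neg_hessian(H) -> np.ndarray:
    """Return a positive-definite precision matrix from ``-H`` by escalating
    ridge regularization."""
    P = -(H + H.T) / 2.0
    for ridge in [0.0] + [1e-6 * 10**k for k in range(10)]:
        try:
            np.linalg.cholesky(P + ridge * np.eye(len(P)))
            return P + ridge * np.eye(len(P))
        except np.linalg.LinAlgError:
            continue
    raise CurvatureError(
        "negative Hessian is indefinite even after ridge regularization; "
        f"eigenvalues {np.linalg.eigvalsh(P)}"
    )


def variational_laplace(
    log_likelihood,
    pE,
    pC,
    tol: float = 1e-3,
    max_iter: int = 32,
    fd_step: float = FD_STEP,
) -> LaplaceResult:
    """Maximize ``log_likelihood(theta) + log N(theta; pE, pC)`` by Newton
    ascent with finite-difference derivatives and step halving.

    Parameters
    ----------
    log_likelihood : callable mapping a parameter vector to a float.
    pE : prior mean vector.
    pC : prior covariance (matrix, or vector of variances).
    tol : convergence tolerance on the change in the objective.
    max_iter : iteration cap.
    """
    pE = np.atleast_1d(np.asarray(pE, dtype=float))
    pC = np.asarray(pC, dtype=float)
    if pC.ndim < 2:
        pC = np.diag(np.atleast_1d(pC))
    if np.any(np.linalg.eigvalsh(pC) <= 0):
        raise ValueError("prior covariance must be positive definite")

    def objective(theta):
        return float(log_likelihood(theta)) + gaussian_log_density(theta, pE, pC)

    theta = pE.copy()
    f_cur = objective(theta)
    trajectory = [(theta.copy(), f_cur)]
    converged = False
    n_iter = 0
    H = -np.linalg.inv(pC)

    for n_iter in range(1, max_iter + 1):
        g, H = _grad_hess(objective, theta, f_cur, fd_step)
        P = _regularize_neg_hessian(H)
        step_dir = np.linalg.solve(P, g)
        # step halving until the objective does not decrease
        scale = 1.0
        for _ in range(16):
            cand = theta + scale * step_dir
            f_cand = objective(cand)
            if f_cand >= f_cur - 1e-12:
                break
            scale /= 2.0
        else:
            f_cand, cand = f_cur, theta
        dF = f_cand - f_cur
        theta, f_cur = cand, f_cand
        trajectory.append((theta.copy(), f_cur))
        if abs(dF) < tol:
            converged = True
            break

    _, H = _grad_hess(objective, theta, f_cur, fd_step)
    P = _regularize_neg_hessian(H)
    Cp = np.linalg.inv(P)
    Cp = (Cp + Cp.T) / 2.0
    d = len(theta)
    sign, logdet = np.linalg.slogdet(Cp)
    F = f_cur + 0.5 * (d * np.log(2 * np.pi) + logdet)
    return LaplaceResult(
        Ep=theta, Cp=Cp, F=float(F),
        trajectory=trajectory, converged=converged, n_iterations=n_iter,
    )
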