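"""Hierarchical (parametric empirical Bayes) inference on subject posteriors.

The second-level model explains each subject's log-scaling parameter as a
linear mixture of between-subject effects plus a random effect:

    theta_i = X_i @ beta_group + epsilon_i,    epsilon_i ~ N(0, sigma_b^2)

where the design matrix ``X`` has a constant (group mean) column and a +1/-1
group-indicator column.  The scheme never refits subjects: Bayesian model
reduction (BMR) gives the closed-form change in each subject's log-evidence
when the original shrinkage prior on the modelled parameter is replaced by
the empirical prior ``N(X_i @ beta, sigma_b^2)``.  Summing those changes over
subjects yields a second-level free energy that is optimized over the group
effects and a log-precision hyperparameter scaling the between-subject
variance (prior variance = first-level prior variance / within:between
ratio).

Reduced second-level models (mean-only, difference-only, null) are scored by
a second application of BMR — collapsing the prior variance of switched-off
design columns — and compared through a softmax over free energies, with a
classical two-sample t test alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._laplace import variational_laplace
from .subject_inversion import SubjectPosterior

__all__ = [
    "DesignMatrix",
    "PEBConfig",
    "PEBResult",
    "Gaussian",
    "bayesian_model_reduction",
    "fit_peb",
    "compare_group_models",
    "classical_group_test",
    "MODEL_SPACE",
]

MODEL_SPACE = ("full", "mean-only", "difference-only", "null")
_OFF_VARIANCE = 1e-8


@dataclass(frozen=True)
class Gaussian:
    """A Gaussian density (mean vector, covariance matrix)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mean", np.atleast_1d(np.asarray(self.mean, float)))
        object.__setattr__(self, "cov", np.atleast_2d(np.asarray(self.cov, float)))

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.cov)


@dataclass(frozen=True)
class DesignMatrix:
    """Between-subject design: column 1 all ones (group mean), column 2 the
    +1/-1 group indicator."""

    X: np.ndarray
    labels: tuple = ("mean", "difference")

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, float))
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("first design column must be constant 1")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", tuple(self.labels))

    @classmethod
    def from_groups(cls, group_indicator) -> "DesignMatrix":
        """Build the mean + difference design from a +1/-1 (or 1/2, or 0/1)
        per-subject group label sequence."""
        g = np.asarray(group_indicator)
        levels = sorted(set(g.tolist()))
        if len(levels) != 2:
            raise ValueError("exactly two group levels are required")
        x = np.where(g == levels[0], 1.0, -1.0)
        return cls(X=np.column_stack([np.ones(len(g)), x]))

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_effects(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class PEBConfig:
    """Second-level configuration.

    ``within_between_ratio`` divides the first-level prior variance to give
    the base between-subject variance; ``hE``/``hC`` are the prior mean and
    variance of the log precision scaling that variance.
    """

    within_between_ratio: float = 16.0
    hE: float = 0.0
    hC: float = 1.0 / 16.0
    second_level_prior_variance: float | None = None  # default: first-level pC

    def __post_init__(self):
        if not self.within_between_ratio > 0:
            raise ValueError("within:between ratio must be positive")


@dataclass
class PEBResult:
    """Posterior over second-level effects, with model-comparison results."""

    Ep2: np.ndarray
    Cp2: np.ndarray
    Eh: float
    F2: float
    design: DesignMatrix
    config: PEBConfig
    field_name: str
    prior2: Gaussian
    between_variance: float
    subject_posteriors_updated: list = field(default_factory=list, repr=False)
    model_space: tuple = MODEL_SPACE
    model_F: dict = field(default_factory=dict)
    model_post: dict = field(default_factory=dict)
    bma_mean: np.ndarray | None = None
    bma_cov: np.ndarray | None = None
    n_iterations: int = 0

    @property
    def group_gap(self) -> float:
        """Estimated group difference (first minus second group level) in the
        modelled parameter: twice the +1/-1 indicator coefficient."""
        return 2.0 * float(self.Ep2[1])

    @property
    def group_gap_sd(self) -> float:
        return 2.0 * float(np.sqrt(self.Cp2[1, 1]))


# ---------------------------------------------------------------------------
# Bayesian model reduction


def bayesian_model_reduction(
    prior: Gaussian, posterior: Gaussian, reduced_prior: Gaussian
) -> tuple[float, Gaussian]:
    """Closed-form re-evaluation of a Gaussian posterior under a new prior.

    Given the prior and posterior of an already-inverted model, returns the
    change in log-evidence ``delta_F`` and the posterior that would have been
    obtained under ``reduced_prior`` — exact for Gaussian pairs, no refit.
    Raises ``np.linalg.LinAlgError`` if the implied reduced precision is
    indefinite.
    """
    P0, m0 = prior.precision, prior.mean
    P, m = posterior.precision, posterior.mean
    Pr, mr = reduced_prior.precision, reduced_prior.mean

    Pq = P + Pr - P0
    np.linalg.cholesky(Pq)  # raises LinAlgError if indefinite
    bq = P @ m + Pr @ mr - P0 @ m0
    mq = np.linalg.solve(Pq, bq)

    def _logdet(M_):
        sign, ld = np.linalg.slogdet(M_)
        if sign <= 0:
            raise np.linalg.LinAlgError("indefinite matrix in model reduction")
        return ld

    quad = mq @ Pq @ mq - m @ P @ m - mr @ Pr @ mr + m0 @ P0 @ m0
    logdet = _logdet(P) + _logdet(Pr) - _logdet(P0) - _logdet(Pq)
    delta_F = 0.5 * (quad + logdet)
    return float(delta_F), Gaussian(mean=mq, cov=np.linalg.inv(Pq))


# ---------------------------------------------------------------------------
# second-level inversion


def _subject_gaussians(posteriors) -> list[tuple[Gaussian, Gaussian]]:
    pairs = []
    for sp in posteriors:
        if sp.pE is None or sp.pC is None:
            raise ValueError("subject posteriors must carry their priors")
        pairs.append(
            (Gaussian(sp.pE, np.atleast_2d(sp.pC)), Gaussian(sp.Ep, sp.Cp))
        )
    return pairs


def _empirical_prior(base_prior: Gaussian, idx: int, mean_j: float, var_j: float) -> Gaussian:
    """First-level prior with the modelled parameter's marginal swapped for
    the empirical (second-level) prior."""
    m = base_prior.mean.copy()
    C = base_prior.cov.copy()
    m[idx] = mean_j
    C[idx, :] = 0.0
    C[:, idx] = 0.0
    C[idx, idx] = var_j
    return Gaussian(m, C)


def fit_peb(
    posteriors,
    X: DesignMatrix,
    field_name: str = "beta",
    cfg: PEBConfig | None = None,
    tol: float = 1e-3,
    max_iter: int = 64,
) -> PEBResult:
    """Empirical-Bayes group inversion of first-level subject posteriors.

    Optimizes the second-level free energy — the sum over subjects of the BMR
    log-evidence change under the empirical prior ``N(X_i @ beta, sigma_b^2
    e^{-h})`` plus shrinkage priors on ``beta`` and ``h`` — by Newton ascent,
    and re-evaluates every subject posterior under the empirical prior at the
    optimum.
    """
    posteriors = list(posteriors)
    if len(posteriors) < 2:
        raise ValueError("PEB requires at least two subjects")
    if cfg is None:
        cfg = PEBConfig()
    if X.n_subjects != len(posteriors):
        raise ValueError("design matrix rows must match the number of subjects")
    fields = posteriors[0].field_names
    if any(sp.field_names != fields for sp in posteriors):
        raise ValueError("subjects have inconsistent parameter fields")
    idx = fields.index(field_name)

    pairs = _subject_gaussians(posteriors)
    pC_j = float(pairs[0][0].cov[idx, idx])
    base_between = pC_j / cfg.within_between_ratio
    var2 = cfg.second_level_prior_variance
    if var2 is None:
        var2 = pC_j

    K = X.n_effects
    pE2 = np.zeros(K + 1)
    pC2 = np.diag([var2] * K + [cfg.hC])
    pE2[-1] = cfg.hE

    def second_level_evidence(phi):
        beta_g, h = phi[:K], phi[-1]
        sigma_b2 = base_between * np.exp(-h)
        total = 0.0
        mu = X.X @ beta_g
        for i, (prior, post) in enumerate(pairs):
            rp = _empirical_prior(prior, idx, mu[i], sigma_b2)
            dF, _ = bayesian_model_reduction(prior, post, rp)
            total += dF
        return total

    res = variational_laplace(second_level_evidence, pE2, pC2, tol=tol, max_iter=max_iter)

    beta_hat, h_hat = res.Ep[:K], float(res.Ep[-1])
    sigma_b2 = base_between * np.exp(-h_hat)
    mu = X.X @ beta_hat
    updated = []
    for i, (sp, (prior, post)) in enumerate(zip(posteriors, pairs)):
        rp = _empirical_prior(prior, idx, float(mu[i]), sigma_b2)
        _, rq = bayesian_model_reduction(prior, post, rp)
        updated.append(
            SubjectPosterior(
                Ep=rq.mean, Cp=rq.cov, F=sp.F, field_names=sp.field_names,
                pE=rp.mean, pC=rp.cov,
            )
        )

    peb = PEBResult(
        Ep2=beta_hat,
        Cp2=res.Cp[:K, :K],
        Eh=h_hat,
        F2=res.F,
        design=X,
        config=cfg,
        field_name=field_name,
        prior2=Gaussian(np.zeros(K), np.diag([var2] * K)),
        between_variance=sigma_b2,
        subject_posteriors_updated=updated,
        n_iterations=res.n_iterations,
    )
    compare_group_models(peb)
    return peb


def _reduced_prior2(prior2: Gaussian, keep_mean: bool, keep_diff: bool) -> Gaussian:
    C = prior2.cov.copy()
    if not keep_mean:
        C[0, 0] = _OFF_VARIANCE
    if not keep_diff:
        C[1, 1] = _OFF_VARIANCE
    return Gaussian(prior2.mean, C)


def compare_group_models(peb: PEBResult) -> dict:
    """Score the four on/off combinations of the design columns by BMR on the
    second-level posterior; posterior model probabilities are the softmax of
    the free energies (uniform model priors).  Also computes the Bayesian
    model average of the second-level effects.
    """
    post2 = Gaussian(peb.Ep2, peb.Cp2)
    switches = {
        "full": (True, True),
        "mean-only": (True, False),
        "difference-only": (False, True),
        "null": (False, False),
    }
    dFs, reduced = {}, {}
    for name, (km, kd) in switches.items():
        rp = _reduced_prior2(peb.prior2, km, kd)
        dF, rq = bayesian_model_reduction(peb.prior2, post2, rp)
        dFs[name] = dF
        reduced[name] = rq
    Fv = np.array([dFs[m] for m in MODEL_SPACE])
    w = np.exp(Fv - Fv.max())
    w /= w.sum()
    peb.model_F = {m: peb.F2 + dFs[m] for m in MODEL_SPACE}
    peb.model_post = {m: float(p) for m, p in zip(MODEL_SPACE, w)}

    bma_mean = sum(w_ * reduced[m].mean for m, w_ in zip(MODEL_SPACE, w))
    bma_cov = sum(
        w_ * (reduced[m].cov + np.outer(reduced[m].mean - bma_mean,
                                        reduced[m].mean - bma_mean))
        for m, w_ in zip(MODEL_SPACE, w)
    )
    peb.bma_mean = bma_mean
    peb.bma_cov = bma_cov
    return peb.model_post


def difference_model_probability(peb: PEBResult) -> float:
    """Combined posterior mass of second-level models containing the
    group-difference effect."""
    return peb.model_post["full"] + peb.model_post["difference-only"]


def classical_group_test(estimates, labels) -> tuple[float, float]:
    """Two-sample pooled-variance t test of per-subject scalar estimates.

    Groups follow the sorted order of the unique labels; the statistic is
    mean(group 2) - mean(group 1) scaled by the pooled standard error, with a
    two-sided p value.
    """
    estimates = np.asarray(estimates, dtype=float)
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    a = estimates[labels == levels[0]]
    b = estimates[labels == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two subjects")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("degenerate zero-variance input")
    t, p = stats.ttest_ind(b, a, equal_var=True)
    return float(t), float(p)
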