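"""Leave-one-out classification of subjects from their parameter estimates.

The roles of the explanatory variable and the parameter estimates are
swapped: for each held-out subject a PEB model is fitted to the remaining
subjects, and the predictive density of the held-out subject's choice data is
evaluated at the two levels of the group indicator (+1 and -1).  The
empirical prior implied by each level — mean ``beta_mean +/- beta_diff``,
variance equal to the between-subject variance plus the propagated
second-level uncertainty — is scored against the subject's first-level
posterior by Bayesian model reduction, and the two log-evidences are
normalized to a Bernoulli posterior over group membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .group_peb import (
    DesignMatrix,
    Gaussian,
    PEBConfig,
    PEBResult,
    bayesian_model_reduction,
    fit_peb,
    _empirical_prior,
)
from .subject_inversion import SubjectPosterior

__all__ = ["LOOResult", "loo_predict", "classify_subject"]


@dataclass
class LOOResult:
    """Per-subject predictive expectations and group-membership posteriors.

    ``group_prob[i]`` is the posterior probability that subject ``i`` belongs
    to the first group (indicator +1); ``predictive_expectation`` is the
    expected indicator ``2 * group_prob - 1``; ``correlation`` the Pearson
    correlation between predicted and true indicators; ``accuracy`` the
    fraction classified correctly at threshold 0.5.
    """

    predictive_expectation: np.ndarray
    group_prob: np.ndarray
    true_indicator: np.ndarray
    correlation: float
    accuracy: float
    folds: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "predictive_expectation": self.predictive_expectation.tolist(),
            "group_prob": self.group_prob.tolist(),
            "true_indicator": self.true_indicator.tolist(),
            "correlation": self.correlation,
            "accuracy": self.accuracy,
        }


def classify_subject(
    peb_from_others: PEBResult, subject_posterior: SubjectPosterior
) -> float:
    """Posterior probability that a subject belongs to the first group.

    Evaluates the BMR log-evidence of the subject's data under the empirical
    prior implied by each group-indicator level and normalizes over the two.
    """
    idx = subject_posterior.field_names.index(peb_from_others.field_name)
    prior = Gaussian(subject_posterior.pE, np.atleast_2d(subject_posterior.pC))
    post = Gaussian(subject_posterior.Ep, subject_posterior.Cp)

    log_ev = {}
    for x in (+1.0, -1.0):
        a = np.array([1.0, x])
        mean_j = float(a @ peb_from_others.Ep2)
        var_j = peb_from_others.between_variance + float(a @ peb_from_others.Cp2 @ a)
        rp = _empirical_prior(prior, idx, mean_j, var_j)
        dF, _ = bayesian_model_reduction(prior, post, rp)
        log_ev[x] = dF
    m = max(log_ev.values())
    w = {x: np.exp(v - m) for x, v in log_ev.items()}
    return float(w[+1.0] / (w[+1.0] + w[-1.0]))


def loo_predict(
    posteriors,
    X: DesignMatrix,
    field_name: str = "beta",
    cfg: PEBConfig | None = None,
) -> LOOResult:
    """Leave-one-out prediction of every subject's group membership.

    For each subject the PEB model is refitted on the other N - 1 subjects
    and the held-out subject is classified from its first-level posterior.
    Deterministic given its inputs.  Raises if fewer than three subjects are
    supplied, the indicator is not binary +1/-1, or a fold leaves only one
    group.
    """
    posteriors = list(posteriors)
    N = len(posteriors)
    if N < 3:
        raise ValueError("leave-one-out requires at least three subjects")
    x_true = X.X[:, 1]
    if not set(np.unique(x_true)) <= {-1.0, 1.0}:
        raise ValueError("second design column must be a +1/-1 indicator")

    probs = np.zeros(N)
    folds = []
    for i in range(N):
        rest = [p for j, p in enumerate(posteriors) if j != i]
        x_rest = np.delete(x_true, i)
        if len(set(x_rest.tolist())) < 2:
            raise ValueError(f"fold {i}: only one group present after hold-out")
        X_rest = DesignMatrix(np.delete(X.X, i, axis=0), X.labels)
        peb = fit_peb(rest, X_rest, field_name=field_name, cfg=cfg)
        probs[i] = classify_subject(peb, posteriors[i])
        folds.append(peb)

    expectation = 2.0 * probs - 1.0
    predicted_group = np.where(probs >= 0.5, 1.0, -1.0)
    accuracy = float(np.mean(predicted_group == x_true))
    if np.std(expectation) == 0 or np.std(x_true) == 0:
        correlation = 0.0
    else:
        correlation = float(np.corrcoef(expectation, x_true)[0, 1])
    return LOOResult(
        predictive_expectation=expectation,
        group_prob=probs,
        true_indicator=x_true.copy(),
        correlation=correlation,
        accuracy=accuracy,
        folds=folds,
    )
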