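"""Inversion of the objective model of choices: variational Laplace estimation
of subject-level log-scaling parameters from observed outcome/action sequences.

The free parameters are log-scaling factors applied to fields of the
subjective generative model — by default the precision hyperprior rate
``beta`` and a common scale ``c_scale`` on the outcome utilities.  A value of
zero leaves the model as specified; shrinkage priors (mean 0, variance 1/16)
regularize the estimates toward that reference point.

The likelihood of a recorded session is obtained by *replaying* it: outcomes
are clamped to those observed, the belief/precision machinery of
:mod:`actinf.active_inference` produces the marginal action probability at
each decision point, and the log-probabilities of the recorded actions are
summed.  In the absence of learning, decisions with identical observation and
action prefixes have identical probabilities, so unique decision contexts are
evaluated once and weighted by their multiplicity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._laplace import variational_laplace
from .active_inference import (
    LOG_FLOOR,
    SubjectDataset,
    action_marginal,
    evaluate_beliefs,
    run_session,
)
from .generative_model import GenerativeModel, normalize_preferences

__all__ = [
    "DEFAULT_FIELDS",
    "SubjectParameters",
    "InversionPriors",
    "SubjectPosterior",
    "apply_parameters",
    "choice_log_likelihood",
    "invert_subject",
    "estimation_curve",
]

DEFAULT_FIELDS = ("beta", "c_scale")
_SCALAR_FIELDS = ("alpha", "beta")


@dataclass(frozen=True)
class SubjectParameters:
    """Log-scaling parameters on named model fields (0 = model as specified)."""

    theta: np.ndarray
    field_names: tuple = DEFAULT_FIELDS

    def __post_init__(self):
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if theta.shape != (len(self.field_names),):
            raise ValueError("theta length must match field_names")
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta must be finite")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "field_names", tuple(self.field_names))

    def as_dict(self) -> dict:
        return dict(zip(self.field_names, self.theta.tolist()))


@dataclass(frozen=True)
class InversionPriors:
    """Shrinkage priors on the log-scaling parameters: mean 0, variance 1/16."""

    pE: float = 0.0
    pC: float = 1.0 / 16.0

    def __post_init__(self):
        if not self.pC > 0:
            raise ValueError("prior variance pC must be positive")

    def expand(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        return np.full(n, self.pE), np.diag(np.full(n, self.pC))


@dataclass
class SubjectPosterior:
    """Gaussian posterior over log-scaling parameters plus the free-energy
    bound on the log-evidence of the observed choices."""

    Ep: np.ndarray
    Cp: np.ndarray
    F: float
    field_names: tuple = DEFAULT_FIELDS
    pE: np.ndarray | None = None
    pC: np.ndarray | None = None
    trajectory: list = field(default_factory=list, repr=False)
    converged: bool = True
    n_iterations: int = 0
    n_floored_decisions: int = 0

    @property
    def posterior_correlation(self) -> np.ndarray:
        """Conditional-dependency diagnostic: correlation matrix from Cp."""
        sd = np.sqrt(np.diag(self.Cp))
        return self.Cp / np.outer(sd, sd)

    def mean_for(self, name: str) -> float:
        return float(self.Ep[self.field_names.index(name)])


def apply_parameters(M: GenerativeModel, params: SubjectParameters) -> GenerativeModel:
    """Return a copy of ``M`` with each targeted field ``x`` scaled to
    ``x * exp(theta)``.  ``c_scale`` multiplies the raw utilities before
    normalization; ``alpha``/``beta`` scale the precision hyperparameters."""
    kw = {}
    for name, th in zip(params.field_names, params.theta):
        s = np.exp(th)
        if name in _SCALAR_FIELDS:
            kw[name] = getattr(M, name) * s
        elif name == "c_scale":
            kw["C_utilities"] = M.C_utilities * s
        else:
            raise KeyError(f"unknown model field {name!r}")
    return M.with_fields(**kw) if kw else M


def _decision_contexts(M: GenerativeModel, dataset: SubjectDataset) -> Counter:
    """Multiplicity of each unique (observation prefix, action prefix,
    recorded action) decision context in the session."""
    contexts: Counter = Counter()
    for trial in dataset:
        for t in range(M.T - 1):
            key = (
                tuple(trial.observations[: t + 1]),
                tuple(trial.actions[:t]),
                int(trial.actions[t]),
            )
            contexts[key] += 1
    return contexts


def choice_log_likelihood(
    M: GenerativeModel,
    params: SubjectParameters,
    dataset: SubjectDataset,
    details: dict | None = None,
) -> float:
    """Log-probability of the recorded actions under the scaled model.

    Replays each decision with observations clamped to those recorded and
    sums ``log P(recorded action)`` over decision points; actions whose
    probability falls below ``exp(-16)`` contribute the floor and are counted
    in ``details['n_floored']``.
    """
    Mp = apply_parameters(M, params)
    contexts = _decision_contexts(Mp, dataset)
    cache: dict = {}
    total = 0.0
    n_floored = 0
    for (obs, acts, a), count in contexts.items():
        key = (obs, acts)
        if key not in cache:
            belief = evaluate_beliefs(Mp, list(obs), list(acts), len(obs) - 1)
            cache[key] = action_marginal(belief.q_pi, Mp.V, len(obs) - 1, Mp.n_actions)
        p = cache[key][a]
        if p < LOG_FLOOR:
            n_floored += count
            p = LOG_FLOOR
        total += count * np.log(p)
    if details is not None:
        details["n_floored"] = n_floored
        details["n_decisions"] = sum(contexts.values())
        details["n_unique_contexts"] = len(cache)
    return float(total)


def invert_subject(
    dataset: SubjectDataset,
    M: GenerativeModel,
    priors: InversionPriors | None = None,
    fields: tuple = DEFAULT_FIELDS,
    tol: float = 1e-3,
    max_iter: int = 32,
) -> SubjectPosterior:
    """Estimate log-scaling parameters for one subject by variational Laplace.

    Newton ascent on ``choice_log_likelihood + log prior`` with numerical
    curvature; the posterior covariance is the inverse negative Hessian at
    the optimum.  A dataset with no decisions returns the prior.
    """
    if priors is None:
        priors = InversionPriors()
    fields = tuple(fields)
    pE, pC = priors.expand(len(fields))

    n_decisions = sum(max(0, len(tr.actions)) for tr in dataset)
    if n_decisions == 0:
        return SubjectPosterior(
            Ep=pE, Cp=pC, F=0.0, field_names=fields, pE=pE, pC=pC,
            converged=True, n_iterations=0,
        )

    def loglik(theta):
        return choice_log_likelihood(M, SubjectParameters(theta, fields), dataset)

    res = variational_laplace(loglik, pE, pC, tol=tol, max_iter=max_iter)
    diag: dict = {}
    choice_log_likelihood(M, SubjectParameters(res.Ep, fields), dataset, details=diag)
    return SubjectPosterior(
        Ep=res.Ep, Cp=res.Cp, F=res.F, field_names=fields, pE=pE, pC=pC,
        trajectory=res.trajectory, converged=res.converged,
        n_iterations=res.n_iterations,
        n_floored_decisions=diag.get("n_floored", 0),
    )


def estimation_curve(
    M: GenerativeModel,
    true_params: SubjectParameters,
    trial_counts,
    n_reps: int,
    rng: np.random.Generator,
    priors: InversionPriors | None = None,
    z: float = 1.645,
):
    """Posterior mean and credible-interval width for the precision
    hyperprior as a function of the number of trials.

    For each replicate a session of ``max(trial_counts)`` stochastic-choice
    trials is simulated under ``true_params`` and inverted on each leading
    subset.  Returns a :class:`pandas.DataFrame` with columns
    ``(n_trials, rep, posterior_mean, ci_width)`` for the first estimated
    field; the 90% interval width is ``2 z sqrt(Cp)`` (prior width at zero
    trials).
    """
    import pandas as pd

    if priors is None:
        priors = InversionPriors()
    trial_counts = sorted(int(n) for n in trial_counts)
    if any(n < 0 for n in trial_counts):
        raise ValueError("trial counts must be non-negative")
    n_max = max(trial_counts) if trial_counts else 0
    Mp = apply_parameters(M, true_params)
    rows = []
    for rep in range(n_reps):
        session = run_session(Mp, max(n_max, 1), rng, stochastic_actions=True)
        for n in trial_counts:
            subset = SubjectDataset(trials=session.trials[:n])
            post = invert_subject(subset, M, priors, true_params.field_names)
            rows.append(
                {
                    "n_trials": n,
                    "rep": rep,
                    "posterior_mean": float(post.Ep[0]),
                    "ci_width": float(2 * z * np.sqrt(post.Cp[0, 0])),
                }
            )
    return pd.DataFrame(rows)
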