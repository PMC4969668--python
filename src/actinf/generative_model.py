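"""Discrete-state generative models for active inference, and the two-step T-maze.

A generative model here is the *subjective* task model of a partially observable
Markov decision process: a likelihood mapping ``A`` from hidden states to
observable outcomes, one column-stochastic transition matrix ``B[u]`` per
action, prior preferences ``C`` over outcomes (log-probabilities), a prior
``D`` over initial hidden states, and a set of allowable policies ``V``
(fixed action sequences over the trial horizon).  Precision of policy
selection is Gamma-distributed with shape ``alpha`` and rate ``beta``.

The canonical example is a two-step T-maze: the agent starts in the middle,
reward is hidden in the left or right arm (the *context*), the arms are
absorbing, and a cue at the bottom of the maze reveals the context.  The
optimal policy samples the cue first and then claims the signalled arm.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenerativeModel",
    "TMazeConfig",
    "ModelValidationError",
    "build_tmaze",
    "normalize_preferences",
    "enumerate_policies",
    "validate_model",
    "TMAZE_STATE_LABELS",
    "TMAZE_OUTCOME_LABELS",
    "TMAZE_ACTION_LABELS",
]

_TOL = 1e-10
SCHEMA_VERSION = 1

# T-maze labelling convention: states are location-major (middle, left, right,
# cue) crossed with context (reward-left, reward-right); 0-based internally.
_LOCATIONS = ("middle", "left", "right", "cue")
_CONTEXTS = ("L", "R")
TMAZE_STATE_LABELS = tuple(f"{loc}/{ctx}" for loc in _LOCATIONS for ctx in _CONTEXTS)
TMAZE_OUTCOME_LABELS = (
    "middle",
    "left+reward",
    "left-noreward",
    "right+reward",
    "right-noreward",
    "cue-left",
    "cue-right",
)
TMAZE_ACTION_LABELS = ("go-middle", "go-left", "go-right", "go-cue")


class ModelValidationError(ValueError):
    """A generative model (or its configuration) violates a structural bound."""


def normalize_preferences(utilities) -> np.ndarray:
    """Convert raw outcome utilities to normalized log-preferences.

    Preferences are prior beliefs about outcomes, so the raw utilities
    (log-preferences up to a constant) are passed through a log-softmax:
    ``C = utilities - logsumexp(utilities)``.  ``exp(C)`` sums to one,
    ``max(C) <= 0``, and differences of ``C`` equal differences of the
    utilities.
    """
    u = np.asarray(utilities, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ModelValidationError("utilities must be a non-empty 1-D vector")
    if not np.all(np.isfinite(u)):
        raise ModelValidationError("utilities must be finite")
    m = u.max()
    return u - (m + np.log(np.exp(u - m).sum()))


def enumerate_policies(n_actions: int, depth: int) -> np.ndarray:
    """All ``n_actions ** depth`` action sequences, lexicographic, as a
    ``(depth, n_policies)`` integer array (one column per policy)."""
    if n_actions < 1 or depth < 1:
        raise ModelValidationError("n_actions and depth must be >= 1")
    cols = list(itertools.product(range(n_actions), repeat=depth))
    return np.array(cols, dtype=int).T


@dataclass(frozen=True)
class TMazeConfig:
    """Configuration of the two-step T-maze task.

    Parameters
    ----------
    p_valid : float
        Probability that the arm matching the context delivers reward; the
        mismatching arm rewards with probability ``1 - p_valid``.  Must lie in
        (0.5, 1].
    utilities : tuple of float
        Raw preference values for (reward, no-reward-in-arm, neutral)
        outcomes, in log space.
    context_prior : float
        Prior probability that the reward is on the left.
    """

    p_valid: float = 0.98
    utilities: tuple = (4.0, -4.0, 0.0)
    context_prior: float = 0.5

    def validate(self) -> None:
        if not (0.5 < self.p_valid <= 1.0):
            raise ModelValidationError(
                f"p_valid must lie in (0.5, 1], got {self.p_valid}"
            )
        if not (0.0 <= self.context_prior <= 1.0):
            raise ModelValidationError(
                f"context_prior must lie in [0, 1], got {self.context_prior}"
            )
        if len(self.utilities) != 3 or not np.all(np.isfinite(self.utilities)):
            raise ModelValidationError(
                "utilities must be three finite values (reward, no-reward, neutral)"
            )


@dataclass(frozen=True)
class GenerativeModel:
    """Subjective generative model of a finite-horizon POMDP trial.

    Fields
    ------
    A : (n_outcomes, n_states) column-stochastic likelihood matrix.
    B : (n_actions, n_states, n_states) stack of column-stochastic
        transition matrices, one per action.
    C : (n_outcomes,) normalized log-preferences over outcomes.
    C_utilities : raw utilities from which ``C`` was derived (kept for
        reporting and for log-scaling during inversion).
    D : (n_states,) prior over initial hidden states.
    V : (T - 1, n_policies) allowable policies (action indices).
    T : trial horizon in time steps.
    alpha, beta : Gamma shape/rate hyperparameters of policy precision.
    """

    A: np.ndarray
    B: np.ndarray
    C_utilities: np.ndarray
    D: np.ndarray
    V: np.ndarray
    T: int
    alpha: float = 2.0
    beta: float = 2.0
    labels: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "B", np.asarray(self.B, dtype=float))
        object.__setattr__(self, "C_utilities", np.asarray(self.C_utilities, dtype=float))
        object.__setattr__(self, "D", np.asarray(self.D, dtype=float))
        object.__setattr__(self, "V", np.asarray(self.V, dtype=int))

    @property
    def C(self) -> np.ndarray:
        return normalize_preferences(self.C_utilities)

    @property
    def n_states(self) -> int:
        return self.A.shape[1]

    @property
    def n_outcomes(self) -> int:
        return self.A.shape[0]

    @property
    def n_actions(self) -> int:
        return self.B.shape[0]

    @property
    def n_policies(self) -> int:
        return self.V.shape[1]

    def with_fields(self, **kw) -> "GenerativeModel":
        return replace(self, **kw)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C_utilities": self.C_utilities.tolist(),
            "D": self.D.tolist(),
            "V": self.V.tolist(),
            "T": int(self.T),
            "alpha": float(self.alpha),
            "beta": float(self.beta),
            "labels": {k: list(v) for k, v in self.labels.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeModel":
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ModelValidationError(f"unsupported model schema version {version}")
        return cls(
            A=np.array(d["A"], dtype=float),
            B=np.array(d["B"], dtype=float),
            C_utilities=np.array(d["C_utilities"], dtype=float),
            D=np.array(d["D"], dtype=float),
            V=np.array(d["V"], dtype=int),
            T=int(d["T"]),
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            labels={k: tuple(v) for k, v in d.get("labels", {}).items()},
        )

    @classmethod
    def from_json(cls, path) -> "GenerativeModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _tmaze_state(loc: int, ctx: int) -> int:
    return 2 * loc + ctx


def build_tmaze(cfg: TMazeConfig | None = None) -> GenerativeModel:
    """Construct the two-step T-maze generative model.

    Eight hidden states (four locations x two contexts), four actions
    (move to middle / left arm / right arm / cue), seven outcomes and a
    horizon of three time steps (the initial state plus two moves).  The
    arms are absorbing; no action changes the context; the cue location
    deterministically reveals the context; arm outcomes are rewarded with
    probability ``p_valid`` when the context matches the arm.

    Policies are the non-redundant two-step action sequences.  Sequences
    that continue from an absorbing arm are behaviourally identical
    regardless of their second action, so each arm-first family collapses
    to a single policy; enumerating all sixteen raw sequences would place
    four-fold prior mass on each gamble.  This leaves ten allowable
    policies (four middle-first, four cue-first, one per arm).
    """
    if cfg is None:
        cfg = TMazeConfig()
    cfg.validate()
    p, q = cfg.p_valid, 1.0 - cfg.p_valid
    n_states, n_outcomes, n_actions, T = 8, 7, 4, 3

    A = np.zeros((n_outcomes, n_states))
    for ctx in range(2):
        A[0, _tmaze_state(0, ctx)] = 1.0  # middle location -> 'middle'
        # left arm: reward w.p. p iff context is L (ctx == 0)
        A[1, _tmaze_state(1, ctx)] = p if ctx == 0 else q
        A[2, _tmaze_state(1, ctx)] = q if ctx == 0 else p
        # right arm: reward w.p. p iff context is R
        A[3, _tmaze_state(2, ctx)] = p if ctx == 1 else q
        A[4, _tmaze_state(2, ctx)] = q if ctx == 1 else p
        # cue location: deterministic, context-true
        A[5 + ctx, _tmaze_state(3, ctx)] = 1.0

    B = np.zeros((n_actions, n_states, n_states))
    for u in range(n_actions):
        for loc in range(4):
            # arms are absorbing; otherwise the action sets the location
            new_loc = loc if loc in (1, 2) else u
            for ctx in range(2):
                B[u, _tmaze_state(new_loc, ctx), _tmaze_state(loc, ctx)] = 1.0

    r, n, m = cfg.utilities
    C_utilities = np.array([m, r, n, r, n, m, m], dtype=float)

    D = np.zeros(n_states)
    D[_tmaze_state(0, 0)] = cfg.context_prior
    D[_tmaze_state(0, 1)] = 1.0 - cfg.context_prior

    V_full = enumerate_policies(n_actions, T - 1)
    # collapse redundant continuations from absorbing arms
    keep = [j for j in range(V_full.shape[1])
            if V_full[0, j] not in (1, 2) or V_full[1, j] == V_full[0, j]]
    V = V_full[:, keep]

    model = GenerativeModel(
        A=A, B=B, C_utilities=C_utilities, D=D, V=V, T=T,
        alpha=2.0, beta=2.0,
        labels={
            "states": TMAZE_STATE_LABELS,
            "outcomes": TMAZE_OUTCOME_LABELS,
            "actions": TMAZE_ACTION_LABELS,
        },
    )
    report = validate_model(model)
    if report:
        raise ModelValidationError("; ".join(report))
    return model


def validate_model(M: GenerativeModel) -> list[str]:
    """Check every structural invariant; return a list of human-readable
    violations (empty iff the model is valid).  Columns are reported
    1-based."""
    problems: list[str] = []
    A, B, D, V = M.A, M.B, M.D, M.V

    if A.ndim != 2:
        problems.append("A must be a 2-D matrix")
        return problems
    if np.any(A < 0):
        problems.append("A has negative entries")
    for j, s in enumerate(A.sum(axis=0)):
        if abs(s - 1.0) > _TOL:
            problems.append(f"A column {j + 1} sums to {s:.12g}, expected 1")

    if B.ndim != 3 or B.shape[1] != B.shape[2] or B.shape[1] != A.shape[1]:
        problems.append("B must be a stack of square matrices matching A's state count")
    else:
        if np.any(B < 0):
            problems.append("B has negative entries")
        for u in range(B.shape[0]):
            for j, s in enumerate(B[u].sum(axis=0)):
                if abs(s - 1.0) > _TOL:
                    problems.append(
                        f"B[{u + 1}] column {j + 1} sums to {s:.12g}, expected 1"
                    )

    if M.C_utilities.shape != (A.shape[0],):
        problems.append("C_utilities length must equal the number of outcomes")
    elif not np.all(np.isfinite(M.C_utilities)):
        problems.append("C_utilities must be finite")

    if D.shape != (A.shape[1],):
        problems.append("D length must equal the number of states")
    else:
        if np.any(D < 0):
            problems.append("D has negative entries")
        if abs(D.sum() - 1.0) > _TOL:
            problems.append(f"D sums to {D.sum():.12g}, expected 1")

    n_actions = B.shape[0] if B.ndim == 3 else 0
    if V.ndim != 2 or V.shape[0] != M.T - 1:
        problems.append("V must have T - 1 rows")
    elif n_actions and (V.min() < 0 or V.max() >= n_actions):
        problems.append(
            f"V contains action indices outside [0, {n_actions})"
        )

    if not M.alpha > 0:
        problems.append(f"alpha must be positive, got {M.alpha}")
    if not M.beta > 0:
        problems.append(f"beta must be positive, got {M.beta}")
    return problems
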