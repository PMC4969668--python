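"""Simulation of Bayes-optimal choice behaviour by expected-free-energy minimization.

Each trial of a finite-horizon POMDP is solved by variational inference:

* per-policy posteriors over hidden-state trajectories, conditioned on the
  outcomes observed so far (exact forward-backward under each policy, which is
  the fixed point of the variational update on a chain);
* the expected free energy ``G(pi)`` of each policy over future time steps —
  risk (KL divergence of predicted from preferred outcomes) plus ambiguity
  (expected outcome entropy given states);
* a Gamma-posterior precision ``gamma_hat`` that scales policy values, found
  by fixed-point iteration jointly with the policy posterior;
* a softmax policy posterior ``q(pi) = softmax(-F(pi) - gamma_hat * G(pi))``
  over policies consistent with the actions already executed, where ``F(pi)``
  accumulates the evidence of past outcomes under the policy;
* action selection from the marginal action probability (argmax by default,
  or sampled when stochastic behaviour is requested).

All logs are floored at ``exp(-16)`` so zero-probability preferences and
observations stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .generative_model import GenerativeModel

__all__ = [
    "BeliefState",
    "TrialRecord",
    "SubjectDataset",
    "DegenerateEvidenceError",
    "PrecisionConvergenceError",
    "infer_states",
    "expected_free_energy",
    "update_precision",
    "policy_posterior",
    "select_action",
    "run_trial",
    "run_session",
]

LOG_FLOOR = np.exp(-16.0)
PRECISION_TOL = 1e-4
PRECISION_MAX_ITER = 16


class DegenerateEvidenceError(ValueError):
    """An observation has zero probability under every policy-consistent state."""


class PrecisionConvergenceError(RuntimeError):
    """The joint (policy, precision) fixed point failed to converge."""


def _log(x):
    return np.log(x + LOG_FLOOR)


def _softmax(v):
    v = np.asarray(v, dtype=float)
    m = v.max()
    e = np.exp(v - m)
    return e / e.sum()


@dataclass
class BeliefState:
    """Posterior beliefs at one moment of a trial.

    ``s_pi_tau[k, tau]`` is the posterior over hidden states at time ``tau``
    under policy ``k``; ``q_pi`` the policy posterior; ``G`` the expected free
    energy per policy (over future time steps); ``F_pi`` the accumulated
    negative log-evidence of past outcomes per policy; ``gamma_hat`` the
    expected precision with posterior Gamma rate ``beta_hat``.
    """

    s_pi_tau: np.ndarray
    q_pi: np.ndarray
    G: np.ndarray
    F_pi: np.ndarray
    gamma_hat: float
    beta_hat: float
    n_iterations: int = 0


@dataclass
class TrialRecord:
    """Observed and latent history of one simulated trial."""

    true_states: list
    observations: list
    actions: list
    belief_trace: list = field(default_factory=list, repr=False)
    precision_trace: list = field(default_factory=list)
    rt_proxy: int = 0
    outcome_utility: float = 0.0


@dataclass
class SubjectDataset:
    """A session of trials from one subject."""

    trials: list
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


# ---------------------------------------------------------------------------
# state estimation


def _policy_trajectories(M: GenerativeModel, observations) -> tuple[np.ndarray, np.ndarray]:
    """Exact smoothing under every policy given a clamped observation prefix.

    Returns ``(s, logev)`` where ``s`` has shape (n_policies, T, n_states)
    with the posterior state marginals, and ``logev[k]`` is the log-evidence
    ``log p(o_1..t | policy k)``.  Observations may cover any prefix of the
    horizon (``None`` entries and missing tail are treated as unobserved).
    """
    T, P, N = M.T, M.n_policies, M.n_states
    obs = list(observations) + [None] * (T - len(observations))

    # forward messages (joint of observed prefix and state), per policy
    fwd = np.zeros((P, T, N))
    like = np.ones((T, N))
    for tau, o in enumerate(obs):
        if o is not None:
            like[tau] = M.A[o]
    fwd[:, 0] = M.D[None, :] * like[0][None, :]
    for tau in range(1, T):
        trans = M.B[M.V[tau - 1]]                      # (P, N, N)
        pred = np.einsum("pij,pj->pi", trans, fwd[:, tau - 1])
        fwd[:, tau] = pred * like[tau][None, :]

    # backward messages
    bwd = np.ones((P, T, N))
    for tau in range(T - 2, -1, -1):
        trans = M.B[M.V[tau]]
        bwd[:, tau] = np.einsum("pij,pi->pj", trans, bwd[:, tau + 1] * like[tau + 1][None, :])

    post = fwd * bwd
    norm = post.sum(axis=2)
    logev = _log(norm[:, -1])
    s = post / np.maximum(norm[..., None], 1e-300)

    # policies under which the observations are impossible get no exact
    # posterior; recompute them with a floored likelihood so every belief
    # slice remains a simplex (they are masked out of q_pi downstream)
    dead = np.flatnonzero(norm.min(axis=1) <= 0)
    if dead.size:
        like_f = like + LOG_FLOOR
        for p in dead:
            f = M.D * like_f[0]
            msgs = [f]
            for tau in range(1, T):
                f = (M.B[M.V[tau - 1, p]] @ f) * like_f[tau]
                msgs.append(f)
            b = np.ones(N)
            s[p, T - 1] = msgs[-1] / msgs[-1].sum()
            for tau in range(T - 2, -1, -1):
                b = M.B[M.V[tau, p]].T @ (b * like_f[tau + 1])
                sl = msgs[tau] * b
                s[p, tau] = sl / sl.sum()
    return s, logev


def infer_states(M: GenerativeModel, observations, policy) -> np.ndarray:
    """Posterior over hidden states at each time step under one policy.

    ``observations`` is a prefix of outcome indices (length <= T);
    ``policy`` supplies the T - 1 actions.  Returns a (T, n_states) array of
    simplexes.  Raises :class:`DegenerateEvidenceError` if the observation
    sequence is impossible under the policy.
    """
    policy = np.asarray(policy, dtype=int).reshape(M.T - 1, 1)
    sub = M.with_fields(V=policy)
    s, logev = _policy_trajectories(sub, observations)
    if not np.isfinite(logev[0]) or logev[0] <= np.log(LOG_FLOOR):
        raise DegenerateEvidenceError(
            "observations have zero probability under this policy"
        )
    return s[0]


# ---------------------------------------------------------------------------
# expected free energy and precision


def expected_free_energy(M: GenerativeModel, s_pi_tau: np.ndarray, t: int = 0) -> np.ndarray:
    """Expected free energy per policy, summed over future time steps.

    ``G(pi) = sum_{tau > t} KL(A s_pi_tau || exp(C)) + sum_j s_pi_tau(j) H(A_:,j)``
    where ``H`` is the Shannon entropy of column ``j`` of ``A``.  Non-negative
    up to the numerical log floor (clipped at zero).
    """
    C = M.C
    H = -(M.A * _log(M.A)).sum(axis=0)             # ambiguity per state
    G = np.zeros(s_pi_tau.shape[0])
    for tau in range(t + 1, M.T):
        s = s_pi_tau[:, tau, :]                    # (P, N)
        qo = s @ M.A.T                             # predicted outcomes (P, O)
        risk = (qo * (_log(qo) - C[None, :])).sum(axis=1)
        G += risk + s @ H
    return np.maximum(G, 0.0)


def update_precision(alpha: float, beta: float, G, q_pi) -> tuple[float, float]:
    """One precision update: ``beta_hat = beta + E_q[G]``, ``gamma_hat =
    alpha / beta_hat``.  Expected precision falls as prospects worsen and is
    bounded above by the prior mean ``alpha / beta``."""
    G = np.asarray(G, dtype=float)
    q = np.asarray(q_pi, dtype=float)
    beta_hat = beta + float(q @ G)
    return beta_hat, alpha / beta_hat


def policy_posterior(F_pi, G, gamma_hat, mask=None) -> np.ndarray:
    """Gibbs posterior over policies, ``softmax(-F_pi - gamma_hat * G)``,
    restricted to ``mask`` (policies consistent with executed actions)."""
    v = -np.asarray(F_pi, dtype=float) - gamma_hat * np.asarray(G, dtype=float)
    if mask is not None:
        v = np.where(mask, v, -np.inf)
    m = v.max()
    e = np.exp(v - m)
    return e / e.sum()


def select_action(q_pi, V, t: int) -> int:
    """Most probable next action: the argmax of the marginal action
    probability ``P(u) = sum_{pi : V[t, pi] = u} q_pi(pi)``, ties broken by
    the lowest action index."""
    P_u = action_marginal(q_pi, V, t)
    return int(np.argmax(P_u))


def action_marginal(q_pi, V, t: int, n_actions: int | None = None) -> np.ndarray:
    """Marginal probability of each action at decision point ``t``."""
    V = np.asarray(V, dtype=int)
    q = np.asarray(q_pi, dtype=float)
    if n_actions is None:
        n_actions = int(V.max()) + 1
    P_u = np.zeros(n_actions)
    np.add.at(P_u, V[t], q)
    return P_u


# ---------------------------------------------------------------------------
# trial engine


def evaluate_beliefs(M: GenerativeModel, observations, executed_actions, t: int) -> BeliefState:
    """Full belief update at time ``t``: state posteriors, policy posterior
    and precision, conditioned on the outcome prefix and the actions already
    executed.

    The (q_pi, gamma_hat) pair is iterated to a joint fixed point; failure to
    converge within 16 iterations raises :class:`PrecisionConvergenceError`.
    """
    s, logev = _policy_trajectories(M, observations)
    F_pi = -logev

    mask = np.ones(M.n_policies, dtype=bool)
    for i, a in enumerate(executed_actions):
        mask &= M.V[i] == a
    mask &= np.isfinite(F_pi) & (logev > np.log(LOG_FLOOR) + 1e-12)
    if not mask.any():
        raise DegenerateEvidenceError(
            "observed outcomes are impossible under every policy consistent "
            "with the executed actions"
        )

    G = expected_free_energy(M, s, t=t)

    gamma_hat = M.alpha / M.beta
    beta_hat = M.beta
    q_pi = policy_posterior(F_pi, G, gamma_hat, mask)
    n_iter = 0
    # the convergence contract is |d gamma| < 1e-4 within 16 iterations; the
    # iteration then continues to numerical precision so that downstream
    # likelihoods are smooth functions of the hyperparameters
    for k in range(1, 4 * PRECISION_MAX_ITER + 1):
        beta_hat, gamma_new = update_precision(M.alpha, M.beta, G, q_pi)
        q_pi = policy_posterior(F_pi, G, gamma_new, mask)
        delta = abs(gamma_new - gamma_hat)
        gamma_hat = gamma_new
        if n_iter == 0 and delta < PRECISION_TOL:
            n_iter = k
        if delta < 1e-12:
            break
    if n_iter == 0 or n_iter > PRECISION_MAX_ITER:
        raise PrecisionConvergenceError(
            f"precision fixed point did not converge within {PRECISION_MAX_ITER} iterations"
        )

    return BeliefState(
        s_pi_tau=s, q_pi=q_pi, G=G, F_pi=F_pi,
        gamma_hat=gamma_hat, beta_hat=beta_hat, n_iterations=n_iter,
    )


def run_trial(
    M: GenerativeModel,
    initial_state: int,
    rng: np.random.Generator,
    stochastic_actions: bool = False,
) -> TrialRecord:
    """Simulate one trial from ``initial_state``.

    Per time step: sample the outcome from the likelihood column of the true
    state, update all policy-conditioned beliefs and precision, then select
    and execute the next action (argmax of the marginal action probability by
    default; sampled from it when ``stochastic_actions``).  ``rt_proxy``
    records the number of precision fixed-point iterations at the first
    decision point, a hardware-independent proxy for choice conflict.
    """
    s_true = int(initial_state)
    rec = TrialRecord(true_states=[], observations=[], actions=[])
    for t in range(M.T):
        rec.true_states.append(s_true)
        o = int(rng.choice(M.n_outcomes, p=M.A[:, s_true]))
        rec.observations.append(o)

        belief = evaluate_beliefs(M, rec.observations, rec.actions, t)
        rec.belief_trace.append(belief)
        rec.precision_trace.append(belief.gamma_hat)
        if t == 0:
            rec.rt_proxy = belief.n_iterations

        if t < M.T - 1:
            P_u = action_marginal(belief.q_pi, M.V, t, M.n_actions)
            if stochastic_actions:
                u = int(rng.choice(M.n_actions, p=P_u / P_u.sum()))
            else:
                u = int(np.argmax(P_u))
            rec.actions.append(u)
            s_true = int(rng.choice(M.n_states, p=M.B[u][:, s_true]))

    rec.outcome_utility = float(M.C[rec.observations[-1]])
    return rec


def run_session(
    M: GenerativeModel,
    n_trials: int,
    rng: np.random.Generator,
    context_sequence=None,
    stochastic_actions: bool = False,
) -> SubjectDataset:
    """Simulate a session of trials.

    Each trial starts from the middle location with the context drawn 50/50
    (or taken from ``context_sequence``, entries 0 = reward-left,
    1 = reward-right).  Initial states are mapped through the T-maze state
    convention (state = 2 * location + context with location 0 = middle).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if context_sequence is None:
        contexts = rng.integers(0, 2, size=n_trials)
    else:
        contexts = np.asarray(context_sequence, dtype=int)
        if len(contexts) != n_trials:
            raise ValueError("context_sequence length must equal n_trials")
    trials = [
        run_trial(M, int(ctx), rng, stochastic_actions=stochastic_actions)
        for ctx in contexts
    ]
    return SubjectDataset(
        trials=trials,
        meta={"n_trials": n_trials, "stochastic_actions": stochastic_actions},
    )
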