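"""File formats and configuration shared by all pipeline stages.

Artifacts are diff-able text: JSON for models and posteriors, CSV for trial
data, YAML for run configurations (UTF-8, LF line endings).  Every writer
embeds the seed and a configuration hash for provenance.  The formats are
documented in FORMATS.md at the repository root.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .active_inference import SubjectDataset, TrialRecord
from .subject_inversion import SubjectPosterior

__all__ = [
    "RunConfig",
    "SessionFormatError",
    "config_hash",
    "write_session",
    "read_session",
    "write_posterior",
    "read_posterior",
]

SESSION_COLUMNS = [
    "trial",
    "time_step",
    "true_state",
    "observation",
    "action",
    "gamma_hat",
    "rt_proxy",
    "outcome_utility",
]


class SessionFormatError(ValueError):
    """A session CSV does not match the documented contract."""


@dataclass(frozen=True)
class RunConfig:
    """Stage defaults serialized into every output artifact."""

    seed: int = 1
    fields: tuple = ("beta", "c_scale")
    prior_mean: float = 0.0
    prior_variance: float = 1.0 / 16.0
    within_between_ratio: float = 16.0
    inversion_tolerance: float = 1e-3
    n_trials: int = 128
    n_per_group: int = 8
    group_difference: float = 0.25
    between_subject_log_precision: float = 4.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fields"] = list(self.fields)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "fields" in d:
            d["fields"] = tuple(d["fields"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# session CSV


def write_session(dataset: SubjectDataset, path) -> None:
    """Write a session to CSV: one row per (trial, time step), deterministic
    order; the action column is -1 at the final time step of each trial."""
    rows = []
    for i, tr in enumerate(dataset):
        for t in range(len(tr.observations)):
            rows.append(
                {
                    "trial": i,
                    "time_step": t,
                    "true_state": tr.true_states[t],
                    "observation": tr.observations[t],
                    "action": tr.actions[t] if t < len(tr.actions) else -1,
                    "gamma_hat": tr.precision_trace[t]
                    if t < len(tr.precision_trace)
                    else np.nan,
                    "rt_proxy": tr.rt_proxy,
                    "outcome_utility": tr.outcome_utility,
                }
            )
    df = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_session(path) -> SubjectDataset:
    """Read a session CSV back into a :class:`SubjectDataset`.

    Integer columns round-trip losslessly and floats to full precision.
    Raises :class:`SessionFormatError` on a missing column, a malformed row,
    or an empty file.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SessionFormatError(f"{path}: empty session file") from None
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise SessionFormatError(f"{path}: session contains no trials")
    for col in ["trial", "time_step", "true_state", "observation", "action"]:
        if not np.issubdtype(df[col].dtype, np.integer):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise SessionFormatError(
                f"{path}: non-integer value in column {col!r} near line {line}"
            )

    trials = []
    for _, g in df.groupby("trial", sort=True):
        g = g.sort_values("time_step")
        actions = [int(a) for a in g["action"].tolist() if a >= 0]
        trials.append(
            TrialRecord(
                true_states=[int(s) for s in g["true_state"]],
                observations=[int(o) for o in g["observation"]],
                actions=actions,
                precision_trace=[float(x) for x in g["gamma_hat"]],
                rt_proxy=int(g["rt_proxy"].iloc[0]),
                outcome_utility=float(g["outcome_utility"].iloc[0]),
            )
        )
    return SubjectDataset(trials=trials, meta={"source": str(path)})


# ---------------------------------------------------------------------------
# posterior JSON


def write_posterior(post: SubjectPosterior, path, seed=None, config=None) -> None:
    payload = {
        "Ep": np.asarray(post.Ep).tolist(),
        "Cp": np.asarray(post.Cp).tolist(),
        "F": post.F,
        "field_names": list(post.field_names),
        "pE": np.asarray(post.pE).tolist() if post.pE is not None else None,
        "pC": np.asarray(post.pC).tolist() if post.pC is not None else None,
        "converged": bool(post.converged),
        "n_iterations": int(post.n_iterations),
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_posterior(path) -> SubjectPosterior:
    with open(path, "r", encoding="utf-8") as fh:
        d = json.load(fh)
    return SubjectPosterior(
        Ep=np.array(d["Ep"], dtype=float),
        Cp=np.array(d["Cp"], dtype=float),
        F=float(d["F"]),
        field_names=tuple(d["field_names"]),
        pE=np.array(d["pE"], dtype=float) if d.get("pE") is not None else None,
        pC=np.array(d["pC"], dtype=float) if d.get("pC") is not None else None,
        converged=bool(d.get("converged", True)),
        n_iterations=int(d.get("n_iterations", 0)),
    )
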