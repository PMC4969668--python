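# File formats

All artifacts are plain text, UTF-8, LF line endings.

## Model JSON (`actinf model build-tmaze`, `GenerativeModel.to_json`)

Keys (canonical sorted order, `schema_version: 1`):

- `A` — likelihood matrix, row-major nested arrays (`n_outcomes x n_states`,
  column-stochastic);
- `B` — array of `n_actions` transition matrices (`n_states x n_states`,
  column-stochastic);
- `C_utilities` — raw outcome utilities (log-preferences before
  normalization);
- `D` — prior over initial hidden states (simplex);
- `V` — allowable policies, `(T - 1) x n_policies` action indices;
- `T`, `alpha`, `beta` — horizon and Gamma precision hyperparameters;
- `labels` — optional state/outcome/action names.

## Session CSV (`actinf simulate`, `write_session`/`read_session`)

One header line, one row per `(trial, time_step)`, deterministic order:

| column | meaning |
| --- | --- |
| `trial` | 0-based trial index |
| `time_step` | 0-based time step within the trial |
| `true_state` | hidden-state index actually occupied |
| `observation` | outcome index observed |
| `action` | action chosen at this step; `-1` at the final step |
| `gamma_hat` | expected precision after the belief update |
| `rt_proxy` | precision fixed-point iterations at the first decision |
| `outcome_utility` | normalized log-preference of the trial's final outcome |

Integer columns round-trip losslessly; floats to 1e-12.

## Subject posterior JSON (`actinf invert`, `write_posterior`)

`Ep` (posterior mean per parameter), `Cp` (posterior covariance),
`F` (free-energy bound on the log-evidence), `field_names`, `pE`/`pC`
(prior mean/covariance), `converged`, `n_iterations`, `seed`,
`config_hash` (provenance).

## Design CSV (`actinf peb`, `actinf loo`)

Columns `subject_id, group`; rows in the same order as the subject posterior
files; `group` takes exactly two levels (first level maps to +1, second to
-1 in the design matrix).

## PEB / LOO JSON

`peb.json`: `Ep2`, `Cp2`, `group_gap` (+1-group minus -1-group level of the
modelled parameter), `group_gap_sd`, `F2`, `model_posteriors` over
`{full, mean-only, difference-only, null}`, `t_statistic`, `p_value`.

`loo.json`: per-subject `group_prob` (posterior probability of the first
group), `predictive_expectation` (`2p - 1`), `true_indicator`, summary
`correlation` and `accuracy`.

## Run configuration YAML

Field-for-field mirror of `actinf.io.RunConfig`; consumed by the demo and
embedded (hashed) in output artifacts.
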