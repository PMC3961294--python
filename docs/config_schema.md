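# Configuration schema

Flat `key = value` text files; `#` starts a comment.  Every model
symbol has exactly one key whose suffix states its unit.  Unknown keys
are rejected by name; a known symbol with the wrong unit suffix is a
hard error; missing keys fall back to the nominal values (logged).

## Model parameters

| key | symbol | unit | nominal | meaning |
|---|---|---|---|---|
| `q_max_per_s` | Q_max | s^-1 | 100 | maximal population firing rate |
| `theta_mV` | theta | mV | 10 | mean firing threshold |
| `sigma_prime_mV` | sigma' | mV | 3 | firing-threshold spread |
| `nu_vm_mVs` | nu_vm | mV s | -2.1 | MA -> VLPO inhibition |
| `nu_mv_mVs` | nu_mv | mV s | -1.8 | VLPO -> MA inhibition |
| `nu_ov_mVs` | nu_ov | mV s | -1.0 | VLPO -> Orx inhibition |
| `nu_mo_mVs` | nu_mo | mV s | 0.30 | Orx -> MA excitation (0 = orexin removed) |
| `nu_om_mVs` | nu_om | mV s | 0 | MA -> Orx weight (neglected) |
| `nu_vc_mV` | nu_vc | mV | -0.30 | circadian input to VLPO |
| `nu_vh_mV` | nu_vh | mV per H unit | 1.0 | homeostatic input to VLPO |
| `nu_oc_mV` | nu_oc | mV | 1.0 | circadian input to Orx |
| `nu_oh_mV` | nu_oh | mV per H unit | 0 | homeostatic input to Orx (neglected) |
| `a_v_mV` | a_v | mV | -8.5 | constant external drive to VLPO |
| `a_m_mV` | a_m | mV | 0.52 | constant external drive to MA |
| `a_o_mV` | a_o | mV | 1.0 | constant external drive to Orx |
| `phase_ref_h` | t_acro | h (clock) | 15.0 | clock time of the circadian maximum |
| `chi_h` | chi | h | 45 | homeostatic clearance time constant |
| `mu_H` | mu | H units | 17 | homeostatic production supremum |
| `q_sat_per_s` | q_sat | s^-1 | 2.3 | production saturation rate scale |
| `tau_v_s` | tau_v | s | 10 | VLPO relaxation time |
| `tau_m_s` | tau_m | s | 10 | MA relaxation time |
| `tau_o_s` | tau_o | s | 120 | Orx relaxation time (sleep-inertia timescale) |
| `sigma_v_mV` | sigma_v | mV | 1 | VLPO noise SD |
| `sigma_m_mV` | sigma_m | mV | 1 | MA noise SD |
| `noise_convention` | — | — | `white-noise-density` | EM discretization rule (`white-noise-density` or `per-step`) |

The circadian angular frequency is fixed at `2*pi/24 h` (an invariant,
not a key).

## Scenario keys

| key | default | meaning |
|---|---|---|
| `duration_days` | 25 | retained simulation length |
| `equilibration_days` | 3 | discarded lead-in |
| `seed` | 0 | master RNG seed |
| `dt_s` | 0.1 | Euler–Maruyama step |
| `noise` | 1 | 0 disables noise (adaptive deterministic solver) |
| `init` | `awake` | initial-state preset (`awake` / `asleep`) |
| `record_dt_s` | 1.0 | trajectory reporting grid |
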