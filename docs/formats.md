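# File formats

## Dataset directory (written by `eewalk simulate` / `datasets.save_dataset`)

```
<dataset>/
  manifest.json
  imu/<trial_id>_<location>.csv
  breath/<trial_id>.csv
```

### `imu/*.csv`

One row per sample, SI units, header exactly:

| column | meaning                       |
|--------|-------------------------------|
| `t_s`  | sample time, s                |
| `ax`, `ay`, `az` | acceleration, m/s²  |
| `gx`, `gy`, `gz` | angular rate, rad/s |

### `breath/*.csv`

| column         | meaning                 |
|----------------|-------------------------|
| `t_s`          | breath time, s          |
| `vo2_ml_min`   | oxygen uptake, mL/min   |
| `vco2_ml_min`  | CO₂ output, mL/min      |

### `manifest.json`

```json
{
  "subjects": [{"id": "S01", "weight_kg": 72.8, "height_m": 1.73}],
  "trials": [{
    "id": "S01_level_walk_4kph",
    "subject": "S01",
    "activity": "level_walk | incline_walk | level_run",
    "speed_kph": 4.0,
    "incline_pct": 0.0,
    "duration_s": 600.0,
    "standing_margin_s": 60.0,
    "imu_files": {"shank": "imu/S01_level_walk_4kph_shank.csv"},
    "breath_file": "breath/S01_level_walk_4kph.csv",
    "latent_ee_w": 251.84,
    "ee_truth_w": 251.71
  }],
  "config_hash": "…",
  "config": {}
}
```

`latent_ee_w` is the simulator's exact plateau (absent for real data);
`ee_truth_w` is the steady-state ground truth extracted from the breath
file.

## Window / stride container (`WindowSet.save`)

A single `.npz` with arrays `x` (N×L×6 float32), `y` (N), `features`
(N×2: weight kg, height m) plus a sidecar `<name>.npz.meta.json` holding
`scaled` and the per-row `subject`/`trial`/`location` metadata.  Stride
sets use the same container with L = 30.

## Model file (`models.save_model`)

A single `.npz`: `header` (JSON as bytes: architecture kind, input length,
hyperparameters, init seed, captured scalers) plus one array per
parameter under `param/…` keys.  `models.load_model` rebuilds the network
and restores predictions exactly.

## Train log (`eewalk train`)

CSV `epoch,lr,train_mse` with one row per epoch; `train_mse` is in
normalized target units.

## Evaluation report (`eewalk evaluate`)

`report.csv`: flat rows
`dataset,location,arch,seq_s,fs_hz,fold,nrmse_w_kg,mape_pct,n_predictions`.
`report.json`: the same rows plus per-cell means and any failed-cell
records.  `config.json`: the grid configuration and its hash.
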