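# cyclenoise

Noise analysis of cell-cycle-coupled bursty gene expression.

A cell traverses `n` sequential cycle stages (exponential sojourns with
rates `λ_i`); a stable protein is produced in instantaneous bursts whose
Poisson arrival rate `k_i` depends on the stage; at division the copy
number is randomly partitioned between daughters (conditional mean `x/2`,
conditional variance `αx/4`). The package computes the steady-state mean
and the intrinsic noise of the protein level — corrected for
cell-cycle-driven fluctuations — through three independent routes:

- **`cyclenoise.analytics`** — exact closed forms for the mean, the
  per-stage conditional means, the regulation parameter `β` (with its
  attainable bounds), and the noise decomposed into bursty-synthesis and
  partitioning-error terms.
- **`cyclenoise.moment_solver`** — the closed linear moment-ODE system
  (stage indicators close the moment hierarchy exactly), solved directly
  for the steady state or integrated in time; an independent oracle for
  the closed forms.
- **`cyclenoise.simulator`** — exact event-driven single-lineage
  simulation (no time discretization), including the paired deterministic
  process `y(t)`, the corrected process `z = x − y`, a two-colour mode,
  optional protein degradation, and an extended promoter/mRNA model with
  cell-cycle-duration memory.
- **`cyclenoise.strategies`** — fixed-mean comparison of regulation
  strategies (start-only, midpoint, constant, duplication, end-only),
  `(T1/T, f)` step-profile scans, and `β` extremization.

## CLI

All commands share one YAML/JSON config schema:

```yaml
n_stages: 20
mean_cycle_time_h: 2     # or explicit lambdas: [...]
strategy: {name: constant, k: 1}   # or explicit ks: [...]
burst: {kind: geometric1, mean: 4}
alpha: 1                 # partitioning-error parameter
seed: 0
```

```sh
cyclenoise analytic  --config model.yaml --out summary.json
cyclenoise moments   --config model.yaml --out moments.json
cyclenoise simulate  --config model.yaml --cycles 5000 --burn-in 50 \
                     --seed 1 --out traj.tsv --summary summary.json
cyclenoise strategies --config model.yaml --target-mean 150 --out table.csv
cyclenoise scan      --config model.yaml --t1-grid 0.05:0.95:19 \
                     --f-grid 1:50:25 --out grid.csv
```

Validation problems exit with code 2. Outputs embed the seed and the
fully resolved configuration; a fixed config + seed reproduces outputs
byte for byte.

## Library example

```python
import cyclenoise as cn

cycle = cn.make_cell_cycle(20, 2.0)           # 20 stages, 2 h mean cycle
model = cn.ModelSpec(
    cycle=cycle,
    regulation=cn.make_strategy("constant", 1.0, cycle),
    burst=cn.BurstModel.geometric1(4.0),
    partition=cn.PartitionModel.from_alpha(1.0),
)
model = cn.calibrate_rate(model, target_mean=150.0)

summary = cn.noise_decomposition(model)       # closed form
state = cn.steady_state(cn.build_system(model))   # moment-ODE route
traj = cn.simulate_lineage(model, n_cycles=5000, burn_in_cycles=50, seed=1)
stats = cn.estimate_stats(traj, burn_in_cycles=50)
```

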