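# patchforage

Simulation and analysis of continuous three-patch variable-interval (VI)
foraging with reliability-controlled dynamic visual cues.

In this task a forager moves freely among three reward patches. Each patch
delivers reward on its own VI schedule: after every button press a fresh
reward-availability interval λᵢ is drawn, and a press is rewarded iff the
time elapsed since the previous press at that patch is at least λᵢ. Patch
quality is set by the mean interval — 7 s (fast), 14 s (medium), 21 s
(slow). Two schedule laws are supported:

* **exponential** — f(λ) = μⱼ e^(−μⱼλ) with μⱼ = 1/mean. The hazard is
  constant, so elapsed time carries no information and a premature reset is
  statistically free (memorylessness).
* **gamma** — f(λ; a, bⱼ) with shape a = 10 and rate bⱼ = a/mean. The hazard
  increases with elapsed time, so premature presses discard accumulated
  progress and are costly.

Each patch's state is signaled by a dynamic 1/f texture whose spatial-mean
color encodes a cue variable X(t) ∈ [0, 1] — the availability probability
1 − e^(−μⱼΔt) under the exponential schedule, or the normalized progression
min(Δt/λᵢ, 1) under the gamma schedule. X is mapped to a phase angle
θ = θ_min + (θ_max − θ_min)X and injected into the texture spectrum as
κ e^{iθ}; the concentration κ controls how reliably the cue can be read out
against the texture.

The package is for behavioral/computational neuroscientists who want to (a)
generate synthetic foraging sessions with controlled schedule and
reliability structure, (b) run the standard analysis battery on press-event
logs (their own or simulated), and (c) render or decode the cue stimulus.
It contains:

* `patchforage.schedules` — interval sampling, hazard, cue and press/reset
  semantics for both variants;
* `patchforage.stimulus` — scale-invariant dynamic texture synthesis
  (AR(1) Fourier coefficients under a 1/f envelope, Hermitian-symmetric),
  phase encoding, CIE-Luv color mapping, and a circular-mean phase decoder;
* `patchforage.agents` — synthetic foragers (random, cue-threshold,
  rate-matching) that emit press-event logs;
* `patchforage.metrics` — push fractions and Spearman correlation with
  quality rank, inter-push-interval (IPI) distributions, transition
  matrices, visit segmentation with stay/return times normalized by a
  rate-matched null model, continuous push rate, and time-resolved
  windowed allocation;
* `patchforage.io` / `patchforage.cli` — the event-log CSV format, YAML
  run configuration, and the `patchforage` command-line tool.

## Worked example

Simulate twenty 15-minute gamma-variant blocks with a cue-threshold agent
under high cue reliability (κ = 4) and run the core analyses:

```python
import numpy as np
import patchforage as pf
from patchforage.metrics import (push_fraction, quality_rank_spearman,
                                 transition_matrix, ipi_distribution,
                                 pooled_normalized_stay_return)

agent = pf.AgentSpec("cue_threshold")
logs = [pf.run_session(pf.SessionConfig(variant=pf.Variant.GAMMA,
                                        kappa=4.0, seed=s), agent)
        for s in range(20)]

rho = quality_rank_spearman([push_fraction(lg) for lg in logs])
print(f"pooled Spearman rho = {rho.rho:.3f} (n = {rho.n})")

counts = sum(transition_matrix(lg).counts for lg in logs)
print("self-transitions:", np.round(np.diag(counts / counts.sum(1, keepdims=True)), 3))
print(f"P(->fast | not fast) = {counts[1:,0].sum()/counts[1:,:].sum():.3f}")

for p in pf.PatchId:
    med = np.median(np.concatenate([ipi_distribution(lg, p).intervals for lg in logs]))
    print(f"median IPI {p.value}: {med:.1f} s")
```

Output:

```
pooled Spearman rho = 0.943 (n = 60)
self-transitions: [0.253 0.01  0.001]
P(->fast | not fast) = 0.731
median IPI fast: 10.2 s
median IPI med: 16.8 s
median IPI slow: 22.6 s
```

Reading the numbers: the agent allocates presses in quality order (pooled ρ
at the tie-corrected ceiling of 0.943 for perfectly ordered blocks, with
n = 3 patches × 20 blocks = 60 observations). Under the increasing-hazard
gamma schedule it almost never presses the same patch twice in a row
(self-transitions 0.25/0.01/0.00 for fast/medium/slow), switches are
directed predominantly toward the fast patch (0.73), and the per-patch
median IPIs track the 7/14/21-s schedule means, since pressing early would
reset a nearly ripe interval.

The same workflow is available from the shell:

```sh
patchforage simulate --variant gamma --kappa 4 --blocks 20 --seed 1 --out events.csv
patchforage analyze --logs events.csv --null-reps 1000 --seed 2 --out analysis/
patchforage stimulus render --kappa 4 --size 128 --frames 100 --seed 3 --out frames/
patchforage run --config experiment.yaml
```

## Documentation

Model assumptions, parameter choices, numerical conventions, and known
limitations are documented in [`docs/methods.md`](docs/methods.md).
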