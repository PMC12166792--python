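# nanolock

Image-based 3D active sample stabilization for widefield microscopy, with a
built-in virtual microscope so the whole feedback loop runs and is testable
without hardware.

Long microscopy acquisitions — single-molecule localization in particular —
are limited by sample drift of tens to hundreds of nanometers per hour.
`nanolock` implements the computation behind an active stabilization unit:
a camera images a static reference structure (holey carbon film, immobilized
beads, a calibration tile target), per-axis displacements from a setpoint
are estimated against pre-acquired reference stacks, and a feedback
controller actuates a piezo stage to hold the sample in place at the
nanometer scale.

## Method

At engagement a **setpoint frame** is saved, then a **reference stack** is
acquired per axis by stepping the stage over a symmetric range (default
±100 nm, 20 nm steps).  Every loop iteration the current frame is matched
against each stack plane:

- lateral: cross-correlation `CC(a,b) = Σᵢⱼ aᵢⱼ·bᵢⱼ` of intensity-normalized
  frames;
- axial: mean squared error `MSE(a,b) = (1/n)·Σᵢ(aᵢ−bᵢ)²` of sorted
  pixel-intensity profiles, whose shape varies smoothly with defocus.

The per-plane curve is min–max scaled (MSE inverted first) and a Gaussian
`A·exp(−(u−µ)²/2w²)+c` is fitted; the center µ, converted through the stack
step, is the displacement.  Errors are referenced to the setpoint frame (not
the stack centers), canceling drift accumulated during stack acquisition.
Corrections follow a discrete PI law with a small second-order integrator:

    u = −(kp·e + ki·Σe + kii·ΣΣe)

Staircase calibration (±20 nm open-loop steps), step-response fitting
(`α·e^(−(t−t0)/τ)`), rolling stability statistics, and rms drift-reduction
factors are provided in `nanolock.analysis`.  See `docs/methods.md` for the
full model description and design rationale.

## Worked example

```python
import numpy as np
from nanolock import (
    AxisStackConfig, ControllerGains, DriftModel, NoiseModel,
    VirtualMicroscope, VirtualScene, engage, run_closed_loop, stability_stats,
)

scene = VirtualScene(pattern="holey_carbon", seed=1)       # 2 µm holes / 2 µm spacing
mic = VirtualMicroscope(
    scene,
    noise=NoiseModel(seed=11),                             # ~70% sensor fill
    drift=DriftModel.linear((0.5, 0.5, 0.5)),              # nm per iteration
    start_position_nm=(0, 0, 2000.0),                      # 2 µm working defocus
    seed=3,
)
cfgs = {ax: AxisStackConfig(axis=ax) for ax in "xyz"}      # ±100 nm, 20 nm steps
stacks, setpoint, state = engage(mic, cfgs)
records = run_closed_loop(mic, stacks, setpoint, ControllerGains(), 400, state=state)

errs = np.array([r.error_nm for r in records])
print("median |e| (final quartile):", np.round(np.median(np.abs(errs[300:]), 0), 3))
print("in-loop sigma (nm):", np.round(stability_stats(records[100:], window=100).sigma_nm, 3))
```

Output:

```
median |e| (final quartile): [0.127 0.169 0.383]
in-loop sigma (nm): [0.2   0.238 0.596]
```

The loop holds the drifting sample at the setpoint to a few tenths of a
nanometer per axis (under these simulated conditions), while without
feedback the same drift would accumulate to 200 nm over the run — a
rejection factor of well over 100.

The same pipeline is available from the shell:

```bash
nanolock run-loop  --config cfg.yaml --iters 400 --log run.jsonl
nanolock staircase --config cfg.yaml --axis x --no-feedback --log stair.jsonl
nanolock calibrate --log stair.jsonl --report cal.json
nanolock analyze   --log run.jsonl --report report.json
```

Logs are JSONL with the fully resolved config and seeds embedded in the
header line, so any run is exactly reproducible from its own log.

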