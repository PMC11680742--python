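# ktpulse

Parallel-transmit (pTx) kT-points RF pulse design that homogenizes the
flip angle **and** the root-mean-squared transmit field (B1rms)
simultaneously, plus the dual-flip-angle R1-mapping pipeline whose
magnetization-transfer (MT) bias the design controls.  Everything runs on
a bundled synthetic 8-channel head phantom; no scanner data is needed.

## The problem

At ultra-high field (7T) the transmit field B1+ is spatially
inhomogeneous.  pTx pulse designs usually homogenize only the flip angle
α of the free-water magnetization.  But biological tissue also contains a
semisolid proton pool whose longitudinal magnetization is saturated at a
rate set by the *sequence B1rms* β through its absorption lineshape g:

    W = π g(Δ) (γ β)²

Exchange with the free pool (magnetization transfer) then makes the
apparent longitudinal rate depend on β:

    R̂1 = R1f + k_fs (1 − k_sf / (R1s + k_sf + W)) .

A pulse optimized for α alone leaves β uncontrolled and spatially
variable, which biases variable-flip-angle R1 maps with a spatial shading
that tracks the β map.

## The method

`ktpulse` designs kT-points pulses (N rectangular subpulses interleaved
with gradient blips) by minimizing the dual cost

    (1 − λ) ‖α(b, g) − α_des‖²_W / ‖α_des‖²_W
      + λ ‖β(b) − β_des‖²_W / ‖β_des‖²_W

over per-channel complex subpulse amplitudes **b** and blip moments
**g**, subject to local (VOP) and global SAR, per-channel average power,
peak voltage, and gradient amplitude/slew limits, using SLSQP with
analytic gradients and a seeded multi-start.  λ = 0 is a conventional
flip-angle (FA) design, λ = 1 a pure-B1rms design, and intermediate λ the
hybrid (HY) design.  Feasible targets obey the analytic bound

    β_min = √p2 · α_des / (γ p1 √(TR·τ)) ,

where p1 and p2 are the mean and mean-square of the unit-normalized RF
envelope; the default targets use β_des = 1.2 β_min.

Ground truth for validation comes from a hard-pulse Bloch simulator and a
binary spin-bath (two-pool) spoiled gradient-echo steady state, and R1 is
fitted voxelwise with the linearized dual-flip-angle regression using the
Bloch-simulated flip angles.

## Worked example

```python
import numpy as np
from ktpulse import (PhantomConfig, SafetyConfig, DesignSpec,
                     SequenceTiming, generate_phantom,
                     generate_safety_model, hybrid_design, kt_beta_min)

setup, tissue = generate_phantom(PhantomConfig(seed=1))
safety = generate_safety_model(SafetyConfig(seed=2), setup)
timing = SequenceTiming()                      # 5 x 200 us + 100 us blips, TR 8 ms
alpha = np.deg2rad(15.0)
beta = 1.2 * kt_beta_min(alpha, timing)        # 0.415 uT
for lam in (0.0, 0.5, 1.0):
    spec = DesignSpec(alpha_des=alpha, beta_des=beta, lam=lam,
                      n_starts=5, seed=7)
    res = hybrid_design(setup, safety, spec, timing)
    print(f"lam={lam}: NRMSE(alpha)={res.nrmse_alpha:.4f} "
          f"NRMSE(beta)={res.nrmse_beta:.4f}")
```

prints

```
lam=0.0: NRMSE(alpha)=0.0120 NRMSE(beta)=0.3041
lam=0.5: NRMSE(alpha)=0.0163 NRMSE(beta)=0.0159
lam=1.0: NRMSE(alpha)=0.3754 NRMSE(beta)=0.0117
```

i.e. the flip-angle-only design leaves a 30% B1rms error, the pure-B1rms
design a 38% flip-angle error, while the hybrid design holds both below
2%.  The full desk-scale protocol (phantom → designs at 3° and 15° →
SPGR simulation → R1 fit → report):

```bash
ktpulse run --seed 1 --out results/run
ktpulse sweep --out results/sweep.csv      # beta_des x lambda trade-off table
```

The run report tabulates per-tissue R1 mean ± SD and the spatial
coefficient of variation (CoV); with the default phantom the
white-matter CoV of the fitted R1 map is an order of magnitude smaller
with HY pulses than with FA pulses, and the FA-pulse R1 map correlates
strongly (|r| > 0.9) with its uncontrolled B1rms map.

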