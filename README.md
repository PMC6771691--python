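# bsmap — Bloch-Siegert B1⁺ mapping with multi-echo GLM estimation

Quantitative MRI (e.g. variable-flip-angle R₁ mapping) needs accurate maps of
the transmit radiofrequency field B1⁺. Bloch-Siegert-shift (BSS) mapping
measures B1⁺ through the phase Φ_BSS that an off-resonance RF pulse imparts on
transverse magnetization,

    Φ_BSS = B₁ₚ² ∫₀ᵀ (γ B₁ⁿᵒʳᵐ(t))² / (2 ω_off) dt ,   B₁ₚ = √(Φ_BSS / K_BSS),

by subtracting the phase of two acquisitions with opposite pulse offsets
(±ω_off). Interleaving the two offsets TR-by-TR makes the measurement robust
to motion and scanner drift — but in a short-TR spoiled gradient-echo sequence
it also perturbs the spoiled steady state: the magnetization settles into a
two-cycle *pseudo*-steady-state whose ± states differ in phase **before** the
off-resonance pulse ever plays. The classic half-difference estimator
(Φ_BSS = ΦDiff/2 at the first post-pulse echo) attributes that extra phase to
the BSS and is biased by several percent, in a way that depends on tissue T₁
and T₂, TR, the RF-spoiling increment, and the pulse amplitude.

This package provides, for sequence developers and quantitative-MRI
methodologists:

* **`bsmap.bloch`** — an isochromat Bloch simulator of the dual-offset
  multi-echo spoiled GRE sequence (8 echoes, off-resonance pulse between
  echoes 2 and 3 flanked by 6π crushers, quadratic RF-spoiling schedule, 6π
  end-of-TR spoiler, interleaved or sequential offset ordering) that
  quantifies the interleave bias against the sequential reference.
* **`bsmap.glm`** — the unbiased estimator: all 16 echo phases are modeled
  voxel-wise by a rank-6 linear model (BSS step, B0 ramp over TE, odd/even
  readout phase, per-offset intercepts, common post-pulse phase) fitted by
  magnitude-weighted least squares after temporal phase unwrapping; the BSS
  coefficient converts to B1⁺ through the pulse constant K_BSS. Because each
  interleave gets its own intercept, the pseudo-steady-state phase difference
  no longer contaminates the estimate.
* **`bsmap.classic`** — the classic subtraction estimator and map-comparison
  statistics.
* **`bsmap.pulse`** — Fermi/rect pulse envelopes, the phase constants, flip
  angle ↔ peak-B1 calibration, and a brute-force off-resonant rotation
  simulator bounding the first-order approximation.
* **`bsmap.phantom`** — digital phantoms: model-matched data for exact
  round-trip validation, and Bloch-simulated data carrying the genuine
  interleave bias.
* **`bsmap` CLI** — `simulate`, `phantom`, `fit`, `fit-classic`, `compare`
  over NIfTI volumes with JSON sidecars.

## Worked example

```python
import numpy as np
from bsmap import (BSPulse, SequenceParams, TissueParams, classic_error_curve,
                   bss_phase_constant, resolved_peak_b1)

pulse = BSPulse()                      # Fermi, 2 ms, 260 deg, +2 kHz
b1p = resolved_peak_b1(pulse)
const = bss_phase_constant(pulse)
print(f"calibrated peak B1+ : {b1p:.2f} uT")
print(f"BSS phase per pulse : {const.k_bss * b1p**2:.3f} rad")

gel = TissueParams(t1=0.55, t2=0.07)   # agar-gel QA phantom
table = classic_error_curve([0, 60, 90, 120, 180], SequenceParams(), gel)
print(table[["phi_base_inc_deg", "error_classic_pct", "error_glm_pct"]]
      .to_string(index=False, float_format=lambda v: f"{v:8.3f}"))
```

Output:

```
calibrated peak B1+ : 11.33 uT
BSS phase per pulse : 0.500 rad
 phi_base_inc_deg  error_classic_pct  error_glm_pct
            0.000              4.840          0.000
           60.000             -0.957          0.000
           90.000             -0.001          0.000
          120.000              0.964          0.000
          180.000             -4.546          0.000
```

Reading: with no RF spoiling the interleaved classic estimate overshoots the
sequential reference by 4.8%; the bias peaks again near 60°, 120° and 180°
increments and vanishes at 90°. The GLM estimate from the *same* interleaved
data tracks the reference at every increment.

The same pipeline runs on image data from the shell:

```bash
bsmap phantom --spec phantom.yaml --out ds/         # synthesize a dataset
bsmap fit --data ds/ --out maps_glm/                # GLM B1+ map
bsmap fit-classic --data ds/ --out maps_classic/    # classic B1+ map
bsmap compare --map-a maps_glm/b1p_uT.nii.gz \
              --map-b maps_classic/b1p_uT.nii.gz --out stats/
```

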