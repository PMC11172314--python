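# abskit

Analysis toolkit for protein purification with ionic-liquid **aqueous
biphasic systems** (ABS), including the fluorinated-ionic-liquid (FIL)
systems used to partition globular proteins such as lysozyme. It is aimed
at bioseparations researchers who need the quantitative backbone of an ABS
partition study as reusable, tested code:

- **Phase diagrams** — fit the Merchuck binodal
  `Y = A·exp(B·X^0.5 − C·X³)` (Y = IL wt%, X = salt/carbohydrate wt%) to
  cloud-point titration data and classify mixtures as mono- or biphasic.
- **Tie-lines** — solve the gravimetric four-equation system (both
  endpoints on the binodal, lever rule on both axes, phase-mass fraction α)
  for coexisting-phase compositions, tie-line length (TLL) and slope (STL).
- **Partition** — extraction efficiency
  `%EE = 100·m_ILrp/(m_ILrp + m_non-ILrp)`, replicate statistics and linear
  calibration with inverse prediction.
- **Binding (MST)** — 16-point 1:1 serial-dilution designs, exact quadratic
  mass-action `fraction bound`, Kd fitting with a principled
  "no binding detected" call and the 50 mM capillary quality cutoff.
- **Thermal stability (DSC)** — polynomial baseline subtraction, two-state
  van't Hoff excess-heat-capacity fitting
  (`Cp_exc = s·ΔH²/(RT²)·K/(1+K)²`), Tm/ΔH/ΔS/ΔG(T), and joint
  multi-transition fits with AICc model comparison.
- **Enzyme activity** — turbidity-decay (A450) slopes and relative activity
  versus a water/buffer reference.
- **Synthetic data** — seeded generators for every stream above, exact on
  the generating model at zero noise.
- Packaged reference tables: the twelve biphasic systems' phase properties,
  the FITC-lysozyme Kd table and the printed lysozyme Tm values.

## Worked example

```python
import numpy as np
from abskit import (BinodalModel, fit_binodal, solve_tieline, TieLineProblem,
                    extraction_efficiency, fit_kd, capillary_quality_filter)
from abskit.simulate import gen_binodal, gen_titration

# 1. Fit a binodal to (synthetic) cloud-point data
truth = BinodalModel(a=80.0, b=-0.3, c=5e-5)
points = gen_binodal(truth, n=20, noise_sd=0.5, rng=1)
model = fit_binodal(points)
print(f"A={model.a:.2f}  B={model.b:.3f}  C={model.c:.2e}")
# A=79.97  B=-0.300  C=5.04e-05

# 2. Solve the tie-line through a biphasic mixture (10% salt, 40% IL, alpha=0.52)
tl = solve_tieline(TieLineProblem(model=model, x_m=10.0, y_m=40.0, alpha=0.52))
print(f"TLL={tl.length:.2f} wt%  STL={tl.slope:.2f}")
# TLL=54.41 wt%  STL=-2.57

# 3. Extraction efficiency from per-phase protein masses (mg)
print(f"%EE = {extraction_efficiency(0.9625, 0.0375):.2f}")
# %EE = 96.25

# 4. Kd from an MST titration (start 34 mM, target 0.41 uM, 2% Fnorm noise)
series = gen_titration(kd=1.27, start=34.0, noise_sd=0.02, rng=2)
filtered, _ = capillary_quality_filter(series, max_conc=50.0)
fit = fit_kd(filtered)
print(f"Kd = {fit.kd:.2f} mM  (binding detected: {fit.binding_detected})")
# Kd = 1.09 mM  (binding detected: True)
```

The tie-line endpoints are the compositions of the coexisting IL-rich and
salt-rich phases; TLL measures how different the phases are, and a steep
negative STL means demixing is driven by the IL axis. The Kd value is the
ligand concentration at half-saturation of the labeled protein — here the
fit recovers the generating 1.27 mM affinity from one noisy 16-point
titration within its sampling error.

The same stages are scriptable from the shell:

```sh
abskit simulate binodal --seed 3 --out points.csv
abskit fit-binodal --in points.csv --out model.json
abskit solve-tieline --model model.json --xm 10 --ym 40 --alpha 0.52 --out tl.json
abskit fit-kd --in titration.csv --target-um 0.41 --cutoff-mm 50 --out kd.json
```

Every command writes a run manifest (inputs, checksums, seed, version)
next to its output.

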