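# lutebg

Modelling the coincidence-mode energy spectrum produced by the **intrinsic
radioactivity of LYSO scintillation crystals**.

LYSO (Lu<sub>1.8</sub>Y<sub>0.2</sub>SiO<sub>5</sub>:Ce), the workhorse
scintillator of PET detectors, contains 2.6% naturally radioactive
<sup>176</sup>Lu (≈ 300 Bq/cm³, T<sub>1/2</sub> = 3.76 × 10<sup>10</sup> y).
Each decay emits a β⁻ particle (E<sub>max</sub> = 593 keV) followed by a
prompt <sup>176</sup>Hf de-excitation cascade: γ₁ = 307 keV, γ₂ = 202 keV,
γ₃ = 88 keV, the latter two competing with internal conversion (IC).  When
two crystals face each other in coincidence mode, this background alone
produces a characteristic spectrum — β continua in the *source* crystal in
coincidence with γ photopeaks in the *detector* crystal — that matters for
detector calibration, quality control and transmission imaging with no
external source.  `lutebg` is for instrumentation physicists who need to
predict or validate that background for a given crystal size and separation.

## What it computes

For each decay, every cascade transition *i* meets one of four fates: IC
(electron deposits E<sub>i</sub> locally), γ fully absorbed in the source
crystal C1, γ absorbed at full energy in the detector crystal C2
(photopeak), or lost.  With per-transition fate probabilities

&nbsp;&nbsp;P(IC) = 1 − P<sub>i</sub>,&nbsp;
P(C1) = P<sub>i</sub> p<sub>C1</sub>(E<sub>i</sub>),&nbsp;
P(C2) = P<sub>i</sub> (1 − p<sub>C1</sub>) p<sub>C2</sub>(E<sub>i</sub>, d),&nbsp;
P(lost) = P<sub>i</sub> (1 − p<sub>C1</sub>)(1 − p<sub>C2</sub>),

the package enumerates all 3 × 4 × 4 = 48 joint fates exactly and keeps
those with a C2 deposit (a *true coincidence*).  The resulting deposit
probability maps feed a spectrum builder: β continua shifted by the C1
cascade energy, photopeak lines at the C2 energies, a variable Gaussian
response σ(E) = 1.15 E<sup>0.52</sup> keV, an 80 keV threshold and area
normalization.  The absorption probabilities p<sub>C1</sub>,
p<sub>C2</sub>(d) come either from the packaged reference values for the
standard 57.4 × 57.4 × 10 mm³ geometry or from the native photon-transport
Monte Carlo (photoelectric + Klein–Nishina Compton, optional Rayleigh and
K-fluorescence).  An event-mode simulator runs both crystals as
simultaneous sources and detectors through a digitizer (10 ns window,
take-all-goods) and classifies true/random/multiple coincidences.

Modules: `nuclear_data`, `beta_spectrum`, `photon_mc`, `cascade_model`,
`spectrum_builder`, `event_simulator`, `pipeline`/`cli`.

## Worked example

```python
from lutebg import (default_decay_scheme, reference_absorption_probabilities,
                    coincidence_table)

scheme = default_decay_scheme()
probs = reference_absorption_probabilities()
table = coincidence_table(probs, scheme, distance=2.5)
print(f"total coincidence probability at d=2.5 cm: {table.total:.4f}")
print(f"202 keV photopeak weight: {table.c2_probs[202]:.3e}")
print(f"307 keV photopeak weight: {table.c2_probs[307]:.3e}")
```

prints

```
total coincidence probability at d=2.5 cm: 0.0614
202 keV photopeak weight: 2.378e-02
307 keV photopeak weight: 3.610e-02
```

i.e. at 2.5 cm separation about 6% of decays in one crystal yield a true
coincidence, dominated by the individual 202 and 307 keV photopeaks — the
two prominent peaks riding on the β continuum in the measured spectrum.
From the shell:

```bash
lutebg spectrum --d 2.5 --out spec_d25.csv   # convolved, thresholded, area = 1
lutebg fit                                   # rate-vs-distance law
```

the fit reports `c = 0.2293  R^2 = 0.9981`, the constant of the
1/(1 + c d²) falloff of the analytic coincidence rate (the peak density of
`spec_d25.csv` sits at 307–308 keV).  `lutebg absorption` regenerates the
absorption-probability table with the native Monte Carlo, `lutebg simulate`
runs the event-mode simulation, and `lutebg pipeline` chains everything
from one YAML config.

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline deterministic
quantity from scratch — it enumerates the 48 cascade fates with the
reference absorption probabilities and reads off the detector-crystal
sum-peak probability (597 keV entry at d = 21 cm) — and writes the result
as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the model, its assumptions, the synthetic
attenuation data, numerical choices and known limitations.
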