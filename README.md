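# nerveimpedance

Equivalent-circuit modelling and fitting of peripheral-nerve
bioimpedance spectra.

Engineered nerve constructs — native (control), decellularized and
recellularized sciatic nerve segments — show distinct impedance
magnitude spectra |Z|(f) over the 10 Hz–80 kHz band, reflecting how
much membrane and interface structure the tissue contains. This package
is for researchers who want to turn such spectra into layer-resolved
electrical parameters: it models the nerve as three series parallel-RC
compartments (endoneurium, perineurium, epineurium) with two
capacitive couplings bridging adjacent compartments, and estimates the
eight circuit parameters

    Rendo, Cendo, Rperi, Cperi, Repi, Cepi, Cendo_peri, Cperi_epi

from a measured |Z| spectrum by bounded nonlinear least squares. Each
layer block has impedance `Z = R / (1 + j 2πf R C)`; at DC the network
reduces to `Rendo + Rperi + Repi` exactly, and a closed-form network
solution is cross-checked against an independent nodal-analysis solve.

Beyond the free eight-parameter fit, three *layer-constrained* schemes
vary one layer's R, C and adjacent coupling(s) while pinning everything
else to a baseline state — a nested-model comparison that attributes a
spectral change (e.g. after recellularizing a decellularized scaffold)
to a specific anatomical layer by ranking the schemes' RMSE%.

Also included: geometry-derived starting values (`C = ε0 εr A/d`,
`R = ρ l/A`), multiplicative parameter bounds, geometric
normalisations (Z/l and the effective resistivity ρ*(ω) = |Z|·S/l), a
goodness-of-fit suite (SSR_rel, RMSE%, SSR_log, RMSE_log, reduced χ²,
R², NMSE), a seeded synthetic-spectrum generator emulating the
sweep-and-average measurement protocol for the three tissue states, and
a CLI (`nerveimp`) binding it all together. See `docs/methods.md` for
the model, numerical choices and limitations.

## Worked example

```python
from nerveimpedance import (
    FitConfig, FrequencyGrid, NoiseModel, default_initial_parameters,
    fit_spectrum, rank_constrained_models, reference_state_parameters,
    simulate_spectrum)

grid = FrequencyGrid.default_sweep()          # 10 Hz..80 kHz, 8000 points

# simulate a control-nerve measurement (2% noise, 3 averaged readings)
truth = reference_state_parameters("CT")
spectrum = simulate_spectrum(truth, grid, NoiseModel(), seed=42)

# fit all eight parameters starting from the literature seed set
res = fit_spectrum(spectrum, default_initial_parameters("reference"),
                   FitConfig(seed=0))
print(f"RMSE% = {res.metrics.rmse_pct:.2f}  R^2 = {res.metrics.r2:.4f}")
# RMSE% = 1.17  R^2 = 0.9999

# which layer explains the recellularized state, given the
# decellularized baseline?
rec = simulate_spectrum(reference_state_parameters("REC"), grid,
                        NoiseModel(), seed=7)
table = rank_constrained_models(rec, reference_state_parameters("DEC"),
                                FitConfig(seed=0))
print(table.to_string(index=False))
#    scheme  rmse_pct       r2  n_free  converged
#  free_epi  6.771445 0.982130       3       True
# free_endo  7.392351 0.925615       3       True
# free_peri  8.503764 0.971766       4       True
```

The fitted RMSE of 1.17% sits at the noise floor of the simulated
measurement (2% per reading, three readings averaged), i.e. the model
reproduces the spectrum as well as the data allow. In the ranking, the
epineurial scheme explains the recellularized spectrum best —
consistent with cells settling predominantly on the outermost layer —
while the other two schemes leave a systematically larger misfit.

The same workflow from the shell:

```sh
nerveimp simulate --out data/ --seed 42
nerveimp fit data/CT.csv --init reference --seed 0 --out results/ct/
nerveimp init-params --source reference --out dec.json   # or any baseline
nerveimp rank data/REC.csv dec.json --seed 0 --out results/rank/
nerveimp normalize data/CT.csv --mode resistivity --out results/ct_rho.csv
```

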