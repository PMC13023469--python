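# Methods

## The model

A peripheral nerve segment between two end electrodes is represented as
three electrically distinct compartments in series — endoneurium,
perineurium and epineurium — each a parallel RC block: the resistance
stands for ionic conduction through that compartment, the capacitance
for charge accumulation at membranes and laminar interfaces. A plain
series chain of three RC blocks produces at most three characteristic
time constants; measured nerve spectra show more slope changes than
that, so two capacitive coupling elements between adjacent compartments
are added, giving eight parameters in total:

    Rendo, Cendo, Rperi, Cperi, Repi, Cepi, Cendo_peri, Cperi_epi

**Topology.** With the series chain on nodes `n0 - n1 - n2 - n3`
(endo, peri, epi in that order), `Cendo_peri` bridges `n0 - n2` and
`Cperi_epi` bridges `n1 - n3`; the drive is at `n0`, return at `n3`.
The placement is a modelling decision: a coupling capacitor merely in
parallel with a single block would be indistinguishable from that
block's own capacitance and would add no new time constants, so the
two-block bridge is the minimal interpretation under which the
couplings do what they are introduced for. The topology lives in one
function (`circuit._layer_admittances` plus the closed form) so
alternatives can be benchmarked. The network is reciprocal: reversing
the layer order leaves the driving-point impedance unchanged (tested).

**Evaluation.** The driving-point impedance is evaluated two ways:
a closed form obtained by eliminating the two interior node voltages
analytically, and an independent numeric solve of the 2x2 interior-node
admittance system. The two agree to better than 1e-10 relative over
randomized parameter sets within ±3 decades of the published tissue
states; that range is part of the test definition because physically
meaningless 8-decade corners can push the agreement to ~5e-10 through
conditioning alone. `f = 0` is handled as the analytic limit (all
capacitors open: the sum of the three resistances, exact), and the
coupling-free case short-circuits to the exact series sum. Only |Z| is
treated as observable — the emulated meter records magnitude only;
whether phase was available is unknown, so it is never relied on.

Standard RC one-port facts used as invariants: |Z| is monotone
non-increasing in frequency, equals the resistance sum at DC, and
collapses toward zero at high frequency when every layer has a
capacitance.

## Geometry-derived parameters

Layer starting values come from the classical relations
`C = eps0 * eps_r * A / d` and `R = rho * l / A` with `A` the full-disc
cross-section `pi (D/2)^2` from the layer diameter, `d` the thickness
and `l` the conduction length (eps0 = 8.854e-12 F/m). The full-disc
convention reproduces the tabulated endoneurial starting capacitance
within ~2%; annular and lateral-area conventions do not, which is why
it is the default and exposed as a plain function.

Two starting sets coexist deliberately:

* `reference` — the published literature-adapted constants, used
  verbatim to seed fits;
* `computed` — the relations above applied to the reference layer
  table. Several reference resistances are *not* recoverable from the
  relations (the published values were further adapted on physical
  grounds by factors of ~4 to ~1e3), so computed values are exposed
  separately and never silently substituted. No relation exists for
  the coupling capacitances; the `computed` set reuses the reference
  coupling seeds.

Two sample-size constants likewise coexist: the nominal external
cross-section of 0.5 mm² used for normalisation, and the 0.504 mm outer
diameter whose disc area is ≈0.2 mm². They are inconsistent with each
other in the source material; each is used where it is defined
(normalisation vs. layer scaling) and neither is "corrected".

Normalisations: `Z/l` (ohm/mm) treats the sample as a bioelectric line;
`|Z| * S / l` (ohm·m) yields the effective resistivity rho*(omega), an
intrinsic, geometry-free tissue property. Defaults: length 5 mm, area
0.5 mm².

## Fitting

Bounded nonlinear least squares (scipy `least_squares`, trust-region
reflective) on residuals between measured and model |Z|:

* **Residuals** — relative `(model - measured)/measured` by default:
  the sweep spans four decades of |Z|, and relative residuals weight it
  evenly while matching the headline linear misfit statistic (the
  minimised objective equals the reported SSR_rel exactly, by
  construction). `log10` and `absolute` modes are available.
* **Log10 parameter space** — parameters span 8+ decades and must stay
  positive.
* **Multistart** — default 5 seeded starts: the supplied initials plus
  uniform log-space draws inside the bounds; best cost wins. All
  randomness flows from one integer seed.
* **Evaluation grid** — fitting and metrics default to a 35-point
  log-spaced subgrid of the 10 Hz–80 kHz sweep (nearest grid members,
  deduplicated); the published metric rows are mutually consistent only
  with N ≈ 35 and p = 8, which is an inference from their arithmetic,
  not a protocol statement. The full 8000-point grid is available via
  `metric_grid_size=None`.
* **Bounds** — when none are supplied, the free fit is two-stage: a
  preliminary fit inside wide bounds (±6 decades around the starting
  set) refines the parameters, then the final fit runs inside
  ±3 decades (configurable) around the refined values. This mirrors
  the published procedure, in which bounds were defined around the
  already-refined parameters; a single-stage ±3-decade box around the
  literature starting set would exclude the known fitted values
  outright (e.g. the fitted perineurial resistance sits three decades
  below its starting value). Constrained fits anchor bounds on the
  baseline state directly, with no preliminary stage.
* **Convergence** — ftol/xtol/gtol 1e-12, max 5000 evaluations per
  start; non-convergence is reported via `converged=False` with the
  best iterate returned, never an exception.

**Constrained schemes.** `free_endo` = {Rendo, Cendo, Cendo_peri};
`free_peri` = {Rperi, Cperi, Cendo_peri, Cperi_epi};
`free_epi` = {Repi, Cepi, Cperi_epi}. Fixed parameters are returned
bit-identical to the baseline. The published description of the
perineurial scheme names an "endo–epi" coupling, an element the model
does not contain; it is read as the two couplings adjacent to the
perineurium. Ranking sorts ascending RMSE%, breaking ties by fewer free
parameters, then the fixed order endo, peri, epi.

**Metrics** (all computed on the same vectors the fit used):
`ssr_rel = Σ((m−f)/m)²`, `rmse_pct = 100·√(ssr_rel/N)`,
`ssr_log = Σ(log10 m − log10 f)²`, `rmse_log = √(ssr_log/N)`,
`chi2_red = ssr_log/(N−p)` with p the number of *free* parameters of
the scheme, `r2 = 1 − SS_res/SS_tot` on linear |Z| (may be negative),
`nmse = SS_res/SS_tot = 1 − r2`. The log-SSR/(N−p) definition of the
reduced chi-square is the only one that reproduces all published rows
from their row companions; it is stated as such.

**Attribution power and its limits.** When synthetic "recellularized"
spectra are generated from the full recellularized parameter set and
ranked against the decellularized baseline, the epineurial scheme is
best in 20/20 replicates at the default noise level, with noiseless
misfit floors of ≈6.7% (epi), 7.1% (endo) and 8.6% (peri). A weaker
construction — truth differing from the baseline *only* in the
epineurial subset, at the magnitudes separating the two published
states — is not resolvable at study noise: the perineurial scheme
shares the peri–epi coupling and can mimic the small remaining
epineurial changes through its own R and C down to a 0.04% RMSE floor,
and its extra free parameter then absorbs slightly more noise. That
construction is therefore tested as a noiseless exactness property
(only the epineurial scheme reaches machine precision), not as a noisy
ranking claim.

## Synthetic data

The generator emulates the measurement protocol: 10 Hz–80 kHz sweep in
10 Hz steps (8000 points), three readings per point averaged into the
recorded value. Per reading, `|Z|·(1+eps) + eta` with
`eps ~ N(0, relative_sd)` (default 2%) and an optional additive floor;
non-positive draws are resampled, never clipped, so high noise adds no
bias (verified: the mean of many replicates matches the noiseless curve
within 3 standard errors pointwise). No noise statistics were published
for the instrument; 2% per reading is a calibration that, combined with
the protocol's averaging, places fitted RMSE values in the published
single-digit-percent band. Cohort simulation adds log-normal parameter
jitter (default sd 0.05 decades — median-unbiased, keeps positivity)
and Gaussian geometry jitter (default 5% relative sd around 5 mm /
0.5 mm²). Everything is reproducible bit-exactly from one seed,
including the CSV fixtures and their manifest.

The generator does **not** emulate electrode polarisation, parasitics,
temperature drift, frequency-dependent material properties, or
cross-frequency noise correlation. Passing tests therefore demonstrate
properties of the estimation machinery under the stated noise model,
not instrument-level fidelity on real nerves.

## Problem sizes and determinism

Test and example workloads use the full 8000-point sweep for
generation, the 35-point subgrid for fitting, 20-seed replicate sets
for stochastic claims, and a few thousand draws for solver-equivalence
sweeps — sizes chosen so each scientific property is exercised at the
scale its claim is stated at while the whole suite remains quick on a
single core. Every stochastic path takes an explicit integer seed;
there is no global random state.

## Known limitations

* Parameter *identifiability* is not guaranteed: distinct
  eight-parameter sets can produce near-identical |Z| spectra
  (magnitude-only data, series-resistance exchange between layers).
  Recovery claims are therefore stated on the fitted spectrum (RMSE%),
  not per parameter.
* No uncertainty quantification of fitted parameters (no CIs or
  bootstrap); an extension point.
* Electrode–tissue interface impedance is taken as negligible, as in
  the measurement setup being emulated; no constant-phase or
  distributed (cable) elements.
* Group-difference statistics on replicate spectra (ANOVA-style
  analyses) are out of scope; the package stops at per-spectrum fits,
  rankings and normalisations.
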