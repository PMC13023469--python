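"""Measurement-like synthetic |Z| spectra.

The generator emulates the bench protocol of the emulated RLC-meter
measurement: a sweep from 10 Hz to 80 kHz in 10 Hz steps (8000 points),
with three consecutive readings per frequency point averaged into the
recorded value.  Noise is multiplicative Gaussian on |Z| (relative
standard deviation, default 2%) with an optional additive ohm-level
floor; non-positive draws are resampled rather than clipped so high
noise introduces no bias.  The 2% default is a calibration choice: with
triplicate averaging it places fitted-spectrum RMSE values in the
single-digit percent band reported for fits to real nerves.  No noise
statistics were published for the instrument itself.

Three reference tissue states are built in — control (CT),
decellularized (DEC) and recellularized (REC) murine sciatic nerve —
each carrying the fitted parameter set reported for that state.
Inter-sample biological variability is modelled as log-normal parameter
jitter (symmetric in decades, median-unbiased) plus Gaussian jitter of
the sample geometry.

What this generator does NOT emulate: electrode polarisation, parasitic
reactances, temperature drift, frequency-dependent material properties,
or any correlation structure across frequencies beyond the circuit
model itself.  Conclusions drawn from it concern the estimation
machinery, not the instrument.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .circuit import (
    CircuitParameters,
    FrequencyGrid,
    ImpedanceSpectrum,
    ParameterError,
    magnitude_spectrum,
)
from .geometry import SampleGeometry

__all__ = [
    "NoiseModel",
    "GroupSpec",
    "SyntheticDataset",
    "GROUP_NAMES",
    "reference_state_parameters",
    "default_group_spec",
    "simulate_spectrum",
    "simulate_group",
    "make_fixtures",
]

GROUP_NAMES = ("CT", "DEC", "REC")

#: Fitted parameter sets reported for the three tissue states of the
#: murine sciatic nerve (control, decellularized, recellularized).
_STATE_PARAMETERS: dict[str, dict[str, float]] = {
    "CT": {
        "Rendo": 3.08e4, "Cendo": 6.07e-11,
        "Rperi": 4.52e3, "Cperi": 3.22e-9,
        "Repi": 1.45e3, "Cepi": 8.16e-7,
        "Cendo_peri": 2.14e-6, "Cperi_epi": 2.23e-6,
    },
    "DEC": {
        "Rendo": 1.74e4, "Cendo": 6.79e-11,
        "Rperi": 1.28e3, "Cperi": 1.66e-7,
        "Repi": 2.21e3, "Cepi": 3.19e-6,
        "Cendo_peri": 8.83e-6, "Cperi_epi": 9.19e-6,
    },
    "REC": {
        "Rendo": 4.09e3, "Cendo": 3.58e-8,
        "Rperi": 5.87e4, "Cperi": 4.19e-11,
        "Repi": 2.05e3, "Cepi": 5.23e-6,
        "Cendo_peri": 8.47e-7, "Cperi_epi": 8.79e-7,
    },
}


def reference_state_parameters(group: str) -> CircuitParameters:
    """The fitted circuit parameters reported for a tissue state."""
    try:
        return CircuitParameters.from_dict(_STATE_PARAMETERS[group])
    except KeyError:
        raise ParameterError(
            f"unknown group {group!r}; expected one of {GROUP_NAMES}"
        ) from None


@dataclass(frozen=True)
class NoiseModel:
    """Per-reading measurement noise and replicate averaging.

    Each recorded point is the mean of ``replicates`` independent
    readings ``|Z| * (1 + eps) + eta`` with
    ``eps ~ N(0, relative_sd)`` and ``eta ~ N(0, additive_floor)``.
    """

    relative_sd: float = 0.02
    replicates: int = 3
    additive_floor: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.relative_sd) or self.relative_sd < 0:
            raise ParameterError("relative_sd must be finite and >= 0")
        if int(self.replicates) < 1:
            raise ParameterError("replicates must be >= 1")
        if not math.isfinite(self.additive_floor) or self.additive_floor < 0:
            raise ParameterError("additive_floor must be finite and >= 0")
        object.__setattr__(self, "replicates", int(self.replicates))


@dataclass(frozen=True)
class GroupSpec:
    """A named tissue state plus its inter-sample variability model."""

    name: str
    params: CircuitParameters
    param_jitter_log10_sd: float = 0.05
    geometry_mean: SampleGeometry = field(default_factory=SampleGeometry)
    geometry_rel_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.param_jitter_log10_sd < 0 or self.geometry_rel_sd < 0:
            raise ParameterError("jitter standard deviations must be >= 0")


def default_group_spec(group: str) -> GroupSpec:
    """GroupSpec for a reference tissue state with default variability."""
    return GroupSpec(name=group, params=reference_state_parameters(group))


@dataclass(frozen=True)
class SyntheticDataset:
    """A reproducible collection of simulated sample spectra."""

    samples: tuple[ImpedanceSpectrum, ...]
    provenance: dict

    def __len__(self) -> int:
        return len(self.samples)


def _positive_normal(rng: np.random.Generator, mean, sd, shape) -> np.ndarray:
    """Gaussian draws with non-positive values resampled (never clipped)."""
    mean_b = np.broadcast_to(np.asarray(mean, dtype=float), shape)
    sd_b = np.broadcast_to(np.asarray(sd, dtype=float), shape)
    out = np.array(mean_b + sd_b * rng.standard_normal(shape), dtype=float)
    bad = out <= 0
    while np.any(bad):
        out[bad] = mean_b[bad] + sd_b[bad] * rng.standard_normal(int(bad.sum()))
        bad = out <= 0
    return out


def simulate_spectrum(params: CircuitParameters,
                      grid: FrequencyGrid | None = None,
                      noise: NoiseModel | None = None,
                      seed: int | None = 0,
                      *,
                      rng: np.random.Generator | None = None,
                      sample_id: str | None = None,
                      group: str | None = None,
                      geometry: SampleGeometry | None = None
                      ) -> ImpedanceSpectrum:
    """Simulate one recorded |Z| spectrum (replicate-averaged, seeded).

    With ``relative_sd = 0`` and ``additive_floor = 0`` the result is
    exactly the noiseless model spectrum.
    """
    grid = grid or FrequencyGrid.default_sweep()
    noise = noise or NoiseModel()
    truth = magnitude_spectrum(params, grid)
    if noise.relative_sd == 0.0 and noise.additive_floor == 0.0:
        z = truth.copy()
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        shape = (noise.replicates, truth.size)
        sd = np.sqrt((noise.relative_sd * truth) ** 2 + noise.additive_floor ** 2)
        draws = _positive_normal(rng, truth[np.newaxis, :], sd[np.newaxis, :], shape)
        z = draws.mean(axis=0)
    return ImpedanceSpectrum(grid=grid, z_abs=z, sample_id=sample_id,
                             group=group, geometry=geometry, seed=seed)


def simulate_group(spec: GroupSpec, n_samples: int,
                   grid: FrequencyGrid | None = None,
                   noise: NoiseModel | None = None,
                   seed: int = 0) -> SyntheticDataset:
    """Simulate a cohort of samples from one tissue state.

    Per sample, the state's parameters are jittered in log10 space
    (log-normal, median-unbiased), the geometry is drawn around its
    mean, and a replicate-averaged spectrum is recorded.  Sample ids and
    every random value are determined by ``seed`` alone.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    grid = grid or FrequencyGrid.default_sweep()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    base = spec.params.to_vector()
    samples = []
    for i in range(n_samples):
        jitter = 10.0 ** (spec.param_jitter_log10_sd * rng.standard_normal(8)) \
            if spec.param_jitter_log10_sd > 0 else np.ones(8)
        params_i = CircuitParameters.from_vector(base * jitter)
        gm = spec.geometry_mean
        if spec.geometry_rel_sd > 0:
            length = float(_positive_normal(
                rng, gm.length_mm, spec.geometry_rel_sd * gm.length_mm, ()))
            area = float(_positive_normal(
                rng, gm.area_mm2, spec.geometry_rel_sd * gm.area_mm2, ()))
        else:
            length, area = gm.length_mm, gm.area_mm2
        sample = simulate_spectrum(
            params_i, grid, noise, seed=seed, rng=rng,
            sample_id=f"{spec.name}-{i:03d}", group=spec.name,
            geometry=SampleGeometry(length_mm=length, area_mm2=area),
        )
        samples.append(sample)
    provenance = {
        "seed": int(seed),
        "group": spec.name,
        "n_samples": int(n_samples),
        "param_jitter_log10_sd": spec.param_jitter_log10_sd,
        "geometry_rel_sd": spec.geometry_rel_sd,
        "noise": {
            "relative_sd": noise.relative_sd,
            "replicates": noise.replicates,
            "additive_floor": noise.additive_floor,
        },
        "grid": {
            "fmin_hz": float(grid.frequencies[0]),
            "fmax_hz": float(grid.frequencies[-1]),
            "n_points": len(grid),
        },
    }
    return SyntheticDataset(samples=tuple(samples), provenance=provenance)


def make_fixtures(output_dir: "str | Path", seed: int = 0,
                  grid: FrequencyGrid | None = None,
                  noise: NoiseModel | None = None) -> dict:
    """Write one fixture spectrum per tissue state plus a manifest.

    Files are byte-identical across runs with the same seed.  Returns
    the manifest (also written as ``manifest.json``).
    """
    from .spectrio import write_spectrum  # local import: io depends on us

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = grid or FrequencyGrid.default_sweep()
    noise = noise or NoiseModel()
    manifest: dict = {"seed": int(seed), "files": {}}
    for i, group in enumerate(GROUP_NAMES):
        group_seed = int(seed) + i
        spectrum = simulate_spectrum(
            reference_state_parameters(group), grid, noise, seed=group_seed,
            sample_id=f"{group}-000", group=group, geometry=SampleGeometry(),
        )
        path = out / f"{group}.csv"
        write_spectrum(spectrum, path)
        manifest["files"][group] = {
            "path": path.name,
            "seed": group_seed,
            "n_points": len(spectrum),
            "noise": {
                "relative_sd": noise.relative_sd,
                "replicates": noise.replicates,
                "additive_floor": noise.additive_floor,
            },
        }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
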