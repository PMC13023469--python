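"""Driving-point impedance of the three-layer coupled-RC nerve model.

A peripheral nerve segment is modelled as three electrically distinct
compartments — endoneurium, perineurium and epineurium — arranged in
series along the current path.  Each compartment is a parallel RC block
(ionic conduction in parallel with membrane/interface polarisation).
Two coupling capacitors represent the electrostatic interaction between
adjacent compartments: with the series chain laid out on nodes
``n0 - n1 - n2 - n3`` (endo, peri, epi blocks in that order),
``c_endo_peri`` bridges ``n0 - n2`` and ``c_peri_epi`` bridges
``n1 - n3``.  The drive is applied at ``n0`` with return at ``n3``.

A capacitor placed merely in parallel with a single block would be
absorbed into that block's own capacitance; bridging the two-block span
is the minimal placement that introduces genuinely new time constants,
which is what the couplings are for.  The network is reciprocal, so
reversing the layer order leaves the driving-point impedance unchanged.

Everything is SI internally (Hz, ohm, farad).  Complex arithmetic is
used throughout; the magnitude is taken only at the measurement
boundary, because the meter being emulated records |Z| alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .geometry import SampleGeometry

__all__ = [
    "PARAM_NAMES",
    "LAYER_LABELS",
    "ParameterError",
    "NumericalError",
    "LayerElement",
    "CircuitParameters",
    "FrequencyGrid",
    "ComplexSpectrum",
    "ImpedanceSpectrum",
    "layer_impedance",
    "circuit_impedance",
    "nodal_solve",
    "magnitude_spectrum",
    "single_element_impedance",
]

#: Canonical flattening order of the eight circuit parameters.  This order
#: is used for vectors, bounds, serialisation keys and report columns.
PARAM_NAMES = (
    "Rendo",
    "Cendo",
    "Rperi",
    "Cperi",
    "Repi",
    "Cepi",
    "Cendo_peri",
    "Cperi_epi",
)

LAYER_LABELS = ("endoneurium", "perineurium", "epineurium")


class ParameterError(ValueError):
    """A circuit parameter or input is outside its physical domain."""


class NumericalError(ArithmeticError):
    """A linear solve or evaluation failed for numerical reasons."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class LayerElement:
    """One tissue compartment: resistance in parallel with capacitance.

    ``capacitance == 0`` degenerates to a purely resistive layer.
    """

    label: str
    resistance: float
    capacitance: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in LAYER_LABELS:
            raise ParameterError(
                f"unknown layer label {self.label!r}; expected one of {LAYER_LABELS}"
            )
        r = _require_finite(f"{self.label} resistance", self.resistance)
        c = _require_finite(f"{self.label} capacitance", self.capacitance)
        if r <= 0:
            raise ParameterError(f"{self.label} resistance must be > 0, got {r}")
        if c < 0:
            raise ParameterError(f"{self.label} capacitance must be >= 0, got {c}")
        object.__setattr__(self, "resistance", r)
        object.__setattr__(self, "capacitance", c)


@dataclass(frozen=True)
class CircuitParameters:
    """The eight degrees of freedom of the coupled three-layer model.

    Three (R, C) layer pairs plus the two inter-layer coupling
    capacitances.  Flattening to/from a vector follows ``PARAM_NAMES``
    and is lossless.
    """

    endo: LayerElement
    peri: LayerElement
    epi: LayerElement
    c_endo_peri: float = 0.0
    c_peri_epi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_endo_peri", "c_peri_epi"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")
            object.__setattr__(self, name, v)
        if self.endo.label != "endoneurium" or self.peri.label != "perineurium" \
                or self.epi.label != "epineurium":
            raise ParameterError("layer elements assigned to wrong slots")

    # -- flat views -------------------------------------------------------

    def to_vector(self) -> np.ndarray:
        return np.array(
            [
                self.endo.resistance,
                self.endo.capacitance,
                self.peri.resistance,
                self.peri.capacitance,
                self.epi.resistance,
                self.epi.capacitance,
                self.c_endo_peri,
                self.c_peri_epi,
            ],
            dtype=float,
        )

    @classmethod
    def from_vector(cls, vec: Iterable[float]) -> "CircuitParameters":
        v = np.asarray(list(vec), dtype=float)
        if v.shape != (8,):
            raise ParameterError(f"expected 8 parameters, got shape {v.shape}")
        return cls(
            endo=LayerElement("endoneurium", v[0], v[1]),
            peri=LayerElement("perineurium", v[2], v[3]),
            epi=LayerElement("epineurium", v[4], v[5]),
            c_endo_peri=v[6],
            c_peri_epi=v[7],
        )

    def to_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.to_vector().tolist()))

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "CircuitParameters":
        missing = [k for k in PARAM_NAMES if k not in data]
        if missing:
            raise ParameterError(f"missing parameter keys: {missing}")
        return cls.from_vector([data[k] for k in PARAM_NAMES])

    def replace(self, **updates: float) -> "CircuitParameters":
        """Return a copy with flat-named parameters replaced."""
        d = self.to_dict()
        unknown = set(updates) - set(PARAM_NAMES)
        if unknown:
            raise ParameterError(f"unknown parameter names: {sorted(unknown)}")
        d.update(updates)
        return self.from_dict(d)

    @property
    def dc_resistance(self) -> float:
        """Zero-frequency limit: all capacitors open, resistances in series."""
        return self.endo.resistance + self.peri.resistance + self.epi.resistance


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of positive measurement frequencies [Hz]."""

    frequencies: np.ndarray
    spacing: str = "explicit"

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ParameterError("frequency grid must be a non-empty 1-d array")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise ParameterError("frequencies must be finite and > 0")
        if np.any(np.diff(f) <= 0):
            raise ParameterError("frequencies must be strictly increasing")
        if self.spacing not in ("linear", "log", "explicit"):
            raise ParameterError(f"unknown spacing {self.spacing!r}")
        f.setflags(write=False)
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return int(self.frequencies.size)

    @classmethod
    def default_sweep(cls) -> "FrequencyGrid":
        """The emulated meter protocol: 10 Hz to 80 kHz in 10 Hz steps."""
        return cls(np.arange(10.0, 80000.0 + 5.0, 10.0), spacing="linear")

    @classmethod
    def log_spaced(cls, n: int = 35, fmin: float = 10.0,
                   fmax: float = 80000.0) -> "FrequencyGrid":
        if n < 2:
            raise ParameterError("log-spaced grid needs n >= 2")
        return cls(np.geomspace(fmin, fmax, int(n)), spacing="log")

    def log_subgrid_indices(self, n: int) -> np.ndarray:
        """Indices of the members nearest (in log f) to an n-point log grid.

        Duplicate picks are collapsed, so the result can be shorter than n
        on coarse grids.
        """
        f = self.frequencies
        n = int(n)
        if n >= f.size:
            return np.arange(f.size)
        targets = np.geomspace(f[0], f[-1], n)
        logf = np.log(f)
        idx = np.searchsorted(logf, np.log(targets))
        idx = np.clip(idx, 1, f.size - 1)
        left = idx - 1
        choose_left = (np.log(targets) - logf[left]) < (logf[idx] - np.log(targets))
        idx = np.where(choose_left, left, idx)
        # nearest picks can collide where the grid is coarse in log space
        # (e.g. the 10 Hz steps at the bottom of the sweep); bump collided
        # picks to the next free member so exactly n points come back
        out = np.empty(n, dtype=int)
        prev = -1
        for i, j in enumerate(idx):
            j = max(int(j), prev + 1)
            j = min(j, f.size - (n - i))
            out[i] = j
            prev = j
        return out


@dataclass(frozen=True)
class ComplexSpectrum:
    """Complex impedance evaluated on a frequency grid."""

    grid: FrequencyGrid
    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=complex)
        if z.shape != (len(self.grid),):
            raise ParameterError("spectrum length must match grid length")
        object.__setattr__(self, "z", z)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.z)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """|Z| values on a grid, with the sample metadata a measurement carries."""

    grid: FrequencyGrid
    z_abs: np.ndarray
    sample_id: str | None = None
    group: str | None = None
    geometry: "SampleGeometry | None" = None
    seed: int | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z_abs, dtype=float)
        if z.shape != (len(self.grid),):
            raise ParameterError("spectrum length must match grid length")
        if not np.all(np.isfinite(z)):
            raise ParameterError("|Z| values must be finite")
        z.setflags(write=False)
        object.__setattr__(self, "z_abs", z)

    def __len__(self) -> int:
        return len(self.grid)

    def select(self, indices: np.ndarray) -> "ImpedanceSpectrum":
        """Sub-spectrum on a subset of grid points (e.g. a metric subgrid)."""
        return ImpedanceSpectrum(
            grid=FrequencyGrid(self.grid.frequencies[indices], spacing="explicit"),
            z_abs=self.z_abs[indices],
            sample_id=self.sample_id,
            group=self.group,
            geometry=self.geometry,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# impedance evaluation
# ---------------------------------------------------------------------------

def _as_frequency_array(f) -> tuple[np.ndarray, bool]:
    arr = np.asarray(f, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ParameterError("frequencies must be finite and >= 0")
    return arr, scalar


def layer_impedance(layer: LayerElement, f) -> complex | np.ndarray:
    """Impedance of a parallel RC block: ``R / (1 + j 2 pi f R C)``.

    Exactly ``R`` at f = 0; |Z| is non-increasing in frequency.
    Vectorised over ``f``.
    """
    fa, scalar = _as_frequency_array(f)
    z = layer.resistance / (
        1.0 + 2j * np.pi * fa * layer.resistance * layer.capacitance
    )
    return complex(z[0]) if scalar else z


def _layer_admittances(params: CircuitParameters, fa: np.ndarray):
    jw = 2j * np.pi * fa
    y1 = (1.0 + jw * params.endo.resistance * params.endo.capacitance) / params.endo.resistance
    y2 = (1.0 + jw * params.peri.resistance * params.peri.capacitance) / params.peri.resistance
    y3 = (1.0 + jw * params.epi.resistance * params.epi.capacitance) / params.epi.resistance
    ya = jw * params.c_endo_peri  # bridges n0 - n2
    yb = jw * params.c_peri_epi  # bridges n1 - n3
    return y1, y2, y3, ya, yb


def circuit_impedance(params: CircuitParameters, f) -> complex | np.ndarray:
    """Closed-form driving-point impedance of the coupled three-layer network.

    Derived by eliminating the two interior node voltages of the bridge
    network analytically.  ``f = 0`` is handled as the analytic limit
    (capacitors open): the sum of the three layer resistances, exactly.
    Vectorised over ``f``.
    """
    fa, scalar = _as_frequency_array(f)
    z = np.empty(fa.shape, dtype=complex)
    dc = fa == 0.0
    if np.any(dc):
        z[dc] = params.dc_resistance
    ac = ~dc
    if np.any(ac):
        if params.c_endo_peri == 0.0 and params.c_peri_epi == 0.0:
            # coupling-free degenerate case: plain series chain, kept exact
            z[ac] = (
                layer_impedance(params.endo, fa[ac])
                + layer_impedance(params.peri, fa[ac])
                + layer_impedance(params.epi, fa[ac])
            )
        else:
            y1, y2, y3, ya, yb = _layer_admittances(params, fa[ac])
            det = y1 * y2 + y1 * y3 + y1 * ya + y2 * y3 + y2 * ya \
                + yb * (y2 + y3 + ya)
            y_in = (
                y1 * (y2 * y3 + yb * (y2 + y3 + ya))
                + ya * (y3 * (y1 + y2 + yb) + y2 * yb)
            ) / det
            z[ac] = 1.0 / y_in
    if not np.all(np.isfinite(z)):
        raise NumericalError("non-finite impedance encountered")
    return complex(z[0]) if scalar else z


#: Condition-number guard for the interior-node solve.
_COND_LIMIT = 1e14


def nodal_solve(params: CircuitParameters, f: float) -> complex:
    """Independent nodal-analysis evaluation of the same network.

    Assembles the 2x2 complex admittance matrix of the interior nodes
    (n1, n2), solves it with unit drive voltage, and returns
    ``V_drive / I_in``.  Serves as a numerically independent cross-check
    of :func:`circuit_impedance`; not vectorised.
    """
    if not math.isfinite(f) or f < 0:
        raise ParameterError("frequency must be finite and >= 0")
    if f == 0.0:
        return complex(params.dc_resistance)
    fa = np.asarray([float(f)])
    y1, y2, y3, ya, yb = (c[0] for c in _layer_admittances(params, fa))
    a = np.array(
        [[y1 + y2 + yb, -y2],
         [-y2, y2 + y3 + ya]],
        dtype=complex,
    )
    b = np.array([y1, ya], dtype=complex)  # drive node at 1 V
    cond = np.linalg.cond(a)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise NumericalError(
            f"interior-node system ill-conditioned at f={f} Hz (cond={cond:.3e})"
        )
    v = np.linalg.solve(a, b)
    i_in = y1 * (1.0 - v[0]) + ya * (1.0 - v[1])
    if i_in == 0:
        raise NumericalError(f"zero input current at f={f} Hz")
    return complex(1.0 / i_in)


def magnitude_spectrum(params: CircuitParameters, grid: FrequencyGrid) -> np.ndarray:
    """|Z| of the coupled network on every grid point."""
    z = np.abs(circuit_impedance(params, grid.frequencies))
    if np.any(z <= 0):
        raise NumericalError("non-positive |Z| encountered")
    return z


def single_element_impedance(mode: str, resistance: float, capacitance: float,
                             f) -> complex | np.ndarray:
    """Impedance of the meter's single-element equivalent representations.

    ``series_rs_cs``:  Z = R + 1/(j 2 pi f C)   (open circuit at DC)
    ``parallel_rp_cp``: Z = R / (1 + j 2 pi f R C)
    """
    r = _require_finite("resistance", resistance)
    c = _require_finite("capacitance", capacitance)
    if r <= 0:
        raise ParameterError(f"resistance must be > 0, got {r}")
    fa, scalar = _as_frequency_array(f)
    if mode == "series_rs_cs":
        if c <= 0:
            raise ParameterError("series mode requires capacitance > 0")
        if np.any(fa == 0):
            raise ParameterError("series Rs-Cs impedance is unbounded at f = 0")
        z = r + 1.0 / (2j * np.pi * fa * c)
    elif mode == "parallel_rp_cp":
        z = r / (1.0 + 2j * np.pi * fa * r * c)
    else:
        raise ParameterError(
            f"unknown mode {mode!r}; expected 'series_rs_cs' or 'parallel_rp_cp'"
        )
    return complex(z[0]) if scalar else z
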