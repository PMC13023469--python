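"""Geometry-informed initial parameters, bounds, and geometric normalisation.

Layer resistances and capacitances follow the classical plate/rod
relations

    C = eps0 * eps_r * A / d        R = rho * l / A

with A the full-disc cross-section pi (D/2)^2 computed from the layer
diameter, d the layer thickness and l the conduction length.  The
full-disc convention is used for both relations because it reproduces
the tabulated endoneurial starting capacitance to within ~2%; annular
or lateral-surface conventions do not come close.  It is exposed as a
plain function so alternative conventions can be substituted.

Two sets of starting parameters exist side by side and are never
silently interchanged:

* ``reference`` — the literature-adapted constants actually used to
  seed the fits (the published starting set);
* ``computed`` — values obtained by applying the relations above to the
  reference layer dimensions and material constants.

Several reference resistances are *not* derivable from the geometric
relations (the published set was additionally adapted on physical
grounds, by up to three orders of magnitude for the epineurium), which
is why both sets are kept accessible.

Normalisations: ``Z/l`` (ohm/mm, bioelectric-line view) and the
effective resistivity ``rho*(omega) = |Z| * S / l`` (ohm m), which
removes sample geometry and leaves an intrinsic tissue property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuit import PARAM_NAMES, CircuitParameters, ParameterError

__all__ = [
    "EPSILON_0",
    "LayerGeometry",
    "MaterialProperties",
    "SampleGeometry",
    "ParameterBounds",
    "REFERENCE_LAYERS",
    "cross_sectional_area",
    "layer_capacitance",
    "layer_resistance",
    "default_initial_parameters",
    "bounds_from_initials",
    "normalize_by_length",
    "effective_resistivity",
    "scaled_layer_geometry",
]

#: Vacuum permittivity [F/m].
EPSILON_0 = 8.854e-12


@dataclass(frozen=True)
class LayerGeometry:
    """Anatomical dimensions of one nerve layer.

    Units follow the conventions of the source measurements: diameter in
    mm, thickness in um, conduction length in m.  Conversion to SI
    happens inside the derivation functions.
    """

    diameter_mm: float
    thickness_um: float
    length_m: float

    def __post_init__(self) -> None:
        for name in ("diameter_mm", "thickness_um", "length_m"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v}")
            object.__setattr__(self, name, v)
        if self.thickness_um >= self.diameter_mm * 1e3 / 2.0:
            raise ParameterError(
                "layer thickness must be smaller than the layer radius"
            )


@dataclass(frozen=True)
class MaterialProperties:
    """Electrical material constants of one layer."""

    resistivity_ohm_m: float
    rel_permittivity: float

    def __post_init__(self) -> None:
        for name, lo in (("resistivity_ohm_m", 0.0), ("rel_permittivity", 1.0)):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < lo or (lo == 0.0 and v <= 0):
                raise ParameterError(f"{name} must be finite and >= {lo}, got {v}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class SampleGeometry:
    """Whole-sample dimensions used for geometric normalisation.

    Defaults are the representative values assumed for the measured
    specimens: 5 mm conduction length, 0.5 mm^2 external cross-section.
    """

    length_mm: float = 5.0
    area_mm2: float = 0.5

    def __post_init__(self) -> None:
        for name in ("length_mm", "area_mm2"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class ParameterBounds:
    """Elementwise box bounds on the flattened eight-parameter vector."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != (len(PARAM_NAMES),) or hi.shape != (len(PARAM_NAMES),):
            raise ParameterError("bounds must be vectors of length 8")
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ParameterError("bounds must be finite")
        if np.any(lo <= 0):
            raise ParameterError("lower bounds must be > 0 (log-space fitting)")
        if np.any(lo >= hi):
            raise ParameterError("lower bounds must be elementwise below upper")
        lo.setflags(write=False)
        hi.setflags(write=False)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    def contains(self, vec: np.ndarray, strict: bool = False) -> bool:
        v = np.asarray(vec, dtype=float)
        if strict:
            return bool(np.all(v > self.lower) and np.all(v < self.upper))
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))


#: Published layer dimensions and material constants for the murine
#: sciatic nerve (outermost diameter 0.504 mm scaled inward by anatomical
#: ratios; resistivity and relative permittivity from the literature).
REFERENCE_LAYERS: dict[str, tuple[LayerGeometry, MaterialProperties]] = {
    "endoneurium": (
        LayerGeometry(diameter_mm=0.18, thickness_um=1.60, length_m=0.005),
        MaterialProperties(resistivity_ohm_m=1.0, rel_permittivity=80.0),
    ),
    "perineurium": (
        LayerGeometry(diameter_mm=0.30, thickness_um=2.73, length_m=0.005),
        MaterialProperties(resistivity_ohm_m=3751.3, rel_permittivity=2018.0),
    ),
    "epineurium": (
        LayerGeometry(diameter_mm=0.504, thickness_um=36.4, length_m=0.005),
        MaterialProperties(resistivity_ohm_m=55.0, rel_permittivity=4.97e6),
    ),
}

#: Literature-adapted starting values for fitting (the published seed set).
#: The coupling printed against the epineurium row carries the raw label
#: "Cendo-epi"; the model defines only adjacent couplings, so it is read
#: as the peri-epi coupling.
_REFERENCE_INITIALS: dict[str, float] = {
    "Rendo": 3.0e3,
    "Cendo": 1.15e-11,
    "Rperi": 1.0e8,
    "Cperi": 1.0e-11,
    "Repi": 1.37e3,
    "Cepi": 3.0e-7,
    "Cendo_peri": 1.0e-11,
    "Cperi_epi": 5.0e-11,
}


def cross_sectional_area(diameter_mm: float) -> float:
    """Full-disc cross-sectional area pi (D/2)^2, in m^2, from D in mm."""
    d = float(diameter_mm)
    if not math.isfinite(d) or d <= 0:
        raise ParameterError(f"diameter must be finite and > 0, got {d}")
    return math.pi * (d * 1e-3 / 2.0) ** 2


def layer_capacitance(geom: LayerGeometry, mat: MaterialProperties) -> float:
    """C = eps0 * eps_r * A / d in farad (A full-disc, d the thickness)."""
    area = cross_sectional_area(geom.diameter_mm)
    return EPSILON_0 * mat.rel_permittivity * area / (geom.thickness_um * 1e-6)


def layer_resistance(geom: LayerGeometry, mat: MaterialProperties) -> float:
    """R = rho * l / A in ohm (l the conduction length, A full-disc)."""
    area = cross_sectional_area(geom.diameter_mm)
    return mat.resistivity_ohm_m * geom.length_m / area


def default_initial_parameters(source: str = "reference") -> CircuitParameters:
    """Starting parameter set for fitting.

    ``reference`` returns the literature-adapted constants verbatim.
    ``computed`` derives each layer's R and C from ``REFERENCE_LAYERS``
    via the plate/rod relations; no relation exists for the coupling
    capacitances, so the reference coupling seeds are used in both modes.
    """
    if source == "reference":
        return CircuitParameters.from_dict(_REFERENCE_INITIALS)
    if source == "computed":
        values: dict[str, float] = {
            "Cendo_peri": _REFERENCE_INITIALS["Cendo_peri"],
            "Cperi_epi": _REFERENCE_INITIALS["Cperi_epi"],
        }
        for label, (rkey, ckey) in (
            ("endoneurium", ("Rendo", "Cendo")),
            ("perineurium", ("Rperi", "Cperi")),
            ("epineurium", ("Repi", "Cepi")),
        ):
            geom, mat = REFERENCE_LAYERS[label]
            values[rkey] = layer_resistance(geom, mat)
            values[ckey] = layer_capacitance(geom, mat)
        return CircuitParameters.from_dict(values)
    raise ParameterError(
        f"unknown initials source {source!r}; expected 'reference' or 'computed'"
    )


def bounds_from_initials(init: CircuitParameters, decades: float = 3.0,
                         coupling_cap_rule: bool = False) -> ParameterBounds:
    """Multiplicative box bounds ``[x / 10^decades, x * 10^decades]``.

    With ``coupling_cap_rule`` the upper bound of each coupling
    capacitance is additionally capped at the smaller of the two
    adjacent layer self-capacitances (couplings modelled as fractions of
    their neighbours).  The cap applies to bound *construction* from a
    starting set; fitted parameter sets are not forced to obey it.
    """
    if not math.isfinite(decades) or decades <= 0:
        raise ParameterError(f"decades must be > 0, got {decades}")
    vec = init.to_vector()
    if np.any(vec <= 0):
        raise ParameterError(
            "multiplicative bounds require strictly positive initials"
        )
    factor = 10.0 ** float(decades)
    lower = vec / factor
    upper = vec * factor
    if coupling_cap_rule:
        d = init.to_dict()
        caps = {
            "Cendo_peri": min(d["Cendo"], d["Cperi"]),
            "Cperi_epi": min(d["Cperi"], d["Cepi"]),
        }
        for name, cap in caps.items():
            i = PARAM_NAMES.index(name)
            upper[i] = min(upper[i], cap)
            if upper[i] <= lower[i]:
                raise ParameterError(
                    f"coupling cap {cap!r} on {name} collapses its bound interval"
                )
    return ParameterBounds(lower=lower, upper=upper)


def normalize_by_length(z_abs: np.ndarray, length_mm: float) -> np.ndarray:
    """Length-normalised impedance Z/l in ohm/mm."""
    l = float(length_mm)
    if not math.isfinite(l) or l <= 0:
        raise ParameterError(f"length_mm must be finite and > 0, got {l}")
    return np.asarray(z_abs, dtype=float) / l


def effective_resistivity(z_abs: np.ndarray, geom: SampleGeometry) -> np.ndarray:
    """Effective resistivity rho*(omega) = |Z| * S / l in ohm m (SI)."""
    factor = (geom.area_mm2 * 1e-6) / (geom.length_mm * 1e-3)  # metres
    return np.asarray(z_abs, dtype=float) * factor


def scaled_layer_geometry(outer_diameter_mm: float,
                          length_mm: float = 5.0) -> dict[str, LayerGeometry]:
    """Layer geometries for an arbitrary outer diameter.

    Inner diameters and thicknesses scale linearly with the ratio of the
    requested outer (epineurial) diameter to the reference outer
    diameter, preserving the anatomical proportions of the reference
    layer set.
    """
    d = float(outer_diameter_mm)
    if not math.isfinite(d) or d <= 0:
        raise ParameterError(f"outer diameter must be finite and > 0, got {d}")
    ref_outer = REFERENCE_LAYERS["epineurium"][0].diameter_mm
    scale = d / ref_outer
    out: dict[str, LayerGeometry] = {}
    for label, (geom, _mat) in REFERENCE_LAYERS.items():
        out[label] = LayerGeometry(
            diameter_mm=geom.diameter_mm * scale,
            thickness_um=geom.thickness_um * scale,
            length_m=float(length_mm) * 1e-3,
        )
    return out
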