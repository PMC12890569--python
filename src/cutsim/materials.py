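"""Constitutive models, property tables and the particle damage state machine.

The bone surrogate is 10 PCF solid rigid polyurethane foam.  Published foam
properties describe the *porous structure as a whole*; the mesh-free model
assigns properties of the *compact polymer* to individual particles, obtained
by scaling the overall modulus and strengths with a bench-calibrated 8.5x
correction coefficient.  For dynamic (cyclic-equivalent) runs the yield and
ultimate stresses are additionally derated by 10% to represent accelerated
damage accumulation over load cycles.

Foam particles follow a compressible neo-Hookean law with a three-state
damage machine (elastic -> yielding -> failed) driven by the maximum-magnitude
principal Cauchy stress; metallic bodies use a maximum principal strain
threshold (they are treated as rigid by the solver, so the metal criterion is
exposed for post-processing only).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "ELASTIC",
    "YIELDING",
    "FAILED",
    "MaterialModel",
    "FoamMaterial",
    "STATIC_CORRECTION",
    "DYNAMIC_DERATING",
    "lookup_material",
    "apply_static_correction",
    "apply_dynamic_derating",
    "foam_material",
    "lame_parameters",
    "neo_hookean_stress",
    "strain_energy_density",
    "damage_update",
    "round_table",
]

# damage state codes (ordered; transitions are one-way)
ELASTIC, YIELDING, FAILED = 0, 1, 2

#: calibration coefficient mapping overall porous-foam properties to the
#: compact-polymer properties assigned to particles (static loading)
STATIC_CORRECTION = 8.5
#: fractional strength reduction applied for dynamic loading
DYNAMIC_DERATING = 0.10


@dataclass(frozen=True)
class MaterialModel:
    """A constitutive + failure parameter set for one material.

    Stresses and moduli in MPa, density in g/mm^3 (consistent with the
    mm / N / MPa / ms unit system used throughout).
    """

    name: str
    behavior: str  # 'rigid' | 'neo-hookean'
    E: float
    nu: float
    yield_stress: float | None = None
    ultimate_stress: float | None = None
    elongation_at_break: float | None = None
    hardening_modulus: float = 0.0
    failure_criterion: str = "max-principal-stress"
    density: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.behavior not in ("rigid", "neo-hookean"):
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.behavior != "rigid" and self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")
        if (
            self.yield_stress is not None
            and self.ultimate_stress is not None
            and self.ultimate_stress < self.yield_stress
        ):
            raise ValueError("ultimate stress must be >= yield stress")


@dataclass(frozen=True)
class FoamMaterial:
    """Overall-structure and compact-polymer property sets of the foam.

    ``overall`` carries the porous-structure values (E = 58 MPa,
    sigma_y = 2.2 MPa at a volume fraction of 0.14); ``compact_static`` and
    ``compact_dynamic`` carry the particle-level values derived from them.
    """

    overall: MaterialModel
    compact_static: MaterialModel
    compact_dynamic: MaterialModel
    volume_fraction: float

    def particles(self, mode: str) -> MaterialModel:
        if mode == "static":
            return self.compact_static
        if mode == "dynamic":
            return self.compact_dynamic
        raise ValueError(f"unknown loading mode {mode!r}")


def round_table(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up at ``ndigits`` decimals, as printed tables do.

    Binary floating point makes ``round`` land below the half for values
    like 19.635; a decimal quantize on the 9-decimal representation keeps
    reported properties consistent with their tabulated form.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(f"{x:.9f}").quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def _load_table() -> dict:
    text = resources.files("cutsim.data").joinpath("materials.yaml").read_text()
    return yaml.safe_load(text)


_ALIASES = {
    "steel-316L": "steel-316L",
    "titanium-Ti6Al4V": "titanium-Ti6Al4V",
    "titanium": "titanium-Ti6Al4V",
    "foam-10PCF-overall": "foam-10PCF-overall",
    "foam-10PCF-compact-static": "foam-10PCF-compact-static",
    "foam-10PCF-compact-dynamic": "foam-10PCF-compact-dynamic",
}


def lookup_material(name: str, **overrides) -> MaterialModel:
    """Return the tabulated material by name.

    Recognized names: ``steel-316L``, ``titanium-Ti6Al4V``,
    ``foam-10PCF-overall``, ``foam-10PCF-compact-static``,
    ``foam-10PCF-compact-dynamic``.  Keyword overrides replace individual
    properties (e.g. a plausible steel hardening modulus).
    """
    try:
        key = _ALIASES[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}") from None

    if key in ("foam-10PCF-compact-static", "foam-10PCF-compact-dynamic"):
        foam = foam_material()
        mat = foam.compact_static if key.endswith("static") else foam.compact_dynamic
        return replace(mat, **overrides) if overrides else mat

    entry = dict(_load_table()[key])
    entry.pop("volume_fraction", None)
    entry.update(overrides)
    return MaterialModel(name=key, **entry)


def apply_static_correction(
    overall: MaterialModel, coeff: float = STATIC_CORRECTION
) -> MaterialModel:
    """Scale overall foam modulus and strengths to compact-polymer values.

    The coefficient (default 8.5) comes from a prior three-point-bending
    calibration of the particle material model against physical foam.
    """
    if coeff <= 0:
        raise ValueError("correction coefficient must be positive")
    return replace(
        overall,
        name=overall.name + "-compact-static",
        E=coeff * overall.E,
        yield_stress=None if overall.yield_stress is None else coeff * overall.yield_stress,
        ultimate_stress=None
        if overall.ultimate_stress is None
        else coeff * overall.ultimate_stress,
    )


def apply_dynamic_derating(
    static: MaterialModel, fraction: float = DYNAMIC_DERATING
) -> MaterialModel:
    """Reduce yield and ultimate stress by ``fraction``; modulus unchanged."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("derating fraction must lie in [0, 1)")
    name = static.name.replace("static", "dynamic")
    if name == static.name:
        name = static.name + "-dynamic"
    return replace(
        static,
        name=name,
        yield_stress=None
        if static.yield_stress is None
        else (1.0 - fraction) * static.yield_stress,
        ultimate_stress=None
        if static.ultimate_stress is None
        else (1.0 - fraction) * static.ultimate_stress,
    )


def foam_material() -> FoamMaterial:
    """The 10 PCF foam property bundle (overall + compact static/dynamic)."""
    table = _load_table()["foam-10PCF-overall"]
    vf = table.pop("volume_fraction")
    overall = MaterialModel(name="foam-10PCF-overall", **table)
    static = apply_static_correction(overall)
    dynamic = apply_dynamic_derating(static)
    return FoamMaterial(
        overall=overall,
        compact_static=replace(static, name="foam-10PCF-compact-static"),
        compact_dynamic=replace(dynamic, name="foam-10PCF-compact-dynamic"),
        volume_fraction=vf,
    )


# ---------------------------------------------------------------------------
# compressible neo-Hookean law
# ---------------------------------------------------------------------------


def lame_parameters(mat: MaterialModel) -> tuple[float, float]:
    """(mu, lambda) from (E, nu)."""
    mu = mat.E / (2.0 * (1.0 + mat.nu))
    lam = mat.E * mat.nu / ((1.0 + mat.nu) * (1.0 - 2.0 * mat.nu))
    return mu, lam


def strain_energy_density(F: np.ndarray, mat: MaterialModel) -> np.ndarray:
    """W(F) = mu/2 (I1 - 3) - mu ln J + lambda/2 (ln J)^2  [MPa]."""
    F = np.asarray(F, dtype=float)
    mu, lam = lame_parameters(mat)
    J = np.linalg.det(F)
    I1 = np.einsum("...ij,...ij->...", F, F)
    return 0.5 * mu * (I1 - 3.0) - mu * np.log(J) + 0.5 * lam * np.log(J) ** 2


def neo_hookean_stress(F: np.ndarray, mat: MaterialModel) -> np.ndarray:
    """Cauchy stress of the compressible neo-Hookean model.

    sigma = (mu (B - I) + lambda ln(J) I) / J with B = F F^T.  Accepts a
    single 3x3 deformation gradient or a batch (..., 3, 3); requires
    det F > 0 everywhere.
    """
    F = np.asarray(F, dtype=float)
    if mat.behavior == "rigid":
        raise ValueError("rigid material has no stress response")
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    mu, lam = lame_parameters(mat)
    B = F @ np.swapaxes(F, -1, -2)
    eye = np.eye(3)
    lnJ = np.log(J)[..., None, None]
    return (mu * (B - eye) + lam * lnJ * eye) / J[..., None, None]


# ---------------------------------------------------------------------------
# damage state machine
# ---------------------------------------------------------------------------


def _max_principal_magnitude(tensor: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(np.asarray(tensor, dtype=float))
    return np.max(np.abs(w), axis=-1)


def damage_update(
    tensor: np.ndarray, mat: MaterialModel, state: np.ndarray | int
) -> np.ndarray | int:
    """Advance the damage state given a stress (foam) or strain (metal) tensor.

    Foam (max-principal-stress criterion): maximum-magnitude principal
    Cauchy stress >= sigma_y marks yielding, >= sigma_u marks failure.
    Metal (max-principal-strain criterion): maximum principal strain >=
    elongation-at-break marks failure.  Transitions are one-way; the
    returned state never decreases.
    """
    tensor = np.asarray(tensor, dtype=float)
    scalar = np.isscalar(state)
    s = np.atleast_1d(np.asarray(state, dtype=np.uint8)).copy()
    value = np.atleast_1d(_max_principal_magnitude(tensor))

    if mat.failure_criterion == "max-principal-stress":
        if mat.yield_stress is None or mat.ultimate_stress is None:
            raise ValueError("stress criterion requires yield and ultimate stress")
        s = np.maximum(s, np.where(value >= mat.yield_stress, YIELDING, ELASTIC))
        s = np.maximum(s, np.where(value >= mat.ultimate_stress, FAILED, ELASTIC))
    elif mat.failure_criterion == "max-principal-strain":
        if mat.elongation_at_break is None:
            raise ValueError("strain criterion requires elongation at break")
        s = np.maximum(s, np.where(value >= mat.elongation_at_break, FAILED, ELASTIC))
    else:
        raise ValueError(f"unknown failure criterion {mat.failure_criterion!r}")

    return int(s[0]) if scalar else s.astype(np.uint8)
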