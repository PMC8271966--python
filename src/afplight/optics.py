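"""Tissue optical properties for liver light-transport simulations.

Holds the absorption coefficient (mu_a), reduced scattering coefficient
(mu_s'), scattering anisotropy (g) and refractive index (n) of a medium at
a given wavelength, together with tabulated presets for native and
thermally ablated (70 degC) liver tissue at 650, 900 and 1050 nm.  The full
scattering coefficient is always derived on demand via mu_s = mu_s'/(1-g);
mu_s' and g are treated as the authoritative inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "OpticalProperties",
    "scattering_from_reduced",
    "table_properties",
    "effective_attenuation",
    "NATIVE",
    "ABLATED_70C",
    "TISSUE_STATES",
    "TABULATED_WAVELENGTHS_NM",
]

NATIVE = "native"
ABLATED_70C = "ablated_70C"
TISSUE_STATES = (NATIVE, ABLATED_70C)
TABULATED_WAVELENGTHS_NM = (650, 900, 1050)


def scattering_from_reduced(mu_s_prime: float, g: float) -> float:
    """Convert a reduced scattering coefficient to the scattering coefficient.

    mu_s = mu_s' / (1 - g), with mu_s' in cm^-1 and g dimensionless in
    [0, 1).  Raises ``ValueError`` for g outside [0, 1) or negative mu_s'.
    """
    if not 0.0 <= g < 1.0:
        raise ValueError(f"anisotropy g must satisfy 0 <= g < 1, got {g}")
    if mu_s_prime < 0.0:
        raise ValueError(f"mu_s_prime must be >= 0, got {mu_s_prime}")
    return mu_s_prime / (1.0 - g)


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of a homogeneous medium at one wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, cm^-1.
    mu_s_prime : float
        Reduced scattering coefficient mu_s' = mu_s (1 - g), cm^-1.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        deflection angle), 0 <= g < 1.
    n : float
        Refractive index, >= 1.
    wavelength : float, optional
        Wavelength in nm (informational).
    """

    mu_a: float
    mu_s_prime: float
    g: float
    n: float = 1.33
    wavelength: float = float("nan")

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_prime < 0:
            raise ValueError(f"mu_s_prime must be >= 0, got {self.mu_s_prime}")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"g must satisfy 0 <= g < 1, got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s'/(1-g), cm^-1."""
        return scattering_from_reduced(self.mu_s_prime, self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, cm^-1."""
        return self.mu_a + self.mu_s

    def as_dict(self) -> dict:
        return {
            "mu_a": self.mu_a,
            "mu_s_prime": self.mu_s_prime,
            "g": self.g,
            "n": self.n,
            "wavelength": self.wavelength,
        }


# Tabulated liver properties: (state, wavelength nm) -> (mu_a, mu_s', g).
# n = 1.33 for both tissue states (no refractive-index data exist for
# ablated liver, so a single index is used and internal refraction is
# ignored).
_LIVER_TABLE: dict[tuple[str, int], tuple[float, float, float]] = {
    (NATIVE, 650): (1.23, 8.26, 0.93),
    (NATIVE, 900): (0.73, 5.04, 0.93),
    (NATIVE, 1050): (0.60, 3.85, 0.93),
    (ABLATED_70C, 650): (0.70, 31.48, 0.90),
    (ABLATED_70C, 900): (0.23, 24.90, 0.90),
    (ABLATED_70C, 1050): (0.24, 18.341, 0.90),
}


def table_properties(tissue_state: str, wavelength: int) -> OpticalProperties:
    """Return the tabulated liver optical properties for a state/wavelength.

    ``tissue_state`` is ``"native"`` or ``"ablated_70C"``; ``wavelength``
    one of 650, 900 or 1050 (nm).  Untabulated combinations raise
    ``KeyError`` — no interpolation is performed, since only these three
    wavelengths were characterized.
    """
    key = (tissue_state, int(wavelength))
    if key not in _LIVER_TABLE:
        raise KeyError(
            f"no tabulated properties for state={tissue_state!r} at "
            f"{wavelength} nm; tabulated: states {TISSUE_STATES}, "
            f"wavelengths {TABULATED_WAVELENGTHS_NM} nm"
        )
    mu_a, mu_s_prime, g = _LIVER_TABLE[key]
    return OpticalProperties(
        mu_a=mu_a, mu_s_prime=mu_s_prime, g=g, n=1.33, wavelength=float(wavelength)
    )


def effective_attenuation(props: OpticalProperties) -> float:
    """Diffusion-theory effective attenuation sqrt(3 mu_a (mu_a + mu_s')), cm^-1.

    Used as an independent closed-form oracle for deep-fluence decay.  For
    mu_a = 0 the diffusion limit is undefined; returns 0 with a warning.
    """
    if props.mu_a == 0.0:
        warnings.warn(
            "effective attenuation undefined for mu_a = 0; returning 0",
            stacklevel=2,
        )
        return 0.0
    return math.sqrt(3.0 * props.mu_a * (props.mu_a + props.mu_s_prime))


def properties_from_mapping(mapping: dict) -> OpticalProperties:
    """Build OpticalProperties from a plain dict (e.g. a parsed YAML block)."""
    return OpticalProperties(
        mu_a=float(mapping["mu_a"]),
        mu_s_prime=float(mapping["mu_s_prime"]),
        g=float(mapping.get("g", 0.9)),
        n=float(mapping.get("n", 1.33)),
        wavelength=float(mapping.get("wavelength", float("nan"))),
    )
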