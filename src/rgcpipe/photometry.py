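"""Photometry of the visual stimulus: photon flux and photoisomerization rates.

For in vivo stimulation, the photon flux at the retina per wavelength
channel is

    I_lambda = T_lambda * F_lambda * A_pupil / A_retina,

with F_lambda = E_lambda / (h*c/lambda) the photon flux at the pupil from
the irradiance E_lambda, A_pupil = pi*(d_pupil/2)^2, and the illuminated
retinal area approximated as
A_retina = (pi*d_retina*omega_az/360) * (pi*d_retina*omega_alt/360).
For an isolated (ex vivo) retina the ocular factors drop out and
I = E / (h*c/lambda).  The photoisomerization rate per photoreceptor is
a * sum_lambda I_lambda * s_lambda with collecting area ``a`` (0.5 um^2
rods, 0.2 um^2 cones) and relative sensitivities per receptor class.

Default constants follow the mouse two-LED (365/454 nm) stimulation setup;
note the recomputation of the retinal fluxes from the irradiances differs
from the printed fluxes by a systematic factor ~1.34 of unknown origin, so
the printed fluxes are accepted directly as inputs for the R* chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import scipy.constants as const

__all__ = [
    "OpticalConfig",
    "photon_flux_at_retina",
    "photon_flux_ex_vivo",
    "photoisomerization_rate",
    "MOUSE_IN_VIVO",
    "PRINTED_FLUX",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical geometry, transmittance and receptor sensitivities.

    Units: irradiance W/m^2, wavelengths m, diameters m, visual coverage
    degrees, collecting areas um^2; transmittance and sensitivities are
    fractions in [0, 1].
    """

    irradiance_w_m2: dict[str, float]
    wavelength_m: dict[str, float]
    transmittance: dict[str, float]
    d_pupil_m: float
    d_retina_m: float
    omega_az_deg: float
    omega_alt_deg: float
    collecting_area_um2: dict[str, float] = field(
        default_factory=lambda: {"rod": 0.5, "S-cone": 0.2, "M-cone": 0.2}
    )
    sensitivity: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.d_pupil_m <= 0 or self.d_retina_m <= 0:
            raise ValueError("diameters must be positive")
        for d in (self.transmittance, *self.sensitivity.values()):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("fractions must lie in [0, 1]")


#: the mouse in vivo stimulation setup: UV (365 nm) and blue (454 nm) channels
MOUSE_IN_VIVO = OpticalConfig(
    irradiance_w_m2={"uv": 15.4e-3, "blue": 15.9e-3},
    wavelength_m={"uv": 365e-9, "blue": 454e-9},
    transmittance={"uv": 0.50, "blue": 0.68},
    d_pupil_m=1e-3,
    d_retina_m=4e-3,
    omega_az_deg=73.0,
    omega_alt_deg=44.0,
    sensitivity={
        "S-cone": {"uv": 0.90, "blue": 0.0},
        "M-cone": {"uv": 0.25, "blue": 0.60},
        "rod": {"uv": 0.25, "blue": 0.60},
    },
)

#: printed retinal photon fluxes (photons/s/um^2), used directly for the
#: R* chain because recomputing them from the irradiances disagrees by a
#: systematic factor (see module docstring)
PRINTED_FLUX = {"uv": 3.81e3, "blue": 6.64e3}


def photon_flux_at_retina(cfg: OpticalConfig, channel: str) -> float:
    """Photon flux at the retina for one channel, photons/s/um^2."""
    lam = cfg.wavelength_m[channel]
    photon_energy = const.h * const.c / lam
    flux_pupil = cfg.irradiance_w_m2[channel] / photon_energy  # photons/s/m^2
    a_pupil = math.pi * (cfg.d_pupil_m / 2.0) ** 2
    a_retina = (math.pi * cfg.d_retina_m * cfg.omega_az_deg / 360.0) * (
        math.pi * cfg.d_retina_m * cfg.omega_alt_deg / 360.0
    )
    if a_retina <= 0:
        raise ValueError("zero illuminated retinal area")
    return cfg.transmittance[channel] * flux_pupil * a_pupil / a_retina / 1e12


def photon_flux_ex_vivo(irradiance_w_m2: float, wavelength_m: float) -> float:
    """Photon flux on an isolated retina (no ocular factors), photons/s/um^2."""
    if wavelength_m <= 0:
        raise ValueError("wavelength must be positive")
    return irradiance_w_m2 / (const.h * const.c / wavelength_m) / 1e12


def photoisomerization_rate(
    flux_per_channel: dict[str, float],
    receptor: str,
    cfg: OpticalConfig = MOUSE_IN_VIVO,
) -> float:
    """R*/receptor/s: collecting area times sensitivity-weighted photon flux."""
    if receptor not in cfg.collecting_area_um2 or receptor not in cfg.sensitivity:
        raise ValueError(f"unknown receptor class {receptor!r}")
    s = cfg.sensitivity[receptor]
    return cfg.collecting_area_um2[receptor] * sum(
        flux * s.get(ch, 0.0) for ch, flux in flux_per_channel.items()
    )
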