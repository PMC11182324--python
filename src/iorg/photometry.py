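"""Stimulus photon-density dosimetry at the retina.

Converts a measured corneal stimulus power density into photons per
square micron delivered to the retina over one stimulus flash:

    photons/s/deg^2 = P / (h c / lambda)

attenuated by lens and macular pigment transmission, multiplied by the
stimulus duration, converted from per-deg^2 to per-µm^2 with the retinal
magnification factor, and corrected for the subject's axial length
relative to a 24 mm reference eye (a longer eye spreads the stimulus
over a larger retinal area, lowering the density).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PhotometryParams", "photon_density"]

PLANCK_H = 6.626e-34  # J s
LIGHT_SPEED = 3.0e8  # m/s


@dataclass
class PhotometryParams:
    """Inputs of the photon-density estimate.

    ``corneal_power_density`` is per square degree of stimulus field by
    default; set ``power_is_total=True`` in :func:`photon_density` when
    supplying total corneal power instead (it is then divided by
    ``stimulus_area``).
    """

    corneal_power_density: float = 17.6  # µW/deg^2
    wavelength: float = 554.0  # nm
    stimulus_duration: float = 0.066  # s
    stimulus_area: float = 1.13  # deg^2
    retinal_magnification: float = 291.0  # µm/deg
    axial_length: float = 24.0  # mm
    reference_axial_length: float = 24.0  # mm
    lens_transmission: float = 1.0
    macular_transmission: float = 1.0
    planck_h: float = PLANCK_H  # J s
    light_speed: float = LIGHT_SPEED  # m/s

    def __post_init__(self) -> None:
        for name in (
            "corneal_power_density", "wavelength", "stimulus_duration",
            "stimulus_area", "retinal_magnification", "axial_length",
            "reference_axial_length", "planck_h", "light_speed",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lens_transmission", "macular_transmission"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


def photon_density(
    params: PhotometryParams,
    axial_convention: str = "area",
    power_is_total: bool = False,
) -> float:
    """Photons per µm^2 delivered to the retina by one stimulus flash.

    Parameters
    ----------
    axial_convention : {"area", "linear"}
        "area" (default) divides by (AL / reference)^2 — the stimulated
        retinal patch grows with the square of axial length, so a longer
        eye receives a lower density.  "linear" multiplies by
        (AL / reference), the literal reading of the ratio correction.
    power_is_total : bool
        Treat ``corneal_power_density`` as total corneal power (µW) and
        divide by ``stimulus_area`` to obtain the per-deg^2 value.
    """
    p = params
    photon_energy_j = p.planck_h * p.light_speed / (p.wavelength * 1e-9)
    power_w_per_deg2 = p.corneal_power_density * 1e-6
    if power_is_total:
        power_w_per_deg2 /= p.stimulus_area
    photons_s_deg2 = power_w_per_deg2 / photon_energy_j
    photons_s_deg2 *= p.lens_transmission * p.macular_transmission
    photons_deg2 = photons_s_deg2 * p.stimulus_duration
    um2_per_deg2 = p.retinal_magnification**2
    density = photons_deg2 / um2_per_deg2
    ratio = p.axial_length / p.reference_axial_length
    if axial_convention == "area":
        density /= ratio**2
    elif axial_convention == "linear":
        density *= ratio
    else:
        raise ValueError("axial_convention must be 'area' or 'linear'")
    return float(density)
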