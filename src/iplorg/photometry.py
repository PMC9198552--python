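"""Stimulus photometry: radiometric to photometric conversions.

The stimulation level of an optoretinography experiment is specified
radiometrically at the retina (spectral irradiance, W m^-2) but reported
photometrically (illuminance in lux, luminance in cd m^-2).  The conversions
are

    Ev = 683 lm/W * integral V(lambda) Ee(lambda) d lambda          (lux)
    Lv = Ev * D^2 / Ap                                              (cd m^-2)

with V the CIE 1924 photopic luminous efficiency function (peak 1 at
555 nm), Ap the pupil area (default 50 mm^2, a dilated ~8 mm pupil) and D
the pupil-to-retina distance (default 17 mm).
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Optional, Tuple

import numpy as np

#: Maximum luminous efficacy of monochromatic 555 nm radiation (lm/W).
LUMINOUS_EFFICACY = 683.0

#: Default dilated-pupil area (mm^2) and pupil-to-retina distance (mm).
DEFAULT_PUPIL_AREA_MM2 = 50.0
DEFAULT_PUPIL_RETINA_DISTANCE_MM = 17.0


def luminous_efficiency() -> Tuple[np.ndarray, np.ndarray]:
    """CIE 1924 photopic V(lambda) table (wavelength in nm, 5 nm steps)."""
    with resources.files("iplorg.data").joinpath("cie1924_photopic.csv").open() as fh:
        data = np.loadtxt(fh, delimiter=",", skiprows=1)
    return data[:, 0], data[:, 1]


def pupil_area(diameter_mm: float = 8.0) -> float:
    """Pupil area (mm^2) of a circular pupil; 8 mm gives ~50.3 mm^2."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    return np.pi * diameter_mm**2 / 4.0


@dataclasses.dataclass
class PhotometrySpec:
    """Inputs and results of a retinal photometry conversion."""

    wavelength_nm: Optional[np.ndarray] = None
    spectral_irradiance: Optional[np.ndarray] = None  # W m^-2 nm^-1
    pupil_area_mm2: float = DEFAULT_PUPIL_AREA_MM2
    distance_mm: float = DEFAULT_PUPIL_RETINA_DISTANCE_MM
    illuminance: Optional[float] = None  # lm m^-2
    luminance: Optional[float] = None  # cd m^-2


def irradiance_to_illuminance(
    wavelength_nm: np.ndarray,
    spectral_irradiance: np.ndarray,
    v_table: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> float:
    """Illuminance Ev = 683 * integral V(l) Ee(l) dl, trapezoidal quadrature.

    ``spectral_irradiance`` is in W m^-2 nm^-1 on the ``wavelength_nm`` grid;
    V is interpolated onto that grid (zero outside its table).  Raises if the
    grids do not overlap.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    ee = np.asarray(spectral_irradiance, dtype=float)
    if wl.shape != ee.shape or wl.ndim != 1 or wl.size < 2:
        raise ValueError("need matching 1-D wavelength and irradiance arrays")
    v_wl, v = v_table if v_table is not None else luminous_efficiency()
    if wl.max() < v_wl.min() or wl.min() > v_wl.max():
        raise ValueError("wavelength grid does not overlap the V(lambda) table")
    v_on_grid = np.interp(wl, v_wl, v, left=0.0, right=0.0)
    return float(LUMINOUS_EFFICACY * np.trapezoid(v_on_grid * ee, wl))


def monochromatic_illuminance(wavelength_nm: float, irradiance: float) -> float:
    """Ev of a monochromatic source: 683 * V(lambda) * Ee (Ee in W m^-2)."""
    v_wl, v = luminous_efficiency()
    if not (v_wl.min() <= wavelength_nm <= v_wl.max()):
        raise ValueError("wavelength outside the V(lambda) table")
    return float(LUMINOUS_EFFICACY * np.interp(wavelength_nm, v_wl, v) * irradiance)


def illuminance_to_luminance(
    illuminance: float,
    pupil_area_mm2: float = DEFAULT_PUPIL_AREA_MM2,
    distance_mm: float = DEFAULT_PUPIL_RETINA_DISTANCE_MM,
) -> float:
    """Luminance Lv = Ev * D^2 / Ap (cd m^-2).

    The ratio D^2 / Ap is dimensionless when both are given in consistent
    units (mm and mm^2 here), converting retinal illuminance into the
    luminance of the stimulus as seen through the pupil.
    """
    if pupil_area_mm2 <= 0 or distance_mm <= 0:
        raise ValueError("pupil area and distance must be positive")
    return float(illuminance * distance_mm**2 / pupil_area_mm2)


def led_spectrum(
    wavelength_nm: Optional[np.ndarray] = None,
    blue_peak_nm: float = 450.0,
    blue_sigma_nm: float = 10.0,
    phosphor_peak_nm: float = 560.0,
    phosphor_sigma_nm: float = 50.0,
    phosphor_fraction: float = 0.75,
) -> Tuple[np.ndarray, np.ndarray]:
    """Parameterised white-LED spectrum (blue die + phosphor band).

    Returns a unit-integral relative spectral power distribution.  This is a
    demonstration model: the spectrum of the LED actually used for retinal
    stimulation is a free parameter of any given experiment, so no claim is
    made that a particular irradiance/luminance pair is reproduced exactly.
    """
    if wavelength_nm is None:
        wavelength_nm = np.arange(380.0, 781.0, 1.0)
    wl = np.asarray(wavelength_nm, dtype=float)
    blue = np.exp(-0.5 * ((wl - blue_peak_nm) / blue_sigma_nm) ** 2)
    phos = np.exp(-0.5 * ((wl - phosphor_peak_nm) / phosphor_sigma_nm) ** 2)
    s = (1.0 - phosphor_fraction) * blue / np.trapezoid(
        blue, wl
    ) + phosphor_fraction * phos / np.trapezoid(phos, wl)
    return wl, s / np.trapezoid(s, wl)


def retinal_photometry(
    irradiance_w_m2: float,
    spectrum: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    pupil_area_mm2: float = DEFAULT_PUPIL_AREA_MM2,
    distance_mm: float = DEFAULT_PUPIL_RETINA_DISTANCE_MM,
) -> PhotometrySpec:
    """Full conversion: total irradiance + relative spectrum -> Ev and Lv."""
    if spectrum is None:
        spectrum = led_spectrum()
    wl, s = spectrum
    s = np.asarray(s, dtype=float)
    ee = irradiance_w_m2 * s / np.trapezoid(s, wl)
    ev = irradiance_to_illuminance(wl, ee)
    lv = illuminance_to_luminance(ev, pupil_area_mm2, distance_mm)
    return PhotometrySpec(
        wavelength_nm=np.asarray(wl),
        spectral_irradiance=ee,
        pupil_area_mm2=pupil_area_mm2,
        distance_mm=distance_mm,
        illuminance=ev,
        luminance=lv,
    )
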