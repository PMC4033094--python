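"""Modified Beer-Lambert Law conversion between ΔOD and ΔHbO/ΔHb.

The MBLL relates the optical-density change at wavelength λ to the
chromophore concentration changes through the molar extinction
coefficients ε, the source–detector separation L and the differential
pathlength factor DPF(λ):

    ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_Hb(λ)·ΔHb] · L · DPF(λ)

With two wavelengths this is a 2×2 linear system per channel per sample;
``mbll_invert`` solves it exactly.
"""

from __future__ import annotations

import numpy as np

from .recording import HemoRecording, OpticalRecording

# Molar extinction coefficients (cm^-1 M^-1) for oxy- and deoxy-hemoglobin,
# transcribed from the Prahl/OMLC tabulation of the Gratzer–Kollias
# compilation (subset of grid points; linear interpolation in between).
# Columns: wavelength nm, eps_HbO2, eps_Hb.
_EXTINCTION_TABLE = np.array([
    [650.0,  368.0, 3750.12],
    [660.0,  319.6, 3226.56],
    [680.0,  277.6, 2407.92],
    [690.0,  276.0, 2051.96],
    [700.0,  290.0, 1794.28],
    [710.0,  314.0, 1540.48],
    [730.0,  390.0, 1102.20],
    [740.0,  446.0, 1115.88],
    [750.0,  518.0, 1405.24],
    [760.0,  586.0, 1548.52],
    [770.0,  650.0, 1311.88],
    [780.0,  710.0, 1075.44],
    [800.0,  816.0,  761.72],
    [810.0,  864.0,  717.08],
    [820.0,  916.0,  693.76],
    [830.0,  974.0,  693.04],
    [840.0, 1022.0,  692.36],
    [850.0, 1058.0,  691.32],
    [880.0, 1154.0,  726.44],
    [900.0, 1198.0,  761.84],
])

SUPPORTED_RANGE = (float(_EXTINCTION_TABLE[0, 0]),
                   float(_EXTINCTION_TABLE[-1, 0]))

#: provenance string naming the bundled table's source
EXTINCTION_SOURCE = (
    "Gratzer–Kollias molar extinction compilation (Prahl/OMLC tabulation), "
    "linear interpolation"
)

MAX_CONDITION = 1e6


def extinction_coefficients(wavelength: float) -> tuple[float, float]:
    """(ε_HbO, ε_Hb) in cm⁻¹·M⁻¹ at ``wavelength`` nm."""
    lo, hi = SUPPORTED_RANGE
    if not lo <= wavelength <= hi:
        raise ValueError(
            f"wavelength {wavelength} nm outside the bundled extinction "
            f"table ({lo:.0f}–{hi:.0f} nm)"
        )
    grid = _EXTINCTION_TABLE[:, 0]
    e_hbo = float(np.interp(wavelength, grid, _EXTINCTION_TABLE[:, 1]))
    e_hb = float(np.interp(wavelength, grid, _EXTINCTION_TABLE[:, 2]))
    return e_hbo, e_hb


def extinction_matrix(wavelengths: tuple[float, float]) -> np.ndarray:
    """2×2 extinction matrix E with E[i, j] = ε_j(λ_i), j = (HbO, Hb)."""
    if len(wavelengths) != 2:
        raise ValueError("exactly two wavelengths required")
    return np.array([extinction_coefficients(wl) for wl in wavelengths])


def _check_conditioning(optical: OpticalRecording) -> np.ndarray:
    E = optical.optics.extinction_array
    cond = np.linalg.cond(E)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise ValueError(
            f"extinction matrix for wavelength pair "
            f"{optical.optics.wavelengths} is ill-conditioned "
            f"(condition number {cond:.3g} > {MAX_CONDITION:.0e}); "
            "choose wavelengths on opposite sides of the isosbestic point"
        )
    return E


def mbll_invert(optical: OpticalRecording) -> HemoRecording:
    """Convert two-wavelength ΔOD to ΔHbO/ΔHb (µM) per channel.

    Solves, per sample, the 2×2 system
    ΔOD(λᵢ) = Σ_c ε_c(λᵢ)·Δc · L · DPF(λᵢ), c ∈ {HbO, Hb}.
    """
    optics = optical.optics
    E = _check_conditioning(optical)
    scale = optics.separation * np.asarray(optics.dpf)  # per wavelength
    Einv = np.linalg.inv(E)
    series: dict[str, dict[str, np.ndarray]] = {}
    for ch in optical.channels:
        od = optical.od[ch]  # (n, 2)
        conc_molar = (od / scale) @ Einv.T  # (n, 2) in mol/L
        conc_um = conc_molar * 1e6
        series[ch] = {"HbO": conc_um[:, 0], "Hb": conc_um[:, 1]}
    rec = HemoRecording(
        rate=optical.rate,
        series=series,
        provenance=[dict(p) for p in optical.provenance],
    )
    rec.log(
        "mbll",
        wavelengths=list(optics.wavelengths),
        separation_cm=optics.separation,
        dpf=list(optics.dpf),
        extinction_source=EXTINCTION_SOURCE,
        condition_number=float(np.linalg.cond(E)),
    )
    return rec
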