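"""Parameter types for the simulator, optics, and filtering chain.

Defaults encode the recording setup the pipeline targets: bilateral
prefrontal measurement at 6.25 Hz, task-evoked hemodynamic responses that
lag stimulus onset by 1–2 s and peak 4–8 s after it, anticorrelated
HbO/Hb, and the standard physiological contaminants (cardiac ≈ 1–1.5 Hz,
respiration ≈ 0.2–0.4 Hz, Mayer waves ≈ 0.1 Hz, slow drift, white noise).
Hemoglobin concentration changes are in µM throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_RATE = 6.25  # Hz


@dataclass(frozen=True)
class HdrParams:
    """Shape of the task-evoked hemodynamic response.

    onset_lag
        Delay between stimulus onset and the start of the response (s).
    time_to_peak
        Time from response start to peak (s); the kernel peaks at
        ``onset_lag + time_to_peak`` after stimulus onset.
    undershoot_fraction
        Relative amplitude of the post-peak undershoot lobe.
    hbo_amplitude
        Plateau ΔHbO under sustained activation, µM.
    hb_to_hbo_ratio
        Negative scalar mapping the HbO response onto Hb (anticorrelation).
    lateralization
        In [0, 1]: left-channel gain is 1, right-channel gain is
        ``1 − lateralization``; 1.0 routes the whole response to the left
        channel so the bilateral difference carries it.
    """

    onset_lag: float = 1.5
    time_to_peak: float = 6.0
    undershoot_fraction: float = 0.1
    hbo_amplitude: float = 1.0
    hb_to_hbo_ratio: float = -1.0 / 3.0
    lateralization: float = 1.0

    def __post_init__(self) -> None:
        if self.time_to_peak <= 0:
            raise ValueError("time_to_peak must be positive")
        if self.onset_lag < 0:
            raise ValueError("onset_lag must be non-negative")
        if self.hb_to_hbo_ratio >= 0:
            raise ValueError("hb_to_hbo_ratio must be negative")
        if not 0.0 <= self.lateralization <= 1.0:
            raise ValueError("lateralization must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseParams:
    """Physiological + instrument noise: (frequency Hz, amplitude µM) pairs.

    ``drift`` is (low-pass cutoff Hz, standard deviation µM) of a filtered
    Gaussian random walk; its cutoff sits below the 0.01 Hz detrending
    cutoff so detrending removes it.
    """

    cardiac: tuple[float, float] = (1.2, 0.4)
    respiration: tuple[float, float] = (0.3, 0.3)
    mayer: tuple[float, float] = (0.1, 0.2)
    drift: tuple[float, float] = (0.004, 1.0)
    white_sd: float = 0.15

    def __post_init__(self) -> None:
        for name in ("cardiac", "respiration", "mayer", "drift"):
            f, a = getattr(self, name)
            if a < 0:
                raise ValueError(f"{name} amplitude must be >= 0")
            if f <= 0:
                raise ValueError(f"{name} frequency must be > 0")
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")
        if self.drift[0] >= 0.01:
            raise ValueError("drift cutoff must sit below 0.01 Hz")

    @classmethod
    def silent(cls) -> "NoiseParams":
        return cls(
            cardiac=(1.2, 0.0),
            respiration=(0.3, 0.0),
            mayer=(0.1, 0.0),
            drift=(0.004, 0.0),
            white_sd=0.0,
        )


@dataclass(frozen=True)
class MotionParams:
    """Motion-artifact process: exponential spikes and baseline shifts.

    Rates are events per minute; amplitudes µM.  With ``common_mode`` the
    artifact is added identically to a channel's HbO and Hb — exactly the
    structure correlation-based correction removes.
    """

    spike_rate: float = 2.0
    spike_amplitude: float = 5.0
    shift_rate: float = 0.5
    shift_amplitude: float = 3.0
    common_mode: bool = True

    def __post_init__(self) -> None:
        for name in ("spike_rate", "spike_amplitude", "shift_rate",
                     "shift_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def none(cls) -> "MotionParams":
        return cls(spike_rate=0.0, spike_amplitude=0.0,
                   shift_rate=0.0, shift_amplitude=0.0)


@dataclass(frozen=True)
class OpticsParams:
    """Forward-optics constants for the two-wavelength measurement.

    ``extinction`` is the 2×2 molar extinction matrix E with
    E[i, j] = ε_j(λ_i), chromophore order (HbO, Hb), in cm⁻¹·M⁻¹;
    ``separation`` the source–detector distance in cm; ``dpf`` the
    differential pathlength factor per wavelength.
    """

    wavelengths: tuple[float, float] = (690.0, 830.0)
    extinction: tuple[tuple[float, float], tuple[float, float]] = ()
    separation: float = 3.0
    dpf: tuple[float, float] = (6.0, 6.0)

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("dpf values must be positive")
        for wl in self.wavelengths:
            if not 650.0 <= wl <= 1000.0:
                raise ValueError(
                    f"wavelength {wl} nm outside the near-infrared window "
                    "(650–1000 nm)"
                )
        if not self.extinction:
            from .mbll import extinction_matrix

            E = extinction_matrix(self.wavelengths)
            object.__setattr__(
                self, "extinction", tuple(tuple(row) for row in E)
            )
        E = self.extinction_array
        if E.shape != (2, 2):
            raise ValueError("extinction must be a 2×2 matrix")
        if np.linalg.cond(E) > 1e6:
            raise ValueError(
                f"extinction matrix for wavelengths {self.wavelengths} is "
                f"near-singular (condition number {np.linalg.cond(E):.3g})"
            )

    @property
    def extinction_array(self) -> np.ndarray:
        return np.asarray(self.extinction, dtype=float)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.extinction_array))


@dataclass(frozen=True)
class FilterSettings:
    """The preprocessing chain's knobs.

    detrend_cut / smooth_cut are the −3 dB targets (Hz) of the degree-
    ``sg_degree`` Savitzky–Golay low-pass filters used for detrending
    (subtraction) and smoothing; ``cbsi_enabled`` gates the final
    correlation-based motion correction.
    """

    detrend_cut: float = 0.01
    smooth_cut: float = 0.15
    sg_degree: int = 1
    cbsi_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.detrend_cut < self.smooth_cut:
            raise ValueError("need 0 < detrend_cut < smooth_cut")
        if self.sg_degree < 1:
            raise ValueError("sg_degree must be >= 1")
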