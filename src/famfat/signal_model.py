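"""Closed-form signal physics for chemical-shift-encoded (CSE) fat-water MRI.

This module implements the voxel-level signal equations that everything else
in the package builds on:

* the multi-peak fat phasor ``c(TE) = sum_p a_p exp(i 2 pi f_p TE)``, with
  peak frequencies ``f_p`` derived from chemical-shift offsets (ppm) at a
  given field strength,
* the multi-echo CSE voxel signal
  ``s(TE_n) = (W + F c_n) exp(-R2* TE_n) exp(i 2 pi psi TE_n)``,
* the spoiled-gradient-echo (SPGR) steady-state signal law
  ``sin(a) (1 - E1) / (1 - E1 cos(a))`` with ``E1 = exp(-TR/T1)``,
* the apparent (T1-biased) PDFF measured by a constant-flip steady-state
  acquisition, obtained by weighting fat and water by their respective
  steady-state signal levels.

Sign conventions: a positive off-resonance ``psi`` (Hz) contributes phase
``+2 pi psi TE``; fat chemical-shift offsets are negative for peaks that
precess slower than water (the main methylene peak sits near -3.4 ppm).
Data acquired with the conjugate convention can be conjugated before use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Reduced gyromagnetic ratio of the proton, MHz/T.
GAMMA_BAR_MHZ_PER_T = 42.5775

#: Additive shift of the fat spectrum relative to water used for gel
#: phantoms imaged at room temperature (ppm).
PHANTOM_TEMP_SHIFT_PPM = 0.11

# Six-peak liver fat spectrum (offsets in ppm relative to water, relative
# amplitudes).  Amplitudes are renormalized to sum exactly to one at
# construction.
DEFAULT_FAT_OFFSETS_PPM = (-3.80, -3.40, -2.60, -1.94, -0.39, 0.60)
DEFAULT_FAT_AMPLITUDES = (0.087, 0.693, 0.128, 0.004, 0.039, 0.048)


@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak fat resonance model.

    Parameters
    ----------
    offsets_ppm:
        Chemical-shift offsets of the fat peaks relative to water, in ppm.
        Negative values denote peaks that precess slower than water.
    amplitudes:
        Relative peak amplitudes.  They are renormalized so that they sum
        to one, which makes the phasor equal exactly ``1 + 0j`` at TE = 0.
    temp_shift_ppm:
        Additive shift applied to every offset, in ppm.  Gel phantoms at
        room temperature shift the water reference by about 0.11 ppm
        relative to body temperature; in vivo use 0.
    """

    offsets_ppm: tuple[float, ...] = DEFAULT_FAT_OFFSETS_PPM
    amplitudes: tuple[float, ...] = DEFAULT_FAT_AMPLITUDES
    temp_shift_ppm: float = 0.0

    def __post_init__(self) -> None:
        if len(self.offsets_ppm) == 0:
            raise ValueError("fat spectrum must contain at least one peak")
        if len(self.offsets_ppm) != len(self.amplitudes):
            raise ValueError("offsets and amplitudes must have equal length")
        amps = np.asarray(self.amplitudes, dtype=float)
        if np.any(amps < 0):
            raise ValueError("amplitudes must be nonnegative")
        total = amps.sum()
        if total <= 0:
            raise ValueError("amplitudes must have a positive sum")
        object.__setattr__(self, "amplitudes", tuple(amps / total))
        object.__setattr__(self, "offsets_ppm", tuple(float(o) for o in self.offsets_ppm))

    def with_temperature_correction(self, shift_ppm: float = PHANTOM_TEMP_SHIFT_PPM) -> "FatSpectrum":
        """Return a copy with the phantom temperature shift applied."""
        return replace(self, temp_shift_ppm=shift_ppm)

    def peak_freqs_hz(self, b0_t: float) -> np.ndarray:
        """Peak frequencies relative to water, in Hz, at field ``b0_t`` (T)."""
        if b0_t <= 0:
            raise ValueError("b0_t must be positive")
        offsets = np.asarray(self.offsets_ppm, dtype=float) + self.temp_shift_ppm
        return GAMMA_BAR_MHZ_PER_T * b0_t * offsets  # MHz/T * T * ppm -> Hz


@dataclass(frozen=True)
class TissueVoxel:
    """Parameters of one voxel in the standard single-R2* fat-water model.

    ``W = m0 (1 - pdff)`` and ``F = m0 pdff`` are the water and fat proton
    densities; both species share a common effective transverse decay rate
    ``r2star_s`` (1/s) and field offset ``psi_hz`` (Hz).
    """

    m0: float = 1.0
    pdff: float = 0.0
    t1_water_ms: float = 1000.0
    t1_fat_ms: float = 300.0
    r2star_s: float = 0.0
    psi_hz: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pdff <= 1.0:
            raise ValueError("pdff must lie in [0, 1]")
        if self.t1_water_ms <= 0 or self.t1_fat_ms <= 0:
            raise ValueError("T1 values must be positive")
        if self.r2star_s < 0:
            raise ValueError("r2star_s must be nonnegative")

    @property
    def water(self) -> float:
        return self.m0 * (1.0 - self.pdff)

    @property
    def fat(self) -> float:
        return self.m0 * self.pdff


def fat_phasor(spectrum: FatSpectrum, te_ms, b0_t: float):
    """Complex fat phasor ``c(TE)`` at echo time(s) ``te_ms`` (ms).

    Returns a complex scalar for scalar input or an array matching the
    input shape.  ``|c| <= 1`` with equality only when all peaks align.
    """
    te = np.asarray(te_ms, dtype=float)
    if np.any(te < 0):
        raise ValueError("te_ms must be nonnegative")
    freqs = spectrum.peak_freqs_hz(b0_t)  # Hz
    amps = np.asarray(spectrum.amplitudes, dtype=float)
    phase = 2.0 * np.pi * np.multiply.outer(te * 1e-3, freqs)  # TE in s
    c = np.tensordot(np.exp(1j * phase), amps, axes=([-1], [0]))
    return complex(c) if np.isscalar(te_ms) else c


def cse_signal(voxel: TissueVoxel, spectrum: FatSpectrum, tes_ms, b0_t: float) -> np.ndarray:
    """Complex multi-echo CSE signal of one voxel.

    ``s(TE_n) = (W + F c_n) exp(-R2* TE_n) exp(+i 2 pi psi TE_n)``.
    """
    tes = np.asarray(tes_ms, dtype=float)
    if tes.ndim != 1 or tes.size < 1:
        raise ValueError("tes_ms must be a 1-D vector")
    if np.any(np.diff(tes) <= 0):
        raise ValueError("echo times must be strictly increasing")
    if np.any(tes < 0):
        raise ValueError("echo times must be nonnegative")
    c = fat_phasor(spectrum, tes, b0_t)
    te_s = tes * 1e-3
    decay = np.exp(-voxel.r2star_s * te_s)
    offres = np.exp(1j * 2.0 * np.pi * voxel.psi_hz * te_s)
    return (voxel.water + voxel.fat * c) * decay * offres


def spgr_steady_state(alpha_deg: float, tr_ms: float, t1_ms: float) -> float:
    """Steady-state SPGR signal as a fraction of the equilibrium magnetization.

    ``S = sin(a) (1 - E1) / (1 - E1 cos(a))``, ``E1 = exp(-TR/T1)``.
    """
    if not 0.0 < alpha_deg <= 90.0:
        raise ValueError("alpha_deg must lie in (0, 90]")
    if tr_ms <= 0 or t1_ms <= 0:
        raise ValueError("tr_ms and t1_ms must be positive")
    a = np.deg2rad(alpha_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    return float(np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a)))


def apparent_pdff_steady_state(
    true_pdff: float,
    alpha_deg: float,
    tr_ms: float,
    t1_water_ms: float,
    t1_fat_ms: float,
) -> float:
    """Apparent PDFF measured by a constant-flip steady-state acquisition.

    Fat and water reach different steady-state signal levels when their T1
    differ, so the measured fat fraction is the signal-weighted

    ``PDFF_app = F g_f / (F g_f + W g_w)``

    with ``g`` the SPGR steady-state factor at each species' T1.  Because
    liver fat has shorter T1 than water (so ``g_f > g_w``), steady-state
    acquisitions overestimate PDFF; the bias vanishes as ``alpha -> 0``.
    Returns a fraction in [0, 1].
    """
    if not 0.0 <= true_pdff <= 1.0:
        raise ValueError("true_pdff must lie in [0, 1]")
    if true_pdff in (0.0, 1.0):
        return float(true_pdff)
    g_w = spgr_steady_state(alpha_deg, tr_ms, t1_water_ms)
    g_f = spgr_steady_state(alpha_deg, tr_ms, t1_fat_ms)
    f = true_pdff * g_f
    w = (1.0 - true_pdff) * g_w
    return float(f / (f + w))
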