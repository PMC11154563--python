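"""Beer–Lambert forward simulation of multiwavelength transmissive PPG.

The simulator produces records with known ground-truth pulsatile (AC) and
static (DC) transmitted intensities so every downstream stage — filtering,
landmark detection, AC/DC extraction, quality scoring and regression — can be
tested against an analytic answer.

Model
-----
For a narrowband LED at wavelength λ the clean transmitted intensity is

    I(t) = Is · 10^(−[ ε_static(λ)·L + (Σ_s ε_s(λ)·C_s) · ΔL · p(t) ])

where the sum runs over the four hemoglobin species (oxy-, reduced, met-,
carboxyhemoglobin), C_s is the species concentration in g/L, L the baseline
optical path, ΔL the peak arterial path modulation and p(t) ∈ [0, 1] the
cardiac pulse waveform (p = 0 at end-diastole, p = 1 at the systolic peak).
The broadband channel is the emission-spectrum-weighted sum of narrowband
responses over the wavelength grid — the discrete form of integrating the
LED spectrum against the per-wavelength transmission.

Ground truth per channel: I_DC is the cycle minimum of the clean intensity
(p = 1), I_AC the cycle peak-to-peak excursion (p = 0 minus p = 1), and the
AC/DC ratio their quotient, which is monotone in hemoglobin concentration
on every channel with nonzero extinction.

The extinction curves are synthetic defaults, not literature digitizations;
they honor only the qualitative ordering that matters (reduced-hemoglobin
absorption peaking near 660 nm, oxyhemoglobin rising toward 880–940 nm).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_io import MultichannelPPG

__all__ = [
    "SPECIES",
    "NARROWBAND_WAVELENGTHS_NM",
    "ExtinctionTable",
    "PulseMorphology",
    "SimConfig",
    "GroundTruth",
    "CohortRecord",
    "default_extinction_table",
    "default_led_spectrum",
    "pulse_waveform",
    "simulate",
    "simulate_cohort",
]

SPECIES = ("oxyhemoglobin", "reduced_hemoglobin", "methemoglobin", "carboxyhemoglobin")

#: Peak wavelengths of the seven narrowband LEDs.
NARROWBAND_WAVELENGTHS_NM = (660.0, 700.0, 730.0, 800.0, 850.0, 880.0, 940.0)

#: Nominal centroid wavelength recorded for the broadband channel.
BROADBAND_NOMINAL_NM = 780.0


@dataclass(frozen=True)
class ExtinctionTable:
    """Per-wavelength absorption coefficients on a common grid.

    ``eps_hb`` has one row per hemoglobin species (order :data:`SPECIES`) in
    L·g⁻¹·mm⁻¹; ``eps_static`` is the lumped static-tissue absorbance per mm
    of path (extinction × concentration already folded together).
    """

    grid_nm: np.ndarray
    eps_hb: np.ndarray        # shape (4, n_grid)
    eps_static: np.ndarray    # shape (n_grid,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_nm", np.asarray(self.grid_nm, dtype=float))
        object.__setattr__(self, "eps_hb", np.asarray(self.eps_hb, dtype=float))
        object.__setattr__(self, "eps_static", np.asarray(self.eps_static, dtype=float))
        if self.eps_hb.shape != (len(SPECIES), self.grid_nm.size):
            raise ValueError("eps_hb must be (n_species, n_grid)")
        if self.eps_static.shape != self.grid_nm.shape:
            raise ValueError("eps_static must match the grid")
        if np.any(np.diff(self.grid_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.eps_hb < 0) or np.any(self.eps_static < 0):
            raise ValueError("absorption coefficients must be non-negative")

    def eps_at(self, wavelength_nm: float) -> np.ndarray:
        """Per-species coefficients at one wavelength (linear interpolation)."""
        return np.array([
            np.interp(wavelength_nm, self.grid_nm, self.eps_hb[i])
            for i in range(len(SPECIES))
        ])

    def static_at(self, wavelength_nm: float) -> float:
        return float(np.interp(wavelength_nm, self.grid_nm, self.eps_static))


def default_extinction_table() -> ExtinctionTable:
    """Deterministic synthetic extinction curves on a 550–1100 nm grid.

    Reduced hemoglobin peaks near 660 nm and falls into the NIR;
    oxyhemoglobin rises toward 880–940 nm; met- and carboxyhemoglobin are
    broad, smaller terms.  Static tissue gets a flat absorbance with a mild
    water-like bump near 980 nm.
    """
    grid = np.arange(550.0, 1100.0 + 1e-9, 5.0)
    oxy = 2.0e-4 + 8.0e-4 / (1.0 + np.exp(-(grid - 800.0) / 60.0))
    red = 2.0e-4 + 1.2e-3 * np.exp(-((grid - 650.0) / 90.0) ** 2)
    met = 1.0e-4 + 6.0e-4 * np.exp(-((grid - 630.0) / 100.0) ** 2)
    carboxy = 5.0e-5 + 8.0e-4 * np.exp(-((grid - 570.0) / 90.0) ** 2)
    static = 0.15 + 0.03 * np.exp(-((grid - 980.0) / 60.0) ** 2)
    return ExtinctionTable(grid, np.vstack([oxy, red, met, carboxy]), static)


def default_led_spectrum(grid_nm: np.ndarray,
                         center_nm: float = BROADBAND_NOMINAL_NM,
                         width_nm: float = 120.0) -> np.ndarray:
    """Normalized emission weights of the broadband LED on the grid."""
    b = np.exp(-((np.asarray(grid_nm, dtype=float) - center_nm) / width_nm) ** 2)
    return b / b.sum()


@dataclass(frozen=True)
class PulseMorphology:
    """Pulse shape parameters in phase units (fractions of one period).

    The waveform is a systolic primary lobe plus a smaller diastolic
    sub-wave (dicrotic bump), each Gaussian in phase.
    """

    primary_center: float = 0.16
    primary_width: float = 0.09
    sub_center: float = 0.52
    sub_width: float = 0.10
    sub_amplitude: float = 0.35


def pulse_waveform(t: np.ndarray, heart_rate_hz: float,
                   morphology: PulseMorphology | None = None) -> np.ndarray:
    """Periodic unitless pulse p(t) normalized to [0, 1] per period.

    Two local maxima per period (primary > sub-wave) unless the sub-wave
    amplitude is zero.  ``heart_rate_hz`` must lie in the physiological band
    (0.6, 3.0).
    """
    if not 0.6 < heart_rate_hz < 3.0:
        raise ValueError(f"heart rate {heart_rate_hz} Hz outside (0.6, 3.0)")
    m = morphology or PulseMorphology()

    def raw(phase: np.ndarray) -> np.ndarray:
        out = np.zeros_like(phase)
        # wrap neighbouring periods so the waveform is smooth across 0/1
        for k in (-1.0, 0.0, 1.0):
            out += np.exp(-0.5 * ((phase - m.primary_center + k) / m.primary_width) ** 2)
            out += m.sub_amplitude * np.exp(
                -0.5 * ((phase - m.sub_center + k) / m.sub_width) ** 2)
        return out

    dense = raw(np.linspace(0.0, 1.0, 4096, endpoint=False))
    lo, hi = dense.min(), dense.max()
    phase = np.mod(np.asarray(t, dtype=float) * heart_rate_hz, 1.0)
    return np.clip((raw(phase) - lo) / (hi - lo), 0.0, 1.0)


@dataclass(frozen=True)
class SimConfig:
    """Forward-model configuration; defaults emulate one finger acquisition.

    Units: concentrations g/L, paths mm, rates Hz, duration s.  ``noise_sd``
    and ``drift_amp`` are relative to each channel's DC level;
    ``artifact_rate`` is motion bursts per second.  ``pressure_ac_coupling``
    scales the pulsatile path with contact pressure,
    ΔL_eff = ΔL·(1 + coupling·(P − P_ref)/P_ref), modelling perfusion change
    under the finger clip.
    """

    hb_g_per_L: float = 135.0
    species_fractions: tuple[float, float, float, float] = (0.94, 0.04, 0.01, 0.01)
    Is: float = 4096.0
    L_mm: float = 10.0
    dL_mm: float = 0.1
    heart_rate_hz: float = 1.2
    fs_hz: float = 500.0
    duration_s: float = 12.8
    noise_sd: float = 0.0
    drift_amp: float = 0.0
    drift_hz: float = 0.25
    artifact_rate: float = 0.0
    pressure_mean: float = 2.0
    pressure_sd: float = 0.0
    pressure_ref: float = 2.0
    pressure_ac_coupling: float = 0.0
    displacement_mm: float = 11.0
    seed: int = 0
    wavelengths_nm: tuple[float, ...] = NARROWBAND_WAVELENGTHS_NM
    led_spectrum: Optional[np.ndarray] = None
    morphology: PulseMorphology = field(default_factory=PulseMorphology)

    def __post_init__(self) -> None:
        if abs(sum(self.species_fractions) - 1.0) > 1e-9:
            raise ValueError("species fractions must sum to 1")
        for name in ("hb_g_per_L", "Is", "L_mm", "heart_rate_hz", "fs_hz",
                     "duration_s", "pressure_mean", "displacement_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.dL_mm < 0 or self.noise_sd < 0 or self.drift_amp < 0 \
                or self.artifact_rate < 0 or self.pressure_sd < 0:
            raise ValueError("noise/drift/artifact/modulation parameters must be >= 0")
        if not 0 < self.drift_hz < 0.5:
            raise ValueError("drift frequency must sit below the 0.6 Hz bandpass edge")


@dataclass(frozen=True)
class GroundTruth:
    """Per-channel analytic AC/DC of the clean signal, channels in record order."""

    ac: np.ndarray
    dc: np.ndarray
    hb_g_per_L: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "ac", np.asarray(self.ac, dtype=float))
        object.__setattr__(self, "dc", np.asarray(self.dc, dtype=float))
        if np.any(self.dc <= 0):
            raise ValueError("ground-truth DC must be positive")

    @property
    def ratio(self) -> np.ndarray:
        return self.ac / self.dc


def _effective_dl(cfg: SimConfig) -> float:
    return cfg.dL_mm * (1.0 + cfg.pressure_ac_coupling
                        * (cfg.pressure_mean - cfg.pressure_ref) / cfg.pressure_ref)


def _clean_channels(cfg: SimConfig, ext: ExtinctionTable,
                    p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clean intensities (n_samples, n_ch) plus endpoint intensities at p=0, p=1."""
    conc = cfg.hb_g_per_L * np.asarray(cfg.species_fractions)
    dl = _effective_dl(cfg)

    def intensity(a_static: np.ndarray, a_dyn: np.ndarray, pulse) -> np.ndarray:
        return cfg.Is * 10.0 ** (-(a_static + np.multiply.outer(pulse, a_dyn)))

    # narrowband channels at their nominal wavelengths
    a_static_nb = np.array([ext.static_at(w) * cfg.L_mm for w in cfg.wavelengths_nm])
    a_dyn_nb = np.array([ext.eps_at(w) @ conc * dl for w in cfg.wavelengths_nm])
    clean_nb = intensity(a_static_nb, a_dyn_nb, p)
    top_nb = intensity(a_static_nb, a_dyn_nb, np.array([0.0]))[0]
    bot_nb = intensity(a_static_nb, a_dyn_nb, np.array([1.0]))[0]

    # broadband channel: spectral sum of per-grid narrowband responses
    b = cfg.led_spectrum if cfg.led_spectrum is not None \
        else default_led_spectrum(ext.grid_nm)
    b = np.asarray(b, dtype=float)
    if b.shape != ext.grid_nm.shape:
        raise ValueError("led_spectrum must be defined on the extinction grid")
    a_static_g = ext.eps_static * cfg.L_mm
    a_dyn_g = (conc @ ext.eps_hb) * dl
    grid_i = intensity(a_static_g, a_dyn_g, p)          # (n_samples, n_grid)
    clean_bb = grid_i @ b
    top_bb = intensity(a_static_g, a_dyn_g, np.array([0.0]))[0] @ b
    bot_bb = intensity(a_static_g, a_dyn_g, np.array([1.0]))[0] @ b

    clean = np.column_stack([clean_nb, clean_bb])
    top = np.append(top_nb, top_bb)
    bot = np.append(bot_nb, bot_bb)
    return clean, top, bot


def simulate(cfg: SimConfig,
             ext: ExtinctionTable | None = None) -> tuple[MultichannelPPG, GroundTruth]:
    """Simulate one multichannel recording and its analytic ground truth.

    Channel order: narrowband channels in the order of ``cfg.wavelengths_nm``,
    broadband last.  Drift, Gaussian noise and Poisson-timed motion-artifact
    bursts are added on top of the clean Beer–Lambert signal; the ground truth
    is always computed from the clean signal.  Deterministic given the seed.
    """
    ext = ext or default_extinction_table()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz
    p = pulse_waveform(t, cfg.heart_rate_hz, cfg.morphology)

    clean, top, bot = _clean_channels(cfg, ext, p)
    truth = GroundTruth(ac=top - bot, dc=bot, hb_g_per_L=cfg.hb_g_per_L)

    signal = clean.copy()
    n_ch = signal.shape[1]
    if cfg.drift_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        drift = np.sin(2 * np.pi * cfg.drift_hz * t[:, None] + phases[None, :])
        signal = signal + cfg.drift_amp * truth.dc[None, :] * drift
    if cfg.noise_sd > 0:
        signal = signal + cfg.noise_sd * truth.dc[None, :] * rng.standard_normal(signal.shape)
    # motion artifacts hit all channels simultaneously, scaled per channel
    n_art = rng.poisson(cfg.artifact_rate * cfg.duration_s)
    for _ in range(n_art):
        onset = rng.uniform(0, cfg.duration_s)
        width = rng.uniform(0.2, 0.6)
        amp = rng.uniform(1.0, 4.0) * rng.choice([-1.0, 1.0])
        mask = (t >= onset) & (t < onset + width)
        if not mask.any():
            continue
        burst = np.sin(np.pi * (t[mask] - onset) / width)
        signal[mask, :] += amp * truth.ac[None, :] * burst[:, None]
    signal = np.clip(signal, 0.0, None)
    if not np.all(np.isfinite(signal)):
        raise FloatingPointError("simulated intensities are not finite")

    pressure = np.full(n, cfg.pressure_mean)
    if cfg.pressure_sd > 0:
        slow = rng.standard_normal(n)
        kernel = np.ones(int(cfg.fs_hz)) / cfg.fs_hz
        pressure = pressure + cfg.pressure_sd * np.convolve(slow, kernel, mode="same")
    displacement = np.full(n, cfg.displacement_mm) + 0.005 * rng.standard_normal(n)

    wavelengths = np.append(np.asarray(cfg.wavelengths_nm), BROADBAND_NOMINAL_NM)
    broadband = np.zeros(n_ch, dtype=bool)
    broadband[-1] = True
    rec = MultichannelPPG(
        time=t, channels=signal, wavelengths_nm=wavelengths, broadband=broadband,
        pressure=pressure, displacement=displacement, fs_hz=cfg.fs_hz)
    return rec, truth


@dataclass(frozen=True)
class CohortRecord:
    record: MultichannelPPG
    truth: GroundTruth
    quality: int          # +1 satisfactory, -1 poor
    config: SimConfig


#: Study conditions for a "satisfactory" vs a "poor" acquisition.
GOOD_CONDITIONS = dict(noise_sd=0.002, drift_amp=0.01, artifact_rate=0.02)
POOR_CONDITIONS = dict(noise_sd=0.02, drift_amp=0.05, artifact_rate=0.6)


def simulate_cohort(n: int,
                    hb_range: tuple[float, float] = (80.0, 160.0),
                    quality_mix: float = 0.3,
                    seed: int = 0,
                    ext: ExtinctionTable | None = None,
                    pressure_coupling: float = 0.5,
                    **overrides) -> list[CohortRecord]:
    """Simulate a cohort of subjects with known hemoglobin and quality labels.

    Hemoglobin is uniform on ``hb_range``; heart rate, contact pressure and
    per-subject optical geometry (±5% pulsatile path, ±10% source intensity
    and baseline path) vary across records.  Exactly ``floor(quality_mix·n)``
    records are "poor" (elevated noise, drift and motion-artifact rate),
    assigned by a seeded permutation.  Contact pressure couples to the
    pulsatile amplitude through ``pressure_coupling`` so that the mean
    pressure is an informative ninth regression feature.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= quality_mix <= 1.0:
        raise ValueError("quality_mix must lie in [0, 1]")
    lo, hi = hb_range
    if not hi > lo:
        raise ValueError("hb_range must be a nonempty (low, high) interval")
    ext = ext or default_extinction_table()
    rng = np.random.default_rng(seed)

    n_bad = int(np.floor(quality_mix * n))
    labels = np.ones(n, dtype=int)
    labels[rng.permutation(n)[:n_bad]] = -1

    base = SimConfig()
    out: list[CohortRecord] = []
    for i in range(n):
        conditions = POOR_CONDITIONS if labels[i] == -1 else GOOD_CONDITIONS
        cfg = dataclasses.replace(
            base,
            hb_g_per_L=float(rng.uniform(lo, hi)),
            heart_rate_hz=float(rng.uniform(1.1, 1.4)),
            pressure_mean=float(rng.uniform(1.5, 2.5)),
            pressure_sd=0.03,
            pressure_ac_coupling=pressure_coupling,
            dL_mm=base.dL_mm * float(rng.uniform(0.95, 1.05)),
            Is=base.Is * float(rng.uniform(0.9, 1.1)),
            L_mm=base.L_mm * float(rng.uniform(0.9, 1.1)),
            seed=int(rng.integers(0, 2**31 - 1)),
            **conditions,
            **overrides,
        )
        rec, truth = simulate(cfg, ext)
        out.append(CohortRecord(rec, truth, int(labels[i]), cfg))
    return out
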