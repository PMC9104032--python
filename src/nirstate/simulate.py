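"""Synthetic CW-fNIRS session generator.

Emulates the statistical structure the downstream analysis assumes: a
block design alternating "relax" and "2-back" (starting and ending with
relax), a canonical double-gamma hemodynamic response on task-positive
long channels, physiological noise (cardiac ~1 Hz, respiration ~0.25 Hz,
Mayer waves ~0.1 Hz, slow drift, white noise), and a forward modified
Beer-Lambert projection to two-wavelength raw intensities.  Everything
is deterministic under a fixed seed.

The defaults describe one session: 10 task blocks of 40 s (ten stimuli a
few seconds apart) interleaved with 11 relax blocks of 20 s, sampled at
10 Hz — about twenty trials, the regime in which a two-class chance
level of 70% applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .mbll import MOLAR_PER_MICROMOLAR, MM_PER_CM, OpticalRecording, OpticsConstants, default_constants
from .montage import MontageSpec, default_montage

__all__ = [
    "BlockDesign",
    "NoiseSpec",
    "SimConfig",
    "GroundTruth",
    "make_block_design",
    "make_trial_list",
    "double_gamma_hrf",
    "simulate_hemodynamics",
    "forward_mbll",
    "simulate_session",
]

RELAX = "relax"
NBACK = "nback"


@dataclass(frozen=True)
class BlockDesign:
    """Ordered, gap-free alternation of relax and task blocks."""

    events: tuple[tuple[float, float, str], ...]  # (onset_s, duration_s, label)
    total_duration: float

    def __post_init__(self) -> None:
        labels = [e[2] for e in self.events]
        if not labels or labels[0] != RELAX or labels[-1] != RELAX:
            raise ValueError("design must start and end with a relax block")
        for a, b in zip(labels, labels[1:]):
            if a == b:
                raise ValueError("block labels must strictly alternate")
        t = 0.0
        for onset, dur, _ in self.events:
            if onset < t - 1e-9:
                raise ValueError("overlapping or unsorted events")
            t = onset + dur

    def labels_per_sample(self, n_samples: int, rate: float) -> np.ndarray:
        """Label each sample by the block covering it."""
        out = np.empty(n_samples, dtype=object)
        t = np.arange(n_samples) / rate
        for onset, dur, label in self.events:
            out[(t >= onset) & (t < onset + dur)] = label
        return out


@dataclass(frozen=True)
class NoiseSpec:
    """Physiological noise amplitudes, in µM of HbO-equivalent concentration."""

    cardiac_freq: float = 1.0
    cardiac_amp: float = 0.2
    respiration_freq: float = 0.25
    respiration_amp: float = 0.1
    mayer_freq: float = 0.1
    mayer_amp: float = 0.1
    drift_slope: float = 0.001  # µM per second, random sign per channel
    white_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("cardiac_amp", "respiration_amp", "mayer_amp", "white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def max_frequency(self) -> float:
        return max(self.cardiac_freq, self.respiration_freq, self.mayer_freq)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of one simulated session."""

    sampling_rate: float = 10.0
    n_nback_blocks: int = 10
    nback_block_duration: float = 40.0
    relax_block_duration: float = 20.0
    hrf_peak_delay: float = 6.0
    hrf_undershoot_delay: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    activation_amplitude_hbo: float = 1.0  # µM
    activation_ratio_hbr: float = -1.0 / 3.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    dpf: tuple[float, float] = (6.0, 6.0)
    baseline_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * self.noise.max_frequency:
            raise ValueError(
                "sampling_rate must exceed twice the highest noise frequency"
            )
        if self.activation_amplitude_hbo < 0:
            raise ValueError("activation amplitude must be non-negative")


@dataclass
class GroundTruth:
    """Noise-inclusive concentration series plus per-sample block labels."""

    time: np.ndarray
    hbo: np.ndarray  # (samples, channels), µM
    hbr: np.ndarray
    channel_ids: tuple[str, ...]
    sampling_rate: float
    labels: np.ndarray  # per-sample block label
    design: BlockDesign
    regressor: np.ndarray  # unit-amplitude task regressor (boxcar ⊛ HRF)


def make_block_design(config: SimConfig) -> BlockDesign:
    """relax, nback, relax, ..., nback, relax — n task blocks, n+1 relax."""
    if config.n_nback_blocks < 1:
        raise ValueError("need at least one task block")
    if config.nback_block_duration <= 0 or config.relax_block_duration <= 0:
        raise ValueError("block durations must be positive")
    events: list[tuple[float, float, str]] = []
    t = 0.0
    for _ in range(config.n_nback_blocks):
        events.append((t, config.relax_block_duration, RELAX))
        t += config.relax_block_duration
        events.append((t, config.nback_block_duration, NBACK))
        t += config.nback_block_duration
    events.append((t, config.relax_block_duration, RELAX))
    t += config.relax_block_duration
    return BlockDesign(events=tuple(events), total_duration=t)


def make_trial_list(seed: int) -> list[str]:
    """Randomised within-block stimulus sequence: 3 targets, 7 non-targets."""
    rng = np.random.default_rng(seed)
    trials = ["target"] * 3 + ["nontarget"] * 7
    rng.shuffle(trials)
    return trials


def double_gamma_hrf(t: np.ndarray, config: SimConfig) -> np.ndarray:
    """Canonical double-gamma impulse response, normalised to unit peak.

    Positive lobe peaking at ``hrf_peak_delay`` s, undershoot peaking at
    ``hrf_undershoot_delay`` s scaled by ``hrf_undershoot_ratio``.
    """
    peak = stats.gamma.pdf(t, config.hrf_peak_delay + 1.0, scale=1.0)
    under = stats.gamma.pdf(t, config.hrf_undershoot_delay + 1.0, scale=1.0)
    h = peak - config.hrf_undershoot_ratio * under
    m = h.max()
    return h / m if m > 0 else h


def task_regressor(design: BlockDesign, config: SimConfig) -> np.ndarray:
    """Boxcar over task blocks convolved with the unit-peak HRF."""
    rate = config.sampling_rate
    n = int(round(design.total_duration * rate))
    box = np.zeros(n)
    for onset, dur, label in design.events:
        if label == NBACK:
            i0 = int(round(onset * rate))
            i1 = int(round((onset + dur) * rate))
            box[i0:i1] = 1.0
    t_hrf = np.arange(0.0, 32.0, 1.0 / rate)
    hrf = double_gamma_hrf(t_hrf, config)
    return np.convolve(box, hrf)[:n]


def _noise_series(rng: np.random.Generator, n: int, rate: float, spec: NoiseSpec) -> np.ndarray:
    """One channel's physiological noise: oscillations with random phase,
    a random-sign linear drift, and white noise."""
    t = np.arange(n) / rate
    out = np.zeros(n)
    for freq, amp in (
        (spec.cardiac_freq, spec.cardiac_amp),
        (spec.respiration_freq, spec.respiration_amp),
        (spec.mayer_freq, spec.mayer_amp),
    ):
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.sin(2 * np.pi * freq * t + phase)
    out += rng.choice([-1.0, 1.0]) * spec.drift_slope * t
    out += rng.normal(0.0, spec.white_sd, n)
    return out


def simulate_hemodynamics(
    design: BlockDesign, config: SimConfig, montage: MontageSpec | None = None
) -> GroundTruth:
    """Concentration ground truth: activation on long channels, noise on all.

    HbO on each long channel is ``amplitude × (boxcar ⊛ HRF) + noise``;
    HbR is the activation scaled by ``activation_ratio_hbr`` (negative:
    washout of deoxy-hemoglobin) plus independent noise at one third the
    HbO noise amplitude.  Short channels carry noise only.
    """
    montage = montage if montage is not None else default_montage()
    rate = config.sampling_rate
    reg = task_regressor(design, config)
    n = len(reg)
    rng = np.random.default_rng(config.seed)
    n_ch = len(montage.channels)
    hbo = np.empty((n, n_ch))
    hbr = np.empty((n, n_ch))
    hbr_noise = replace(
        config.noise,
        cardiac_amp=config.noise.cardiac_amp / 3,
        respiration_amp=config.noise.respiration_amp / 3,
        mayer_amp=config.noise.mayer_amp / 3,
        white_sd=config.noise.white_sd / 3,
    )
    for j, ch in enumerate(montage.channels):
        act = config.activation_amplitude_hbo * reg if ch.kind == "long" else 0.0
        hbo[:, j] = act + _noise_series(rng, n, rate, config.noise)
        hbr[:, j] = config.activation_ratio_hbr * act + _noise_series(
            rng, n, rate, hbr_noise
        )
    return GroundTruth(
        time=np.arange(n) / rate,
        hbo=hbo,
        hbr=hbr,
        channel_ids=tuple(c.id for c in montage.channels),
        sampling_rate=rate,
        labels=design.labels_per_sample(n, rate),
        design=design,
        regressor=reg,
    )


def forward_mbll(
    truth: GroundTruth,
    montage: MontageSpec | None = None,
    config: SimConfig | None = None,
    constants: OpticsConstants | None = None,
) -> OpticalRecording:
    """Project concentrations to raw two-wavelength intensities.

    I_λ(t) = I₀ · 10^(−(ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR) · d · DPF_λ) with d
    in cm and concentrations in mol/L — the exact inverse of the MBLL
    conversion when the same constants are used.
    """
    montage = montage if montage is not None else default_montage()
    config = config if config is not None else SimConfig()
    constants = constants if constants is not None else default_constants()
    wl = montage.wavelengths_nm
    e = constants.matrix(wl)  # (2 wavelengths, 2 chromophores)
    dpf = np.asarray(config.dpf, dtype=float)
    n = truth.hbo.shape[0]
    n_ch = len(truth.channel_ids)
    intensity = np.empty((n, n_ch, 2))
    for j, cid in enumerate(truth.channel_ids):
        ch = montage.channel(cid)
        pathlen = (ch.distance_mm / MM_PER_CM) * dpf  # cm per wavelength
        conc = np.stack([truth.hbo[:, j], truth.hbr[:, j]]) * MOLAR_PER_MICROMOLAR
        od = (e * pathlen[:, None]) @ conc  # (2, samples)
        intensity[:, j, :] = config.baseline_intensity * 10.0 ** (-od.T)
    return OpticalRecording(
        time=truth.time,
        intensity=intensity,
        channel_ids=truth.channel_ids,
        wavelengths_nm=(wl[0], wl[1]),
        sampling_rate=truth.sampling_rate,
        events=[tuple(ev) for ev in truth.design.events],
        montage=montage,
    )


def simulate_session(
    config: SimConfig | None = None, montage: MontageSpec | None = None
) -> tuple[OpticalRecording, GroundTruth]:
    """Convenience wrapper: design → hemodynamics → raw optical recording."""
    config = config if config is not None else SimConfig()
    montage = montage if montage is not None else default_montage()
    design = make_block_design(config)
    truth = simulate_hemodynamics(design, config, montage)
    rec = forward_mbll(truth, montage, config)
    return rec, truth
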