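"""Synthetic bilateral smart-insole accelerometer data.

Real insole recordings of level walking are quasi-periodic at the stride
frequency, with the right-foot signal a roughly half-stride-delayed copy of
the left-foot signal and per-subject differences in cadence, speed, and the
harmonic content of the acceleration waveform.  This module generates data
with exactly that structure: each simulated user is a :class:`GaitProfile`
(a small set of latent gait parameters), each 10 m walk a sum of H harmonics
of the user's stride frequency per channel, perturbed by per-trial jitter and
additive white Gaussian noise.

The generator makes no claim of biomechanical fidelity (no ground-reaction
shapes, no gravity offset -- units are arbitrary because everything is
z-scored downstream); it reproduces only the statistical premises the
classifier relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SAMPLE_RATE_HZ, AccelRecording

#: harmonics of the stride frequency per channel
N_HARMONICS = 4

# A 10 m walk must last between 7.2 s (216 samples) and 9.6 s (290 samples);
# hence speeds in [10/9.6, 10/7.2] m/s.
SPEED_MIN = 10.0 / 9.6
SPEED_MAX = 10.0 / 7.2

# Default profile sampling narrows the speed band so that cadence jitter
# (truncated to [0.94, 1.06]) cannot push a trial outside [216, 290] samples.
_CADENCE_JITTER_SD = 0.02
_CADENCE_JITTER_BOUND = 0.06
_AMPLITUDE_JITTER_SD = 0.05
_SPEED_LO = 10.0 / (9.6 * (1 - _CADENCE_JITTER_BOUND))
_SPEED_HI = 10.0 / (7.2 * (1 + _CADENCE_JITTER_BOUND))

_STRIDE_FREQ_LO = 0.85
_STRIDE_FREQ_HI = 1.05

SEPARATION_LEVELS = ("low", "default", "high")


@dataclass(frozen=True)
class GaitProfile:
    """Latent per-user gait parameters driving the simulator.

    ``harmonic_amplitudes`` and ``harmonic_phases`` are (6, H) arrays; the
    right-foot rows (3..5) equal the left-foot rows (0..2) up to a positive
    per-user asymmetry scale, and the right-foot channels are additionally
    delayed by ``left_right_offset`` stride periods at generation time.
    """

    user_id: int
    stride_frequency: float  # Hz, full left+right gait cycles per second
    walking_speed: float  # m/s
    harmonic_amplitudes: np.ndarray  # (6, H)
    harmonic_phases: np.ndarray  # (6, H), radians
    left_right_offset: float = 0.5  # fraction of stride period
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.user_id < 0:
            raise ValueError("user_id must be >= 0")
        if not self.stride_frequency > 0:
            raise ValueError("stride_frequency must be positive")
        if not (SPEED_MIN <= self.walking_speed <= SPEED_MAX):
            raise ValueError(
                f"walking_speed {self.walking_speed:.4f} outside "
                f"[{SPEED_MIN:.4f}, {SPEED_MAX:.4f}] m/s (10 m walk in 7.2-9.6 s)"
            )
        if not (0.4 <= self.left_right_offset <= 0.6):
            raise ValueError("left_right_offset must lie in [0.4, 0.6]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        amps = np.asarray(self.harmonic_amplitudes, dtype=np.float64)
        phases = np.asarray(self.harmonic_phases, dtype=np.float64)
        if amps.shape != phases.shape or amps.ndim != 2 or amps.shape[0] != 6:
            raise ValueError("harmonic arrays must both have shape (6, H)")
        if amps.shape[1] < 3:
            raise ValueError("need at least 3 harmonics per channel")
        object.__setattr__(self, "harmonic_amplitudes", amps)
        object.__setattr__(self, "harmonic_phases", phases)


@dataclass(frozen=True)
class TrialJitter:
    """Per-trial multiplicative cadence/amplitude jitter and a phase shift."""

    cadence_scale: float = 1.0
    amplitude_scale: float = 1.0
    phase_shift: float = 0.0  # radians of stride phase

    def __post_init__(self) -> None:
        if self.cadence_scale <= 0 or self.amplitude_scale <= 0:
            raise ValueError("jitter scales must be positive")


IDENTITY_JITTER = TrialJitter()


def _draw_channel_params(rng: np.random.Generator):
    """Left-foot harmonic amplitudes/phases plus mirrored right-foot rows."""
    # amplitudes decay with harmonic order, as in real gait spectra
    left_amp = rng.uniform(0.3, 1.0, size=(3, N_HARMONICS)) / np.arange(
        1, N_HARMONICS + 1
    )
    left_phase = rng.uniform(0.0, 2 * np.pi, size=(3, N_HARMONICS))
    asym = rng.uniform(0.9, 1.1)
    amps = np.vstack([left_amp, asym * left_amp])
    phases = np.vstack([left_phase, left_phase])
    return amps, phases


def sample_profiles(
    n_users: int,
    rng_seed: int,
    separation: str = "default",
    noise_sd: float = 0.2,
) -> list[GaitProfile]:
    """Draw ``n_users`` gait profiles, deterministically from ``rng_seed``.

    ``separation`` controls how distinguishable users are:

    - ``"default"``: independent draws from the documented parameter ranges.
    - ``"high"``: cadences spaced on an even grid over a widened band and
      independent harmonic signatures -- maximally separable.
    - ``"low"``: every user shares one parameter point, so the label carries
      no information (a chance-level control).
    """
    if n_users < 0:
        raise ValueError("n_users must be >= 0")
    if separation not in SEPARATION_LEVELS:
        raise ValueError(f"separation must be one of {SEPARATION_LEVELS}")
    rng = np.random.default_rng(rng_seed)
    profiles: list[GaitProfile] = []
    if n_users == 0:
        return profiles

    if separation == "low":
        amps, phases = _draw_channel_params(rng)
        freq = rng.uniform(_STRIDE_FREQ_LO, _STRIDE_FREQ_HI)
        speed = rng.uniform(_SPEED_LO, _SPEED_HI)
        for uid in range(n_users):
            profiles.append(
                GaitProfile(
                    user_id=uid,
                    stride_frequency=freq,
                    walking_speed=speed,
                    harmonic_amplitudes=amps,
                    harmonic_phases=phases,
                    left_right_offset=0.5,
                    noise_sd=noise_sd,
                )
            )
        return profiles

    if separation == "high":
        freqs = np.linspace(0.80, 1.10, n_users) if n_users > 1 else np.array([0.95])
    else:
        freqs = rng.uniform(_STRIDE_FREQ_LO, _STRIDE_FREQ_HI, size=n_users)

    for uid in range(n_users):
        amps, phases = _draw_channel_params(rng)
        speed = rng.uniform(_SPEED_LO, _SPEED_HI)
        offset = rng.uniform(0.45, 0.55)
        profiles.append(
            GaitProfile(
                user_id=uid,
                stride_frequency=float(freqs[uid]),
                walking_speed=float(speed),
                harmonic_amplitudes=amps,
                harmonic_phases=phases,
                left_right_offset=float(offset),
                noise_sd=noise_sd,
            )
        )
    return profiles


def sample_jitter(rng: np.random.Generator) -> TrialJitter:
    """Draw one trial's jitter from the documented truncated-normal defaults."""
    lo, hi = 1 - _CADENCE_JITTER_BOUND, 1 + _CADENCE_JITTER_BOUND
    cadence = float(np.clip(rng.normal(1.0, _CADENCE_JITTER_SD), lo, hi))
    amp = float(max(rng.normal(1.0, _AMPLITUDE_JITTER_SD), 0.5))
    phase = float(rng.uniform(0.0, 2 * np.pi))
    return TrialJitter(cadence_scale=cadence, amplitude_scale=amp, phase_shift=phase)


def generate_trial(
    profile: GaitProfile,
    distance_m: float = 10.0,
    rng: np.random.Generator | None = None,
    jitter: TrialJitter = IDENTITY_JITTER,
    recording_id: str | None = None,
    trial_id: int = 0,
) -> AccelRecording:
    """Simulate one walk of ``distance_m`` meters for ``profile``.

    The recording length is L = round(duration x 30) with
    duration = distance / (walking_speed x cadence_scale).  Each left-foot
    channel is a sum of H harmonics of the jittered stride frequency; the
    corresponding right-foot channel is the same waveform delayed by
    ``left_right_offset`` stride periods.  White Gaussian noise of the
    profile's ``noise_sd`` is added to every channel.
    """
    if distance_m <= 0:
        raise ValueError("distance_m must be positive")
    if rng is None:
        rng = np.random.default_rng()
    duration = distance_m / (profile.walking_speed * jitter.cadence_scale)
    L = int(round(duration * SAMPLE_RATE_HZ))
    freq = profile.stride_frequency * jitter.cadence_scale
    t = np.arange(L) / SAMPLE_RATE_HZ  # (L,)
    # stride-phase shift expressed as a time shift
    t0 = jitter.phase_shift / (2 * np.pi * freq)
    delay = profile.left_right_offset / freq

    k = np.arange(1, profile.harmonic_amplitudes.shape[1] + 1)  # (H,)
    amps = profile.harmonic_amplitudes * jitter.amplitude_scale  # (6, H)
    phases = profile.harmonic_phases  # (6, H)

    samples = np.empty((L, 6), dtype=np.float64)
    for c in range(6):
        tc = t + t0 - (delay if c >= 3 else 0.0)
        # (L, H) harmonic bank summed over harmonics
        arg = 2 * np.pi * freq * np.outer(tc, k) + phases[c]
        samples[:, c] = np.sin(arg) @ amps[c]
    if profile.noise_sd > 0:
        samples += rng.normal(0.0, profile.noise_sd, size=samples.shape)

    rid = recording_id or f"user{profile.user_id:03d}_trial{trial_id:03d}"
    return AccelRecording(
        recording_id=rid,
        user_id=profile.user_id,
        trial_id=trial_id,
        samples=samples,
    )


def generate_dataset(
    profiles: list[GaitProfile],
    n_trials: int = 10,
    rng_seed: int = 0,
    distance_m: float = 10.0,
) -> list[AccelRecording]:
    """Simulate ``n_trials`` walks per profile; deterministic given the seed.

    Every trial gets fresh :class:`TrialJitter`; recordings are ordered by
    (user, trial).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng_seed)
    recordings: list[AccelRecording] = []
    for profile in profiles:
        for trial in range(n_trials):
            jit = sample_jitter(rng)
            recordings.append(
                generate_trial(
                    profile,
                    distance_m=distance_m,
                    rng=rng,
                    jitter=jit,
                    trial_id=trial,
                )
            )
    return recordings
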