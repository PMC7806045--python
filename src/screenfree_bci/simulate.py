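"""Synthetic screen-free BCI sessions with controllable subclass structure.

Emulates the highlighting paradigm: per trial, each of ``n_objects`` candidate
objects is highlighted in turn with a 3 s laser-stimulus sequence (100 ms
flashes at an SOA of 250 or 500 ms), repeated ``n_repetitions`` times; the
user attends exactly one target object per trial.  The generated 31-channel
recording superimposes event-related responses — a biphasic sensory
deflection for every highlighting plus a parietal P300-like bump for
targets — with per-object gain and latency heterogeneity, an amplitude
boost for the first stimulus of each sequence, spatially correlated pink
noise, and occasional high-amplitude blink artifacts.

The default configuration is 24 trials balanced over 4 candidate objects,
3 repetitions, 250 ms SOA, 1 kHz sampling on 31 channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft

from .data import ContinuousRecording, EventSchedule

__all__ = [
    "SessionConfig",
    "build_schedule",
    "generate_recording",
    "simulate_session",
    "heterogeneity_presets",
]


@dataclass(frozen=True)
class SessionConfig:
    """Simulator parameters.

    Amplitudes are in uV at the scalp maximum of the respective component;
    ``noise_scale`` is the per-channel RMS of the background noise.
    """

    n_trials: int = 24
    n_repetitions: int = 3
    n_objects: int = 4
    soa: float = 0.25
    sequence_duration: float = 3.0
    stimulus_duration: float = 0.1
    rate: float = 1000.0
    n_channels: int = 31
    gains: tuple = ()  # per-object multipliers; empty -> all 1
    latency_shifts_ms: tuple = ()  # per-object, empty -> all 0
    target_p3_amplitude: float = 6.0
    initial_boost: float = 1.5
    noise_scale: float = 10.0
    artifact_rate: float = 2.0  # blinks per minute
    inter_sequence_gap: float = 1.0
    lead_in: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_seq = self.sequence_duration / self.soa
        if abs(n_seq - round(n_seq)) > 1e-9:
            raise ValueError(
                f"sequence_duration/soa = {n_seq} must be a positive integer"
            )
        if self.gains and len(self.gains) != self.n_objects:
            raise ValueError("gains must have one entry per object")
        if self.latency_shifts_ms and len(self.latency_shifts_ms) != self.n_objects:
            raise ValueError("latency_shifts_ms must have one entry per object")

    @property
    def stimuli_per_sequence(self) -> int:
        return int(round(self.sequence_duration / self.soa))

    @property
    def object_gains(self) -> np.ndarray:
        return np.asarray(self.gains or (1.0,) * self.n_objects, dtype=float)

    @property
    def object_latencies_s(self) -> np.ndarray:
        raw = self.latency_shifts_ms or (0.0,) * self.n_objects
        return np.asarray(raw, dtype=float) / 1000.0


def heterogeneity_presets() -> dict[str, SessionConfig]:
    """Named configurations for the two object-saliency regimes.

    ``homogeneous``: identical per-object responses.  ``heterogeneous``:
    two salient objects (gains 1.5, 1.2) and two low-salience ones (0.7,
    0.5) with latency shifts, echoing the salient/less-salient split
    found among everyday objects under laser highlighting.
    """
    return {
        "homogeneous": SessionConfig(),
        "heterogeneous": SessionConfig(
            gains=(1.5, 1.2, 0.7, 0.5),
            latency_shifts_ms=(0.0, 0.0, 10.0, 25.0),
        ),
    }


def build_schedule(cfg: SessionConfig) -> EventSchedule:
    """Event schedule: trials x repetitions x objects x stimuli.

    Targets are balanced across objects when ``n_trials`` is divisible by
    ``n_objects`` (round-robin target list, order shuffled from the seed);
    within a repetition, the object highlighting order is a seeded
    permutation.  Sequence positions q are numbered from 1; consecutive
    sequences are separated by ``inter_sequence_gap``.
    """
    rng = np.random.default_rng(cfg.seed)
    objects = np.arange(1, cfg.n_objects + 1)
    reps = int(np.ceil(cfg.n_trials / cfg.n_objects))
    targets = np.tile(objects, reps)[: cfg.n_trials]
    rng.shuffle(targets)
    n_seq = cfg.stimuli_per_sequence
    rows = []
    t = cfg.lead_in
    for trial in range(1, cfg.n_trials + 1):
        target = targets[trial - 1]
        for rep in range(1, cfg.n_repetitions + 1):
            order = rng.permutation(objects)
            for obj in order:
                for q in range(1, n_seq + 1):
                    rows.append(
                        (t + (q - 1) * cfg.soa, obj, trial, rep, q, obj == target)
                    )
                t += cfg.sequence_duration + cfg.inter_sequence_gap
    frame = pd.DataFrame(
        rows,
        columns=["onset_s", "object", "trial", "repetition", "seq_position", "is_target"],
    )
    return EventSchedule(frame)


def _component_kernel(rate: float, center: float, sigma: float, length: float = 0.8) -> np.ndarray:
    t = np.arange(0.0, length, 1.0 / rate)
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _montage_positions(n_channels: int) -> np.ndarray:
    """Fictitious 2-D montage: concentric rings on the unit disk.

    y > 0 is frontal, y < 0 parietal/occipital; used both for component
    spatial patterns and for the noise correlation kernel.
    """
    ring_sizes = [1, 8, 10, 12]
    radii = [0.0, 0.35, 0.7, 1.0]
    pos = []
    for size, r in zip(ring_sizes, radii):
        for i in range(size):
            theta = 2 * np.pi * i / size + (0.5 if r > 0 else 0.0)
            pos.append((r * np.cos(theta), r * np.sin(theta)))
    pos = np.asarray(pos)
    if len(pos) < n_channels:
        raise ValueError(f"montage supports at most {len(pos)} channels")
    return pos[:n_channels]


def _spatial_pattern(pos: np.ndarray, center: tuple, sigma: float = 0.55) -> np.ndarray:
    d2 = ((pos - np.asarray(center)) ** 2).sum(axis=1)
    p = np.exp(-0.5 * d2 / sigma**2)
    return p / p.max()


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """Unit-RMS pink (1/f amplitude) noise, independent across channels."""
    n_fft = scipy.fft.next_fast_len(n_samples)
    white = rng.standard_normal((n_channels, n_fft))
    spec = scipy.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_fft)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = scipy.fft.irfft(spec * scale, n=n_fft, axis=1)[:, :n_samples]
    return pink / pink.std(axis=1, keepdims=True)


def generate_recording(cfg: SessionConfig, sched: EventSchedule) -> ContinuousRecording:
    """Render the schedule into a continuous multi-channel recording.

    Linear superposition of per-event component kernels scaled by object
    gain and (for q = 1) the initial boost, shifted by the object's
    latency, projected through fixed spatial patterns; plus spatially
    correlated pink noise and Poisson-placed frontal blink artifacts.
    Bit-reproducible from the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    rate = cfg.rate
    n_samples = int(round((sched.onsets[-1] + 2.0) * rate))
    pos = _montage_positions(cfg.n_channels)
    patterns = np.stack(
        [
            _spatial_pattern(pos, (0.0, -0.75)),  # N1: posterior
            _spatial_pattern(pos, (0.0, 0.15)),   # P2: central
            _spatial_pattern(pos, (0.0, -0.35)),  # P300: parietal
        ]
    )  # 3 x n_channels
    # component amplitudes (uV): biphasic sensory response for every
    # highlighting; the P300 bump only for targets
    kernels = [
        -3.0 * _component_kernel(rate, 0.12, 0.025),
        4.0 * _component_kernel(rate, 0.20, 0.035),
        cfg.target_p3_amplitude * _component_kernel(rate, 0.30, 0.040),
    ]
    comp = np.zeros((3, n_samples))
    gains = cfg.object_gains
    lats = cfg.object_latencies_s
    frame = sched.frame
    onsets = sched.onsets
    for i in range(len(sched)):
        obj = frame["object"].iat[i] - 1
        amp = gains[obj] * (cfg.initial_boost if frame["seq_position"].iat[i] == 1 else 1.0)
        start = int(round((onsets[i] + lats[obj]) * rate))
        active = [0, 1, 2] if frame["is_target"].iat[i] else [0, 1]
        for c in active:
            k = kernels[c]
            stop = min(start + k.shape[0], n_samples)
            comp[c, start:stop] += amp * k[: stop - start]
    signal = patterns.T @ comp
    if cfg.noise_scale > 0:
        dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        K = np.exp(-dist / 0.5)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(cfg.n_channels))
        noise = L @ _pink_noise(rng, cfg.n_channels, n_samples)
        noise *= cfg.noise_scale / noise.std(axis=1, keepdims=True)
        signal = signal + noise
    if cfg.artifact_rate > 0:
        blink_pattern = _spatial_pattern(pos, (0.0, 0.95), sigma=0.4)
        n_blinks = rng.poisson(cfg.artifact_rate * n_samples / rate / 60.0)
        blink_kernel = 150.0 * _component_kernel(rate, 0.18, 0.06, length=0.4)
        for _ in range(n_blinks):
            start = int(rng.integers(0, max(1, n_samples - blink_kernel.shape[0])))
            stop = start + blink_kernel.shape[0]
            signal[:, start:stop] += np.outer(blink_pattern, blink_kernel)
    names = [f"SIM{i + 1:02d}" for i in range(cfg.n_channels)]
    return ContinuousRecording(data=signal, rate=rate, channel_names=names)


def simulate_session(cfg: SessionConfig) -> tuple[ContinuousRecording, EventSchedule]:
    """Convenience wrapper: schedule plus rendered recording."""
    sched = build_schedule(cfg)
    return generate_recording(cfg, sched), sched
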