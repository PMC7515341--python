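"""Synthetic RR-interval generator with controllable spectral structure.

Beats are emitted by an integrate-to-threshold rule (IPFM-style): given a
continuous modulating tachogram r(t) in ms, the next beat follows the current
one after r(t)/1000 seconds. The tachogram is a mean RR plus sinusoidal
components in the VLF/LF/HF bands, optionally amplitude-modulated by a slow
"apnea cycle" (period 25-60 s, the cyclical-variation timescale of obstructive
events); white jitter models beat-to-beat noise and a small per-beat ectopic
rate injects doubled intervals the median filter must catch. Minutes
containing an apnea-cycle trough are annotated "apnea", so the labeling logic
of the preprocessing stage has real work to do on synthetic records.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import (
    HRVSegment,
    MinuteAnnotations,
    RRSeries,
    interpolate_resample,
    remove_artifacts,
    segment_and_label,
)

__all__ = [
    "SynthConfig",
    "CohortSpec",
    "generate_rr",
    "generate_cohort",
    "apnea_like_config",
    "normal_like_config",
]

_MINUTE_S = 60.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic record.

    ``osc_components`` is a tuple of (frequency Hz, amplitude ms, phase rad)
    sinusoids; ``apnea_cycle`` is an optional (period s, depth fraction)
    amplitude modulation whose troughs mark apneic minutes.
    """

    mean_rr: float = 850.0
    osc_components: tuple = ((0.1, 25.0, 0.0), (0.25, 25.0, 0.0))
    apnea_cycle: tuple | None = None
    noise_sd: float = 10.0
    artifact_rate: float = 0.0
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if any(f >= 2.0 or f <= 0 for f, _, _ in self.osc_components):
            raise ValueError("oscillator frequencies must lie in (0, 2) Hz")
        if self.apnea_cycle is not None:
            period, depth = self.apnea_cycle
            if not 25.0 <= period <= 60.0:
                raise ValueError("apnea-cycle period must lie in [25, 60] s")
            if not 0.0 <= depth <= 1.0:
                raise ValueError("apnea-cycle depth must lie in [0, 1]")
        if self.noise_sd < 0 or not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("noise_sd must be >= 0 and artifact_rate in [0, 1)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """A two-group synthetic cohort: group name -> SynthConfig template."""

    n_per_group: int = 100
    group_configs: dict = field(
        default_factory=lambda: {
            "apnea-like": apnea_like_config(),
            "normal-like": normal_like_config(),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not self.group_configs:
            raise ValueError("group_configs must not be empty")


def apnea_like_config(seed: int = 0) -> SynthConfig:
    """LF-enhanced, HF-suppressed spectrum with apnea-cycle modulation —
    sympathetic dominance typical of obstructive events."""
    return SynthConfig(
        mean_rr=900.0,
        osc_components=((0.015, 15.0, 0.0), (0.10, 50.0, 0.0), (0.25, 10.0, 0.0)),
        apnea_cycle=(45.0, 0.25),
        noise_sd=15.0,
        artifact_rate=0.005,
        seed=seed,
    )


def normal_like_config(seed: int = 0) -> SynthConfig:
    """HF-dominant spectrum of normal sleep (respiratory sinus arrhythmia
    strong, sympathetic LF modest), no apnea cycle."""
    return SynthConfig(
        mean_rr=850.0,
        osc_components=((0.01, 10.0, 0.0), (0.10, 15.0, 0.0), (0.25, 40.0, 0.0)),
        apnea_cycle=None,
        noise_sd=10.0,
        artifact_rate=0.0,
        seed=seed,
    )


def _modulation(t: np.ndarray | float, cycle: tuple | None):
    """Amplitude-modulation factor in [1 - depth, 1]; troughs at T/2 + kT."""
    if cycle is None:
        return 1.0
    period, depth = cycle
    return 1.0 - depth / 2.0 + (depth / 2.0) * np.cos(2 * np.pi * np.asarray(t) / period)


def _tachogram_value(t: float, config: SynthConfig) -> float:
    r = config.mean_rr
    for f, amp, phase in config.osc_components:
        r += amp * np.sin(2 * np.pi * f * t + phase)
    return float(r * _modulation(t, config.apnea_cycle))


def generate_rr(config: SynthConfig) -> tuple[RRSeries, MinuteAnnotations]:
    """Emit a seeded synthetic RR series plus per-minute apnea annotations.

    Rejects (before emitting anything) configurations whose deterministic
    tachogram envelope can reach zero; a noise draw that still produces a
    non-positive interval raises during emission.
    """
    total_amp = sum(abs(a) for _, a, _ in config.osc_components)
    depth = 0.0 if config.apnea_cycle is None else config.apnea_cycle[1]
    if (config.mean_rr - total_amp) * (1.0 - depth) <= 0.0:
        raise ValueError("configuration allows RR <= 0: reduce amplitudes or depth")

    rng = np.random.default_rng(config.seed)
    times = [0.0]
    rr_values = []
    t = 0.0
    while t < config.duration_s:
        rr = _tachogram_value(t, config) + rng.normal(0.0, config.noise_sd)
        if rr <= 0:
            raise ValueError(f"noise drove RR below zero at t={t:.2f} s")
        rr_values.append(rr)
        t += rr / 1000.0
        times.append(t)

    rr_arr = np.asarray(rr_values)
    if config.artifact_rate > 0:
        spikes = rng.random(len(rr_arr)) < config.artifact_rate
        rr_arr = np.where(spikes, rr_arr * 2.0, rr_arr)
    series = RRSeries.from_intervals(0.0, rr_arr, record_id=f"synth-{config.seed}")

    n_minutes = int(config.duration_s // _MINUTE_S)
    labels = ["normal"] * n_minutes
    if config.apnea_cycle is not None and config.apnea_cycle[1] > 0:
        period = config.apnea_cycle[0]
        trough = period / 2.0
        while trough < n_minutes * _MINUTE_S:
            labels[int(trough // _MINUTE_S)] = "apnea"
            trough += period
    return series, MinuteAnnotations(tuple(labels))


def generate_cohort(spec: CohortSpec) -> list[HRVSegment]:
    """Generate labeled 5-min segments, one group at a time, through the full
    preprocessing pipeline (median filter, labeling, spline resampling).

    Per-member seeds are derived deterministically from ``spec.seed`` and the
    member's position, so two calls with the same spec are identical. Each
    returned segment carries its synthetic group name as ``group_label``.
    """
    segments: list[HRVSegment] = []
    for g_idx, (group, template) in enumerate(sorted(spec.group_configs.items())):
        record_class = "A" if template.apnea_cycle is not None else "C"
        for i in range(spec.n_per_group):
            member_seed = (spec.seed * 100_003 + g_idx * 10_007 + i) % (2**31 - 1)
            config = replace(template, seed=member_seed)
            try:
                rr, ann = generate_rr(config)
                rr = remove_artifacts(rr)
                windows = segment_and_label(rr, ann, record_class)
                if not windows:
                    raise ValueError("record produced no usable 5-min window")
                seg = interpolate_resample(windows[0])
            except ValueError as exc:
                raise ValueError(f"cohort member {group}[{i}] failed: {exc}") from exc
            segments.append(seg.relabel(group, source=f"{group}-{i:04d}"))
    return segments
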