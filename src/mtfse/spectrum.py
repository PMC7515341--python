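"""Burg autoregressive spectral estimation and the time-frequency spectrum image.

A 5-minute tachogram is too short for high-resolution nonparametric spectra, so
the power spectral density is estimated parametrically from an all-pole AR
model

    x(t) = -sum_{k=1..p} a_k x(t - k) + u(t),        u ~ white noise, var d2

whose PSD is  S(f) = d2 / |1 + sum_k a_k exp(-2 pi i f k / fs)|^2.  The Burg
(lattice) method estimates the a_k by minimizing the summed forward and
backward prediction-error power at each order stage, which is well conditioned
on short segments and guarantees |reflection coefficient| < 1, hence a stable
model.

Sliding an AR fit across the segment yields the time-frequency spectrum image
(TFSI): rows are window positions, columns a uniform frequency grid over the
physiologically relevant 0-0.4 Hz range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ARModel", "TFSI", "burg_fit", "ar_psd", "build_tfsi", "F_MAX_HZ"]

#: upper edge of the analyzed HRV spectrum (HF band ends at 0.4 Hz).
F_MAX_HZ = 0.4


@dataclass(frozen=True)
class ARModel:
    """Order-p AR coefficients a_1..a_p plus innovation variance.

    Sign convention: the polynomial 1 + sum a_k z^{-k} is the PSD denominator,
    i.e. a process x(t) = 0.5 x(t-1) + u(t) has a_1 = -0.5.
    """

    order: int
    coefficients: np.ndarray
    innovation_variance: float
    sample_rate: float

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if self.order < 1 or len(coef) != self.order:
            raise ValueError("coefficients length must equal a positive order")
        if self.innovation_variance < 0:
            raise ValueError("innovation variance must be non-negative")


@dataclass(frozen=True)
class TFSI:
    """Time-frequency spectrum image: power[n_time, n_freq] with explicit axes."""

    power: np.ndarray
    time_axis: np.ndarray
    freq_axis: np.ndarray
    window_length_s: float
    hop_s: float

    def __post_init__(self) -> None:
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "power", power)
        object.__setattr__(self, "time_axis", np.asarray(self.time_axis, dtype=float))
        object.__setattr__(self, "freq_axis", np.asarray(self.freq_axis, dtype=float))
        if power.shape != (len(self.time_axis), len(self.freq_axis)):
            raise ValueError("power shape must be (n_time, n_freq)")
        if not np.all(np.isfinite(power)) or np.any(power < 0):
            raise ValueError("TFSI power values must be finite and non-negative")

    @property
    def n_time(self) -> int:
        return self.power.shape[0]

    @property
    def n_freq(self) -> int:
        return self.power.shape[1]

    def scaled(self, factor: float) -> "TFSI":
        """Return a copy with all power values multiplied by ``factor``."""
        return TFSI(
            self.power * factor,
            self.time_axis,
            self.freq_axis,
            self.window_length_s,
            self.hop_s,
        )


def burg_fit(signal: np.ndarray, order: int, sample_rate: float = 4.0) -> ARModel:
    """Fit an AR(order) model by Burg's lattice recursion.

    The signal mean is removed before fitting. At each stage the reflection
    coefficient minimizing the summed forward+backward prediction-error power
    is computed in closed form and the coefficient vector updated by the
    Levinson recursion; the returned innovation variance is the final
    prediction-error power.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if order < 1:
        raise ValueError("AR order must be >= 1")
    n = len(x)
    if n <= 2 * order:
        raise ValueError(f"need more than {2 * order} samples to fit AR({order})")
    x = x - x.mean()
    energy = float(np.dot(x, x))
    if energy == 0.0:
        raise ValueError("degenerate segment: signal is constant (zero variance)")

    err_power = energy / n
    ef = x[1:].copy()  # forward prediction errors
    eb = x[:-1].copy()  # backward prediction errors
    a = np.zeros(0)
    for _ in range(order):
        den = float(np.dot(ef, ef) + np.dot(eb, eb))
        if den == 0.0:
            raise ValueError("degenerate segment: prediction error vanished")
        k = -2.0 * float(np.dot(ef, eb)) / den
        a = np.concatenate((a + k * a[::-1], (k,)))
        err_power *= 1.0 - k * k
        ef, eb = ef[1:] + k * eb[1:], eb[:-1] + k * ef[:-1]
    return ARModel(
        order=order,
        coefficients=a,
        innovation_variance=max(err_power, 0.0),
        sample_rate=sample_rate,
    )


def ar_psd(model: ARModel, freqs: np.ndarray) -> np.ndarray:
    """Evaluate the AR power spectrum S(f) = d2 / |1 + sum a_k e^{-2pi i f k/fs}|^2.

    ``freqs`` must satisfy |f| <= Nyquist; S is even in f.
    """
    f = np.atleast_1d(np.asarray(freqs, dtype=float))
    nyquist = model.sample_rate / 2.0
    if np.any(np.abs(f) > nyquist + 1e-12):
        raise ValueError(f"frequencies beyond the Nyquist limit {nyquist} Hz")
    k = np.arange(1, model.order + 1)
    # denominator polynomial evaluated on the unit circle, one row per frequency
    phases = np.exp(-2j * np.pi * np.outer(f, k) / model.sample_rate)
    denom = 1.0 + phases @ model.coefficients
    return model.innovation_variance / np.abs(denom) ** 2


def build_tfsi(
    segment,
    window_length_s: float = 64.0,
    hop_s: float = 4.0,
    n_freq: int = 256,
    order: int = 16,
) -> TFSI:
    """Slide an AR(order) fit across a segment's tachogram to form the TFSI.

    Each window position is mean-removed, Burg-fitted, and its PSD evaluated
    on an ``n_freq``-point uniform grid over [0, 0.4] Hz. Rows are ordered by
    time (window centers), columns by frequency.
    """
    fs = segment.sample_rate
    tach = segment.tachogram
    win = int(round(window_length_s * fs))
    hop = int(round(hop_s * fs))
    if hop < 1:
        raise ValueError("hop_s must be positive")
    if win > len(tach):
        raise ValueError("window_length_s exceeds the segment duration")
    if win <= 2 * order:
        raise ValueError(
            f"window of {win} samples cannot support AR({order}); "
            "increase window_length_s or lower the order"
        )
    if n_freq < 2:
        raise ValueError("n_freq must be >= 2")
    freqs = np.linspace(0.0, F_MAX_HZ, n_freq)
    starts = range(0, len(tach) - win + 1, hop)
    rows = []
    centers = []
    for idx, s in enumerate(starts):
        try:
            model = burg_fit(tach[s : s + win], order, sample_rate=fs)
        except ValueError as exc:
            raise ValueError(f"AR fit failed in window {idx} (start {s / fs} s): {exc}")
        rows.append(ar_psd(model, freqs))
        centers.append(segment.start_s + (s + (win - 1) / 2.0) / fs)
    return TFSI(
        power=np.vstack(rows),
        time_axis=np.asarray(centers),
        freq_axis=freqs,
        window_length_s=window_length_s,
        hop_s=hop_s,
    )
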