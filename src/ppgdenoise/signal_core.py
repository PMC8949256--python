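"""Synthetic PPG generation, signal containers, file I/O, and preprocessing.

The preprocessing chain mirrors the standard protocol for heterogeneous PPG
corpora: band-limited resampling to a common rate (50 Hz by default),
segmentation into fixed-length windows (6 s), and per-segment min-max
normalization into ``[-1, 1]``.

The synthetic generator produces a quasi-periodic pulse waveform — per beat a
systolic bump followed by a smaller dicrotic bump — with heart-rate jitter and
sinusoidal baseline wander, so every downstream stage (corruption, denoising,
scoring) is testable without any recorded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sp_signal

from .exceptions import (
    ContractError,
    DegenerateInputError,
    FormatError,
    ParameterError,
    ParseError,
)

__all__ = [
    "RawSignal",
    "Segment",
    "PpgSynthParams",
    "synthesize_ppg",
    "resample",
    "segment",
    "normalize",
    "read_signal",
    "write_signal",
    "DEFAULT_FS",
    "DEFAULT_SEGMENT_SECONDS",
]

#: Common sampling rate all signals are resampled to before segmentation.
DEFAULT_FS = 50.0
#: Segment duration in seconds.
DEFAULT_SEGMENT_SECONDS = 6.0

RangeTag = Optional[Literal["signed_unit", "unit"]]

_RANGE_BOUNDS = {"signed_unit": (-1.0, 1.0), "unit": (0.0, 1.0)}


@dataclass(frozen=True)
class RawSignal:
    """A continuous single-channel signal with its sampling rate.

    Parameters
    ----------
    samples : array-like
        Finite real sample values, arbitrary units.
    fs : float
        Sampling rate in Hz, strictly positive.
    source_id : str
        Free-text provenance label.
    """

    samples: np.ndarray
    fs: float
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1 or arr.size == 0:
            raise ParameterError("samples must be a non-empty 1D sequence")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("samples must be finite")
        if not (self.fs > 0):
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class Segment:
    """A fixed-length window of a signal, the unit of corruption and scoring.

    ``range_tag`` declares the value range the samples are guaranteed to lie
    in: ``"signed_unit"`` for ``[-1, 1]``, ``"unit"`` for ``[0, 1]``, or
    ``None`` for raw (unnormalized) windows straight out of :func:`segment`.
    """

    samples: np.ndarray
    fs: float
    duration: float = DEFAULT_SEGMENT_SECONDS
    range_tag: RangeTag = None
    origin: Tuple[str, int] = ("", 0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise ParameterError("segment samples must be 1D")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("segment samples must be finite")
        if not (self.fs > 0):
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        expected = int(round(self.duration * self.fs))
        if len(arr) != expected:
            raise ContractError(
                f"segment length {len(arr)} != round(duration*fs) = {expected}"
            )
        if self.range_tag is not None:
            if self.range_tag not in _RANGE_BOUNDS:
                raise ParameterError(f"unknown range_tag {self.range_tag!r}")
            lo, hi = _RANGE_BOUNDS[self.range_tag]
            # tiny tolerance for float round-off from affine maps
            if arr.size and (arr.min() < lo - 1e-12 or arr.max() > hi + 1e-12):
                raise ContractError(
                    f"samples outside declared range {self.range_tag}: "
                    f"[{arr.min():.6g}, {arr.max():.6g}]"
                )
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "duration", float(self.duration))

    def __len__(self) -> int:
        return len(self.samples)

    def with_samples(self, samples: np.ndarray, range_tag: RangeTag) -> "Segment":
        """Return a copy with new samples and range tag, same geometry."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       range_tag=range_tag)


@dataclass(frozen=True)
class PpgSynthParams:
    """Parameters of the synthetic PPG generator.

    pulse_shape is ``(systolic_amp, dicrotic_amp, systolic_width,
    dicrotic_width)`` with widths as fractions of the beat period; the
    systolic bump peaks at 15% of the period and the dicrotic bump at 45%,
    reproducing the systolic-peak-plus-dicrotic-notch morphology of a pulse
    waveform. baseline_wander is ``(amplitude, frequency_hz)`` of an additive
    sinusoid emulating respiratory drift.
    """

    heart_rate_bpm: float = 70.0
    hr_jitter: float = 0.03
    pulse_shape: Tuple[float, float, float, float] = (1.0, 0.35, 0.10, 0.14)
    baseline_wander: Tuple[float, float] = (0.15, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (30.0 <= self.heart_rate_bpm <= 220.0):
            raise ParameterError(
                f"heart_rate_bpm must be in [30, 220], got {self.heart_rate_bpm}"
            )
        if self.hr_jitter < 0:
            raise ParameterError("hr_jitter must be >= 0")
        sys_amp, dic_amp, sys_w, dic_w = self.pulse_shape
        if sys_amp < 0 or dic_amp < 0:
            raise ParameterError("pulse amplitudes must be >= 0")
        if sys_w <= 0 or dic_w <= 0:
            raise ParameterError("pulse widths must be > 0")
        if self.baseline_wander[0] < 0:
            raise ParameterError("baseline wander amplitude must be >= 0")


# beat-phase positions of the two bumps, as fractions of the beat period
_SYSTOLIC_PHASE = 0.15
_DICROTIC_PHASE = 0.45


def synthesize_ppg(params: PpgSynthParams, n_seconds: float, fs: float) -> RawSignal:
    """Generate a quasi-periodic synthetic PPG signal.

    Each beat contributes two Gaussian bumps (systolic and dicrotic) placed
    on the beat phase; beat periods are drawn i.i.d. around
    ``60 / heart_rate_bpm`` with relative standard deviation ``hr_jitter``
    (truncated at half the mean so periods stay positive). A sinusoidal
    baseline wander is added. The function is a pure function of
    ``(params, n_seconds, fs)``.
    """
    if not isinstance(params, PpgSynthParams):
        params = PpgSynthParams(**params)  # type: ignore[arg-type]
    if not (fs > 0):
        raise ParameterError("fs must be > 0")
    n_samples = int(round(n_seconds * fs))
    if n_samples < 1:
        raise ParameterError("n_seconds*fs must be >= 1")

    rng = np.random.default_rng(params.seed)
    mean_period = 60.0 / params.heart_rate_bpm
    sys_amp, dic_amp, sys_w, dic_w = params.pulse_shape

    # Beat onsets covering [-2 periods, n_seconds + 2 periods] so edge beats
    # contribute their full tails and a jitter-free signal is exactly periodic
    # in the interior.
    onsets = [-2.0 * mean_period]
    while onsets[-1] < n_seconds + 2.0 * mean_period:
        jitter = rng.normal(0.0, params.hr_jitter)
        jitter = float(np.clip(jitter, -0.5, 0.5))
        onsets.append(onsets[-1] + mean_period * (1.0 + jitter))
    onsets_arr = np.array(onsets[:-1])
    periods = np.diff(np.array(onsets))

    t = np.arange(n_samples) / fs
    x = np.zeros(n_samples)
    for onset, period in zip(onsets_arr, periods):
        for amp, phase, width in (
            (sys_amp, _SYSTOLIC_PHASE, sys_w),
            (dic_amp, _DICROTIC_PHASE, dic_w),
        ):
            center = onset + phase * period
            w = width * period
            x += amp * np.exp(-0.5 * ((t - center) / w) ** 2)

    bw_amp, bw_freq = params.baseline_wander
    if bw_amp > 0:
        x += bw_amp * np.sin(2.0 * math.pi * bw_freq * t)

    return RawSignal(samples=x, fs=fs, source_id=f"synth(seed={params.seed})")


def resample(sig: RawSignal, target_fs: float) -> RawSignal:
    """Band-limited resampling to ``target_fs``.

    Uses polyphase resampling when the rate ratio is rational with a small
    denominator, falling back to FFT resampling otherwise. The output length
    is exactly ``round(len(sig) * target_fs / sig.fs)``.
    """
    if not (target_fs > 0):
        raise ParameterError(f"target_fs must be > 0, got {target_fs}")
    if target_fs == sig.fs:
        return RawSignal(sig.samples.copy(), sig.fs, sig.source_id)
    n_out = int(round(len(sig) * target_fs / sig.fs))
    if n_out < 1:
        raise ParameterError("resampled signal would be empty")
    frac = Fraction(target_fs / sig.fs).limit_denominator(1000)
    approx = float(frac)
    if abs(approx - target_fs / sig.fs) < 1e-9:
        y = sp_signal.resample_poly(sig.samples, frac.numerator, frac.denominator,
                                    padtype="line")
        if len(y) > n_out:
            y = y[:n_out]
        elif len(y) < n_out:  # pragma: no cover - polyphase length is >= n_out
            y = np.pad(y, (0, n_out - len(y)), mode="edge")
    else:
        y = sp_signal.resample(sig.samples, n_out)
    return RawSignal(y, float(target_fs), sig.source_id)


def segment(sig: RawSignal, duration_s: float = DEFAULT_SEGMENT_SECONDS
            ) -> list[Segment]:
    """Cut a signal into consecutive non-overlapping windows.

    Windows are ``round(duration_s * fs)`` samples long; a trailing remainder
    shorter than one window is dropped. Each window records its source and
    start index in ``origin``.
    """
    win = int(round(duration_s * sig.fs))
    if win < 1:
        raise ParameterError("duration_s*fs must be >= 1")
    n = len(sig) // win
    return [
        Segment(
            samples=sig.samples[i * win:(i + 1) * win],
            fs=sig.fs,
            duration=duration_s,
            range_tag=None,
            origin=(sig.source_id, i * win),
        )
        for i in range(n)
    ]


def normalize(seg: Segment, target: Literal["signed_unit", "unit"] = "signed_unit"
              ) -> Segment:
    """Per-segment affine min-max normalization onto the target range.

    The segment minimum maps to the lower bound and the maximum to the upper
    bound; idempotent when the segment already spans the target range.
    Constant segments are rejected.
    """
    if target not in _RANGE_BOUNDS:
        raise ParameterError(f"unknown target range {target!r}")
    lo, hi = _RANGE_BOUNDS[target]
    x = seg.samples
    xmin, xmax = x.min(), x.max()
    if xmin == xmax:
        raise DegenerateInputError("cannot normalize a constant segment")
    y = lo + (x - xmin) * (hi - lo) / (xmax - xmin)
    return seg.with_samples(np.clip(y, lo, hi), target)


# ---------------------------------------------------------------------------
# File I/O — plain-text CSV dialect: a `# fs=<Hz>` header then one sample per
# line. (An optional `# source_id=<label>` header is preserved round-trip.)

def write_signal(sig: RawSignal | Segment, path: str | Path,
                 format: str = "csv") -> None:
    if format != "csv":
        raise FormatError(f"unsupported format {format!r}; only 'csv' is supported")
    path = Path(path)
    lines = [f"# fs={sig.fs!r}"]
    src = sig.source_id if isinstance(sig, RawSignal) else sig.origin[0]
    if src:
        lines.append(f"# source_id={src}")
    lines.extend(repr(float(v)) for v in sig.samples)
    path.write_text("\n".join(lines) + "\n")


def read_signal(path: str | Path, format: str = "csv") -> RawSignal:
    if format != "csv":
        raise FormatError(f"unsupported format {format!r}; only 'csv' is supported")
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    fs: Optional[float] = None
    source_id = ""
    values: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("fs="):
                try:
                    fs = float(body[3:])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad fs value") from exc
            elif body.startswith("source_id="):
                source_id = body[len("source_id="):]
            continue
        try:
            values.append(float(line))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if fs is None:
        raise FormatError(f"{path}: missing '# fs=<Hz>' header")
    if not values:
        raise ParseError(f"{path}: no samples")
    return RawSignal(np.array(values), fs, source_id)
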