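"""Noise synthesis: five single-noise generators, mixed-noise chains, and
motion artifacts.

All corruption happens in unit space ``[0, 1]``: a clean segment normalized to
``[-1, 1]`` is mapped by the fixed affine ``x -> (x+1)/2``, the noise stages
are applied in order, the result is clipped to ``[0, 1]`` and mapped back by
``x -> 2x-1``. The fixed (not data-dependent) maps keep clean and noisy
segments comparable sample by sample.

Noise kinds and their default parameters:

==============  =====================================================
gaussian        additive ``N(0, sigma^2)``, sigma = 0.01
poisson         shot noise ``Poisson(x*scale)/scale``, scale = 255
salt_pepper     ``round(rate*L)`` samples forced to 0 or 1, rate = 0.05
speckle         multiplicative ``x*(1+N(0, sigma^2))``, sigma = 0.01
uniform         additive ``U[lo, hi]``, lo = 0, hi = 0.1
motion          band-limited artifact blended into part of the window
==============  =====================================================

Reproducibility: every stochastic stage draws from a ``numpy`` generator
seeded either by the stage's own seed or by a splitmix64-derived sub-seed of
the chain's master seed, so a serialized chain reproduces its noisy segment
bit for bit regardless of evaluation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal as sp_signal

from .exceptions import ContractError, ParameterError
from .signal_core import RawSignal, Segment

__all__ = [
    "SINGLE_NOISE_KINDS",
    "NOISE_DEFAULTS",
    "NoiseSpec",
    "NoiseChain",
    "CorruptedPair",
    "to_unit",
    "from_unit",
    "add_gaussian",
    "add_poisson",
    "add_salt_pepper",
    "add_speckle",
    "add_uniform",
    "corrupt",
    "random_mixed_chain",
    "synthesize_motion_artifact",
    "inject_motion_artifact",
    "derive_seed",
]

#: The five single-noise kinds eligible for mixing.
SINGLE_NOISE_KINDS = ("gaussian", "poisson", "salt_pepper", "speckle", "uniform")

NOISE_DEFAULTS: dict[str, dict[str, float]] = {
    "gaussian": {"sigma": 0.01},
    "poisson": {"scale": 255.0},
    "salt_pepper": {"rate": 0.05},
    "speckle": {"sigma": 0.01},
    "uniform": {"lo": 0.0, "hi": 0.1},
    "motion": {"ratio": 0.3, "start_index": 0},
}


def derive_seed(master_seed: int, index: int) -> int:
    """Derive a reproducible sub-seed via a splitmix64 step.

    ``master_seed`` is advanced by ``index`` golden-ratio increments and mixed
    through the splitmix64 finalizer; the result is reduced below 2**31 so it
    is a portable seed for any generator.
    """
    mask = (1 << 64) - 1
    z = (int(master_seed) + (index + 1) * 0x9E3779B97F4A7C15) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z = z ^ (z >> 31)
    return int(z % (1 << 31))


def _validate_params(kind: str, params: Mapping[str, float]) -> dict[str, float]:
    if kind not in NOISE_DEFAULTS:
        raise ParameterError(f"unknown noise kind {kind!r}")
    merged = dict(NOISE_DEFAULTS[kind])
    unknown = set(params) - set(merged)
    if unknown:
        raise ParameterError(f"unknown parameters {sorted(unknown)} for {kind}")
    merged.update({k: float(v) for k, v in params.items()})
    if kind in ("gaussian", "speckle") and merged["sigma"] < 0:
        raise ParameterError("sigma must be >= 0")
    if kind == "salt_pepper" and not (0.0 <= merged["rate"] <= 1.0):
        raise ParameterError("rate must be in [0, 1]")
    if kind == "poisson" and merged["scale"] <= 0:
        raise ParameterError("scale must be > 0")
    if kind == "uniform" and merged["lo"] > merged["hi"]:
        raise ParameterError("lo must be <= hi")
    if kind == "motion":
        if not (0.0 < merged["ratio"] <= 1.0):
            raise ParameterError("ratio must be in (0, 1]")
        merged["start_index"] = int(merged["start_index"])
    return merged


@dataclass(frozen=True)
class NoiseSpec:
    """One parameterized noise process, with an optional per-stage seed."""

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", _validate_params(self.kind, self.params))

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: Mapping) -> "NoiseSpec":
        return cls(kind=d["kind"], params=d.get("params", {}), seed=d.get("seed"))


@dataclass(frozen=True)
class NoiseChain:
    """An ordered composition of noise stages with a master seed.

    Stage ``i`` draws from a generator seeded by the stage's own seed if set,
    else by ``derive_seed(master_seed, i)``.
    """

    specs: Sequence[NoiseSpec]
    master_seed: int = 0

    def __post_init__(self) -> None:
        specs = tuple(self.specs)
        if not (1 <= len(specs) <= 6):
            raise ParameterError("chain must have between 1 and 6 stages")
        kinds = [s.kind for s in specs]
        if len(set(kinds)) != len(kinds):
            raise ParameterError("kinds within a chain must be distinct")
        object.__setattr__(self, "specs", specs)

    def stage_seed(self, i: int) -> int:
        spec = self.specs[i]
        return spec.seed if spec.seed is not None else derive_seed(self.master_seed, i)

    def to_dict(self) -> dict:
        return {"master_seed": self.master_seed,
                "specs": [s.to_dict() for s in self.specs]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "NoiseChain":
        return cls(specs=[NoiseSpec.from_dict(s) for s in d["specs"]],
                   master_seed=d.get("master_seed", 0))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NoiseChain":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CorruptedPair:
    """A (clean, noisy) segment pair with the chain that produced it."""

    clean: Segment
    noisy: Segment
    chain: NoiseChain

    def __post_init__(self) -> None:
        if len(self.clean) != len(self.noisy) or self.clean.fs != self.noisy.fs:
            raise ContractError("clean and noisy must share length and fs")


# ---------------------------------------------------------------------------
# Range maps

def to_unit(seg: Segment) -> Segment:
    """Fixed affine map [-1,1] -> [0,1]: x -> (x+1)/2."""
    if seg.range_tag != "signed_unit":
        raise ContractError(f"expected signed_unit segment, got {seg.range_tag!r}")
    return seg.with_samples((seg.samples + 1.0) / 2.0, "unit")


def from_unit(seg: Segment) -> Segment:
    """Fixed affine map [0,1] -> [-1,1]: x -> 2x-1."""
    if seg.range_tag != "unit":
        raise ContractError(f"expected unit segment, got {seg.range_tag!r}")
    return seg.with_samples(2.0 * seg.samples - 1.0, "signed_unit")


# ---------------------------------------------------------------------------
# Single-noise generators (unit space). Each op takes and returns a unit
# segment; outputs are clipped to [0, 1].

def _require_unit(seg: Segment) -> np.ndarray:
    if seg.range_tag != "unit":
        raise ContractError(f"expected unit segment, got {seg.range_tag!r}")
    return seg.samples


def add_gaussian(seg: Segment, sigma: float = 0.01, seed: int = 0) -> Segment:
    """Additive zero-mean Gaussian noise with standard deviation ``sigma``."""
    x = _require_unit(seg)
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if sigma == 0:
        return seg.with_samples(x.copy(), "unit")
    rng = np.random.default_rng(seed)
    y = x + rng.normal(0.0, sigma, size=x.shape)
    return seg.with_samples(np.clip(y, 0.0, 1.0), "unit")


def add_poisson(seg: Segment, scale: float = 255.0, seed: int = 0) -> Segment:
    """Shot noise: ``y = Poisson(x*scale)/scale`` (image-processing convention,
    scale plays the role of the intensity quantization, default 255)."""
    x = _require_unit(seg)
    if scale <= 0:
        raise ParameterError("scale must be > 0")
    rng = np.random.default_rng(seed)
    y = rng.poisson(x * scale).astype(np.float64) / scale
    return seg.with_samples(np.clip(y, 0.0, 1.0), "unit")


def add_salt_pepper(seg: Segment, rate: float = 0.05, seed: int = 0) -> Segment:
    """Impulse noise: exactly ``round(rate*L)`` positions, chosen without
    replacement, are set to 0 or 1 with equal probability."""
    x = _require_unit(seg)
    if not (0.0 <= rate <= 1.0):
        raise ParameterError("rate must be in [0, 1]")
    n_hit = int(round(rate * len(x)))
    y = x.copy()
    if n_hit > 0:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(x), size=n_hit, replace=False)
        y[idx] = rng.integers(0, 2, size=n_hit).astype(np.float64)
    return seg.with_samples(y, "unit")


def add_speckle(seg: Segment, sigma: float = 0.01, seed: int = 0) -> Segment:
    """Multiplicative speckle noise: ``y = x*(1 + N(0, sigma^2))``."""
    x = _require_unit(seg)
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if sigma == 0:
        return seg.with_samples(x.copy(), "unit")
    rng = np.random.default_rng(seed)
    y = x * (1.0 + rng.normal(0.0, sigma, size=x.shape))
    return seg.with_samples(np.clip(y, 0.0, 1.0), "unit")


def add_uniform(seg: Segment, lo: float = 0.0, hi: float = 0.1,
                seed: int = 0) -> Segment:
    """Additive uniform noise on ``[lo, hi]`` (a positive-offset corruption
    for the default range)."""
    x = _require_unit(seg)
    if lo > hi:
        raise ParameterError("lo must be <= hi")
    if lo == hi == 0.0:
        return seg.with_samples(x.copy(), "unit")
    rng = np.random.default_rng(seed)
    y = x + rng.uniform(lo, hi, size=x.shape)
    return seg.with_samples(np.clip(y, 0.0, 1.0), "unit")


_SINGLE_OPS = {
    "gaussian": add_gaussian,
    "poisson": add_poisson,
    "salt_pepper": add_salt_pepper,
    "speckle": add_speckle,
    "uniform": add_uniform,
}


def _apply_spec(seg: Segment, spec: NoiseSpec, seed: int) -> Segment:
    if spec.kind == "motion":
        n = len(seg)
        artifact_raw = synthesize_motion_artifact(n, seg.fs, seed=seed)
        artifact = Segment(artifact_raw.samples, seg.fs, seg.duration,
                           "signed_unit", ("motion", 0))
        # unit-space blend, re-using the signed segment wrapped from this one
        signed = from_unit(seg)
        pair = inject_motion_artifact(signed, artifact,
                                      ratio=spec.params["ratio"],
                                      start_index=int(spec.params["start_index"]))
        return to_unit(pair.noisy)
    op = _SINGLE_OPS[spec.kind]
    return op(seg, seed=seed, **spec.params)


def corrupt(clean: Segment, chain: NoiseChain) -> CorruptedPair:
    """Apply a noise chain to a clean ``[-1, 1]`` segment.

    Pipeline: map to unit space, apply every stage in order, clip to
    ``[0, 1]``, map back to ``[-1, 1]``. Deterministic given the chain.
    """
    if clean.range_tag != "signed_unit":
        raise ContractError("corrupt expects a signed_unit clean segment")
    u = to_unit(clean)
    for i, spec in enumerate(chain.specs):
        u = _apply_spec(u, spec, chain.stage_seed(i))
    u = u.with_samples(np.clip(u.samples, 0.0, 1.0), "unit")
    return CorruptedPair(clean=clean, noisy=from_unit(u), chain=chain)


def random_mixed_chain(k: int, master_seed: int = 0) -> NoiseChain:
    """Draw ``k`` distinct single-noise kinds in random order, default params.

    The kind subset and order are uniform over the ordered k-subsets of the
    five kinds; each stage gets a splitmix-derived sub-seed of the master.
    """
    if not (2 <= k <= 5):
        raise ParameterError(f"k must be in [2, 5], got {k}")
    rng = np.random.default_rng(derive_seed(master_seed, 0xC0))
    kinds = rng.choice(SINGLE_NOISE_KINDS, size=k, replace=False)
    specs = [NoiseSpec(kind=str(kind), seed=derive_seed(master_seed, i))
             for i, kind in enumerate(kinds)]
    return NoiseChain(specs=specs, master_seed=master_seed)


# ---------------------------------------------------------------------------
# Motion artifacts

#: Passband of the synthetic motion-artifact process, Hz. Wrist-motion
#: artifacts during walking/running/cycling concentrate in roughly this band.
MOTION_BAND_HZ = (0.5, 5.0)


def synthesize_motion_artifact(n_samples: int, fs: float, seed: int = 0
                               ) -> RawSignal:
    """Synthesize a band-limited stochastic motion-artifact process.

    A Gaussian random walk (integrated white noise, giving the low-frequency
    emphasis of limb movement) is band-pass filtered to 0.5-5 Hz with a
    zero-phase Butterworth filter and min-max normalized to ``[-1, 1]`` so its
    amplitude is comparable to a normalized clean segment.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    if not (fs > 0):
        raise ParameterError("fs must be > 0")
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.normal(0.0, 1.0, size=n_samples))
    lo, hi = MOTION_BAND_HZ
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    sos = sp_signal.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    padlen = min(3 * 8 * 2, n_samples - 1)
    y = sp_signal.sosfiltfilt(sos, walk, padlen=padlen)
    span = y.max() - y.min()
    if span > 0:
        y = -1.0 + 2.0 * (y - y.min()) / span
    return RawSignal(y, fs, source_id=f"motion(seed={seed})")


def inject_motion_artifact(clean: Segment, artifact: Segment, ratio: float,
                           start_index: int = 0) -> CorruptedPair:
    """Blend a motion artifact into ``round(ratio*L)`` samples of a segment.

    Inside the window the artifact (halved, so its ``[-1, 1]`` swing matches
    the half-range of unit space) is added to the clean signal in unit space
    and clipped; outside the window the signal goes through the same
    unit-space round trip untouched.
    """
    if clean.range_tag != "signed_unit" or artifact.range_tag != "signed_unit":
        raise ContractError("clean and artifact must be signed_unit segments")
    L = len(clean)
    if len(artifact) != L:
        raise ContractError("artifact must match the clean segment length")
    if not (0.0 < ratio <= 1.0):
        raise ParameterError("ratio must be in (0, 1]")
    win = int(round(ratio * L))
    if start_index < 0 or start_index + win > L:
        raise ParameterError(
            f"window [{start_index}, {start_index + win}) out of bounds for L={L}"
        )
    u = to_unit(clean).samples
    y = u.copy()
    sl = slice(start_index, start_index + win)
    y[sl] = np.clip(u[sl] + 0.5 * artifact.samples[sl], 0.0, 1.0)
    noisy = from_unit(clean.with_samples(y, "unit"))
    chain = NoiseChain(
        specs=[NoiseSpec("motion",
                         {"ratio": ratio, "start_index": start_index})],
        master_seed=0,
    )
    return CorruptedPair(clean=clean, noisy=noisy, chain=chain)
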