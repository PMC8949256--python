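"""The 1D reference-based texture-transformer network.

The denoiser treats a noisy pulse waveform the way reference-based
super-resolution treats a low-resolution image. Four aligned inputs are
prepared from a noisy segment and a clean reference segment:

* the noisy segment itself (backbone input, features ``F``),
* the reference segment (value input, features ``V``),
* the reference after a down/up-sampling round trip (key input, ``K``),
* the noisy segment after the same round trip (query input, ``Q``).

``Q``, ``K`` and ``V`` are produced by one shared convolutional texture
encoder. Overlapping feature patches of ``Q`` and ``K`` are compared by
normalized inner products (the relevance embedding); per query patch the hard
attention map ``H`` records the best-matching reference patch and the soft
attention map ``S`` its score. Reference texture patches of ``V`` gathered by
``H`` are folded back to signal geometry (``T``) and fused into the backbone
features, gated by ``S``; a small decoder emits the restored segment, clamped
to ``[-1, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from ..exceptions import ContractError, ParameterError
from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ModelConfig",
    "AttentionMaps",
    "NPDNet",
    "prepare_inputs",
    "downsample",
    "upsample",
    "relevance_embedding",
    "hard_soft_attention",
    "transfer_textures",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    scale_factor is the down/up ratio used to build the degraded query/key
    domains; patch_size/patch_stride control the texture patches of the
    relevance embedding; levels is the depth (number of convolution layers)
    of the texture encoder and backbone; channels their width.
    """

    scale_factor: int = 4
    channels: int = 16
    patch_size: int = 3
    patch_stride: int = 1
    levels: int = 3
    kernel_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_factor < 1:
            raise ParameterError("scale_factor must be >= 1")
        if self.patch_size % 2 == 0 or self.patch_size < 1:
            raise ParameterError("patch_size must be odd and >= 1")
        if self.patch_stride < 1:
            raise ParameterError("patch_stride must be >= 1")
        if self.levels < 1:
            raise ParameterError("levels must be >= 1")
        if self.channels < 1:
            raise ParameterError("channels must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ParameterError("kernel_size must be odd")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("scale_factor", "channels", "patch_size", "patch_stride",
                 "levels", "kernel_size", "seed")}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass(frozen=True)
class AttentionMaps:
    """Hard index map H and soft score map S of the relevance embedding."""

    H: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        if self.H.shape != self.S.shape:
            raise ContractError("H and S must share shape")


# ---------------------------------------------------------------------------
# Input preparation (plain numpy; these are data transforms, not learnable)

def downsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Keep every ``factor``-th sample along the last axis."""
    if factor < 1:
        raise ParameterError("factor must be >= 1")
    return np.asarray(x, dtype=np.float64)[..., ::factor]


def upsample(x: np.ndarray, factor: int, out_len: int) -> np.ndarray:
    """Linear interpolation back to ``out_len`` samples along the last axis.

    The retained samples of :func:`downsample` sit at positions
    ``0, factor, 2*factor, ...``; values beyond the last retained sample are
    extended by its value.
    """
    x = np.asarray(x, dtype=np.float64)
    if factor < 1:
        raise ParameterError("factor must be >= 1")
    t_src = np.arange(x.shape[-1]) * factor
    t_dst = np.arange(out_len)
    if x.ndim == 1:
        return np.interp(t_dst, t_src, x)
    flat = x.reshape(-1, x.shape[-1])
    return np.stack([np.interp(t_dst, t_src, row) for row in flat]
                    ).reshape(x.shape[:-1] + (out_len,))


def prepare_inputs(noisy: np.ndarray, reference: np.ndarray, scale_factor: int
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Build the four aligned network inputs.

    Returns ``(noisy, reference, ref_down_up, noisy_up)``, all of the input
    length. ``ref_down_up`` is the reference after a down/up round trip at
    ``scale_factor``; ``noisy_up`` is the noisy signal pushed through the same
    round trip, so the query and key textures live in the same degraded
    domain.
    """
    noisy = np.asarray(noisy, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if noisy.shape != reference.shape:
        raise ContractError("noisy and reference must share shape")
    L = noisy.shape[-1]
    ref_down_up = upsample(downsample(reference, scale_factor), scale_factor, L)
    noisy_up = upsample(downsample(noisy, scale_factor), scale_factor, L)
    return noisy, reference, ref_down_up, noisy_up


# ---------------------------------------------------------------------------
# Attention operations (public, array-in/array-out; used by the network and
# directly testable against brute-force oracles)

def _ensure_batched(x: np.ndarray) -> Tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        return x[None], True
    if x.ndim == 3:
        return x, False
    raise ContractError("expected a (C, L) or (B, C, L) feature array")


def relevance_embedding(Q: np.ndarray, K: np.ndarray, patch_size: int = 3,
                        patch_stride: int = 1) -> np.ndarray:
    """Normalized inner products between overlapping feature patches.

    Entry ``(i, j)`` is the cosine similarity between patch ``i`` of ``Q``
    and patch ``j`` of ``K`` (patches span all channels); every entry lies in
    ``[-1, 1]``.
    """
    Qb, squeeze = _ensure_batched(Q)
    Kb, _ = _ensure_batched(K)
    if Qb.shape[1] != Kb.shape[1]:
        raise ContractError("Q and K must share the channel dimension")
    if patch_size > Qb.shape[2] or patch_size > Kb.shape[2]:
        raise ParameterError("patch longer than the feature length")
    qn = ad.l2normalize(ad.unfold1d(Tensor(Qb), patch_size, patch_stride), axis=2)
    kn = ad.l2normalize(ad.unfold1d(Tensor(Kb), patch_size, patch_stride), axis=2)
    rel = ad.matmul(qn, ad.transpose(kn, (0, 2, 1))).data
    return rel[0] if squeeze else rel


def hard_soft_attention(rel: np.ndarray) -> AttentionMaps:
    """Row-wise argmax of the relevance matrix (ties break to the lowest
    index) and the score at that index."""
    rel = np.asarray(rel, dtype=np.float64)
    if rel.size == 0:
        raise ContractError("empty relevance matrix")
    if not np.all(np.isfinite(rel)):
        raise ContractError("relevance matrix must be finite")
    H = np.argmax(rel, axis=-1)
    S = np.take_along_axis(rel, H[..., None], axis=-1)[..., 0]
    return AttentionMaps(H=H, S=S)


def transfer_textures(V: np.ndarray, H: np.ndarray, patch_size: int = 3,
                      patch_stride: int = 1) -> np.ndarray:
    """Gather V-patches by the hard attention map and overlap-average them
    back to per-position features of the query geometry."""
    Vb, squeeze = _ensure_batched(V)
    Hb = np.asarray(H)
    if Hb.ndim == 1:
        Hb = Hb[None]
    vp = ad.unfold1d(Tensor(Vb), patch_size, patch_stride)
    if Hb.min() < 0 or Hb.max() >= vp.shape[1]:
        raise ContractError("hard-attention index out of range for V patches")
    gathered = ad.gather_patches(vp, Hb)
    T = ad.fold1d(gathered, Vb.shape[1], patch_size, patch_stride).data
    return T[0] if squeeze else T


# ---------------------------------------------------------------------------
# Network

class NPDNet:
    """Texture-transformer denoiser with a shared texture encoder, a backbone,
    an attention-gated fusion convolution, and a decoder."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        self.params: Dict[str, Tensor] = {}
        rng = np.random.default_rng(config.seed)
        C, k = config.channels, config.kernel_size

        def conv_param(name: str, cout: int, cin: int) -> None:
            std = np.sqrt(2.0 / (cin * k))
            self.params[f"{name}.w"] = Tensor(
                rng.normal(0.0, std, size=(cout, cin, k)), requires_grad=True)
            self.params[f"{name}.b"] = Tensor(np.zeros(cout), requires_grad=True)

        for block in ("encoder", "backbone"):
            conv_param(f"{block}.0", C, 1)
            for i in range(1, config.levels):
                conv_param(f"{block}.{i}", C, C)
        conv_param("fusion.0", C, 2 * C)
        conv_param("decoder.0", C, C)
        conv_param("decoder.1", 1, C)

    # -- blocks -------------------------------------------------------------
    def _stack(self, name: str, x: Tensor, n_layers: int) -> Tensor:
        h = x
        for i in range(n_layers):
            if i > 0:
                h = ad.relu(h)
            h = ad.conv1d(h, self.params[f"{name}.{i}.w"],
                          self.params[f"{name}.{i}.b"])
        return h

    def encode(self, x: Tensor) -> Tensor:
        """Shared texture encoder (used for Q, K and V)."""
        return self._stack("encoder", x, self.config.levels)

    def backbone(self, x: Tensor) -> Tensor:
        return self._stack("backbone", x, self.config.levels)

    def fuse(self, F: Tensor, T: Tensor, S_map: Tensor) -> Tensor:
        """Residual attention-gated fusion followed by the decoder.

        ``F' = F + conv(concat(F, T)) * S_map``; the decoder maps ``F'`` to a
        one-channel signal clamped to ``[-1, 1]``. With ``S_map = 0`` the
        transfer branch is gated off and the output is the backbone-only
        reconstruction.
        """
        x = ad.concat([F, T], axis=1)
        gate = ad.mul(ad.conv1d(x, self.params["fusion.0.w"],
                                self.params["fusion.0.b"]), S_map)
        fused = ad.add(F, gate)
        h = ad.relu(fused)
        h = ad.conv1d(h, self.params["decoder.0.w"], self.params["decoder.0.b"])
        h = ad.relu(h)
        h = ad.conv1d(h, self.params["decoder.1.w"], self.params["decoder.1.b"])
        return ad.clip(h, -1.0, 1.0)

    # -- forward ------------------------------------------------------------
    def forward(self, noisy: np.ndarray, reference: np.ndarray
                ) -> Tuple[Tensor, AttentionMaps]:
        """Run the full denoising pass on batches of shape (B, L).

        Returns the restored batch as a (B, L) tensor together with the
        attention maps.
        """
        noisy = np.atleast_2d(np.asarray(noisy, dtype=np.float64))
        reference = np.atleast_2d(np.asarray(reference, dtype=np.float64))
        cfg = self.config
        _, _, ref_down_up, noisy_up = prepare_inputs(noisy, reference,
                                                     cfg.scale_factor)
        B, L = noisy.shape
        p, s = cfg.patch_size, cfg.patch_stride

        Q = self.encode(Tensor(noisy_up[:, None, :]))
        K = self.encode(Tensor(ref_down_up[:, None, :]))
        V = self.encode(Tensor(reference[:, None, :]))

        qn = ad.l2normalize(ad.unfold1d(Q, p, s), axis=2)
        kn = ad.l2normalize(ad.unfold1d(K, p, s), axis=2)
        rel = ad.matmul(qn, ad.transpose(kn, (0, 2, 1)))
        H = np.argmax(rel.data, axis=2)
        S = ad.gather_scores(rel, H)

        vp = ad.unfold1d(V, p, s)
        T = ad.fold1d(ad.gather_patches(vp, H), cfg.channels, p, s)

        # per-sample soft score: overlap-average the patch scores like a
        # one-channel fold so the gate aligns with signal positions
        S_map = ad.fold1d(_tile_scores(S, p), 1, p, s)

        F = self.backbone(Tensor(noisy[:, None, :]))
        out = self.fuse(F, T, S_map)
        restored = ad.sum_(out, axis=1)  # (B, 1, L) -> (B, L)
        return restored, AttentionMaps(H=H, S=S.data)

    def denoise(self, noisy: np.ndarray, reference: np.ndarray) -> np.ndarray:
        """Deterministic forward pass returning a numpy array."""
        restored, _ = self.forward(noisy, reference)
        out = restored.data
        return out[0] if np.asarray(noisy).ndim == 1 else out

    # -- weights ------------------------------------------------------------
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise ContractError(f"unexpected weight {k!r}")
            if self.params[k].data.shape != np.asarray(v).shape:
                raise ContractError(f"shape mismatch for weight {k!r}")
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()


def _tile_scores(S: Tensor, patch: int) -> Tensor:
    """Tile per-patch scores (B, N) into one-channel patches (B, N, patch)
    so they can be overlap-averaged to per-position gates."""
    ones = Tensor(np.ones((1, 1, patch)))
    B, N = S.data.shape
    return ad.mul(_reshape(S, (B, N, 1)), ones)


def _reshape(a: Tensor, shape: tuple) -> Tensor:
    old = a.data.shape

    def bwd(out: Tensor):
        def fn():
            if a.requires_grad:
                a.accumulate(out.grad.reshape(old))
        return fn

    return ad._make(a.data.reshape(shape), (a,), bwd)
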