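"""Model/Results interface for training and applying the neural denoiser.

:class:`NPDModel` is built from a dataset of (corrupted pair, reference)
examples; :meth:`NPDModel.fit` minimizes the mean absolute reconstruction
error with Adam and returns an :class:`NPDResults` carrying the trained
weights, the loss history, diagnostics, and ``denoise``/``summary``/``save``
methods. Training is fully seeded and bitwise reproducible on one device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from ..exceptions import ContractError, ParameterError
from ..noise import CorruptedPair
from ..signal_core import Segment
from . import autodiff as ad
from .network import ModelConfig, NPDNet

__all__ = ["TrainConfig", "NPDModel", "NPDResults", "save_checkpoint",
           "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for :meth:`NPDModel.fit`."""

    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 2e-3
    loss: str = "l1"
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if self.loss != "l1":
            raise ParameterError("only the 'l1' reconstruction loss is supported")
        if self.device != "cpu":
            raise ParameterError("only device='cpu' is supported")

    def to_dict(self) -> dict:
        return {"epochs": self.epochs, "batch_size": self.batch_size,
                "learning_rate": self.learning_rate, "loss": self.loss,
                "seed": self.seed, "device": self.device}


def _extract(seg_or_array) -> np.ndarray:
    if isinstance(seg_or_array, Segment):
        return seg_or_array.samples
    return np.asarray(seg_or_array, dtype=np.float64)


class NPDModel:
    """The texture-transformer denoiser, bound to a training dataset.

    Parameters
    ----------
    dataset : sequence of (CorruptedPair, reference)
        Each example pairs a corrupted segment (input and target come from
        the pair's noisy and clean members) with a clean reference segment.
        The reference must be a different clean segment, never the example's
        own ground truth.
    config : ModelConfig
        Architecture hyperparameters.
    """

    def __init__(self, dataset: Sequence[Tuple[CorruptedPair, Segment]],
                 config: Optional[ModelConfig] = None) -> None:
        if len(dataset) == 0:
            raise ParameterError("dataset must be non-empty")
        noisy, clean, refs = [], [], []
        length = None
        for pair, ref in dataset:
            x, y, r = _extract(pair.noisy), _extract(pair.clean), _extract(ref)
            if length is None:
                length = len(x)
            if not (len(x) == len(y) == len(r) == length):
                raise ContractError("all segments must share one length")
            noisy.append(x)
            clean.append(y)
            refs.append(r)
        self.noisy = np.stack(noisy)
        self.clean = np.stack(clean)
        self.refs = np.stack(refs)
        self.config = config or ModelConfig()

    @classmethod
    def from_arrays(cls, noisy: np.ndarray, clean: np.ndarray,
                    refs: np.ndarray, config: Optional[ModelConfig] = None
                    ) -> "NPDModel":
        """Construct directly from (n, L) arrays, bypassing Segment wrappers."""
        model = cls.__new__(cls)
        noisy, clean, refs = (np.atleast_2d(np.asarray(a, dtype=np.float64))
                              for a in (noisy, clean, refs))
        if not (noisy.shape == clean.shape == refs.shape):
            raise ContractError("noisy, clean and refs must share shape")
        model.noisy, model.clean, model.refs = noisy, clean, refs
        model.config = config or ModelConfig()
        return model

    def fit(self, train_config: Optional[TrainConfig] = None) -> "NPDResults":
        """Train with Adam on the L1 reconstruction loss."""
        tc = train_config or TrainConfig()
        net = NPDNet(self.config)
        rng = np.random.default_rng(tc.seed)
        n = len(self.noisy)
        params = list(net.params.values())
        m = [np.zeros_like(p.data) for p in params]
        v = [np.zeros_like(p.data) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        loss_history: list[float] = []

        for _ in range(tc.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, tc.batch_size):
                idx = order[start:start + tc.batch_size]
                restored, _ = net.forward(self.noisy[idx], self.refs[idx])
                target = ad.Tensor(self.clean[idx])
                loss = ad.mean_(ad.absval(ad.sub(restored, target)))
                for p in params:
                    p.zero_grad()
                loss.backward()
                step += 1
                lr_t = tc.learning_rate * np.sqrt(1 - beta2 ** step) / \
                    (1 - beta1 ** step)
                for i, p in enumerate(params):
                    g = p.grad if p.grad is not None else np.zeros_like(p.data)
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    p.data = p.data - lr_t * m[i] / (np.sqrt(v[i]) + eps)
                epoch_loss += float(loss.data)
                n_batches += 1
            loss_history.append(epoch_loss / n_batches)

        return NPDResults(net=net, model=self, train_config=tc,
                          loss_history=loss_history,
                          rng_state=rng.bit_generator.state)


class NPDResults:
    """Fitted denoiser: weights, loss history, diagnostics and prediction."""

    def __init__(self, net: NPDNet, model: Optional[NPDModel],
                 train_config: TrainConfig, loss_history: Sequence[float],
                 rng_state: Optional[dict] = None) -> None:
        self.net = net
        self.model = model
        self.train_config = train_config
        self.loss_history = list(loss_history)
        self.rng_state = rng_state

    @property
    def config(self) -> ModelConfig:
        return self.net.config

    def denoise(self, noisy, reference):
        """Restore a noisy segment using a clean reference segment.

        Accepts a :class:`Segment` (returned as a Segment with the same
        geometry, range tag ``signed_unit``) or a plain array.
        """
        x = _extract(noisy)
        r = _extract(reference)
        if x.shape != r.shape:
            raise ContractError("noisy and reference must share shape")
        y = self.net.denoise(x, r)
        if isinstance(noisy, Segment):
            return noisy.with_samples(y, "signed_unit")
        return y

    def summary(self) -> str:
        """Human-readable fit report."""
        cfg = self.net.config
        lines = [
            "Neural PPG denoiser — fit results",
            "=" * 40,
            f"parameters:        {self.net.n_parameters()}",
            f"channels/levels:   {cfg.channels}/{cfg.levels}",
            f"patch size/stride: {cfg.patch_size}/{cfg.patch_stride}",
            f"scale factor:      {cfg.scale_factor}",
            f"epochs:            {self.train_config.epochs}",
            f"batch size:        {self.train_config.batch_size}",
            f"learning rate:     {self.train_config.learning_rate}",
            f"loss (L1):         initial {self.loss_history[0]:.6f}  "
            f"final {self.loss_history[-1]:.6f}",
        ]
        if self.model is not None:
            lines.append(f"training examples: {len(self.model.noisy)}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        save_checkpoint(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "NPDResults":
        return load_checkpoint(path)


def save_checkpoint(results: NPDResults, path: str | Path) -> None:
    """Serialize weights, configs, loss history and RNG state to JSON."""
    payload = {
        "model_config": results.net.config.to_dict(),
        "train_config": results.train_config.to_dict(),
        "loss_history": results.loss_history,
        "rng_state": _jsonify(results.rng_state),
        "weights": {k: v.tolist() for k, v in results.net.state_dict().items()},
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def load_checkpoint(path: str | Path) -> NPDResults:
    payload = json.loads(Path(path).read_text())
    net = NPDNet(ModelConfig.from_dict(payload["model_config"]))
    net.load_state_dict({k: np.array(v) for k, v in payload["weights"].items()})
    tc = TrainConfig(**payload["train_config"])
    return NPDResults(net=net, model=None, train_config=tc,
                      loss_history=payload["loss_history"],
                      rng_state=payload.get("rng_state"))


def _jsonify(obj):
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
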