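"""EE regression architectures: hybrid CNN-LSTM, CNN, LSTM, and stride-MLP.

All four map an input array (a fixed window of L x 6 IMU samples, or a
stride normalized to 30 x 6) plus two subject features (weight, height) to a
single scalar EE prediction in normalized target space.  Hyperparameters
are fixed package-wide: 64 conv filters with kernel 3 and stride
1, pooling kernel 3 and stride 1, 64 LSTM hidden units, 400-unit MLP hidden
layers, dropout 0.5.  Convolutions and pooling are valid (no padding), so
sequence lengths shrink deterministically (L -> L-2 per layer) and every
shape is checkable in closed form: for a 200-sample window the CNN-LSTM
produces conv 198 -> pool 196 -> flattened 196 x 64 = 12544 features, and
the head sees 12546 inputs after the two subject features are appended.

Subject features always join at the same point — immediately after the
flatten — in all four architectures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from . import _nn
from .gait import STRIDE_LEN
from .preprocess import ScalerParams, WindowSet

__all__ = [
    "ArchitectureSpec",
    "ModelState",
    "DEFAULT_HYPERPARAMS",
    "build_cnn_lstm",
    "build_cnn",
    "build_lstm",
    "build_mlp",
    "build_model",
    "predict",
    "save_model",
    "load_model",
]

N_CHANNELS = 6
N_SUBJECT_FEATURES = 2

DEFAULT_HYPERPARAMS: Dict[str, float] = {
    "filters": 64,
    "kernel": 3,
    "stride": 1,
    "lstm_units": 64,
    "mlp_hidden": 400,
    "dropout": 0.5,
}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Architecture kind, input length and the hyperparameter map."""

    kind: str
    input_len: int
    n_channels: int = N_CHANNELS
    hyperparams: Tuple[Tuple[str, float], ...] = tuple(sorted(DEFAULT_HYPERPARAMS.items()))

    def __post_init__(self) -> None:
        if self.kind not in ("cnn_lstm", "cnn", "lstm", "mlp"):
            raise ValueError(f"unknown architecture kind {self.kind!r}")

    @property
    def hp(self) -> Dict[str, float]:
        return dict(self.hyperparams)


@dataclass
class ModelState:
    """An architecture plus its trainable state and captured scalers."""

    spec: ArchitectureSpec
    net: _nn.Regressor
    scalers: Optional[ScalerParams] = None
    seed: int = 0

    def n_params(self) -> int:
        return self.net.n_params()


def _hp(overrides: Optional[Dict[str, float]]) -> Dict[str, float]:
    hp = dict(DEFAULT_HYPERPARAMS)
    if overrides:
        hp.update(overrides)
    return hp


def shape_trace(spec: ArchitectureSpec) -> list:
    """Per-sample shapes after each sequence layer; closed-form testable."""
    shape = (spec.input_len, spec.n_channels)
    net = _build_net(spec, seed=0)
    out = [shape]
    for layer in net.seq_layers:
        shape = layer.out_shape(shape)
        out.append(shape)
    return out


def _build_net(spec: ArchitectureSpec, seed: int) -> _nn.Regressor:
    rng = np.random.default_rng(seed)
    hp = spec.hp
    k = int(hp["kernel"])
    filters = int(hp["filters"])
    units = int(hp["lstm_units"])
    hidden = int(hp["mlp_hidden"])
    p = float(hp["dropout"])
    L = spec.input_len
    C = spec.n_channels

    if spec.kind == "cnn_lstm":
        if L < 5:
            raise ValueError("input_len must be >= 5 for conv + pool with kernel 3")
        seq = [
            _nn.Conv1d(C, filters, k, rng),
            _nn.MaxPool1d(k),
            _nn.LSTM(filters, units, rng),
            _nn.Dropout(p),
            _nn.LSTM(units, units, rng),
        ]
        flat = (L - 2 * (k - 1)) * units
        return _nn.Regressor(seq, [_nn.Dense(flat + N_SUBJECT_FEATURES, 1, rng)],
                             flatten_dropout=_nn.Dropout(p))

    if spec.kind == "cnn":
        if L < 6 * (k - 1) + 1:
            raise ValueError("input_len too short for three conv + pool blocks")
        seq = []
        c_in = C
        for _ in range(3):
            seq.append(_nn.Conv1d(c_in, filters, k, rng))
            seq.append(_nn.MaxPool1d(k))
            c_in = filters
        flat = (L - 6 * (k - 1)) * filters
        return _nn.Regressor(seq, [_nn.Dense(flat + N_SUBJECT_FEATURES, 1, rng)],
                             flatten_dropout=_nn.Dropout(p))

    if spec.kind == "lstm":
        seq = [
            _nn.LSTM(C, units, rng),
            _nn.Dropout(p),
            _nn.LSTM(units, units, rng),
            _nn.Dropout(p),
            _nn.LSTM(units, units, rng),
        ]
        flat = L * units
        return _nn.Regressor(seq, [_nn.Dense(flat + N_SUBJECT_FEATURES, 1, rng)],
                             flatten_dropout=_nn.Dropout(p))

    # mlp: flattened stride (30 x 6 = 180) + 2 features -> 3 x 400 ReLU -> 1
    d_in = L * C + N_SUBJECT_FEATURES
    post = []
    prev = d_in
    for _ in range(3):
        post.append(_nn.Dense(prev, hidden, rng))
        post.append(_nn.ReLU())
        prev = hidden
    post.append(_nn.Dense(prev, 1, rng))
    return _nn.Regressor([], post, flatten_dropout=None)


def _build(kind: str, input_len: int, seed: int, hyperparams: Optional[Dict[str, float]]) -> ModelState:
    spec = ArchitectureSpec(kind=kind, input_len=input_len,
                            hyperparams=tuple(sorted(_hp(hyperparams).items())))
    return ModelState(spec=spec, net=_build_net(spec, seed), seed=seed)


def build_cnn_lstm(input_len: int, seed: int = 0,
                   hyperparams: Optional[Dict[str, float]] = None) -> ModelState:
    """Conv(6->64, k3) -> maxpool(k3) -> LSTM(64) -> LSTM(64) -> flatten ->
    concat subject features -> linear head.  Dropout 0.5 between the LSTM
    layers and between the flatten and the head (training only)."""
    return _build("cnn_lstm", input_len, seed, hyperparams)


def build_cnn(input_len: int, seed: int = 0,
              hyperparams: Optional[Dict[str, float]] = None) -> ModelState:
    """Three conv + maxpool blocks (64 filters, kernel 3) -> flatten ->
    concat subject features -> linear head."""
    return _build("cnn", input_len, seed, hyperparams)


def build_lstm(input_len: int, seed: int = 0,
               hyperparams: Optional[Dict[str, float]] = None) -> ModelState:
    """Three stacked LSTM layers (64 units) -> flatten -> concat subject
    features -> linear head."""
    return _build("lstm", input_len, seed, hyperparams)


def build_mlp(seed: int = 0, hyperparams: Optional[Dict[str, float]] = None) -> ModelState:
    """Stride MLP: flatten(30 x 6) + 2 subject features = 182 inputs ->
    three 400-unit ReLU hidden layers -> linear head.  No dropout."""
    return _build("mlp", STRIDE_LEN, seed, hyperparams)


def build_model(kind: str, input_len: Optional[int] = None, seed: int = 0,
                hyperparams: Optional[Dict[str, float]] = None) -> ModelState:
    """Dispatch on architecture kind; ``input_len`` is ignored for the MLP."""
    if kind == "mlp":
        return build_mlp(seed=seed, hyperparams=hyperparams)
    if input_len is None:
        raise ValueError("input_len required for window architectures")
    return _build(kind, input_len, seed, hyperparams)


def predict(model: ModelState, x: np.ndarray, subject_features: np.ndarray) -> np.ndarray:
    """EE predictions in watts for raw (unscaled) inputs.

    Applies the scalers captured at training time, runs the network with
    dropout inactive, and inverse-transforms the normalized output through
    the target min-max.  Deterministic at inference.
    """
    if model.scalers is None:
        raise ValueError("model has no captured scalers; train it first")
    x = np.asarray(x)
    feats = np.asarray(subject_features, dtype=float)
    if x.ndim != 3 or x.shape[1] != model.spec.input_len or x.shape[2] != model.spec.n_channels:
        raise ValueError(
            f"expected input (N, {model.spec.input_len}, {model.spec.n_channels}), got {x.shape}"
        )
    if feats.ndim != 2 or feats.shape[1] != N_SUBJECT_FEATURES:
        raise ValueError("subject_features must be (N, 2)")
    sp = model.scalers
    out = model.net.forward(sp.scale_x(x), sp.scale_features(feats), train=False)
    return sp.invert_y(out.astype(np.float64))


def predict_set(model: ModelState, ws: WindowSet, batch_size: int = 512) -> np.ndarray:
    """Batched prediction over an unscaled window or stride set, watts."""
    if ws.scaled:
        raise ValueError("predict_set expects an unscaled set")
    out = []
    for i in range(0, len(ws), batch_size):
        out.append(predict(model, ws.x[i:i + batch_size], ws.subject_features[i:i + batch_size]))
    return np.concatenate(out) if out else np.zeros(0)


def save_model(model: ModelState, path) -> None:
    """Single-file persistence: JSON header + parameter arrays (.npz)."""
    header = {
        "kind": model.spec.kind,
        "input_len": model.spec.input_len,
        "n_channels": model.spec.n_channels,
        "hyperparams": model.spec.hp,
        "seed": model.seed,
        "scalers": model.scalers.to_dict() if model.scalers is not None else None,
    }
    arrays = {f"param/{k}": v for k, v in model.net.state_arrays().items()}
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> ModelState:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    spec = ArchitectureSpec(
        kind=header["kind"],
        input_len=int(header["input_len"]),
        n_channels=int(header["n_channels"]),
        hyperparams=tuple(sorted(header["hyperparams"].items())),
    )
    net = _build_net(spec, seed=int(header["seed"]))
    net.load_state_arrays(state)
    scalers = (ScalerParams.from_dict(header["scalers"])
               if header["scalers"] is not None else None)
    return ModelState(spec=spec, net=net, scalers=scalers, seed=int(header["seed"]))
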