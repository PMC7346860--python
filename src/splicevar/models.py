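"""Splice-site classifier architectures and the scikit-learn estimator.

Three convolutional architectures are provided, named by their
convolution-layer count:

* ``CNN_3`` — three conv layers (70/100/150 filters, kernels 9/7/7), two
  2-wide max-pools, dropout 0.2 throughout, dense 512, 2-way softmax.
* ``CNN_4`` — four conv layers (70/100/100/200 filters, kernel 3), two
  2-wide max-pools, dropout 0.2, dense 512, 2-way softmax.
* ``CNN_LSTM`` — one conv layer (320 filters, kernel 26), max-pool 13,
  a bidirectional LSTM with 320 units per direction, dropout 0.5, dense
  925, 2-way softmax.

The first convolution's filters span the full 4-nucleotide channel axis
((9,4)/(3,4) filters on the N x 4 one-hot matrix), collapsing it; later
convolutions run along the sequence axis only. Hidden activations are
ReLU; the output is a softmax over the two classes.

Training follows one fixed recipe: SGD with Nesterov momentum 0.9,
categorical cross-entropy, 30 epochs, batch size 64, initial learning
rate 0.05 halved every 5 epochs (the decay factor is configurable; the
halving default is this package's choice).
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .encoding import encode_batch
from .nn import BiLSTM, Conv1D, Dense, Dropout, Flatten, MaxPool1D, Network, ReLU


class Architecture(str, enum.Enum):
    CNN_3 = "CNN_3"
    CNN_4 = "CNN_4"
    CNN_LSTM = "CNN_LSTM"


@dataclass(frozen=True)
class LayerSpec:
    """One row of an architecture table: layer kind plus size parameters."""

    kind: str  # conv2d | conv1d | maxpool | dropout | dense | bilstm | softmax
    filters: int | None = None
    size: tuple[int, ...] | None = None
    pool: int | None = None
    rate: float | None = None
    units: int | None = None

    def __post_init__(self) -> None:
        for val in (self.filters, self.pool, self.units):
            if val is not None and val < 1:
                raise ValueError(f"{self.kind}: size parameters must be positive")
        if self.rate is not None and not 0.0 < self.rate < 1.0:
            raise ValueError(f"dropout rate must be in (0, 1), got {self.rate}")


_ARCHITECTURES: dict[Architecture, list[LayerSpec]] = {
    Architecture.CNN_3: [
        LayerSpec("conv2d", filters=70, size=(9, 4)),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("conv2d", filters=100, size=(7, 1)),
        LayerSpec("maxpool", pool=2),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("conv2d", filters=150, size=(7, 1)),
        LayerSpec("maxpool", pool=2),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("dense", units=512),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("softmax", units=2),
    ],
    Architecture.CNN_4: [
        LayerSpec("conv2d", filters=70, size=(3, 4)),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("conv2d", filters=100, size=(3, 1)),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("conv2d", filters=100, size=(3, 1)),
        LayerSpec("maxpool", pool=2),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("conv2d", filters=200, size=(3, 1)),
        LayerSpec("maxpool", pool=2),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("dense", units=512),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("softmax", units=2),
    ],
    Architecture.CNN_LSTM: [
        LayerSpec("conv1d", filters=320, size=(26,)),
        LayerSpec("maxpool", pool=13),
        LayerSpec("dropout", rate=0.2),
        LayerSpec("bilstm", units=320),
        LayerSpec("dropout", rate=0.5),
        LayerSpec("dense", units=925),
        LayerSpec("softmax", units=2),
    ],
}

_ALIASES = {"cnn3": Architecture.CNN_3, "cnn_3": Architecture.CNN_3,
            "cnn4": Architecture.CNN_4, "cnn_4": Architecture.CNN_4,
            "cnnlstm": Architecture.CNN_LSTM, "cnn_lstm": Architecture.CNN_LSTM}


def resolve_architecture(name: str | Architecture) -> Architecture:
    if isinstance(name, Architecture):
        return name
    key = name.lower().replace("-", "_")
    if key in _ALIASES:
        return _ALIASES[key]
    return Architecture(name)


@dataclass(frozen=True)
class ModelSpec:
    """A named architecture bound to a concrete input length."""

    name: Architecture
    input_length: int
    layers: tuple[LayerSpec, ...]

    def dump(self) -> list[dict]:
        """Layer-by-layer dump (kind + non-null size parameters)."""
        out = []
        for layer in self.layers:
            d = {k: v for k, v in asdict(layer).items() if v is not None}
            out.append(d)
        return out


@dataclass(frozen=True)
class TrainConfig:
    """The fixed training recipe; only the decay factor and seed vary."""

    optimizer: str = "sgd-nesterov"
    momentum: float = 0.9
    loss: str = "categorical-crossentropy"
    epochs: int = 30
    batch_size: int = 64
    lr0: float = 0.05
    decay_every: int = 5
    decay_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.decay_factor <= 1.0:
            raise ValueError("decay_factor must be in (0, 1]")


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Step decay: ``lr0 * decay_factor ** floor(epoch / decay_every)``."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    return config.lr0 * config.decay_factor ** (epoch // config.decay_every)


def build_model(name: str | Architecture, input_length: int) -> ModelSpec:
    """Instantiate an architecture spec for a given window length.

    Raises if the conv/pool stack does not admit ``input_length`` (the
    error states the minimum admissible length).
    """
    arch = resolve_architecture(name)
    layers = tuple(_ARCHITECTURES[arch])
    spec = ModelSpec(arch, input_length, layers)
    try:
        compile_network(spec)
    except ValueError as exc:
        raise ValueError(
            f"{arch.value} does not admit input length {input_length} "
            f"(minimum is {minimum_input_length(arch)}): {exc}"
        ) from exc
    return spec


def minimum_input_length(name: str | Architecture) -> int:
    """Smallest window length the architecture's conv/pool stack admits."""
    arch = resolve_architecture(name)
    for L in range(2, 1000):
        try:
            compile_network(ModelSpec(arch, L, tuple(_ARCHITECTURES[arch])))
            return L
        except ValueError:
            continue
    raise RuntimeError("no admissible length below 1000")  # pragma: no cover


def compile_network(spec: ModelSpec) -> Network:
    """Translate a :class:`ModelSpec` into an initialisable network.

    ReLU follows every convolution and hidden dense layer; a flatten is
    inserted before the first dense layer; the softmax row becomes the
    final logits layer (the softmax itself is applied at prediction).
    """
    layers = []
    shape: tuple = (spec.input_length, 4)
    for ls in spec.layers:
        if ls.kind in ("conv2d", "conv1d"):
            kernel = ls.size[0]
            layer = Conv1D(shape[1], ls.filters, kernel)
            shape = layer.out_shape(shape)
            layers += [layer, ReLU()]
        elif ls.kind == "maxpool":
            layer = MaxPool1D(ls.pool)
            shape = layer.out_shape(shape)
            layers.append(layer)
        elif ls.kind == "dropout":
            layers.append(Dropout(ls.rate))
        elif ls.kind == "bilstm":
            layer = BiLSTM(shape[1], ls.units)
            shape = layer.out_shape(shape)
            layers.append(layer)
        elif ls.kind in ("dense", "softmax"):
            if len(shape) == 2:
                flat = Flatten()
                shape = flat.out_shape(shape)
                layers.append(flat)
            layer = Dense(shape[0], ls.units)
            shape = layer.out_shape(shape)
            layers.append(layer)
            if ls.kind == "dense":
                layers.append(ReLU())
        else:  # pragma: no cover
            raise ValueError(f"unknown layer kind {ls.kind!r}")
    return Network(layers)


def parameter_count(spec: ModelSpec) -> int:
    net = compile_network(spec)
    return int(sum(p.size for p in net.params()))


class SpliceSiteClassifier(ClassifierMixin, BaseEstimator):
    """Convolutional splice-site classifier with a scikit-learn interface.

    Parameters
    ----------
    architecture : str
        ``"CNN_3"``, ``"CNN_4"`` or ``"CNN_LSTM"`` (case-insensitive
        aliases ``cnn3``/``cnn4``/``cnnlstm`` accepted).
    epochs, batch_size, lr0, decay_every, decay_factor, momentum
        The training recipe (defaults follow the fixed recipe above).
    random_state : int
        Seeds weight initialisation, batch shuffling and dropout masks;
        identical seeds give identical training histories.

    Attributes
    ----------
    spec_ : ModelSpec
        The architecture bound to the fitted input length.
    network_ : Network
        The trained parameter store.
    history_ : list of dict
        Per-epoch ``{"epoch", "lr", "loss"}``.
    classes_ : ndarray
        ``[0, 1]``; class 1 is "true splice site".

    Examples
    --------
    >>> clf = SpliceSiteClassifier("CNN_4", epochs=2, random_state=0)
    >>> clf = clf.fit(X, y)          # X: (B, L, 4) one-hot or sequences
    >>> clf.predict_proba_splice(["ACGT..."])
    """

    def __init__(self, architecture: str = "CNN_4", *, epochs: int = 30,
                 batch_size: int = 64, lr0: float = 0.05,
                 decay_every: int = 5, decay_factor: float = 0.5,
                 momentum: float = 0.9, random_state: int = 0):
        self.architecture = architecture
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.decay_every = decay_every
        self.decay_factor = decay_factor
        self.momentum = momentum
        self.random_state = random_state

    # -- data marshalling ---------------------------------------------------

    def _encode(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            if X.shape[2] != 4:
                raise ValueError(f"one-hot input must have 4 channels, "
                                 f"got {X.shape[2]}")
            return np.asarray(X, dtype=float)
        return encode_batch(X)

    def train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           lr0=self.lr0, decay_every=self.decay_every,
                           decay_factor=self.decay_factor,
                           momentum=self.momentum, seed=self.random_state)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        """Train on one-hot matrices (B, L, 4) or sequences, labels 0/1."""
        x = self._encode(X)
        y = np.asarray([_label_to_int(v) for v in y], dtype=int)
        if len(x) != len(y):
            raise ValueError(f"X has {len(x)} rows but y has {len(y)}")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        config = self.train_config()
        self.spec_ = build_model(self.architecture, x.shape[1])
        self.network_ = compile_network(self.spec_)
        self.network_.init(config.seed)
        onehot = np.eye(2)[y]
        self.history_ = self.network_.fit(
            x, onehot, epochs=config.epochs, batch_size=config.batch_size,
            lr_for_epoch=lambda e: lr_schedule(e, config),
            momentum=config.momentum, seed=config.seed + 1)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = x.shape[1] * 4
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, columns ordered as ``classes_`` (neg, pos)."""
        self._check_fitted()
        x = self._encode(X)
        if x.shape[1] != self.spec_.input_length:
            raise ValueError(
                f"input length {x.shape[1]} does not match fitted "
                f"length {self.spec_.input_length}"
            )
        return self.network_.predict_proba(x)

    def predict_proba_splice(self, X) -> np.ndarray:
        """Probability of the positive (true splice site) class."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        """0/1 labels under the strict ``probability > 0.5`` rule."""
        return (self.predict_proba_splice(X) > 0.5).astype(int)

    def history_digest(self) -> str:
        """SHA-256 over the training history; equal for identical runs."""
        self._check_fitted()
        payload = json.dumps(self.history_, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def _check_fitted(self) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted; call fit() first")

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Save to a self-describing ``.npz`` archive (metadata + weights)."""
        self._check_fitted()
        meta = {"architecture": self.spec_.name.value,
                "input_length": self.spec_.input_length,
                "params": self.get_params(),
                "history": self.history_,
                "version": 1}
        arrays = {f"param_{i}": p
                  for i, p in enumerate(self.network_.params())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "SpliceSiteClassifier":
        """Restore a classifier saved with :meth:`save`."""
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            weights = [archive[f"param_{i}"]
                       for i in range(len(archive.files) - 1)]
        clf = cls(**meta["params"])
        clf.spec_ = build_model(meta["architecture"], meta["input_length"])
        clf.network_ = compile_network(clf.spec_)
        params = clf.network_.params()
        if len(params) != len(weights):
            raise ValueError("weight count does not match architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape {w.shape} != expected {p.shape}")
            p[...] = w
        clf.history_ = meta["history"]
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = meta["input_length"] * 4
        return clf


def train(spec: ModelSpec, train_data, config: TrainConfig
          ) -> SpliceSiteClassifier:
    """Train a fresh classifier from a spec and a (X, y) pair or record list."""
    clf = SpliceSiteClassifier(
        spec.name.value, epochs=config.epochs, batch_size=config.batch_size,
        lr0=config.lr0, decay_every=config.decay_every,
        decay_factor=config.decay_factor, momentum=config.momentum,
        random_state=config.seed)
    X, y = _as_xy(train_data)
    return clf.fit(X, y)


def predict_proba(model: SpliceSiteClassifier, sequences) -> np.ndarray:
    """Positive-class probability for each sequence."""
    return model.predict_proba_splice(sequences)


def _label_to_int(v) -> int:
    if isinstance(v, (bool, int, np.integer)):
        return int(v)
    s = str(getattr(v, "value", v)).lower()
    return 1 if s in ("1", "positive", "pos", "true") else 0


def _as_xy(train_data):
    if isinstance(train_data, tuple):
        return train_data
    # list of SpliceSequence records
    y = [1 if r.label.value == "positive" else 0 for r in train_data]
    return train_data, np.asarray(y)
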