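"""Feed-forward classifier separating true variants from FFPE artifacts.

The network has three linear layers (input->32->16->2) with ReLU on the
two hidden layers, a batch-normalization layer after each hidden
activation, and a two-node softmax output whose positive node is the
probability of being a true variant.  Cross entropy on that probability
(binary cross entropy) is minimised with Adam.  Everything is plain
numpy: forward, backward and the optimizer are written out explicitly,
which keeps training bit-reproducible from a single integer seed.

:class:`FFPEClassifier` follows the scikit-learn estimator protocol
(``fit`` / ``predict`` / ``predict_proba`` / ``get_params``), so it
composes with sklearn model selection; the module-level functions are
thin wrappers over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import DEFAULT_SCHEMA, FeatureScaler, FeatureSchema
from .variants import Label

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
BUNDLE_FORMAT = "ffpefilter-model-1"


@dataclass
class ClassifierConfig:
    """Hyperparameters of the default architecture.

    The layer widths and loss follow the fixed design; learning rate,
    batch size and epoch count are pinned defaults chosen for
    reproducibility and can be overridden.
    """

    layer_widths: Tuple[int, int, int] = (41, 32, 16)
    learning_rate: float = 1e-3
    batch_size: int = 256
    n_epochs: int = 100
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class FFPEClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style estimator around the numpy MLP.

    Parameters
    ----------
    layer_widths : tuple of three ints
        Input width and the two hidden widths; (41, 32, 16) matches the
        default 41-entry feature schema.
    learning_rate, batch_size, n_epochs : Adam hyperparameters.
    threshold : float in (0, 1)
        Decision cutoff on the true-variant probability; predictions at
        or above it are true variants (boundary inclusive).
    random_state : int
        Seeds weight initialisation and batch shuffling.
    schema : FeatureSchema, optional
        When given (or when the input width is 41, where the default
        schema applies) its one-hot mask controls which features the
        internal scaler standardises; other features are z-scored.
    """

    def __init__(
        self,
        layer_widths: Tuple[int, int, int] = (41, 32, 16),
        learning_rate: float = 1e-3,
        batch_size: int = 256,
        n_epochs: int = 100,
        threshold: float = 0.5,
        random_state: int = 0,
        schema: Optional[FeatureSchema] = None,
    ):
        self.layer_widths = layer_widths
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.threshold = threshold
        self.random_state = random_state
        self.schema = schema

    # -- construction ------------------------------------------------------

    def _resolved_schema(self) -> Optional[FeatureSchema]:
        if self.schema is not None:
            return self.schema
        if self.layer_widths[0] == len(DEFAULT_SCHEMA):
            return DEFAULT_SCHEMA
        return None

    def _check_config(self) -> None:
        if len(self.layer_widths) != 3 or any(w <= 0 for w in self.layer_widths):
            raise ValueError(f"layer_widths must be three positive ints, got {self.layer_widths}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        schema = self._resolved_schema()
        if schema is not None and len(schema) != self.layer_widths[0]:
            raise ValueError(
                f"input width {self.layer_widths[0]} does not match the "
                f"{len(schema)}-entry feature schema"
            )

    def init_weights(self, rng: Optional[np.random.Generator] = None) -> "FFPEClassifier":
        """Deterministic He-style initialisation; leaves the model untrained."""
        self._check_config()
        rng = rng or np.random.default_rng(self.random_state)
        d_in, h1, h2 = self.layer_widths
        def he(n_in, n_out):
            return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.weights_: Dict[str, np.ndarray] = {
            "W1": he(d_in, h1), "b1": np.zeros(h1),
            "g1": np.ones(h1), "beta1": np.zeros(h1),
            "W2": he(h1, h2), "b2": np.zeros(h2),
            "g2": np.ones(h2), "beta2": np.zeros(h2),
            "W3": he(h2, 2), "b3": np.zeros(2),
        }
        self.running_mean_ = {"bn1": np.zeros(h1), "bn2": np.zeros(h2)}
        self.running_var_ = {"bn1": np.ones(h1), "bn2": np.ones(h2)}
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = d_in
        self.history_: list = []
        return self

    @property
    def n_parameters_(self) -> int:
        """Count of trainable parameters (weights, biases, BN scale/shift)."""
        return int(sum(v.size for v in self.weights_.values()))

    # -- forward / backward ------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool):
        w = self.weights_
        cache = {}
        z1 = X @ w["W1"] + w["b1"]
        a1 = _relu(z1)
        bn1, c1 = self._batchnorm(a1, "bn1", w["g1"], w["beta1"], training)
        z2 = bn1 @ w["W2"] + w["b2"]
        a2 = _relu(z2)
        bn2, c2 = self._batchnorm(a2, "bn2", w["g2"], w["beta2"], training)
        logits = bn2 @ w["W3"] + w["b3"]
        probs = _softmax(logits)
        cache.update(X=X, z1=z1, a1=a1, bn1=bn1, c1=c1, z2=z2, a2=a2, bn2=bn2, c2=c2, probs=probs)
        return probs, cache

    def _batchnorm(self, x, name, gamma, beta, training):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean_[name] = (1 - _BN_MOMENTUM) * self.running_mean_[name] + _BN_MOMENTUM * mu
            self.running_var_[name] = (1 - _BN_MOMENTUM) * self.running_var_[name] + _BN_MOMENTUM * var
        else:
            mu = self.running_mean_[name]
            var = self.running_var_[name]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu) * inv_std
        return gamma * xhat + beta, (xhat, inv_std)

    @staticmethod
    def _bn_backward(dy, gamma, cache):
        xhat, inv_std = cache
        B = dy.shape[0]
        dgamma = (dy * xhat).sum(axis=0)
        dbeta = dy.sum(axis=0)
        dxhat = dy * gamma
        dx = (inv_std / B) * (
            B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        return dx, dgamma, dbeta

    def _backward(self, y_onehot: np.ndarray, cache) -> Dict[str, np.ndarray]:
        w = self.weights_
        B = y_onehot.shape[0]
        g: Dict[str, np.ndarray] = {}
        dlogits = (cache["probs"] - y_onehot) / B
        g["W3"] = cache["bn2"].T @ dlogits
        g["b3"] = dlogits.sum(axis=0)
        dbn2 = dlogits @ w["W3"].T
        da2, g["g2"], g["beta2"] = self._bn_backward(dbn2, w["g2"], cache["c2"])
        dz2 = da2 * (cache["z2"] > 0)
        g["W2"] = cache["bn1"].T @ dz2
        g["b2"] = dz2.sum(axis=0)
        dbn1 = dz2 @ w["W2"].T
        da1, g["g1"], g["beta1"] = self._bn_backward(dbn1, w["g1"], cache["c1"])
        dz1 = da1 * (cache["z1"] > 0)
        g["W1"] = cache["X"].T @ dz1
        g["b1"] = dz1.sum(axis=0)
        return g

    # -- estimator API -----------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FFPEClassifier":
        """Train with Adam on binary cross entropy; deterministic per seed."""
        self._check_config()
        X = np.asarray(X, dtype=float)
        y = list(y)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("training set must be a nonempty 2-D matrix")
        if X.shape[1] != self.layer_widths[0]:
            raise ValueError(f"expected {self.layer_widths[0]} features, got {X.shape[1]}")
        y = self._encode_labels(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes (true variants and artifacts)")

        rng = np.random.default_rng(self.random_state)
        self.init_weights(rng=rng)
        self.scaler_ = self._make_scaler().fit(X)
        Xs = self.scaler_.transform(X)
        if not np.isfinite(Xs).all():
            raise ValueError("non-finite feature values after scaling")

        m = {k: np.zeros_like(v) for k, v in self.weights_.items()}
        v = {k: np.zeros_like(val) for k, val in self.weights_.items()}
        t = 0
        n = Xs.shape[0]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        onehot = np.eye(2)[y]
        self.history_ = []
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                probs, cache = self._forward(Xs[idx], training=True)
                p = np.clip(probs[np.arange(len(idx)), y[idx]], 1e-12, None)
                epoch_loss += float(-np.log(p).sum())
                grads = self._backward(onehot[idx], cache)
                t += 1
                for k in self.weights_:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v[k] / (1 - beta2**t)
                    self.weights_[k] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.history_.append(epoch_loss / n)
        self.final_loss_ = self.history_[-1]
        return self

    def _encode_labels(self, y) -> np.ndarray:
        out = np.empty(len(y), dtype=int)
        for i, v in enumerate(y):
            if isinstance(v, Label):
                out[i] = 1 if v is Label.TRUE_VARIANT else 0
            elif isinstance(v, str):
                out[i] = 1 if v.endswith(Label.TRUE_VARIANT.value) else 0
            else:
                out[i] = int(v)
        if not set(np.unique(out)) <= {0, 1}:
            raise ValueError("labels must be binary (true variant = 1, artifact = 0)")
        return out

    def _make_scaler(self) -> FeatureScaler:
        schema = self._resolved_schema()
        if schema is None:
            # widths other than 41 get a plain all-numeric schema
            schema = FeatureSchema(
                names=tuple(f"f{i}" for i in range(self.layer_widths[0])),
                version="generic",
            )
        return FeatureScaler(schema)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities [P(artifact), P(true variant)]; rows sum to 1."""
        if not hasattr(self, "weights_"):
            raise ValueError("model is not initialised; call fit or init_weights first")
        X = np.asarray(X, dtype=float)
        one = X.ndim == 1
        if one:
            X = X[None, :]
        if X.shape[1] != self.layer_widths[0]:
            raise ValueError(f"expected {self.layer_widths[0]} features, got {X.shape[1]}")
        if hasattr(self, "scaler_"):
            X = self.scaler_.transform(X)
        else:
            X = np.where(np.isnan(X), 0.0, X)
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values after scaling")
        probs, _ = self._forward(X, training=False)
        return probs[0] if one else probs

    def predict(self, X: np.ndarray, threshold: Optional[float] = None) -> np.ndarray:
        """1 (true variant) where P(true variant) >= threshold, else 0."""
        thr = self.threshold if threshold is None else threshold
        if not (0.0 < thr < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {thr}")
        proba = self.predict_proba(X)
        pos = proba[..., 1]
        return (pos >= thr).astype(int)


# -- module-level wrappers (thin, per the library surface) -----------------


def init_classifier(config: ClassifierConfig = ClassifierConfig()) -> FFPEClassifier:
    """Untrained model with deterministically initialised weights."""
    return FFPEClassifier(
        layer_widths=config.layer_widths,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        n_epochs=config.n_epochs,
        threshold=config.threshold,
        random_state=config.seed,
    ).init_weights()


def train(
    model: FFPEClassifier, X: np.ndarray, y: Sequence, config: Optional[ClassifierConfig] = None
) -> FFPEClassifier:
    if config is not None:
        model.set_params(
            layer_widths=config.layer_widths,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            n_epochs=config.n_epochs,
            threshold=config.threshold,
            random_state=config.seed,
        )
    return model.fit(X, y)


def predict_proba(model: FFPEClassifier, X: np.ndarray) -> np.ndarray:
    """Positive-class (true variant) probability per call."""
    return np.asarray(model.predict_proba(X))[..., 1]


def classify(model: FFPEClassifier, X: np.ndarray, threshold: Optional[float] = None):
    """Map calls to labels using the inclusive-boundary threshold rule."""
    pred = np.atleast_1d(model.predict(X, threshold=threshold))
    labels = [Label.TRUE_VARIANT if p == 1 else Label.FFPE_ARTIFACT for p in pred]
    return labels[0] if np.asarray(X).ndim == 1 else labels


def save_model(model: FFPEClassifier, path: str) -> None:
    """Serialise weights, BN statistics, scaler, schema and threshold (.npz)."""
    if not hasattr(model, "weights_"):
        raise ValueError("cannot save an uninitialised model")
    schema = model.scaler_.schema if hasattr(model, "scaler_") else model._resolved_schema()
    meta = {
        "format": BUNDLE_FORMAT,
        "layer_widths": list(model.layer_widths),
        "threshold": model.threshold,
        "seed": model.random_state,
        "learning_rate": model.learning_rate,
        "batch_size": model.batch_size,
        "n_epochs": model.n_epochs,
        "schema_names": list(schema.names) if schema else None,
        "schema_version": schema.version if schema else None,
        "schema_fingerprint": schema.fingerprint if schema else None,
        "final_loss": getattr(model, "final_loss_", None),
    }
    arrays = {f"w_{k}": v for k, v in model.weights_.items()}
    for k, v in model.running_mean_.items():
        arrays[f"rm_{k}"] = v
    for k, v in model.running_var_.items():
        arrays[f"rv_{k}"] = v
    if hasattr(model, "scaler_"):
        arrays["sc_median"] = model.scaler_.median_
        arrays["sc_mean"] = model.scaler_.mean_
        arrays["sc_scale"] = model.scaler_.scale_
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str) -> FFPEClassifier:
    with np.load(path if str(path).endswith(".npz") else str(path)) as bundle:
        meta = json.loads(bytes(bundle["meta_json"].tobytes()).decode())
        if meta.get("format") != BUNDLE_FORMAT:
            raise ValueError(f"unrecognised model bundle format {meta.get('format')!r}")
        widths = tuple(meta["layer_widths"])
        names = meta.get("schema_names")
        schema = None
        if names is not None:
            if len(names) != widths[0]:
                raise ValueError(
                    f"bundle schema has {len(names)} names but the model takes {widths[0]} inputs"
                )
            schema = FeatureSchema(names=tuple(names), version=meta.get("schema_version", "v1"))
            if meta.get("schema_fingerprint") and schema.fingerprint != meta["schema_fingerprint"]:
                raise ValueError("schema fingerprint mismatch: bundle was built for a different layout")
        model = FFPEClassifier(
            layer_widths=widths,
            learning_rate=meta["learning_rate"],
            batch_size=meta["batch_size"],
            n_epochs=meta["n_epochs"],
            threshold=meta["threshold"],
            random_state=meta["seed"],
            schema=schema,
        ).init_weights()
        model.weights_ = {k[2:]: bundle[k].copy() for k in bundle.files if k.startswith("w_")}
        model.running_mean_ = {k[3:]: bundle[k].copy() for k in bundle.files if k.startswith("rm_")}
        model.running_var_ = {k[3:]: bundle[k].copy() for k in bundle.files if k.startswith("rv_")}
        if "sc_mean" in bundle.files:
            scaler = model._make_scaler()
            scaler.median_ = bundle["sc_median"].copy()
            scaler.mean_ = bundle["sc_mean"].copy()
            scaler.scale_ = bundle["sc_scale"].copy()
            model.scaler_ = scaler
        if meta.get("final_loss") is not None:
            model.final_loss_ = meta["final_loss"]
    return model
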