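"""The LSTM classifier and its training/evaluation harnesses.

:class:`LSTMClassifier` is a scikit-learn style estimator
(fit/predict/predict_proba/get_params) over the numpy LSTM in
:mod:`preictal._lstm`.  It consumes windows shaped ``(n_samples,
time_steps, channels)`` — at the standard settings a 5-s window at 256 Hz
over 23 channels, i.e. a 1280 x 23 sequence per sample — and emits one
probability vector per window over {preictal, interictal} or {preictal,
interictal, postictal}.

The module-level operations wrap the estimator for the package's
:class:`~preictal.preprocessing.Sample` lists: patient-style first-k-seizure
splits, stratified k-fold cross-validation, and leave-one-seizure-out
rounds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from ._lstm import LSTMNet, TrainHistory
from .io import SeizureEvent
from .preprocessing import Sample, balance_classes
from .staging import Stage

__all__ = [
    "ModelConfig",
    "LSTMClassifier",
    "build_model",
    "train",
    "predict_samples",
    "split_first_k_seizures",
    "kfold_cv",
    "loocv_by_seizure",
    "samples_to_arrays",
]


@dataclass
class ModelConfig:
    """Architecture and optimization settings for the LSTM classifier.

    ``input_len`` must equal ``fs * window_s`` of the samples being fed in
    (1280 at 256 Hz and 5-s windows).  ``time_pool > 1`` RMS-pools the
    window over non-overlapping blocks of that many points before the
    recurrence, preserving the band-power envelope while shortening the
    sequence; the full-scale profile uses ``time_pool=1`` (raw sequence).
    """

    input_len: int = 1280
    n_channels: int = 23
    lstm_units: int = 128
    dropout: float = 0.5
    n_classes: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 5
    validation_fraction: float = 0.1
    time_pool: int = 1
    normalize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lstm_units < 1:
            raise ValueError("lstm_units must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.input_len < 1 or self.time_pool < 1:
            raise ValueError("input_len and time_pool must be positive")

    @classmethod
    def reduced(cls, **overrides) -> "ModelConfig":
        """CPU-friendly test profile: 32 units, <= 10 epochs, 32-point RMS pooling."""
        base = dict(
            lstm_units=32,
            max_epochs=10,
            patience=3,
            time_pool=32,
            batch_size=64,
        )
        base.update(overrides)
        return cls(**base)


class LSTMClassifier(BaseEstimator, ClassifierMixin):
    """Sequence classifier: LSTM -> dropout -> fully connected -> softmax.

    Parameters mirror :class:`ModelConfig`; ``fit`` expects ``X`` with shape
    ``(n_samples, time_steps, channels)`` and integer or string labels
    ``y``.  Per-channel z-score normalization statistics are computed from
    the training samples only and reapplied at prediction time.  Ten percent
    of the training data (seeded) is held out to drive early stopping.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray
        Sorted class labels.
    net_ : LSTMNet
        The fitted network.
    history_ : TrainHistory
        Per-epoch loss/accuracy trace.
    norm_mean_, norm_std_ : ndarray, shape (channels,)
        Training-set normalization statistics (pooled domain).
    """

    def __init__(
        self,
        n_units: int = 128,
        dropout: float = 0.5,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 30,
        patience: int = 5,
        validation_fraction: float = 0.1,
        time_pool: int = 1,
        normalize: bool = True,
        random_state: int | None = 0,
    ) -> None:
        self.n_units = n_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.time_pool = time_pool
        self.normalize = normalize
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _check_X(self, X: np.ndarray, fitted: bool) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (n_samples, time_steps, channels), got shape {X.shape}"
            )
        if fitted:
            if X.shape[2] != self.n_features_in_:
                raise ValueError(
                    f"X has {X.shape[2]} channels, model was fitted with "
                    f"{self.n_features_in_}"
                )
            if X.shape[1] != self.input_len_:
                raise ValueError(
                    f"X has {X.shape[1]} time steps, model expects {self.input_len_}"
                )
        return X

    def _pool(self, X: np.ndarray) -> np.ndarray:
        p = int(self.time_pool)
        if p <= 1:
            return X
        n, T, C = X.shape
        T2 = T // p
        Xb = X[:, : T2 * p, :].reshape(n, T2, p, C)
        return np.sqrt(np.mean(Xb**2, axis=2))  # RMS preserves band power

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        Xp = self._pool(X)
        if self.normalize:
            Xp = (Xp - self.norm_mean_) / self.norm_std_
        return Xp

    # -- estimator API -----------------------------------------------------

    def fit(self, X: np.ndarray, y) -> "LSTMClassifier":
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        X = self._check_X(X, fitted=False)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        self.n_features_in_ = X.shape[2]
        self.input_len_ = X.shape[1]

        rng = np.random.default_rng(self.random_state)
        Xp = self._pool(X)
        if self.normalize:
            flat = Xp.reshape(-1, Xp.shape[2])
            self.norm_mean_ = flat.mean(axis=0)
            sd = flat.std(axis=0)
            self.norm_std_ = np.where(sd > 0, sd, 1.0)
            Xp = (Xp - self.norm_mean_) / self.norm_std_
        else:
            self.norm_mean_ = np.zeros(Xp.shape[2])
            self.norm_std_ = np.ones(Xp.shape[2])

        self.net_ = LSTMNet(
            n_features=Xp.shape[2],
            n_units=self.n_units,
            n_classes=len(self.classes_),
            dropout=self.dropout,
            rng=rng,
        )
        self.history_ = self.net_.fit(
            Xp,
            y_idx,
            rng=rng,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            validation_fraction=self.validation_fraction,
        )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = self._check_X(X, fitted=True)
        if X.shape[0] == 0:
            return np.empty((0, len(self.classes_)))
        return self.net_.predict_proba(self._prepare(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax labels; exact probability ties resolve to the first class
        in ``classes_`` sort order, which for stage labels is 'interictal'
        (the non-alarm class)."""
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def save(self, path) -> None:
        """Persist weights (npz) plus a JSON sidecar of params and stats."""
        check_is_fitted(self, "net_")
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net_.get_weights())
        sidecar = {
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "norm_mean": self.norm_mean_.tolist(),
            "norm_std": self.norm_std_.tolist(),
            "input_len": int(self.input_len_),
            "n_channels": int(self.n_features_in_),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "LSTMClassifier":
        """Restore a classifier from :meth:`save` output."""
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        clf = cls(**sidecar["params"])
        clf.classes_ = np.array(sidecar["classes"])
        clf.norm_mean_ = np.array(sidecar["norm_mean"])
        clf.norm_std_ = np.array(sidecar["norm_std"])
        clf.input_len_ = int(sidecar["input_len"])
        clf.n_features_in_ = int(sidecar["n_channels"])
        with np.load(path.with_suffix(".npz")) as w:
            weights = {k: w[k] for k in w.files}
        clf.net_ = LSTMNet(
            n_features=clf.n_features_in_,
            n_units=clf.n_units,
            n_classes=len(clf.classes_),
            dropout=clf.dropout,
        )
        clf.net_.set_weights(weights)
        clf.history_ = TrainHistory()
        return clf


# ---------------------------------------------------------------------------
# Sample-list harnesses
# ---------------------------------------------------------------------------


def samples_to_arrays(samples: list[Sample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples to ``X`` (n, time, channels) and string labels ``y``."""
    if not samples:
        raise ValueError("empty sample list")
    X = np.stack([s.data.T for s in samples])
    y = np.array([s.stage.value for s in samples])
    return X, y


def build_model(config: ModelConfig) -> LSTMClassifier:
    """Instantiate an untrained classifier from a :class:`ModelConfig`."""
    return LSTMClassifier(
        n_units=config.lstm_units,
        dropout=config.dropout,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        validation_fraction=config.validation_fraction,
        time_pool=config.time_pool,
        normalize=config.normalize,
        random_state=config.seed,
    )


def train(samples: list[Sample], config: ModelConfig) -> LSTMClassifier:
    """Fit a fresh classifier on a sample list."""
    X, y = samples_to_arrays(samples)
    if X.shape[1] != config.input_len or X.shape[2] != config.n_channels:
        raise ValueError(
            f"samples are {X.shape[1]} x {X.shape[2]} but config expects "
            f"{config.input_len} x {config.n_channels}"
        )
    return build_model(config).fit(X, y)


def predict_samples(
    model: LSTMClassifier, samples: list[Sample]
) -> tuple[np.ndarray, list[Stage]]:
    """Per-sample class probabilities and argmax stage labels."""
    if not samples:
        return np.empty((0, 0)), []
    X, _ = samples_to_arrays(samples)
    proba = model.predict_proba(X)
    labels = [Stage(v) for v in model.predict(X)]
    return proba, labels


# -- seizure-aware bookkeeping ----------------------------------------------


def _owning_seizure(sample: Sample, leading: list[SeizureEvent]) -> int:
    """Index of the leading seizure a sample belongs to."""
    t = sample.start_s
    if sample.stage is Stage.PREICTAL:
        for i, ev in enumerate(leading):
            if t < ev.onset_s:
                return i
        return len(leading) - 1
    if sample.stage is Stage.POSTICTAL:
        idx = [i for i, ev in enumerate(leading) if ev.offset_s <= t]
        return idx[-1] if idx else 0
    # interictal: nearest leading onset
    dists = [abs(ev.onset_s - t) for ev in leading]
    return int(np.argmin(dists))


def split_first_k_seizures(
    samples: list[Sample],
    events: list[SeizureEvent],
    k: int = 2,
    train_on: str = "all",
) -> tuple[list[Sample], list[Sample]]:
    """Patient-style chronological split on the first ``k`` leading seizures.

    Training: preictal/postictal samples of the first ``k`` leading seizures
    plus interictal samples before the (k+1)-th leading seizure's onset.
    Test: everything else.  The two sets are disjoint by construction.

    ``train_on`` restricts which stages enter the *training* half:
    ``"all"`` keeps every early-sample stage (the 3-class task needs all
    three); ``"preictal+interictal"`` is the standard binary recipe;
    ``"postictal+interictal"`` is the variant that trains on the early
    seizures' postictal hours instead of their preictal hours (postictal
    EEG resembles preictal EEG and can serve as the alarm class when the
    brain's baseline shifts after the first seizures).
    """
    allowed = {"all", "preictal+interictal", "postictal+interictal"}
    if train_on not in allowed:
        raise ValueError(f"train_on must be one of {sorted(allowed)}")
    leading = [ev for ev in events if ev.leading]
    if len(leading) < k + 1:
        raise ValueError(
            f"need at least {k + 1} leading seizures for a first-{k} split, "
            f"have {len(leading)}"
        )
    boundary = leading[k].onset_s
    if train_on == "all":
        train_stages = set(Stage)
    elif train_on == "preictal+interictal":
        train_stages = {Stage.INTERICTAL, Stage.PREICTAL}
    else:
        train_stages = {Stage.INTERICTAL, Stage.POSTICTAL}
    train_set: list[Sample] = []
    test_set: list[Sample] = []
    for s in samples:
        if s.stage is Stage.INTERICTAL:
            early = s.start_s < boundary
        else:
            early = _owning_seizure(s, leading) < k
        if early:
            if s.stage in train_stages:
                train_set.append(s)
        else:
            test_set.append(s)
    return train_set, test_set


def kfold_cv(
    samples: list[Sample],
    k: int = 10,
    config: ModelConfig | None = None,
):
    """Stratified k-fold cross-validation over pooled samples.

    Returns a list of per-fold :class:`~preictal.evaluation.SegmentEvalResult`
    (each 5-s sample scored as its own segment).  Fold assignment is seeded
    by ``config.seed``; normalization is refitted inside every fold, so no
    test statistics leak into training.
    """
    from .evaluation import segment_metrics

    config = config or ModelConfig.reduced()
    X, y = samples_to_arrays(samples)
    if len(samples) < k:
        raise ValueError(f"cannot make {k} folds from {len(samples)} samples")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError("every class needs at least k samples for stratified folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    results = []
    for tr_idx, te_idx in skf.split(X, y):
        clf = build_model(config).fit(X[tr_idx], y[tr_idx])
        pred = clf.predict(X[te_idx])
        results.append(
            segment_metrics(
                [Stage(v) for v in y[te_idx]], [Stage(v) for v in pred]
            )
        )
    return results


@dataclass
class LOORound:
    """One leave-one-seizure-out round."""

    held_out: SeizureEvent
    test_samples: list[Sample] = field(default_factory=list)
    proba: np.ndarray | None = None
    labels: list[Stage] = field(default_factory=list)


def loocv_by_seizure(
    samples: list[Sample],
    events: list[SeizureEvent],
    config: ModelConfig | None = None,
) -> list[LOORound]:
    """Leave-one-seizure-out rounds for event-level evaluation.

    Every sample is attributed to its nearest leading seizure.  For each
    round the held-out seizure's samples (its preictal hour, its share of
    interictal, and its postictal hour when present) form the test set; the
    classifier trains on the remaining seizures' samples with the interictal
    class balanced down inside the training split.
    """
    config = config or ModelConfig.reduced()
    leading = [ev for ev in events if ev.leading]
    if len(leading) < 2:
        raise ValueError("leave-one-seizure-out needs at least 2 leading seizures")
    owners = np.array([_owning_seizure(s, leading) for s in samples])
    rounds: list[LOORound] = []
    for i, held in enumerate(leading):
        test = [s for s, o in zip(samples, owners) if o == i]
        train_pool = [s for s, o in zip(samples, owners) if o != i]
        train_bal = balance_classes(train_pool, seed=config.seed + i)
        stages_present = {s.stage for s in train_bal}
        if len(stages_present) < 2:
            warnings.warn(
                f"round {i}: training pool has a single class; skipping",
                stacklevel=2,
            )
            rounds.append(LOORound(held_out=held, test_samples=test))
            continue
        cfg = ModelConfig(
            **{
                **asdict(config),
                "seed": config.seed + i,
                "input_len": train_bal[0].data.shape[1],
                "n_channels": train_bal[0].data.shape[0],
            }
        )
        clf = train(train_bal, cfg)
        proba, labels = predict_samples(clf, test)
        rounds.append(LOORound(held, test, proba, labels))
    return rounds
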