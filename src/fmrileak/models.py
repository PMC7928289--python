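"""The four decoders: PLR, linear SVM, orthogonal-plane 2D CNN, 3D CNN.

The linear families (L2-penalized logistic regression and linear SVM) run
on averaged trial volumes after univariate ANOVA voxel selection, with the
regularization strength tuned by nested cross-validation on the training
set only — selection and tuning never see validation or test trials.

The multichannel 2D CNN (M2DCNN) feeds the averaged volume through three
parallel 2D convolutional branches, one per orthogonal plane (slices along
each axis become input channels), concatenates the branch features and
classifies through a dropout-regularized dense layer. The 3D CNN consumes
the un-averaged boxcar volumes as input channels of stacked 3D
convolutions, capturing local spatiotemporal structure. Both train with
softmax cross-entropy, Adam (lr 0.001, betas 0.9/0.999) and an
exponentially decaying learning rate for up to 300 epochs, reporting the
parameters from the epoch with the best validation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import LinearSVC

from . import nn
from .preprocess import TrialDataset

FAMILIES = ("plr", "svm", "m2dcnn", "cnn3d")
LINEAR_FAMILIES = ("plr", "svm")
NETWORK_FAMILIES = ("m2dcnn", "cnn3d")


class ModelError(ValueError):
    pass


class TrainingError(RuntimeError):
    """Raised when network optimization diverges; carries the epoch index."""

    def __init__(self, message: str, epoch: int):
        super().__init__(message)
        self.epoch = epoch


@dataclass
class ModelConfig:
    """Hyperparameters for any decoder family.

    ``reg_grid`` spans 1e-3..1e3 in 7 log steps for the nested-CV search
    of the linear families. Network optimizer settings follow the study
    configuration (Adam, lr 0.001, betas (0.9, 0.999), 300 epochs,
    exponential decay); layer widths are configurable since they are not
    pinned down by the architecture description.
    """

    family: str = "plr"
    n_selected_voxels: int = 500
    inner_folds: int = 3
    reg_grid: Tuple[float, ...] = tuple(float(c) for c in np.logspace(-3, 3, 7))
    learning_rate: float = 0.001
    adam_betas: Tuple[float, float] = (0.9, 0.999)
    epochs: int = 300
    lr_decay_gamma: float = 0.99
    dropout_fc: float = 0.5
    batch_size: int = 32
    n_filters: int = 32
    kernel_2d: int = 3
    kernel_3d: int = 3
    pool_size: int = 2
    n_conv3d_layers: int = 2
    stop_at_train_accuracy: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelError(f"unknown family {self.family!r}")
        if not self.reg_grid:
            raise ModelError("regularization grid must be nonempty")
        if not (0.0 <= self.dropout_fc < 1.0):
            raise ModelError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ModelError("epochs must be >= 1")
        if not (0.0 < self.lr_decay_gamma <= 1.0):
            raise ModelError("lr_decay_gamma must be in (0, 1]")


@dataclass
class TrainedModel:
    family: str
    estimator: object = None  # fitted sklearn estimator or network object
    selected_voxels: Optional[np.ndarray] = None
    best_param: Optional[float] = None
    history: Dict[str, List[float]] = field(default_factory=dict)

    def predict(self, features: np.ndarray) -> np.ndarray:
        if self.family in LINEAR_FAMILIES:
            flat = features.reshape(features.shape[0], -1)
            if self.selected_voxels is None:
                raise ModelError("linear model missing voxel selection")
            if flat.shape[1] <= self.selected_voxels.max():
                raise ModelError(
                    f"feature dimension {flat.shape[1]} incompatible with "
                    f"selected voxel indices"
                )
            return self.estimator.predict(flat[:, self.selected_voxels])
        scores = _network_scores(self.estimator, features)
        return np.argmax(scores, axis=1)


def anova_select(
    train_features: np.ndarray, train_labels: np.ndarray, k: int = 500
) -> np.ndarray:
    """Indices of the k voxels with the largest between-class F statistic.

    Computed on training data only. Zero-variance voxels get F = 0; ties
    break toward the lower voxel index.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2:
        X = X.reshape(X.shape[0], -1)
    y = np.asarray(train_labels)
    if k > X.shape[1]:
        raise ModelError(f"k={k} exceeds {X.shape[1]} voxels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ModelError("need >=2 trials per class for ANOVA selection")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features warn inside f_classif
        f, _ = f_classif(X, y)
    f = np.nan_to_num(f, nan=0.0, posinf=np.inf)
    order = np.argsort(-f, kind="stable")  # stable => ascending index among ties
    return np.sort(order[:k])


def fit_linear_decoder(
    config: ModelConfig, train: TrialDataset, valid: TrialDataset | None = None
) -> TrainedModel:
    """Fit PLR or linear SVM with ANOVA selection + nested-CV tuning.

    The validation subset is unused for these families: their tuning is
    internal (inner k-fold over the regularization grid on Train), after
    which the model is refit on the full training set at the best value.
    """
    if config.family not in LINEAR_FAMILIES:
        raise ModelError(f"{config.family} is not a linear family")
    if train.form != "averaged":
        raise ModelError("linear decoders expect averaged-form features")
    X = train.flat_features()
    y = train.labels
    if len(np.unique(y)) < 2:
        raise ModelError("training set contains a single class")
    k = min(config.n_selected_voxels, X.shape[1])
    sel = anova_select(X, y, k=k)
    Xs = X[:, sel]
    if config.family == "plr":
        # L2 penalty is the sklearn default; stated explicitly it trips a
        # deprecation warning in recent releases
        base = LogisticRegression(solver="lbfgs", max_iter=5000)
    else:
        base = LinearSVC(max_iter=20000)
    inner = KFold(n_splits=config.inner_folds, shuffle=False)
    search = GridSearchCV(
        base, {"C": list(config.reg_grid)}, cv=inner, scoring="accuracy", refit=True
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        search.fit(Xs, y)
    return TrainedModel(
        family=config.family,
        estimator=search.best_estimator_,
        selected_voxels=sel,
        best_param=float(search.best_params_["C"]),
    )


# ---------------------------------------------------------------------------
# networks


class M2DCNN:
    """Three orthogonal-plane 2D convolutional branches over one volume.

    Input is an averaged trial volume (x, y, z). Branch 0 treats z-slices
    as channels and convolves over (x, y); branch 1 treats y-slices as
    channels over (x, z); branch 2 treats x-slices as channels over
    (y, z). Each branch is conv -> mish -> max-pool -> flatten; the
    concatenated features pass through dropout and a dense 2-way output.
    """

    # channel axis moved to position 1; remaining two axes are the plane
    _TRANSPOSES = ((0, 3, 1, 2), (0, 2, 1, 3), (0, 1, 2, 3))

    def __init__(
        self,
        spatial_shape: Tuple[int, int, int],
        n_filters: int = 32,
        kernel: int = 3,
        pool: int = 2,
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        if rng is None:
            rng = np.random.default_rng(0)
        if len(spatial_shape) != 3:
            raise ModelError(f"expected 3D spatial shape, got {spatial_shape}")
        if min(spatial_shape) < kernel:
            raise ModelError(
                f"spatial shape {spatial_shape} smaller than kernel {kernel}"
            )
        self.spatial_shape = tuple(spatial_shape)
        self.branches = []
        feat_total = 0
        for tp in self._TRANSPOSES:
            c_in = spatial_shape[tp[1] - 1]
            plane = tuple(spatial_shape[a - 1] for a in tp[2:])
            conv = nn.Conv2d(c_in, n_filters, kernel, rng)
            out_plane = tuple((d - kernel + 1) // pool for d in plane)
            if min(out_plane) < 1:
                raise ModelError(f"plane {plane} too small for kernel+pool")
            feat_total += n_filters * out_plane[0] * out_plane[1]
            self.branches.append(
                nn.Sequential([conv, nn.Mish(), nn.MaxPool(pool, ndim=2), nn.Flatten()])
            )
        self.dropout = nn.Dropout(dropout, rng)
        self.head = nn.Dense(feat_total, 2, rng)
        self._split_sizes: List[int] = []

    @property
    def input_form(self) -> str:
        return "averaged"

    def parameters(self) -> List[nn.Param]:
        ps = [p for b in self.branches for p in b.params()]
        return ps + self.head.params()

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1:] != self.spatial_shape:
            raise ModelError(
                f"expected (n, {self.spatial_shape}) input, got {x.shape}"
            )
        outs = []
        self._split_sizes = []
        for tp, branch in zip(self._TRANSPOSES, self.branches):
            h = branch.forward(np.transpose(x, tp), train=train)
            outs.append(h)
            self._split_sizes.append(h.shape[1])
        feats = np.concatenate(outs, axis=1)
        return self.head.forward(self.dropout.forward(feats, train=train), train=train)

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        dfeats = self.dropout.backward(self.head.backward(dscores))
        dx = None
        start = 0
        for tp, branch, size in zip(self._TRANSPOSES, self.branches, self._split_sizes):
            dpart = branch.backward(dfeats[:, start : start + size])
            start += size
            inv = np.argsort(tp)
            dvol = np.transpose(dpart, inv)
            dx = dvol if dx is None else dx + dvol
        return dx


class CNN3D:
    """Stacked 3D convolutions over the boxcar time series.

    The T response-window volumes enter as input channels; two (by
    default) conv -> mish -> max-pool stages are followed by dropout and
    a dense 2-way output.
    """

    def __init__(
        self,
        spatial_shape: Tuple[int, int, int],
        t_boxcars: int,
        n_filters: int = 32,
        kernel: int = 3,
        pool: int = 2,
        n_conv_layers: int = 2,
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        if rng is None:
            rng = np.random.default_rng(0)
        if t_boxcars < 1:
            raise ModelError("need at least one boxcar channel")
        self.spatial_shape = tuple(spatial_shape)
        self.t_boxcars = t_boxcars
        layers = []
        c_in = t_boxcars
        shape = np.array(spatial_shape)
        for _ in range(n_conv_layers):
            if (shape < kernel).any():
                raise ModelError(
                    f"spatial extent {tuple(shape)} smaller than kernel {kernel}"
                )
            layers += [nn.Conv3d(c_in, n_filters, kernel, rng), nn.Mish(),
                       nn.MaxPool(pool, ndim=3)]
            shape = (shape - kernel + 1) // pool
            if (shape < 1).any():
                raise ModelError("volume exhausted by conv/pool stack")
            c_in = n_filters
        layers.append(nn.Flatten())
        self.body = nn.Sequential(layers)
        feat = int(n_filters * np.prod(shape))
        self.dropout = nn.Dropout(dropout, rng)
        self.head = nn.Dense(feat, 2, rng)

    @property
    def input_form(self) -> str:
        return "boxcar"

    def parameters(self) -> List[nn.Param]:
        return self.body.params() + self.head.params()

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != self.t_boxcars or x.shape[2:] != self.spatial_shape:
            raise ModelError(
                f"expected (n, {self.t_boxcars}, {self.spatial_shape}) input, "
                f"got {x.shape}"
            )
        feats = self.body.forward(x, train=train)
        return self.head.forward(self.dropout.forward(feats, train=train), train=train)

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        dfeats = self.dropout.backward(self.head.backward(dscores))
        return self.body.backward(dfeats)


def build_m2dcnn(
    spatial_shape: Tuple[int, int, int], config: ModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> M2DCNN:
    config = config or ModelConfig(family="m2dcnn")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return M2DCNN(
        spatial_shape,
        n_filters=config.n_filters,
        kernel=config.kernel_2d,
        pool=config.pool_size,
        dropout=config.dropout_fc,
        rng=rng,
    )


def build_3dcnn(
    spatial_shape: Tuple[int, int, int], t_boxcars: int,
    config: ModelConfig | None = None, rng: np.random.Generator | None = None,
) -> CNN3D:
    config = config or ModelConfig(family="cnn3d")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return CNN3D(
        spatial_shape,
        t_boxcars,
        n_filters=config.n_filters,
        kernel=config.kernel_3d,
        pool=config.pool_size,
        n_conv_layers=config.n_conv3d_layers,
        dropout=config.dropout_fc,
        rng=rng,
    )


def m2dcnn_param_count(
    spatial_shape: Tuple[int, int, int], n_filters: int = 32, kernel: int = 3,
    pool: int = 2,
) -> int:
    """Closed-form parameter count of the orthogonal-plane network."""
    total = 0
    feat = 0
    shapes = [
        (spatial_shape[2], (spatial_shape[0], spatial_shape[1])),
        (spatial_shape[1], (spatial_shape[0], spatial_shape[2])),
        (spatial_shape[0], (spatial_shape[1], spatial_shape[2])),
    ]
    for c_in, plane in shapes:
        total += n_filters * (c_in * kernel * kernel) + n_filters
        out = [(d - kernel + 1) // pool for d in plane]
        feat += n_filters * out[0] * out[1]
    total += feat * 2 + 2  # dense head
    return total


def _network_scores(net, features: np.ndarray, batch: int = 64) -> np.ndarray:
    parts = [
        net.forward(features[i : i + batch], train=False)
        for i in range(0, features.shape[0], batch)
    ]
    return np.concatenate(parts)


def learning_rate_at(config: ModelConfig, epoch: int) -> float:
    """Exponential schedule: lr0 * gamma**epoch (epoch 0-based)."""
    return config.learning_rate * config.lr_decay_gamma**epoch


def train_network(
    net,
    config: ModelConfig,
    train: TrialDataset,
    valid: TrialDataset | None,
    seed: int | None = None,
) -> TrainedModel:
    """Train a network with Adam + exponential lr decay, tracking Valid.

    Records per-epoch training loss/accuracy and validation accuracy, and
    restores the parameters from the epoch with the best validation
    accuracy (falling back to training accuracy when no validation set is
    given). ``config.stop_at_train_accuracy`` optionally halts early once
    training accuracy reaches a target — useful for capacity checks.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    X = np.asarray(train.features, dtype=float)
    y = train.labels
    Xv = yv = None
    if valid is not None and valid.n_trials > 0:
        Xv = np.asarray(valid.features, dtype=float)
        yv = valid.labels
    params = net.parameters()
    opt = nn.Adam(params, lr=config.learning_rate, betas=config.adam_betas)
    history: Dict[str, List[float]] = {"loss": [], "train_acc": [], "valid_acc": [], "lr": []}
    best_metric, best_state, n = -np.inf, None, X.shape[0]
    for epoch in range(config.epochs):
        opt.lr = learning_rate_at(config, epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            scores = net.forward(X[idx], train=True)
            loss, dscores = nn.cross_entropy_loss(scores, y[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}", epoch)
            opt.zero_grad()
            net.backward(dscores)
            opt.step()
            losses.append(loss)
        train_pred = np.argmax(_network_scores(net, X), axis=1)
        train_acc = float(np.mean(train_pred == y))
        if Xv is not None:
            valid_pred = np.argmax(_network_scores(net, Xv), axis=1)
            metric = float(np.mean(valid_pred == yv))
        else:
            metric = train_acc
        history["loss"].append(float(np.mean(losses)))
        history["train_acc"].append(train_acc)
        history["valid_acc"].append(metric if Xv is not None else float("nan"))
        history["lr"].append(opt.lr)
        if metric > best_metric:
            best_metric = metric
            best_state = nn.get_state(params)
        if (
            config.stop_at_train_accuracy is not None
            and train_acc >= config.stop_at_train_accuracy
        ):
            break
    if best_state is not None:
        nn.set_state(params, best_state)
    return TrainedModel(family=config.family, estimator=net, history=history)


def fit_decoder(
    config: ModelConfig, train: TrialDataset, valid: TrialDataset | None, seed: int | None = None
) -> TrainedModel:
    """Family dispatch: fit any of the four decoders on one fold."""
    if config.family in LINEAR_FAMILIES:
        return fit_linear_decoder(config, train, valid)
    if config.family == "m2dcnn":
        if train.form != "averaged":
            raise ModelError("m2dcnn expects averaged-form features")
        rng = np.random.default_rng(seed if seed is not None else config.seed)
        net = build_m2dcnn(train.spatial_shape, config, rng=rng)
        return train_network(net, config, train, valid, seed=seed)
    if config.family == "cnn3d":
        if train.form != "boxcar":
            raise ModelError("cnn3d expects boxcar-form features")
        rng = np.random.default_rng(seed if seed is not None else config.seed)
        net = build_3dcnn(train.spatial_shape, train.n_boxcars, config, rng=rng)
        return train_network(net, config, train, valid, seed=seed)
    raise ModelError(f"unknown family {config.family!r}")


def predict_labels(model: TrainedModel, dataset: TrialDataset) -> Tuple[np.ndarray, float]:
    """Predicted labels and accuracy on a dataset."""
    pred = model.predict(dataset.features)
    acc = float(np.mean(pred == dataset.labels))
    return pred, acc
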