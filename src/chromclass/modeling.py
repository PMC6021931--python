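"""Ripening-stage classification with an MLP under replicate-grouped double CV.

The classifier is a 1-2 hidden-layer perceptron with sigmoid hidden units
(hyperbolic tangent or logistic), four linear outputs, one-hot class targets,
and a least-squares objective, trained full-batch with resilient
backpropagation (iRprop-: sign-based per-weight step sizes, eta+ = 1.2,
eta- = 0.5, steps bounded to [1e-6, 50]).

Model selection and assessment use repeated three-way random subsampling
(double cross-validation): 70% of the oils train the network, 10% drive
early stopping and architecture choice (internal validation), and an
untouched 20% measures performance (external validation).  Splits are
stratified per class and grouped per oil — all replicates of an oil always
land in the same subset, so replicate identity can never leak between
subsets.  The figure of merit is the correct classification rate
CCR = Nright / N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import expit

SUBSETS = ("train", "internal_validation", "external_validation")
ACTIVATIONS = ("tanh_sigmoid", "logistic_sigmoid")


# ---------------------------------------------------------------------------
# splits


@dataclass
class SplitPlan:
    """Per-oil assignment to train / internal / external subsets."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20)
    partition_index: int = 0

    def samples(self, subset: str) -> list[str]:
        if subset not in SUBSETS:
            raise KeyError(subset)
        return [s for s, a in self.assignment.items() if a == subset]

    def row_mask(self, manifest: pd.DataFrame, *subsets: str) -> np.ndarray:
        wanted = set(subsets)
        bad = wanted - set(SUBSETS)
        if bad:
            raise KeyError(sorted(bad))
        return (
            manifest["sample_id"].map(self.assignment).isin(wanted).to_numpy()
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def grouped_stratified_split(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    rng: np.random.Generator | None = None,
) -> SplitPlan:
    """Random three-way split, stratified per class and grouped per oil.

    Per class, the training count is round-to-nearest of f_train * n and the
    internal-validation count round-to-nearest of f_val * n (reduced if the
    rounding would overdraw the class); the external set takes the remainder.
    A 27-oil class at the default fractions sends 19 oils to training.  All
    replicate rows of an oil follow the oil.
    """
    if rng is None:
        rng = np.random.default_rng()
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three values summing to 1")
    assignment: dict[str, str] = {}
    samples = manifest.drop_duplicates("sample_id")
    for cls, grp in samples.groupby("class_label", sort=True):
        ids = grp["sample_id"].to_numpy()
        n = len(ids)
        if n < len(SUBSETS):
            raise ValueError(
                f"class {cls} has only {n} oils; need at least {len(SUBSETS)}"
            )
        n_tr = _round_half_up(fractions[0] * n)
        n_iv = _round_half_up(fractions[1] * n)
        n_iv = min(n_iv, n - n_tr)
        if n_tr + n_iv > n:
            n_tr = n - n_iv
        counts = [n_tr, n_iv, n - n_tr - n_iv]
        # every subset must see at least one oil of each class
        while min(counts) < 1:
            counts[int(np.argmax(counts))] -= 1
            counts[int(np.argmin(counts))] += 1
        ids = ids[rng.permutation(n)]
        bounds = np.cumsum([0] + counts)
        for subset, a, b in zip(SUBSETS, bounds[:-1], bounds[1:]):
            for s in ids[a:b]:
                assignment[s] = subset
    return SplitPlan(assignment=assignment, fractions=fractions)


# ---------------------------------------------------------------------------
# scaling


@dataclass
class Scaler:
    """Per-column z-score fitted on training rows only."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.sd


def standardize(
    X: np.ndarray | pd.DataFrame, train_mask: np.ndarray
) -> tuple[np.ndarray, Scaler]:
    """Standardize all rows with mean/sd estimated from training rows."""
    Xa = np.asarray(X, dtype=float)
    train = Xa[np.asarray(train_mask, bool)]
    if train.shape[0] == 0:
        raise ValueError("empty training subset")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance column(s); using unit divisor",
            stacklevel=2,
        )
        sd = np.where(zero, 1.0, sd)
    scaler = Scaler(mean=mean, sd=sd)
    return scaler.transform(Xa), scaler


# ---------------------------------------------------------------------------
# the network


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and training settings of the perceptron."""

    n_inputs: int
    hidden_layers: tuple[int, ...] = (8,)
    hidden_activation: str = "tanh_sigmoid"
    algorithm: str = "rprop"
    max_epochs: int = 300
    patience: int = 30
    seed: int = 0
    n_outputs: int = 4

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if not 1 <= len(self.hidden_layers) <= 2 or any(
            h < 1 for h in self.hidden_layers
        ):
            raise ValueError("hidden_layers must be 1 or 2 positive widths")
        if self.hidden_activation not in ACTIVATIONS:
            raise ValueError(f"hidden_activation must be one of {ACTIVATIONS}")
        if self.algorithm != "rprop":
            raise ValueError("only resilient backpropagation ('rprop') is available")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden_layers, self.n_outputs)

    @property
    def n_weights(self) -> int:
        sizes = self.layer_sizes
        return int(sum((a + 1) * b for a, b in zip(sizes[:-1], sizes[1:])))


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh_sigmoid":
        return np.tanh(x)
    return expit(x)


def _act_deriv(a: np.ndarray, kind: str) -> np.ndarray:
    # derivative expressed through the activation value
    if kind == "tanh_sigmoid":
        return 1.0 - a * a
    return a * (1.0 - a)


@dataclass
class TrainedModel:
    """Weights of a trained perceptron plus its prediction rule."""

    config: MLPConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    classes: np.ndarray
    n_epochs: int = 0
    best_epoch: int = 0

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Linear-output activations, shape (n, 4)."""
        a = np.asarray(X, dtype=float)
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = z if i == last else _act(z, self.config.hidden_activation)
        return a

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class labels: argmax over the four linear outputs."""
        return self.classes[np.argmax(self.forward(X), axis=1)]


class _Rprop:
    """iRprop- per-parameter step-size adaptation."""

    ETA_PLUS = 1.2
    ETA_MINUS = 0.5
    STEP_MIN = 1e-6
    STEP_MAX = 50.0
    STEP_INIT = 0.07

    def __init__(self, params: list[np.ndarray]):
        self.steps = [np.full_like(p, self.STEP_INIT) for p in params]
        self.prev = [np.zeros_like(p) for p in params]

    def update(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g, step, prev in zip(params, grads, self.steps, self.prev):
            sign_change = g * prev
            np.multiply(
                step,
                np.where(
                    sign_change > 0,
                    self.ETA_PLUS,
                    np.where(sign_change < 0, self.ETA_MINUS, 1.0),
                ),
                out=step,
            )
            np.clip(step, self.STEP_MIN, self.STEP_MAX, out=step)
            g = np.where(sign_change < 0, 0.0, g)
            p -= np.sign(g) * step
            prev[...] = g


def one_hot(labels: np.ndarray, classes: np.ndarray | None = None) -> np.ndarray:
    """One-hot target coding (1 marks class membership)."""
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    Y = (labels[:, None] == np.asarray(classes)[None, :]).astype(float)
    if not np.all(Y.sum(axis=1) == 1):
        raise ValueError("labels contain values outside the class set")
    return Y


def train_mlp(
    X: np.ndarray,
    Y: np.ndarray,
    config: MLPConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    classes: np.ndarray | None = None,
) -> TrainedModel:
    """Train the perceptron by full-batch resilient backpropagation.

    ``Y`` is the one-hot target matrix.  When a validation set is supplied,
    training early-stops once the internal-validation CCR has not improved
    for ``config.patience`` epochs, and the best-CCR weights are restored.
    Equal CCRs are tie-broken by the validation squared error, so the chosen
    epoch keeps improving decision margins after the (discrete) CCR
    saturates.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] < Y.shape[1]:
        raise ValueError("need at least as many training rows as classes")
    if X.shape[1] != config.n_inputs:
        raise ValueError(f"X has {X.shape[1]} columns; config expects {config.n_inputs}")
    if classes is None:
        classes = np.arange(1, config.n_outputs + 1)
    classes = np.asarray(classes)

    rng = np.random.default_rng(config.seed)
    sizes = config.layer_sizes
    weights = []
    biases = []
    for a, b in zip(sizes[:-1], sizes[1:]):
        r = np.sqrt(6.0 / (a + b))
        weights.append(rng.uniform(-r, r, size=(a, b)))
        biases.append(np.zeros(b))
    params = weights + biases
    opt = _Rprop(params)
    kind = config.hidden_activation
    last = len(weights) - 1

    best_key = (-np.inf, -np.inf)  # (val CCR, -val SSE)
    best_state: tuple[list[np.ndarray], list[np.ndarray]] | None = None
    best_epoch = 0
    epochs_run = 0
    y_val_onehot = None
    if X_val is not None and y_val is not None:
        y_val_onehot = (np.asarray(y_val)[:, None] == classes[None, :]).astype(float)

    for epoch in range(1, config.max_epochs + 1):
        epochs_run = epoch
        # forward
        acts = [X]
        for i, (W, b) in enumerate(zip(weights, biases)):
            z = acts[-1] @ W + b
            acts.append(z if i == last else _act(z, kind))
        out = acts[-1]
        loss = float(np.sum((out - Y) ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch} "
                f"(architecture {sizes}, activation {kind})"
            )
        # backward
        delta = 2.0 * (out - Y)
        grads_W: list[np.ndarray] = [None] * len(weights)  # type: ignore[list-item]
        grads_b: list[np.ndarray] = [None] * len(biases)  # type: ignore[list-item]
        for i in range(last, -1, -1):
            grads_W[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ weights[i].T) * _act_deriv(acts[i], kind)
        opt.update(params, grads_W + grads_b)

        if X_val is not None and y_val is not None:
            model = TrainedModel(config, weights, biases, classes)
            val_out = model.forward(X_val)
            val_ccr = ccr(classes[np.argmax(val_out, axis=1)], y_val)
            key = (val_ccr, -float(np.sum((val_out - y_val_onehot) ** 2)))
            if key > best_key:
                best_key = key
                best_epoch = epoch
                best_state = (
                    [W.copy() for W in weights],
                    [b.copy() for b in biases],
                )
            elif epoch - best_epoch >= config.patience:
                break

    if best_state is not None:
        weights, biases = best_state
    else:
        best_epoch = epochs_run
    return TrainedModel(
        config=config,
        weights=weights,
        biases=biases,
        classes=classes,
        n_epochs=epochs_run,
        best_epoch=best_epoch,
    )


# ---------------------------------------------------------------------------
# scoring


def ccr(predicted: np.ndarray, true: np.ndarray) -> float:
    """Correct classification rate, Nright / N."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true must have equal length")
    if predicted.size == 0:
        raise ValueError("cannot score an empty prediction set")
    return float(np.mean(predicted == true))


def confusion_counts(
    true: np.ndarray, predicted: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """Raw confusion counts, rows = true class, columns = predicted."""
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((k, k))
    for t, p in zip(np.asarray(true), np.asarray(predicted)):
        mat[idx[t], idx[p]] += 1
    return mat


def averaged_confusion(matrices: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of row-normalized confusion matrices, in percent.

    Rows with no samples in a given partition are excluded from that row's
    average rather than contributing zeros.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one confusion matrix")
    normed = []
    for m in matrices:
        m = np.asarray(m, dtype=float)
        sums = m.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            normed.append(np.where(sums > 0, 100.0 * m / sums, np.nan))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(np.stack(normed), axis=0)
    return np.nan_to_num(out)


# ---------------------------------------------------------------------------
# double cross-validation


@dataclass
class CVResult:
    """Per-partition scores of one architecture under double CV."""

    config: MLPConfig
    internal_ccr: np.ndarray
    external_ccr: np.ndarray
    external_ccr_by_oil: np.ndarray  # replicate majority vote per oil
    confusions: np.ndarray  # (R, 4, 4) external counts
    models: list[TrainedModel] = field(default_factory=list, repr=False)
    scalers: list[Scaler] = field(default_factory=list, repr=False)
    plans: list[SplitPlan] = field(default_factory=list, repr=False)
    search_scores: pd.DataFrame | None = None

    @property
    def confusion_percent(self) -> np.ndarray:
        return averaged_confusion(list(self.confusions))

    def summary(self) -> dict:
        return {
            "architecture": "-".join(map(str, self.config.layer_sizes)),
            "hidden_activation": self.config.hidden_activation,
            "internal_ccr_mean": float(self.internal_ccr.mean()),
            "internal_ccr_sd": float(self.internal_ccr.std(ddof=1))
            if len(self.internal_ccr) > 1
            else 0.0,
            "external_ccr_mean": float(self.external_ccr.mean()),
            "external_ccr_sd": float(self.external_ccr.std(ddof=1))
            if len(self.external_ccr) > 1
            else 0.0,
            "external_ccr_by_oil_mean": float(self.external_ccr_by_oil.mean()),
            "n_partitions": int(len(self.external_ccr)),
        }


def _assert_no_leakage(plan: SplitPlan, manifest: pd.DataFrame) -> None:
    subsets = manifest["sample_id"].map(plan.assignment)
    spans = manifest.assign(_s=subsets).groupby("sample_id")["_s"].nunique()
    if (spans > 1).any():
        bad = spans[spans > 1].index.tolist()
        raise AssertionError(f"replicates of {bad} span multiple subsets")


def _majority_vote_ccr(manifest: pd.DataFrame, mask: np.ndarray, pred: np.ndarray) -> float:
    sub = manifest.loc[mask, ["sample_id", "class_label"]].copy()
    sub["pred"] = pred
    right = 0
    groups = sub.groupby("sample_id")
    for _, g in groups:
        votes = g["pred"].value_counts()
        top = votes[votes == votes.max()].index.min()  # tie -> smallest label
        right += int(top == g["class_label"].iloc[0])
    return right / groups.ngroups


def make_partition_plans(
    manifest: pd.DataFrame,
    n_partitions: int,
    rng: np.random.Generator,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
) -> list[SplitPlan]:
    """R independent grouped stratified splits with derived seeds."""
    plans = []
    for r in range(n_partitions):
        prng = np.random.default_rng(int(rng.integers(2**31)))
        plan = grouped_stratified_split(manifest, fractions, prng)
        plan.partition_index = r + 1
        _assert_no_leakage(plan, manifest)
        plans.append(plan)
    return plans


def run_cv(
    X: np.ndarray | pd.DataFrame,
    manifest: pd.DataFrame,
    config: MLPConfig,
    n_partitions: int = 50,
    rng: np.random.Generator | None = None,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    plans: list[SplitPlan] | None = None,
) -> CVResult:
    """Double cross-validation of one architecture.

    Per partition: fit the scaler and network on the training oils with early
    stopping on the internal-validation CCR, record that CCR, then retrain on
    the fused train + internal data for the early-stopped epoch count and
    score the untouched external oils.
    """
    if rng is None:
        rng = np.random.default_rng()
    Xa = np.asarray(X, dtype=float)
    labels = manifest["class_label"].to_numpy()
    classes = np.unique(labels)
    if plans is None:
        plans = make_partition_plans(manifest, n_partitions, rng, fractions)
    cfg = replace(config, n_inputs=Xa.shape[1], n_outputs=len(classes))

    internal = np.empty(len(plans))
    external = np.empty(len(plans))
    by_oil = np.empty(len(plans))
    confusions = np.empty((len(plans), len(classes), len(classes)))
    models: list[TrainedModel] = []
    scalers: list[Scaler] = []
    for r, plan in enumerate(plans):
        _assert_no_leakage(plan, manifest)
        m_tr = plan.row_mask(manifest, "train")
        m_iv = plan.row_mask(manifest, "internal_validation")
        m_ex = plan.row_mask(manifest, "external_validation")
        Xs, scaler = standardize(Xa, m_tr)
        cfg_r = replace(cfg, seed=int(np.random.SeedSequence([cfg.seed, r]).generate_state(1)[0] % 2**31))
        model = train_mlp(
            Xs[m_tr],
            one_hot(labels[m_tr], classes),
            cfg_r,
            X_val=Xs[m_iv],
            y_val=labels[m_iv],
            classes=classes,
        )
        internal[r] = ccr(model.predict(Xs[m_iv]), labels[m_iv])
        # retrain fusing train + internal validation, for the chosen epoch count
        m_fused = m_tr | m_iv
        Xs2, scaler2 = standardize(Xa, m_fused)
        cfg_fused = replace(cfg_r, max_epochs=max(model.best_epoch, 1), patience=cfg.max_epochs)
        fused = train_mlp(
            Xs2[m_fused], one_hot(labels[m_fused], classes), cfg_fused, classes=classes
        )
        pred = fused.predict(Xs2[m_ex])
        external[r] = ccr(pred, labels[m_ex])
        by_oil[r] = _majority_vote_ccr(manifest, m_ex, pred)
        confusions[r] = confusion_counts(labels[m_ex], pred, classes)
        models.append(fused)
        scalers.append(scaler2)
    return CVResult(
        config=cfg,
        internal_ccr=internal,
        external_ccr=external,
        external_ccr_by_oil=by_oil,
        confusions=confusions,
        models=models,
        scalers=scalers,
        plans=list(plans),
    )


def default_search_space(
    widths: tuple[int, ...] = (2, 4, 8, 13, 16),
    depths: tuple[int, ...] = (1, 2),
    activations: tuple[str, ...] = ACTIVATIONS,
) -> list[MLPConfig]:
    """Candidate architectures: 1-2 hidden layers over a small width grid."""
    space = []
    for depth in depths:
        for layers in product(widths, repeat=depth):
            for act in activations:
                space.append(
                    MLPConfig(n_inputs=1, hidden_layers=layers, hidden_activation=act)
                )
    return space


def select_architecture(
    X: np.ndarray | pd.DataFrame,
    manifest: pd.DataFrame,
    search_space: list[MLPConfig] | None = None,
    n_partitions: int = 50,
    rng: np.random.Generator | None = None,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    base_config: MLPConfig | None = None,
) -> tuple[MLPConfig, CVResult]:
    """Choose an architecture on internal-validation CCR, then assess it.

    Every candidate is scored on the same partitions; the winner has the
    highest mean internal CCR, with candidates within one standard deviation
    of the best resolved in favour of the fewest weights (parsimony).  The
    winner is then retrained per partition on train + internal data and
    scored on the external sets.
    """
    if rng is None:
        rng = np.random.default_rng()
    if search_space is None:
        search_space = default_search_space()
    if not search_space:
        raise ValueError("empty search space")
    Xa = np.asarray(X, dtype=float)
    labels = manifest["class_label"].to_numpy()
    classes = np.unique(labels)
    plans = make_partition_plans(manifest, n_partitions, rng, fractions)
    base = base_config or MLPConfig(n_inputs=Xa.shape[1])

    rows = []
    for ci, cand in enumerate(search_space):
        cand = replace(
            cand,
            n_inputs=Xa.shape[1],
            n_outputs=len(classes),
            max_epochs=base.max_epochs,
            patience=base.patience,
        )
        scores = np.empty(len(plans))
        for r, plan in enumerate(plans):
            m_tr = plan.row_mask(manifest, "train")
            m_iv = plan.row_mask(manifest, "internal_validation")
            Xs, _ = standardize(Xa, m_tr)
            seed = int(np.random.SeedSequence([base.seed, ci, r]).generate_state(1)[0] % 2**31)
            model = train_mlp(
                Xs[m_tr],
                one_hot(labels[m_tr], classes),
                replace(cand, seed=seed),
                X_val=Xs[m_iv],
                y_val=labels[m_iv],
                classes=classes,
            )
            scores[r] = ccr(model.predict(Xs[m_iv]), labels[m_iv])
        rows.append(
            {
                "config": cand,
                "hidden_layers": cand.hidden_layers,
                "hidden_activation": cand.hidden_activation,
                "n_weights": cand.n_weights,
                "internal_ccr_mean": scores.mean(),
                "internal_ccr_sd": scores.std(ddof=1) if len(scores) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    best_mean = table["internal_ccr_mean"].max()
    best_sd = float(
        table.loc[table["internal_ccr_mean"].idxmax(), "internal_ccr_sd"]
    )
    tied = table[table["internal_ccr_mean"] >= best_mean - best_sd]
    winner_row = tied.sort_values(
        ["n_weights", "internal_ccr_mean"], ascending=[True, False], kind="stable"
    ).iloc[0]
    winner: MLPConfig = replace(winner_row["config"], seed=base.seed)

    result = run_cv(Xa, manifest, winner, rng=rng, fractions=fractions, plans=plans)
    result.search_scores = table.drop(columns=["config"])
    return winner, result
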