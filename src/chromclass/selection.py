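"""Input ranking by sensitivity analysis and sequential rank-based selection.

The sensitivity of the trained network to each input (Lek profile method) is
the range of each class output while that input sweeps its observed range in
small steps and every other input is locked at its mean.  Per class, inputs
are ranked by descending sensitivity; the feature subset is then grown by the
sequential rank-addition rule: at each step, add every not-yet-included peak
found at the lowest rank (across the four class rankings) that contributes at
least one new peak.  Each candidate subset is scored by the modeling module's
double CV on internal-validation CCR, and the best-scoring step wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .modeling import CVResult, MLPConfig, TrainedModel, run_cv

#: Reference per-class sensitivity rankings (rank 1 first) for the 22-peak
#: bitter-orange ripening profile; rows are the four ripening classes.  Used
#: as the worked example for the sequential addition rule.
REFERENCE_RANKINGS = np.array(
    [
        [11, 1, 3, 15, 18, 19, 20, 10, 4, 5, 9, 17, 21, 14, 12, 13, 22, 6, 8, 2, 16, 7],
        [11, 19, 18, 10, 3, 20, 4, 22, 15, 13, 17, 1, 9, 21, 12, 5, 8, 14, 2, 6, 16, 7],
        [19, 1, 11, 10, 18, 20, 15, 17, 14, 5, 4, 22, 3, 21, 13, 12, 9, 8, 6, 2, 16, 7],
        [1, 19, 11, 18, 10, 20, 15, 22, 21, 17, 5, 3, 14, 4, 13, 9, 6, 12, 16, 2, 8, 7],
    ]
)


@dataclass
class SensitivityTable:
    """Per-input, per-class output ranges of the probed network."""

    S: np.ndarray  # (P, n_classes), >= 0
    grid_steps: int
    reference: np.ndarray  # per-input locking values (column means)
    peak_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if (self.S < 0).any():
            raise ValueError("sensitivities must be non-negative")
        if self.peak_ids is None:
            self.peak_ids = np.arange(1, self.S.shape[0] + 1)


@dataclass
class RankTable:
    """Per-class permutations of peak ids, most sensitive first."""

    ranks: np.ndarray  # (n_classes, P) of peak ids

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        P = self.ranks.shape[1]
        for row in self.ranks:
            if sorted(row) != list(range(1, P + 1)):
                raise ValueError("each class ranking must be a permutation of 1..P")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.ranks,
            index=[f"class_{i}" for i in range(1, self.ranks.shape[0] + 1)],
            columns=[f"rank_{r}" for r in range(1, self.ranks.shape[1] + 1)],
        )


@dataclass
class SelectionStep:
    """One step of the sequential addition search."""

    added: tuple[int, ...]
    cumulative: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.cumulative)


@dataclass
class SelectionTrace:
    """Ordered steps of the search, optionally with per-step CV scores."""

    steps: list[SelectionStep]
    internal_ccr: np.ndarray | None = None  # mean internal CCR per step
    external_ccr: np.ndarray | None = None
    best_step_index: int | None = None  # 0-based
    step_results: list[CVResult] = field(default_factory=list, repr=False)

    @property
    def counts(self) -> list[int]:
        return [s.count for s in self.steps]

    @property
    def best_step(self) -> SelectionStep:
        if self.best_step_index is None:
            raise ValueError("trace has not been evaluated")
        return self.steps[self.best_step_index]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "step": np.arange(1, len(self.steps) + 1),
                "n_peaks": self.counts,
                "peaks_added": [",".join(map(str, s.added)) for s in self.steps],
            }
        )
        if self.internal_ccr is not None:
            df["internal_ccr"] = self.internal_ccr
        if self.external_ccr is not None:
            df["external_ccr"] = self.external_ccr
        return df


def sensitivity_analysis(
    model: TrainedModel, X: np.ndarray | pd.DataFrame, grid_steps: int = 50
) -> SensitivityTable:
    """Lek-style sensitivity of each network output to each input.

    For input j, evaluate the network on ``grid_steps`` equally spaced values
    spanning the observed [min, max] of column j with all other inputs locked
    at their column means; the sensitivity for class c is the max - min of
    output c over that sweep.  Depends only on column statistics, so it is
    invariant to the row order of ``X``.
    """
    if grid_steps < 3:
        raise ValueError("grid_steps must be >= 3")
    Xa = np.asarray(X, dtype=float)
    means = Xa.mean(axis=0)
    P = Xa.shape[1]
    n_out = model.config.n_outputs
    S = np.empty((P, n_out))
    for j in range(P):
        grid = np.linspace(Xa[:, j].min(), Xa[:, j].max(), grid_steps)
        probe = np.tile(means, (grid_steps, 1))
        probe[:, j] = grid
        out = model.forward(probe)
        S[j] = out.max(axis=0) - out.min(axis=0)
    peak_ids = None
    if isinstance(X, pd.DataFrame):
        peak_ids = np.array([int(c.split("_")[-1]) for c in X.columns])
    return SensitivityTable(S=S, grid_steps=grid_steps, reference=means, peak_ids=peak_ids)


def average_sensitivity(
    result: CVResult, X: np.ndarray | pd.DataFrame, grid_steps: int = 50
) -> SensitivityTable:
    """Mean sensitivity over the per-partition winning models.

    Each partition's model is probed on the feature matrix standardized with
    that partition's scaler; the resulting tables are averaged element-wise.
    """
    if not result.models:
        raise ValueError("CV result carries no models")
    tables = []
    for model, scaler in zip(result.models, result.scalers):
        Xs = scaler.transform(np.asarray(X, dtype=float))
        tables.append(sensitivity_analysis(model, Xs, grid_steps))
    S = np.mean([t.S for t in tables], axis=0)
    peak_ids = None
    if isinstance(X, pd.DataFrame):
        peak_ids = np.array([int(c.split("_")[-1]) for c in X.columns])
    return SensitivityTable(
        S=S, grid_steps=grid_steps, reference=tables[0].reference, peak_ids=peak_ids
    )


def rank_inputs(table: SensitivityTable) -> RankTable:
    """Per-class ranking of peaks by descending sensitivity.

    Ties are broken by ascending peak id.
    """
    S = table.S
    peak_ids = np.asarray(table.peak_ids)
    ranks = []
    for c in range(S.shape[1]):
        order = np.lexsort((peak_ids, -S[:, c]))
        ranks.append(peak_ids[order])
    return RankTable(ranks=np.asarray(ranks))


def sequential_rank_addition(ranks: RankTable | np.ndarray) -> SelectionTrace:
    """Grow the input set by the skip-rank sequential addition rule.

    Starting from an empty set and rank pointer r = 1, advance r until the
    union over classes of the rank-r peaks contains at least one peak not yet
    included; add all such new peaks as one step; repeat until every peak is
    in the set.  Ranks that contribute nothing new are skipped without
    producing a step.
    """
    if not isinstance(ranks, RankTable):
        ranks = RankTable(ranks=np.asarray(ranks))
    R = ranks.ranks
    P = R.shape[1]
    included: list[int] = []
    steps: list[SelectionStep] = []
    for r in range(P):
        new = sorted(int(p) for p in set(R[:, r]) - set(included))
        if not new:
            continue
        included.extend(new)
        steps.append(
            SelectionStep(added=tuple(new), cumulative=tuple(sorted(included)))
        )
        if len(included) == P:
            break
    return SelectionTrace(steps=steps)


def evaluate_trace(
    trace: SelectionTrace,
    X: pd.DataFrame,
    manifest: pd.DataFrame,
    config: MLPConfig,
    n_partitions: int = 20,
    rng: np.random.Generator | None = None,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
) -> SelectionTrace:
    """Score every cumulative peak set of the trace under double CV.

    The network input layer is resized to each subset; the best step is the
    one with the highest mean internal-validation CCR, ties resolved in
    favour of fewer peaks (the earlier step).
    """
    if rng is None:
        rng = np.random.default_rng()
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame with peak_XX columns")
    col_by_id = {int(c.split("_")[-1]): c for c in X.columns}
    internal = np.empty(len(trace.steps))
    external = np.empty(len(trace.steps))
    results: list[CVResult] = []
    for i, step in enumerate(trace.steps):
        cols = [col_by_id[p] for p in step.cumulative]
        cfg = replace(config, n_inputs=len(cols))
        res = run_cv(
            X[cols], manifest, cfg, n_partitions=n_partitions, rng=rng, fractions=fractions
        )
        internal[i] = res.internal_ccr.mean()
        external[i] = res.external_ccr.mean()
        results.append(res)
    best = int(np.argmax(internal))  # argmax takes the first (fewest peaks) on ties
    return SelectionTrace(
        steps=trace.steps,
        internal_ccr=internal,
        external_ccr=external,
        best_step_index=best,
        step_results=results,
    )
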