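"""Permutation significance of the classification accuracy.

The null distribution of the correct classification rate is built by
re-running the learning procedure on data whose class labels were randomly
permuted at the oil level (replicates keep a common label, so replicate
identity never leaks into the null).  The observed and null CCR samples are
then compared with a Mann-Whitney U test of equal population medians, and an
empirical permutation p-value is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .modeling import MLPConfig, run_cv


@dataclass
class MannWhitneyResult:
    U: float  # U of the first sample: #(a > b) pairs, ties counted 1/2
    p_value: float
    method: str  # "exact" or "asymptotic"


@dataclass
class PermutationResult:
    """Observed and null CCR distributions with the U test verdict."""

    observed_ccrs: np.ndarray
    null_ccrs: np.ndarray
    U: float
    p_value: float
    p_empirical: float
    n_permutations: int

    def summary(self) -> dict:
        return {
            "observed_ccr_mean": float(self.observed_ccrs.mean()),
            "null_ccr_mean": float(self.null_ccrs.mean()),
            "U": float(self.U),
            "p_value": float(self.p_value),
            "p_empirical": float(self.p_empirical),
            "n_permutations": int(self.n_permutations),
        }


def permute_labels(
    manifest: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Permute class labels at the oil level.

    The multiset of class sizes is preserved and all replicates of an oil
    receive the same permuted label.
    """
    samples = manifest.drop_duplicates("sample_id")[["sample_id", "class_label"]]
    labels = samples["class_label"].to_numpy()
    permuted = labels[rng.permutation(len(labels))]
    mapping = dict(zip(samples["sample_id"], permuted))
    out = manifest.copy()
    out["class_label"] = out["sample_id"].map(mapping)
    return out


def _exact_u_pvalue(a: np.ndarray, b: np.ndarray, u_obs: float, alternative: str) -> float:
    """Exact U p-value by dynamic programming over pooled midranks.

    Counts, for every subset of size ``len(a)`` of the pooled sample, the
    subsets attaining each possible rank sum (midranks doubled to integers),
    which yields the exact permutation distribution of U including ties.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    r2 = np.rint(2.0 * rankdata(pooled)).astype(int)  # doubled midranks
    total = int(r2.sum())
    # dp[k][s] = number of size-k subsets with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(min(n1, 1_000_000), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n1]
    sums = np.flatnonzero(counts)
    probs = counts[sums] / counts.sum()
    u_vals = sums / 2.0 - n1 * (n1 + 1) / 2.0
    center = n1 * n2 / 2.0
    eps = 1e-9
    if alternative == "two-sided":
        mask = np.abs(u_vals - center) >= abs(u_obs - center) - eps
    elif alternative == "greater":
        mask = u_vals >= u_obs - eps
    elif alternative == "less":
        mask = u_vals <= u_obs + eps
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(probs[mask].sum())


def mann_whitney_u(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> MannWhitneyResult:
    """Mann-Whitney U test with midranks for ties.

    Returns U of the first sample (number of (a, b) pairs with a > b, ties
    counted one half; identical samples give U = n^2 / 2).  The p-value is
    exact (full permutation distribution, tie-aware) when n_a * n_b <= 400,
    otherwise from the tie-corrected normal approximation with continuity
    correction.  Two samples with all values identical give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    U = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    pooled_constant = np.all(a == a.flat[0]) and np.all(b == a.flat[0])
    if pooled_constant:
        return MannWhitneyResult(U=U, p_value=1.0, method="degenerate")
    if a.size * b.size <= 400:
        p = _exact_u_pvalue(a, b, U, alternative)
        return MannWhitneyResult(U=U, p_value=min(p, 1.0), method="exact")
    res = mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return MannWhitneyResult(U=float(res.statistic), p_value=float(res.pvalue), method="asymptotic")


def ccr_histogram(
    result: PermutationResult, bins: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Density histograms of the observed and null CCR samples on shared bins."""
    lo = min(result.observed_ccrs.min(), result.null_ccrs.min())
    hi = max(result.observed_ccrs.max(), result.null_ccrs.max())
    edges = np.linspace(lo, hi + 1e-12, bins + 1)
    obs, _ = np.histogram(result.observed_ccrs, bins=edges, density=True)
    null, _ = np.histogram(result.null_ccrs, bins=edges, density=True)
    return edges, obs, null


def permutation_test(
    X: np.ndarray | pd.DataFrame,
    manifest: pd.DataFrame,
    config: MLPConfig,
    n_permutations: int = 200,
    rng: np.random.Generator | None = None,
    n_partitions_observed: int = 50,
    n_partitions_null: int = 20,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    alternative: str = "two-sided",
) -> PermutationResult:
    """Label-permutation test of the external-validation CCR.

    The observed distribution holds one external CCR per partition of the
    real-label double CV; each permutation re-labels the oils and repeats the
    CV at a reduced partition count (the architecture stays fixed), recording
    its mean external CCR.  Reported are the Mann-Whitney U comparison of the
    two CCR samples and the empirical permutation p-value
    (1 + #{null >= mean observed}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    observed = run_cv(
        X, manifest, config, n_partitions=n_partitions_observed, rng=rng,
        fractions=fractions,
    ).external_ccr

    ref_counts = manifest.drop_duplicates("sample_id")["class_label"].value_counts()
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = permute_labels(manifest, rng)
        counts = perm.drop_duplicates("sample_id")["class_label"].value_counts()
        assert counts.sort_index().equals(ref_counts.sort_index()), "class sizes changed"
        assert (
            perm.groupby("sample_id")["class_label"].nunique() == 1
        ).all(), "replicates split across labels"
        null[i] = run_cv(
            X, perm, config, n_partitions=n_partitions_null, rng=rng,
            fractions=fractions,
        ).external_ccr.mean()

    mw = mann_whitney_u(observed, null, alternative=alternative)
    p_emp = (1.0 + float(np.sum(null >= observed.mean()))) / (1.0 + n_permutations)
    return PermutationResult(
        observed_ccrs=observed,
        null_ccrs=null,
        U=mw.U,
        p_value=mw.p_value,
        p_empirical=p_emp,
        n_permutations=n_permutations,
    )
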