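"""Repeated-subsampling t-test vote-counting feature selection.

The selector repeats the following ``n_reps`` times (default 100): draw 80%
of the samples of each class without replacement, run a two-sample t-test on
every feature, and give one vote to each feature with p < alpha (default
0.05).  A feature set is then the features whose vote total reaches a
threshold (e.g. >= 50 of 100), or the top-k features by votes.

All ``n_reps`` repetitions are evaluated in a single pass: per-repetition
group sums and sums of squares for every feature come from two indicator-
matrix products, from which the t statistics of every (repetition, feature)
cell follow vectorised.  ``scipy.stats.ttest_ind`` is deliberately not on
this path so the test suite can use it as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import stdtr

from .datatypes import FeatureMatrix

_VARIANTS = ("pooled", "welch")


@dataclass
class VoteParams:
    """Parameters of the subsampling vote selector."""

    n_reps: int = 100
    subsample_frac: float = 0.8
    alpha: float = 0.05
    t_variant: str = "pooled"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.subsample_frac <= 1:
            raise ValueError("subsample_frac must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.t_variant not in _VARIANTS:
            raise ValueError(f"t_variant must be one of {_VARIANTS}")


@dataclass
class VoteTable:
    """Per-feature vote totals and mean p-values over the repetitions."""

    feature_ids: list[str]
    votes: np.ndarray  # int, in [0, n_reps]
    mean_p: np.ndarray  # in [0, 1]
    params: VoteParams

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=int)
        self.mean_p = np.asarray(self.mean_p, dtype=float)
        n = len(self.feature_ids)
        if len(self.votes) != n or len(self.mean_p) != n:
            raise ValueError("votes/mean_p length must match feature_ids")
        if (self.votes < 0).any() or (self.votes > self.params.n_reps).any():
            raise ValueError("votes out of [0, n_reps]")

    def ranking(self) -> np.ndarray:
        """Canonical order: votes desc, then mean p asc, then feature position asc.

        The two secondary keys make every downstream sweep deterministic.
        """
        # np.lexsort sorts by the LAST key first; all keys ascending, so negate votes.
        pos = np.arange(len(self.votes))
        return np.lexsort((pos, self.mean_p, -self.votes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": self.feature_ids, "votes": self.votes, "mean_p": self.mean_p}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SelectionResult:
    """Features passing a vote threshold, ordered by descending votes."""

    feature_ids: list[str]
    threshold: int
    votes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_selected(self) -> int:
        return len(self.feature_ids)

    @property
    def is_empty(self) -> bool:
        return self.n_selected == 0


def _t_and_p(
    diff: np.ndarray,
    ss0: np.ndarray,
    ss1: np.ndarray,
    m0: int,
    m1: int,
    variant: str,
) -> tuple[np.ndarray, np.ndarray]:
    """t statistic and two-sided p from group mean difference and corrected
    sums of squares; degenerate zero-variance cells map to (0, 1) when the
    means agree and (+-inf, 0) when they do not."""
    ss0 = np.maximum(ss0, 0.0)  # guard tiny negative values from cancellation
    ss1 = np.maximum(ss1, 0.0)
    if variant == "pooled":
        sp2 = (ss0 + ss1) / (m0 + m1 - 2)
        se2 = sp2 * (1.0 / m0 + 1.0 / m1)
        df = np.asarray(float(m0 + m1 - 2))
    else:  # welch
        v0 = ss0 / (m0 - 1)
        v1 = ss1 / (m1 - 1)
        se2 = v0 / m0 + v1 / m1
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v0 / m0) ** 2 / (m0 - 1) + (v1 / m1) ** 2 / (m1 - 1))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        zero_se = se2 == 0
        zero_diff = diff == 0
        t = np.where(zero_se & zero_diff, 0.0, t)
        t = np.where(zero_se & ~zero_diff, np.sign(diff) * np.inf, t)
    df = np.where(np.broadcast_to(np.isfinite(df) & (df > 0), t.shape), df, 1.0)

    p = 2.0 * stdtr(df, -np.abs(t))
    p = np.where(zero_se & zero_diff, 1.0, p)
    p = np.where(zero_se & ~zero_diff, 0.0, p)
    return t, p


def unpaired_t_test(
    x: Sequence[float], y: Sequence[float], variant: str = "pooled"
) -> tuple[float, float]:
    """Two-sample t-test of equal means; two-sided p-value.

    ``variant='pooled'`` is the classical Student test (equal variances
    assumed, df = n_x + n_y - 2); ``'welch'`` uses per-group variances with
    Welch–Satterthwaite df.  Both groups need >= 2 observations.  Degenerate
    zero-variance inputs return (0, 1) for equal means and (+-inf, 0)
    otherwise.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = x.mean() - y.mean()
    ss_x = ((x - x.mean()) ** 2).sum()
    ss_y = ((y - y.mean()) ** 2).sum()
    t, p = _t_and_p(np.asarray(diff), np.asarray(ss_x), np.asarray(ss_y), x.size, y.size, variant)
    return float(t), float(p)


def _subsample_indicators(
    rng: np.random.Generator, n: int, m: int, n_reps: int
) -> np.ndarray:
    """(n_reps, n) 0/1 matrix; each row marks m samples drawn without replacement."""
    out = np.zeros((n_reps, n))
    for r in range(n_reps):
        out[r, rng.choice(n, size=m, replace=False)] = 1.0
    return out


def _vote_count_arrays(
    X: np.ndarray, labels: np.ndarray, params: VoteParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vote totals and mean p-values from raw arrays (hot path of the CV loops)."""
    X0 = X[labels == 0]
    X1 = X[labels == 1]
    n0, n1 = len(X0), len(X1)
    m0 = int(np.floor(params.subsample_frac * n0))
    m1 = int(np.floor(params.subsample_frac * n1))
    if m0 < 2 or m1 < 2:
        raise ValueError(
            f"subsample sizes ({m0}, {m1}) too small: need >= 2 per class; "
            "increase subsample_frac or sample count"
        )

    I0 = _subsample_indicators(rng, n0, m0, params.n_reps)
    I1 = _subsample_indicators(rng, n1, m1, params.n_reps)

    # Per-repetition, per-feature group sums and sums of squares via BLAS.
    S0, S1 = I0 @ X0, I1 @ X1
    Q0, Q1 = I0 @ (X0**2), I1 @ (X1**2)
    diff = S0 / m0 - S1 / m1
    ss0 = Q0 - S0**2 / m0
    ss1 = Q1 - S1**2 / m1

    _, p = _t_and_p(diff, ss0, ss1, m0, m1, params.t_variant)
    votes = (p < params.alpha).sum(axis=0)
    return votes, p.mean(axis=0)


def vote_count(train: FeatureMatrix, params: VoteParams) -> VoteTable:
    """Run the repeated-subsampling t-test vote selector on a training matrix.

    Each repetition draws ``floor(subsample_frac * n_c)`` samples per class
    without replacement and adds one vote to every feature whose t-test
    p-value falls below ``alpha``.  Reproducible under ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    votes, mean_p = _vote_count_arrays(train.values, train.labels, params, rng)
    return VoteTable(list(train.feature_ids), votes, mean_p, params)


def select_by_threshold(votes: VoteTable, threshold: int) -> SelectionResult:
    """All features with vote total >= threshold, in canonical ranking order.

    ``threshold`` may range from 0 to ``n_reps + 1`` (the latter forces an
    empty selection).  An empty result is returned as-is; fallback policy is
    the caller's (the CV protocols substitute the single top-voted feature).
    """
    n_reps = votes.params.n_reps
    if not 0 <= threshold <= n_reps + 1:
        raise ValueError(f"threshold must be in [0, {n_reps + 1}]")
    order = votes.ranking()
    keep = order[votes.votes[order] >= threshold]
    return SelectionResult(
        feature_ids=[votes.feature_ids[i] for i in keep],
        threshold=threshold,
        votes=votes.votes[keep].copy(),
    )


def rank_features(votes: VoteTable, k: int) -> list[str]:
    """The k top-voted features under the canonical deterministic ranking."""
    if not 1 <= k <= len(votes.feature_ids):
        raise ValueError(f"k must be in [1, {len(votes.feature_ids)}]")
    order = votes.ranking()[:k]
    return [votes.feature_ids[i] for i in order]
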