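"""Tissue-type discrimination: random forest vs majority-class baseline.

The protocol draws bootstrap training sets, evaluates both a random-forest
classifier on genus-level relative abundances and a constant majority-class
predictor on the out-of-bag samples of each replicate, and compares the two
paired error columns with a Friedman rank test (replicates as blocks).  The
forest uses the classic defaults of the original algorithm: 500 trees and
sqrt(p) candidate features per split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .core import TestResult, ValidationError

__all__ = ["BootstrapErrors", "bootstrap_compare", "friedman_compare"]


@dataclass(frozen=True)
class BootstrapErrors:
    """Paired out-of-bag error estimates for the two predictors.

    ``errors`` is n_boot x 2 with column 0 the random forest and column 1
    the majority-class baseline, both evaluated on the same out-of-bag test
    partitions.  ``n_redraws`` counts replicates that had to be redrawn for
    an empty out-of-bag set or single-class training sample.
    """

    errors: np.ndarray
    n_boot: int
    seed: int | None
    n_redraws: int = 0

    def __post_init__(self):
        if self.errors.shape != (self.n_boot, 2):
            raise ValidationError("errors must be n_boot x 2")
        if ((self.errors < 0) | (self.errors > 1)).any():
            raise ValidationError("errors must lie in [0, 1]")


def bootstrap_compare(
    X,
    y,
    n_boot: int = 100,
    seed: int | None = None,
    n_estimators: int = 500,
) -> BootstrapErrors:
    """Bootstrap comparison of a random forest against majority-class guessing.

    Per replicate a bootstrap sample (with replacement, size n) forms the
    training set; both predictors are evaluated on the out-of-bag samples.
    Degenerate replicates (no out-of-bag samples, or a single-class training
    set) are redrawn and counted.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    classes, class_counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("need at least 2 classes")
    if class_counts.min() < 5:
        raise ValidationError("need at least 5 samples per class")
    rng = np.random.default_rng(seed)
    errors = np.empty((n_boot, 2))
    n_redraws = 0
    for b in range(n_boot):
        while True:
            train = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), train)
            if oob.size and np.unique(y[train]).size >= 2:
                break
            n_redraws += 1
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
        )
        rf.fit(X[train], y[train])
        rf_err = float(np.mean(rf.predict(X[oob]) != y[oob]))
        # majority class of the training draw; ties -> first in sorted order
        labels, counts = np.unique(y[train], return_counts=True)
        majority = labels[np.argmax(counts)]
        base_err = float(np.mean(y[oob] != majority))
        errors[b] = (rf_err, base_err)
    return BootstrapErrors(errors=errors, n_boot=n_boot, seed=seed, n_redraws=n_redraws)


def friedman_test(data: np.ndarray) -> TestResult:
    """Friedman rank test for k treatments over n blocks (rows).

    Ranks within each block (average ranks on ties), computes
    ``Q = 12n/(k(k+1)) * sum_j (Rbar_j - (k+1)/2)^2`` with the standard tie
    correction, and refers Q to chi-square with k-1 degrees of freedom.
    Implemented directly so the two-treatment case of the bootstrap
    comparison is supported (SciPy requires k >= 3).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValidationError("need >=2 blocks and >=2 treatments")
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rbar = ranks.mean(axis=0)
    q = 12.0 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2.0) ** 2)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += np.sum(counts**3 - counts)
    denom = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if denom <= 0:  # every block fully tied
        return TestResult(statistic=0.0, p_value=1.0, method="friedman")
    q /= denom
    p = float(stats.chi2.sf(q, k - 1))
    return TestResult(statistic=float(q), p_value=p, method="friedman")


def friedman_compare(errors: BootstrapErrors) -> TestResult:
    """Friedman test comparing the two predictors across bootstrap blocks."""
    if errors.n_boot < 10:
        raise ValidationError("need at least 10 bootstrap replicates")
    return friedman_test(errors.errors)
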