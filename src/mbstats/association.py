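"""Community-level association tests.

The workhorse is a kernel association score test in the MiRKAT family: an
ecological distance matrix is Gower-centered into a positive-semidefinite
kernel K, a null model regresses the outcome on covariates only (OLS for
continuous outcomes, logistic for binary), and the score statistic
Q = r' K r on the null residuals r is referenced against its residual-
permutation distribution.  Permutation (Freedman-Lane style) rather than the
asymptotic mixture-of-chi-squares tail keeps the test assumption-light at
the small sample sizes typical of tissue-microbiome cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from skbio import DistanceMatrix

from .core import TestResult, ValidationError

__all__ = [
    "KernelMatrix",
    "gower_kernel",
    "kernel_association_test",
    "alpha_diversity_regression",
    "paired_distance_test",
]


@dataclass(frozen=True)
class KernelMatrix:
    """Sample x sample positive-semidefinite similarity matrix."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("kernel shape inconsistent with ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("kernel must be symmetric")


def gower_kernel(dm, ids=None) -> KernelMatrix:
    """Gower-center a distance matrix into a kernel: K = -1/2 J D^2 J.

    J = I - 11'/n is the centering projector.  For a Euclidean distance
    matrix this recovers the centered inner-product (Gram) matrix of the
    underlying configuration; for non-Euclidean dissimilarities the result
    can be indefinite, so negative eigenvalues are zeroed to project onto
    the positive-semidefinite cone (standard MiRKAT practice).

    Accepts a ``skbio.DistanceMatrix`` or a plain square array (with
    optional ``ids``).
    """
    if isinstance(dm, DistanceMatrix):
        d = np.asarray(dm.data, dtype=float)
        ids = tuple(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        ids = tuple(ids) if ids is not None else tuple(map(str, range(len(d))))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    k = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(k)
    evals = np.clip(evals, 0.0, None)
    k_psd = (evecs * evals) @ evecs.T
    k_psd = 0.5 * (k_psd + k_psd.T)
    return KernelMatrix(ids, k_psd)


def _null_residuals(outcome: np.ndarray, design: np.ndarray, binary: bool) -> np.ndarray:
    if binary:
        model = sm.GLM(outcome, design, family=sm.families.Binomial())
    else:
        model = sm.OLS(outcome, design)
    fit = model.fit()
    return outcome - fit.fittedvalues


def _design_matrix(n: int, covariates) -> np.ndarray:
    if covariates is None:
        x = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if not np.allclose(cov[:, 0], 1.0):
            cov = np.column_stack([np.ones(len(cov)), cov])
        x = cov
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("covariate design matrix is rank-deficient")
    return x


def kernel_association_test(
    kernel: KernelMatrix,
    outcome,
    covariates=None,
    n_perm: int = 999,
    seed: int | None = None,
    outcome_type: str = "auto",
) -> TestResult:
    """Kernel score test of an outcome against a community kernel.

    Parameters
    ----------
    kernel
        PSD kernel from :func:`gower_kernel`.
    outcome
        Per-sample trait; binary outcomes (two unique values) use a logistic
        null model, continuous ones OLS.  Force with ``outcome_type``.
    covariates
        Optional design columns (e.g. sequencing batch, depth); an intercept
        is always included.
    n_perm, seed
        Residual permutations for the p-value; deterministic given seed.

    Returns
    -------
    TestResult with Q = r'Kr and p = (1 + #{Q_perm >= Q_obs}) / (1 + n_perm).
    """
    y = np.asarray(outcome, dtype=float)
    n = len(kernel.ids)
    if y.shape != (n,):
        raise ValidationError("outcome length does not match kernel")
    uniques = np.unique(y)
    if uniques.size < 2:
        raise ValidationError("outcome is constant")
    if outcome_type == "auto":
        binary = uniques.size == 2 and set(uniques) <= {0.0, 1.0}
    elif outcome_type in ("binary", "continuous"):
        binary = outcome_type == "binary"
    else:
        raise ValidationError(f"unknown outcome_type {outcome_type!r}")
    x = _design_matrix(n, covariates)
    r = _null_residuals(y, x, binary)

    k = kernel.values
    q_obs = float(r @ k @ r)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    rp = r[perms]  # n_perm x n
    q_perm = np.einsum("bi,ij,bj->b", rp, k, rp)
    p = (1.0 + np.count_nonzero(q_perm >= q_obs)) / (1.0 + n_perm)
    return TestResult(
        statistic=q_obs,
        p_value=p,
        n_permutations=n_perm,
        method="kernel_score_permutation",
        seed=seed,
    )


def alpha_diversity_regression(alpha, group, covariates=None) -> TestResult:
    """OLS of an alpha-diversity metric on group with optional covariates.

    Fits ``alpha ~ intercept + covariates + group`` and reports the Wald
    test for the group coefficient.  Sequencing depth or batch indicators
    enter through ``covariates``.  The full coefficient table is returned in
    ``TestResult.extra["params"]``.
    """
    y = np.asarray(alpha, dtype=float)
    g = np.asarray(group, dtype=float)
    n = y.size
    if np.ptp(y) == 0:  # constant outcome: no association, by convention p = 1
        return TestResult(statistic=0.0, p_value=1.0, method="ols_wald")
    x = _design_matrix(n, covariates)
    if n <= x.shape[1] + 2:
        raise ValidationError("too few samples for the requested model")
    design = np.column_stack([x, g])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("group is collinear with covariates")
    fit = sm.OLS(y, design).fit()
    coef = float(fit.params[-1])
    pval = float(fit.pvalues[-1])
    if np.isnan(pval):  # zero residual variance
        pval = 1.0
    return TestResult(
        statistic=coef,
        p_value=pval,
        n_permutations=0,
        method="ols_wald",
        extra={"params": fit.params.tolist(), "bse": fit.bse.tolist(),
               "tvalues": fit.tvalues.tolist()},
    )


def paired_distance_test(
    dm: DistanceMatrix,
    pairs: dict,
    n_perm: int = 999,
    seed: int | None = None,
) -> TestResult:
    """Within- vs between-subject distance permutation test for paired tissues.

    ``pairs`` maps each subject to its two samples of different types (e.g.
    breast tissue and skin tissue).  The statistic is the mean within-subject
    cross-type distance minus the mean between-subject cross-type distance;
    the null permutes which second-type sample belongs to which subject.  The
    p-value is one-sided for the within < between alternative.
    """
    subjects = list(pairs)
    if len(subjects) < 3:
        raise ValidationError("need at least 3 complete pairs")
    first = [pairs[s][0] for s in subjects]
    second = [pairs[s][1] for s in subjects]
    idx = {sid: i for i, sid in enumerate(dm.ids)}
    a = np.array([idx[s] for s in first])
    b = np.array([idx[s] for s in second])
    d = np.asarray(dm.data, dtype=float)
    cross = d[np.ix_(a, b)]  # cross[i, j] = d(first_i, second_j)
    m = len(subjects)
    off_mask = ~np.eye(m, dtype=bool)

    def stat(perm):
        mat = cross[:, perm]
        return mat.trace() / m - mat[off_mask].mean()

    obs = stat(np.arange(m))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if stat(rng.permutation(m)) <= obs:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return TestResult(
        statistic=obs,
        p_value=p,
        n_permutations=n_perm,
        method="paired_distance_permutation",
        seed=seed,
    )
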