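"""Robust pseudo-value regression machinery: LTS fit, t-test, q-values.

Jackknife pseudo-values are heavy-tailed (a single influential subject can
produce an extreme pseudo-value), so the per-taxon regression uses least
trimmed squares (LTS): minimise the sum of the h smallest squared
residuals, which tolerates up to n - h arbitrarily bad points in either
the response or the predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["LtsConfig", "lts_fit", "test_beta", "qvalues"]


@dataclass
class LtsConfig:
    """Trimming configuration for the LTS solver.

    ``trim_c`` in [0.5, 1] sets the subset size through
    h = floor(n * (1 - c)) + 1; the default c = 0.5 gives the
    maximum-breakdown choice h = floor(n/2) + 1.  ``h`` may be given
    directly to override the formula.  ``n_starts`` random elemental
    starts are each refined by concentration steps.
    """

    trim_c: float = 0.5
    h: int | None = None
    n_starts: int = 40
    max_csteps: int = 30
    #: refit by weighted OLS on points within ``reweight_cutoff`` robust
    #: scale units of the raw LTS fit (the standard FAST-LTS reweighting
    #: step); final coefficients/SEs come from that fit.  Set False to
    #: use the raw h-subset fit directly.
    reweight: bool = True
    reweight_cutoff: float = 2.5

    def subset_size(self, n: int, n_coef: int) -> int:
        if self.h is not None:
            h = int(self.h)
        else:
            if not 0.5 <= self.trim_c <= 1.0:
                raise ValueError("trim_c must lie in [0.5, 1]")
            h = int(np.floor(n * (1.0 - self.trim_c))) + 1
        h = min(h, n)
        if h < n_coef + 1:
            raise ValueError(
                f"subset size h={h} too small for {n_coef} coefficients")
        return h


def _check_full_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the collinearity for the message
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j] if names is not None else f"col{j}")
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {bad}")


def _lts_consistency_factor(h: int, n: int) -> float:
    """Variance inflation correcting for estimating scale on the central h.

    The h retained residuals of a normal sample cover the central
    alpha = h/n mass; their mean square underestimates sigma^2 by the factor
    1 - 2 q phi(q) / alpha with q = Phi^{-1}((alpha + 1) / 2).
    """
    alpha = h / n
    if alpha >= 1.0:
        return 1.0
    q = stats.norm.ppf((alpha + 1.0) / 2.0)
    shrink = 1.0 - 2.0 * q * stats.norm.pdf(q) / alpha
    return 1.0 / shrink


def lts_fit(
    y: np.ndarray,
    X: np.ndarray,
    config: LtsConfig | None = None,
    seed: int | np.random.Generator = 0,
    column_names=None,
):
    """Least trimmed squares regression with classical SEs on the kept subset.

    Minimises sum of the h smallest squared residuals using randomized
    elemental starts followed by concentration steps (each step refits OLS
    on the h best-fitting points, which never increases the objective), a
    FAST-LTS style approximation.  An OLS start is always included, so with
    h = n the result is exactly OLS.

    Returns
    -------
    coef : ndarray (k,)
    se : ndarray (k,)
        Classical least-squares standard errors on the h retained points,
        inflated by the LTS consistency factor for the truncated variance.
    df : int
        Degrees of freedom for the t reference, n - k.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > number of coefficients + 1")
    if config is None:
        config = LtsConfig()
    _check_full_rank(X, column_names)
    h = config.subset_size(n, k)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def cstep_from(coef):
        best_obj = np.inf
        for _ in range(config.max_csteps):
            resid2 = (y - X @ coef) ** 2
            subset = np.argpartition(resid2, h - 1)[:h]
            coef_new, _, rank, _ = np.linalg.lstsq(X[subset], y[subset], rcond=None)
            if rank < k:
                break
            obj = np.sort((y - X @ coef_new) ** 2)[:h].sum()
            if obj >= best_obj - 1e-12:
                coef = coef_new
                best_obj = obj
                break
            coef, best_obj = coef_new, obj
        resid2 = (y - X @ coef) ** 2
        subset = np.argpartition(resid2, h - 1)[:h]
        return coef, np.sort(resid2)[:h].sum(), subset

    # deterministic OLS start plus randomized elemental starts
    ols_coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    starts = [ols_coef]
    if h < n:
        for _ in range(config.n_starts):
            idx = rng.choice(n, size=k, replace=False)
            c, _, rank, _ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
            if rank == k:
                starts.append(c)

    best = (None, np.inf, None)
    for c0 in starts:
        c, obj, subset = cstep_from(c0)
        if obj < best[1]:
            best = (c, obj, subset)
    coef, _, subset = best

    if config.reweight:
        # standard reweighting step: the raw LTS fit only identifies the
        # outliers; points within the cutoff of the consistency-corrected
        # raw scale are refit by OLS, which is where coefficients and
        # classical SEs are taken from (cf. ltsReg conventions)
        resid = y - X @ coef
        s_raw = np.sqrt(np.sort(resid**2)[:h].sum() / h
                        * _lts_consistency_factor(h, n))
        if s_raw <= 0:
            keep = np.ones(n, dtype=bool)
        else:
            keep = np.abs(resid) <= config.reweight_cutoff * s_raw
        if keep.sum() < k + 1:
            keep = np.argsort(np.abs(resid))[: k + 1]
            keep = np.isin(np.arange(n), keep)
        Xw, yw = X[keep], y[keep]
        coef, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < k:  # fall back to the raw-subset fit
            keep = np.isin(np.arange(n), subset)
            Xw, yw = X[keep], y[keep]
            coef = best[0]
        resid_w = yw - Xw @ coef
        nw = int(keep.sum())
        # variance consistency for the hard 2.5-sigma truncation
        c = config.reweight_cutoff
        mass = 2 * stats.norm.cdf(c) - 1
        shrink = 1.0 - 2.0 * c * stats.norm.pdf(c) / mass
        s2 = resid_w @ resid_w / max(nw - k, 1) / shrink
        XtX_inv = np.linalg.inv(Xw.T @ Xw)
    else:
        Xh, yh = X[subset], y[subset]
        resid_h = yh - Xh @ coef
        s2 = (resid_h @ resid_h / max(h - k, 1)
              * _lts_consistency_factor(h, n))
        XtX_inv = np.linalg.inv(Xh.T @ Xh)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * s2, 0.0, None))
    df = n - k
    return coef, se, df


def test_beta(beta_hat: float, se: float, df: int):
    """Two-sided t-test of H0: beta = 0.

    Returns (U, p) with U = beta_hat / se and p from a t distribution with
    ``df`` degrees of freedom.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if se == 0:
        warnings.warn("zero standard error in t-test", RuntimeWarning,
                      stacklevel=2)
        return (np.inf if beta_hat > 0 else (-np.inf if beta_hat < 0 else 0.0),
                0.0 if beta_hat != 0 else 1.0)
    U = beta_hat / se
    p = 2.0 * stats.t.sf(abs(U), df)
    return U, min(p, 1.0)


def estimate_pi0(p_values) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on the grid
    lambda = 0.05, 0.10, ..., 0.95, a cubic trend is fitted and evaluated
    at the largest lambda; the result is clamped to [1/m, 1].  Under a
    uniform (null) p-value distribution the trend is flat at 1; when most
    p-values are small the estimate approaches the floor, making the
    q-values correspondingly less conservative than Benjamini-Hochberg.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    lams = np.arange(0.05, 0.951, 0.05)
    pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lams])
    coef = np.polyfit(lams, pi0_lam, 3)
    pi0 = float(np.polyval(coef, lams[-1]))
    return min(max(pi0, 1.0 / m), 1.0)


def qvalues(p_values, pi0: float | None = None, min_tests_for_pi0: int = 20):
    """Storey-type q-values with an estimated null proportion.

    The null proportion is estimated by :func:`estimate_pi0` (Storey's
    smoother); q-values are then pi0 times the Benjamini-Hochberg step-up
    adjusted p-values (monotone in p by construction).  With fewer than
    ``min_tests_for_pi0`` tests the pi0 estimate is too unstable and the
    procedure falls back to plain Benjamini-Hochberg (pi0 = 1).

    Parameters
    ----------
    p_values : array-like in [0, 1]
    pi0 : float, optional
        Override the estimate (e.g. force 1.0 for pure BH).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = 1.0 if m < min_tests_for_pi0 else estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    return np.clip(pi0 * bh, 0.0, 1.0)
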