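"""SparCC-style compositional correlation estimation.

Counts from amplicon or shotgun sequencing carry only relative information,
so naive Pearson correlation of relative abundances is distorted by the
unit-sum constraint.  SparCC instead works with variances of log-ratios

    t_jk = Var(log u_j / u_k) = sigma_j^2 + sigma_k^2 - 2 rho_jk sigma_j sigma_k,

which are invariant to per-sample scaling.  Under a sparsity assumption
(most true correlations are weak) the unobservable "basis" variances
sigma_j^2 of the log absolute abundances can be recovered from the row sums
of the t matrix by a linear system, giving the basis correlation

    rho_jk = (sigma_j^2 + sigma_k^2 - t_jk) / (2 sigma_j sigma_k).

Strongly correlated pairs violate the sparsity approximation, so the
estimate is refined by iteratively excluding the strongest pair from the
basis-variance system and re-solving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .data import AbundanceTable, to_fractions

__all__ = [
    "AssociationMatrix",
    "logratio_variances",
    "basis_variances",
    "sparcc_correlation",
    "sparcc_exclusion_pairs",
]

#: lower bound for basis variances, preventing division by zero
VARIANCE_FLOOR = 1e-8


@dataclass
class AssociationMatrix:
    """Symmetric p x p taxon-taxon correlation matrix with unit diagonal."""

    rho: np.ndarray
    taxon_ids: list[str] = field(default=None)
    #: set when the iterative exclusion had to stop early (too few taxa left)
    degraded: bool = False

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        p = self.rho.shape[0]
        if self.rho.shape != (p, p):
            raise ValueError("association matrix must be square")
        if self.taxon_ids is None:
            self.taxon_ids = [f"T{j}" for j in range(p)]

    @property
    def n_taxa(self) -> int:
        return self.rho.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.taxon_ids,
                            columns=self.taxon_ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().rename_axis("taxon_id").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "AssociationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns))


def logratio_variances(fractions: np.ndarray) -> np.ndarray:
    """Matrix of sample variances of pairwise log-ratios.

    t_jk = Var_i(log u_ij / u_ik), computed for all pairs at once from the
    covariance matrix S of the log fractions via
    t_jk = S_jj + S_kk - 2 S_jk (so t is symmetric with zero diagonal).

    Parameters
    ----------
    fractions : ndarray, shape (n, p)
        Strictly positive relative abundances; n >= 2.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[0] < 2:
        raise ValueError("variance undefined: need at least 2 samples")
    if np.any(fractions <= 0):
        raise ValueError("fractions must be strictly positive")
    logf = np.log(fractions)
    cov = np.cov(logf, rowvar=False)
    d = np.diag(cov)
    t = d[:, None] + d[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    # numerical noise can push near-zero variances slightly negative
    return np.clip(t, 0.0, None)


def basis_variances(t: np.ndarray, included=None) -> np.ndarray:
    """Solve for basis log-abundance variances from log-ratio variances.

    Under sparsity of correlations, the row sum of t over the included taxa
    approximately satisfies

        sum_{k != j} t_jk ~= (m - 1) sigma_j^2 + sum_{k != j} sigma_k^2

    for m included taxa, a linear system ((m-2) I + J) sigma^2 = rowsum(t).
    Negative solutions (sparsity violated) are clipped to a small positive
    floor.

    Parameters
    ----------
    t : ndarray (p, p)
        Symmetric log-ratio variance matrix.
    included : iterable of int, optional
        Taxon indices forming the system (default all); at least 3.

    Returns
    -------
    ndarray, shape (len(included),)
        Basis variances for the included taxa, in their order.
    """
    t = np.asarray(t, dtype=float)
    p = t.shape[0]
    idx = np.arange(p) if included is None else np.asarray(sorted(included))
    m = idx.size
    if m < 3:
        raise ValueError("basis-variance system needs at least 3 taxa")
    sub = t[np.ix_(idx, idx)]
    M = np.ones((m, m)) + (m - 2) * np.eye(m)
    row_sums = sub.sum(axis=1)
    try:
        sigma2 = np.linalg.solve(M, row_sums)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - M is full rank
        raise np.linalg.LinAlgError(
            f"singular basis-variance system for {m} taxa") from exc
    return np.clip(sigma2, VARIANCE_FLOOR, None)


def _solve_with_exclusions(t: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Solve M sigma^2 = rowsum(t over non-excluded pairs) with clipping.

    ``M`` is the coefficient matrix maintained by the exclusion loop:
    M_jk = 1 for a retained pair, 0 for an excluded one, and M_jj holds the
    number of retained partners of taxon j.  ``t`` must already have the
    excluded entries zeroed.
    """
    row_sums = t.sum(axis=1)
    sigma2 = np.linalg.solve(M, row_sums)
    return np.clip(sigma2, VARIANCE_FLOOR, None)


def _rho_from_basis(t: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    sigma = np.sqrt(sigma2)
    rho = (sigma2[:, None] + sigma2[None, :] - t) / (2.0 * np.outer(sigma, sigma))
    rho = np.clip(rho, -1.0, 1.0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return rho


def _iterate_exclusions(
    t_full: np.ndarray,
    exclusion_threshold: float,
    max_exclusion_iters: int,
    pairs: list | None = None,
):
    """Run (or replay) the sparsity-refinement exclusion loop.

    With ``pairs`` given, the adaptive selection is skipped and exactly
    those pairs are excluded from the basis-variance system.  Returns
    (rho, chosen_pairs, degraded).
    """
    p = t_full.shape[0]
    t_work = t_full.copy()
    M = np.ones((p, p)) + (p - 2) * np.eye(p)
    degraded = False
    chosen: list[tuple[int, int]] = []

    def exclude(j: int, k: int) -> bool:
        nonlocal degraded
        if M[j, j] <= 2 or M[k, k] <= 2:
            # a taxon excluded against (almost) everyone makes the
            # system uninformative; keep the current estimate
            degraded = True
            warnings.warn(
                "SparCC exclusion stopped early: fewer than 3 effective "
                "taxa would remain", RuntimeWarning, stacklevel=3)
            return False
        chosen.append((j, k))
        t_work[j, k] = t_work[k, j] = 0.0
        M[j, k] = M[k, j] = 0.0
        M[j, j] -= 1
        M[k, k] -= 1
        return True

    sigma2 = _solve_with_exclusions(t_work, M)
    rho = _rho_from_basis(t_full, sigma2)

    if pairs is not None:
        for j, k in pairs:
            if not exclude(j, k):
                break
        if pairs:
            sigma2 = _solve_with_exclusions(t_work, M)
            rho = _rho_from_basis(t_full, sigma2)
        return rho, chosen, degraded

    excluded = np.zeros((p, p), dtype=bool)
    for _ in range(max_exclusion_iters):
        cand = np.abs(rho)
        cand[np.tril_indices(p)] = 0.0
        cand[excluded] = 0.0
        j, k = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[j, k] <= exclusion_threshold:
            break
        if not exclude(j, k):
            break
        excluded[j, k] = excluded[k, j] = True
        sigma2 = _solve_with_exclusions(t_work, M)
        rho = _rho_from_basis(t_full, sigma2)
    return rho, chosen, degraded


def sparcc_correlation(
    table: AbundanceTable,
    pseudocount: float = 0.5,
    exclusion_threshold: float = 0.1,
    max_exclusion_iters: int = 10,
    exclusion_pairs=None,
) -> AssociationMatrix:
    """Estimate the taxon-taxon association matrix from a count table.

    Runs the basis-variance solve, then iteratively removes the most
    strongly correlated remaining pair from the variance system (the
    sparsity refinement) until no newly considered pair exceeds
    ``exclusion_threshold`` in absolute correlation or the iteration budget
    is exhausted.  The estimate is deterministic: zeros are handled by a
    constant pseudocount rather than resampling.

    Parameters
    ----------
    exclusion_pairs : list of (j, k) pairs, optional
        Exclude exactly these pairs instead of selecting them adaptively.
        Used by the jackknife so that every leave-one-out re-estimate
        evaluates the same smooth functional (the adaptive selection is
        made once, on the full sample); see
        :func:`sparcc_exclusion_pairs`.

    Returns
    -------
    AssociationMatrix
        Symmetric, unit diagonal, entries in [-1, 1].  ``degraded`` is set
        if exclusions left fewer than 3 effective taxa and iteration had to
        stop early.
    """
    if isinstance(table, AbundanceTable):
        taxon_ids = list(table.taxon_ids)
    else:
        table = AbundanceTable(np.asarray(table, dtype=float))
        taxon_ids = list(table.taxon_ids)
    p = table.n_taxa
    if p < 4:
        raise ValueError("need at least 4 taxa for SparCC estimation")
    fracs = to_fractions(table, pseudocount)
    t_full = logratio_variances(fracs)
    rho, _, degraded = _iterate_exclusions(
        t_full, exclusion_threshold, max_exclusion_iters, exclusion_pairs)
    return AssociationMatrix(rho, taxon_ids, degraded=degraded)


def sparcc_exclusion_pairs(
    table: AbundanceTable,
    pseudocount: float = 0.5,
    exclusion_threshold: float = 0.1,
    max_exclusion_iters: int = 10,
) -> list:
    """Adaptively chosen exclusion pairs for a table (in exclusion order).

    The jackknife freezes these on the full sample of a group and replays
    them for every leave-one-out re-estimate: the exclusion choice is a
    discrete decision, and re-making it per deletion would make the
    leave-one-out estimates target slightly different functionals, which
    inflates the bias-correction term of the pseudo-values.
    """
    fracs = to_fractions(table, pseudocount)
    t_full = logratio_variances(fracs)
    _, chosen, _ = _iterate_exclusions(
        t_full, exclusion_threshold, max_exclusion_iters, None)
    return chosen
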