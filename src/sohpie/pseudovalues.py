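"""Degree centrality and leave-one-out jackknife pseudo-values.

The per-taxon network summary tested downstream is degree centrality: the
marginal (column) sum of the estimated association matrix.  Because the
association matrix is a functional of the whole sample, a subject-level
surrogate observation is obtained through jackknife pseudo-values

    theta~_ik = n * theta^_k - (n - 1) * theta^_k(i),

where theta^_k(i) is the degree recomputed with subject i removed.  The
pseudo-values behave asymptotically like i.i.d. observations with mean
theta_k and can be regressed on covariates.  Pseudo-values are computed
within each group separately (group-specific sample size and estimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .data import AbundanceTable
from .sparcc import AssociationMatrix, sparcc_correlation

__all__ = [
    "DegreeVector",
    "PseudoValueMatrix",
    "degree_centrality",
    "jackknife_pseudovalues",
    "paired_difference_association",
]


@dataclass
class DegreeVector:
    theta: np.ndarray
    taxon_ids: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.taxon_ids is None:
            self.taxon_ids = [f"T{j}" for j in range(self.theta.size)]


@dataclass
class PseudoValueMatrix:
    """n x p matrix of jackknife pseudo-values (rows follow input samples)."""

    pv: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    group_of_sample: np.ndarray = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.pv, index=self.sample_ids,
                            columns=self.taxon_ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().rename_axis("sample_id").to_csv(path, sep="\t")


def degree_centrality(assoc: AssociationMatrix | np.ndarray) -> DegreeVector:
    """Marginal sum of the association matrix per taxon.

    The unit diagonal is included in the sum; it contributes the same
    constant to every taxon and therefore moves only the intercept of any
    downstream regression, never the group coefficient.
    """
    if isinstance(assoc, AssociationMatrix):
        rho, ids = assoc.rho, assoc.taxon_ids
    else:
        rho, ids = np.asarray(assoc, dtype=float), None
    return DegreeVector(rho.sum(axis=0), ids)


def _as_theta(result) -> np.ndarray:
    if isinstance(result, DegreeVector):
        return result.theta
    if isinstance(result, AssociationMatrix):
        return degree_centrality(result).theta
    return np.asarray(result, dtype=float)


def jackknife_pseudovalues(
    table: AbundanceTable,
    estimator: Callable[[AbundanceTable], "DegreeVector | np.ndarray"] = None,
    n_jobs: int = 1,
) -> PseudoValueMatrix:
    """Leave-one-out jackknife pseudo-values of a per-taxon statistic.

    Invokes ``estimator`` once on the full table and once per leave-one-out
    subtable (n + 1 invocations in total) and forms
    ``pv[i] = n * theta_full - (n - 1) * theta_without_i``.

    Parameters
    ----------
    table : AbundanceTable
        Samples of one group (the caller is responsible for the group
        split); needs at least 5 samples so each subtable is estimable.
    estimator : callable, optional
        Maps an AbundanceTable to a DegreeVector (or a plain vector).
        Defaults to SparCC degree centrality.
    n_jobs : int
        Workers for the leave-one-out loop.  Results are ordered by sample
        position, so the output is identical for any worker count.
    """
    if estimator is None:
        estimator = lambda tab: degree_centrality(sparcc_correlation(tab))
    n = table.n_samples
    if n < 5:
        raise ValueError("need at least 5 samples per group for the jackknife")
    theta_full = _as_theta(estimator(table))

    def loo(i: int) -> np.ndarray:
        try:
            return _as_theta(estimator(table.drop_sample(i)))
        except Exception as exc:
            raise RuntimeError(
                f"estimator failed on leave-one-out subtable without "
                f"sample {table.sample_ids[i]!r}") from exc

    if n_jobs == 1:
        loos = [loo(i) for i in range(n)]
    else:
        loos = Parallel(n_jobs=n_jobs)(delayed(loo)(i) for i in range(n))
    theta_loo = np.vstack(loos)
    pv = n * theta_full[None, :] - (n - 1) * theta_loo
    return PseudoValueMatrix(pv, list(table.sample_ids), list(table.taxon_ids))


def paired_difference_association(
    table_t1: AbundanceTable,
    table_t2: AbundanceTable,
    **sparcc_opts,
) -> np.ndarray:
    """Difference of association matrices between two time points.

    For paired designs (same subjects sampled before and after an
    intervention) the analysed network statistic is A(t2) - A(t1), whose
    degree captures the temporal change of each taxon's connectivity.
    """
    if table_t1.sample_ids != table_t2.sample_ids:
        raise ValueError("time points must share the same samples in order")
    if table_t1.taxon_ids != table_t2.taxon_ids:
        raise ValueError("time points must share the same taxa")
    a1 = sparcc_correlation(table_t1, **sparcc_opts)
    a2 = sparcc_correlation(table_t2, **sparcc_opts)
    return a2.rho - a1.rho


def paired_degree_estimator(exclusion_pairs_t1=None, exclusion_pairs_t2=None,
                            **sparcc_opts) -> Callable:
    """Estimator for the temporal mode, usable with jackknife_pseudovalues.

    Operates on a "stacked" table whose first half of columns is time 1 and
    second half time 2 (see :func:`stack_timepoints`); leave-one-out then
    removes the subject from both time points jointly.  Frozen SparCC
    exclusion pairs may be supplied per time point.
    """

    def estimate(stacked: AbundanceTable) -> DegreeVector:
        p = stacked.n_taxa // 2
        t1 = stacked.subset_taxa(range(p))
        t2 = stacked.subset_taxa(range(p, 2 * p))
        t2.taxon_ids = list(t1.taxon_ids)
        a1 = sparcc_correlation(t1, exclusion_pairs=exclusion_pairs_t1,
                                **sparcc_opts)
        a2 = sparcc_correlation(t2, exclusion_pairs=exclusion_pairs_t2,
                                **sparcc_opts)
        diff = a2.rho - a1.rho
        return DegreeVector(diff.sum(axis=0), list(t1.taxon_ids))

    return estimate


def stack_timepoints(table_t1: AbundanceTable,
                     table_t2: AbundanceTable) -> AbundanceTable:
    """Column-concatenate two matched time points into one table."""
    if table_t1.sample_ids != table_t2.sample_ids:
        raise ValueError("time points must share the same samples in order")
    if table_t1.taxon_ids != table_t2.taxon_ids:
        raise ValueError("time points must share the same taxa")
    counts = np.hstack([table_t1.counts, table_t2.counts])
    ids = [f"{t}@t1" for t in table_t1.taxon_ids] + \
          [f"{t}@t2" for t in table_t2.taxon_ids]
    return AbundanceTable(counts, list(table_t1.sample_ids), ids)
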