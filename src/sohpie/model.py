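"""Covariate-adjusted differential network model (SOHPIE-DNA).

The model asks, per taxon, whether network degree centrality differs
between two groups after adjusting for clinical covariates.  Degree is
computed from a SparCC compositional co-abundance network estimated per
group; leave-one-out jackknife pseudo-values turn the group-level degree
into subject-level responses

    E[theta~_ik | Z_i, X_i] = alpha_k + beta_k Z_i + sum_m gamma_km X_im,

fitted robustly by least trimmed squares.  beta_k is the group difference
in centrality for taxon k; H0: beta_k = 0 is tested with a t-statistic and
the p taxa are corrected by q-values.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from .data import AbundanceTable
from .pseudovalues import (
    degree_centrality,
    jackknife_pseudovalues,
    paired_degree_estimator,
    stack_timepoints,
)
from .robust import LtsConfig, lts_fit, qvalues, test_beta
from .sparcc import sparcc_correlation, sparcc_exclusion_pairs

__all__ = ["SOHPIE", "SOHPIEResults", "sohpie_dna"]


def _build_design(metadata: pd.DataFrame, group: str, covariates):
    """Design matrix: intercept, 0/1 group code, covariate columns.

    Categorical covariates are expanded to reference-coded indicators with
    the lexicographically first level as reference.  Rows with missing
    group or covariate values are not tolerated here (callers drop and
    report them); an informative error lists the offending samples.
    """
    cols = [group] + list(covariates)
    missing_cols = [c for c in cols if c not in metadata.columns]
    if missing_cols:
        raise KeyError(f"metadata is missing columns {missing_cols}")
    sub = metadata[cols]
    bad = sub.index[sub.isna().any(axis=1)]
    if len(bad):
        raise ValueError(
            f"missing group/covariate values for samples {list(bad)}; "
            "drop them before fitting (no imputation is performed)")

    levels = sorted(pd.unique(sub[group]).tolist(), key=str)
    if len(levels) != 2:
        raise ValueError(
            f"group column {group!r} must have exactly 2 levels, "
            f"found {levels}")
    z = (sub[group] == levels[1]).to_numpy(dtype=float)

    pieces = [pd.Series(1.0, index=sub.index, name="intercept"),
              pd.Series(z, index=sub.index, name=f"{group}[{levels[1]}]")]
    for c in covariates:
        col = sub[c]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
                col.dtype, pd.CategoricalDtype):
            pieces.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=c, dtype=float)
            dummies = dummies[sorted(dummies.columns)]
            pieces.append(dummies.iloc[:, 1:])  # drop reference level
    design = pd.concat(pieces, axis=1)
    return design, levels


class SOHPIE:
    """Differential co-abundance network model for a two-group comparison.

    Parameters
    ----------
    counts : AbundanceTable or DataFrame
        Samples x taxa non-negative counts (DataFrame indexed by sample).
    metadata : DataFrame
        Indexed by sample ID; must contain ``group`` and the covariates.
    group : str
        Binary group column; the lexicographically larger level is coded 1.
    covariates : sequence of str
        Clinical adjustment variables (numeric used as-is, categorical
        dummy-coded against the first level).
    counts_t2 : AbundanceTable or DataFrame, optional
        Second time point for the paired/temporal mode: the analysed
        statistic becomes the degree of A(t2) - A(t1), the change in
        connectivity, and leave-one-out removes a subject from both time
        points jointly.
    alpha : float
        q-value threshold used for the differential-connectivity flag.
    pseudocount, exclusion_threshold, max_exclusion_iters :
        SparCC network options.
    lts : LtsConfig, optional
        Trimming configuration for the robust per-taxon regression.
    absolute_degree : bool
        Sum |rho| instead of signed correlations (sensitivity analysis).

    Examples
    --------
    >>> model = SOHPIE(counts, metadata, group="status", covariates=["age"])
    >>> res = model.fit(seed=1)
    >>> res.summary()
    """

    def __init__(
        self,
        counts,
        metadata: pd.DataFrame,
        group: str,
        covariates=(),
        counts_t2=None,
        alpha: float = 0.05,
        pseudocount: float = 0.5,
        exclusion_threshold: float = 0.1,
        max_exclusion_iters: int = 10,
        lts: LtsConfig | None = None,
        absolute_degree: bool = False,
        freeze_exclusions: bool = False,
    ):
        if isinstance(counts, pd.DataFrame):
            counts = AbundanceTable.from_dataframe(counts)
        self.counts = counts
        if counts_t2 is not None and isinstance(counts_t2, pd.DataFrame):
            counts_t2 = AbundanceTable.from_dataframe(counts_t2)
        self.counts_t2 = counts_t2
        self.metadata = metadata.loc[counts.sample_ids]
        self.group = group
        self.covariates = list(covariates)
        self.alpha = float(alpha)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.network_opts = dict(
            pseudocount=pseudocount,
            exclusion_threshold=exclusion_threshold,
            max_exclusion_iters=max_exclusion_iters,
        )
        self.lts = lts if lts is not None else LtsConfig()
        self.absolute_degree = absolute_degree
        self.freeze_exclusions = freeze_exclusions
        self.design, self.group_levels = _build_design(
            self.metadata, group, self.covariates)
        if self.design.shape[0] <= self.design.shape[1] + 1:
            raise ValueError("too few samples for the design matrix")

    # ------------------------------------------------------------------
    def _group_estimator(self, group_table: AbundanceTable):
        """Degree estimator for one group's (possibly stacked) table.

        By default the SparCC sparsity refinement re-selects its excluded
        pairs inside every leave-one-out re-estimate, exactly as when the
        estimator is run stand-alone.  With ``freeze_exclusions`` the
        adaptive choice is made once on the full group sample and replayed
        for each deletion, so the jackknife differentiates a single smooth
        functional (see :func:`sohpie.sparcc.sparcc_exclusion_pairs`).
        """
        opts = self.network_opts
        if self.counts_t2 is not None:
            kw = {}
            if self.freeze_exclusions:
                p = group_table.n_taxa // 2
                t1 = group_table.subset_taxa(range(p))
                t2 = group_table.subset_taxa(range(p, 2 * p))
                kw = dict(
                    exclusion_pairs_t1=sparcc_exclusion_pairs(t1, **opts),
                    exclusion_pairs_t2=sparcc_exclusion_pairs(t2, **opts))
            return paired_degree_estimator(**kw, **opts)

        pairs = (sparcc_exclusion_pairs(group_table, **opts)
                 if self.freeze_exclusions else None)

        def estimate(tab):
            assoc = sparcc_correlation(tab, exclusion_pairs=pairs, **opts)
            rho = np.abs(assoc.rho) if self.absolute_degree else assoc.rho
            return degree_centrality(rho)

        return estimate

    def _analysis_table(self) -> AbundanceTable:
        if self.counts_t2 is None:
            return self.counts
        return stack_timepoints(self.counts, self.counts_t2)

    def fit(self, seed: int = 0, n_jobs: int = 1) -> "SOHPIEResults":
        """Run the full pipeline and return per-taxon inference.

        Steps: split samples by group; per group estimate the association
        matrix plus its n_z leave-one-out re-estimates and form jackknife
        pseudo-values; stack the groups; LTS-regress each taxon's
        pseudo-values on intercept + group + covariates; t-test the group
        coefficient; q-values across taxa.  Deterministic given ``seed``.
        """
        z = self.design.iloc[:, 1].to_numpy()
        table = self._analysis_table()
        pv_rows = np.empty((table.n_samples, self.counts.n_taxa))
        group_code = np.where(z == 0, 1, 2)
        for gz in (0.0, 1.0):
            mask = z == gz
            if mask.sum() < 5:
                raise ValueError("each group needs at least 5 samples")
            sub = table.subset_samples(mask)
            pv = jackknife_pseudovalues(sub, self._group_estimator(sub),
                                        n_jobs=n_jobs)
            pv_rows[mask] = pv.pv
        X = self.design.to_numpy(dtype=float)
        names = list(self.design.columns)

        rows = []
        gammas = np.empty((self.counts.n_taxa, X.shape[1] - 2))
        ss = np.random.SeedSequence(seed)
        taxon_seeds = ss.generate_state(self.counts.n_taxa)
        for k in range(self.counts.n_taxa):
            coef, se, df = lts_fit(pv_rows[:, k], X, self.lts,
                                   seed=int(taxon_seeds[k] % (2**31)),
                                   column_names=names)
            U, pval = test_beta(coef[1], se[1], df)
            rows.append((coef[1], se[1], U, pval, coef[0]))
            gammas[k] = coef[2:]
        res = pd.DataFrame(
            rows, columns=["beta", "se", "t", "p", "alpha_hat"],
            index=pd.Index(self.counts.taxon_ids, name="taxon_id"))
        res["q"] = qvalues(res["p"].to_numpy())
        res["dc"] = (res["q"] < self.alpha).astype(int)
        for j, name in enumerate(names[2:]):
            res[f"gamma[{name}]"] = gammas[:, j]
        pvmat = pd.DataFrame(pv_rows, index=self.counts.sample_ids,
                             columns=self.counts.taxon_ids)
        return SOHPIEResults(self, res, pvmat, group_code, seed)


class SOHPIEResults:
    """Per-taxon estimates, tests and FDR flags from a fitted model.

    Attributes
    ----------
    table : DataFrame
        One row per taxon: beta (group effect on degree centrality), se,
        t, p, q, dc flag, intercept and covariate coefficients.
    pseudovalues : DataFrame
        The stacked n x p jackknife pseudo-value response.
    """

    def __init__(self, model: SOHPIE, table: pd.DataFrame,
                 pseudovalues: pd.DataFrame, group_code: np.ndarray,
                 seed: int):
        self.model = model
        self.table = table
        self.pseudovalues = pseudovalues
        self.group_code = group_code
        self.seed = seed

    @property
    def dc_taxa(self) -> list[str]:
        """Taxa flagged as differentially connected at q < alpha."""
        return list(self.table.index[self.table["dc"] == 1])

    @property
    def n_dc(self) -> int:
        return int(self.table["dc"].sum())

    def summary(self) -> str:
        m = self.model
        lines = [
            "Differential co-abundance network analysis (pseudo-value regression)",
            "=" * 68,
            f"Taxa: {m.counts.n_taxa}    Samples: {m.counts.n_samples} "
            f"(group {m.group_levels[0]}: {int((self.group_code == 1).sum())}, "
            f"group {m.group_levels[1]}: {int((self.group_code == 2).sum())})",
            f"Covariates: {', '.join(m.covariates) if m.covariates else 'none'}",
            f"Mode: {'paired two-time-point' if m.counts_t2 is not None else 'single time point'}",
            f"DC taxa at q < {m.alpha:g}: {self.n_dc}",
            "-" * 68,
        ]
        cols = ["beta", "se", "t", "p", "q", "dc"]
        tab = self.table.sort_values("q")[cols]
        lines.append(tab.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)

    def to_tsv(self, path, config_sidecar: bool = True) -> None:
        """Write the result table (sorted by q) plus a JSON config echo."""
        out = self.table.sort_values("q")
        out.to_csv(path, sep="\t")
        if config_sidecar:
            m = self.model
            cfg = {
                "group": m.group,
                "group_levels": [str(l) for l in m.group_levels],
                "covariates": m.covariates,
                "alpha": m.alpha,
                "network": m.network_opts,
                "lts": asdict(m.lts),
                "absolute_degree": m.absolute_degree,
                "paired": m.counts_t2 is not None,
                "seed": self.seed,
            }
            with open(str(path) + ".config.json", "w") as fh:
                json.dump(cfg, fh, indent=1)


def sohpie_dna(
    table,
    metadata,
    group_col: str,
    covariate_cols=(),
    alpha: float = 0.05,
    network_opts: dict | None = None,
    lts_opts: LtsConfig | dict | None = None,
    seed: int = 0,
    table_t2=None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Functional one-call interface; returns the per-taxon result table."""
    network_opts = network_opts or {}
    if isinstance(lts_opts, dict):
        lts_opts = LtsConfig(**lts_opts)
    model = SOHPIE(table, metadata, group_col, covariate_cols,
                   counts_t2=table_t2, alpha=alpha, lts=lts_opts,
                   **network_opts)
    return model.fit(seed=seed, n_jobs=n_jobs).table
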