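"""Core data container for taxa count tables.

Microbiome sequencing yields, per sample, non-negative read counts over a
set of taxa (OTUs/ASVs).  Counts are compositional: only relative
information is meaningful, which is why downstream correlation estimation
works on log-ratios of per-sample fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable", "to_fractions"]


@dataclass
class AbundanceTable:
    """A samples x taxa table of non-negative counts.

    Parameters
    ----------
    counts : ndarray, shape (n_samples, n_taxa)
        Non-negative counts (floats are accepted but must be >= 0).
    sample_ids, taxon_ids : sequences of str
        Unique identifiers for rows and columns.
    """

    counts: np.ndarray
    sample_ids: list[str] = field(default=None)
    taxon_ids: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x taxa matrix")
        n, p = self.counts.shape
        if self.sample_ids is None:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if self.taxon_ids is None:
            self.taxon_ids = [f"T{j}" for j in range(p)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match counts")
        if len(self.taxon_ids) != p:
            raise ValueError("taxon_ids length does not match counts")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.taxon_ids)) != p:
            raise ValueError("duplicate taxon identifiers")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, index) -> "AbundanceTable":
        """Return a new table restricted to the given sample positions."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return AbundanceTable(
            self.counts[index],
            [self.sample_ids[i] for i in index],
            list(self.taxon_ids),
        )

    def drop_sample(self, i: int) -> "AbundanceTable":
        """Leave-one-out deletion of sample at position ``i``."""
        keep = [k for k in range(self.n_samples) if k != i]
        return self.subset_samples(keep)

    def subset_taxa(self, index) -> "AbundanceTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return AbundanceTable(
            self.counts[:, index],
            list(self.sample_ids),
            [self.taxon_ids[j] for j in index],
        )

    # ---- pandas / TSV round trips -------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceTable":
        """Build from a DataFrame indexed by sample ID with taxon columns."""
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids,
                            columns=self.taxon_ids)

    @classmethod
    def read_tsv(cls, path) -> "AbundanceTable":
        """Read a TSV whose first column holds sample IDs, header taxon IDs."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_dataframe(df)

    def write_tsv(self, path) -> None:
        self.to_dataframe().rename_axis("sample_id").to_csv(path, sep="\t")


def to_fractions(table, pseudocount: float = 0.5) -> np.ndarray:
    """Convert counts to per-sample fractions (relative abundances).

    A constant pseudocount is added to every cell before normalisation so
    that log-ratios are finite in the presence of sampling zeros.  With
    ``pseudocount=0`` the input must contain no all-zero sample, and rows
    containing zeros will yield zero fractions.

    Parameters
    ----------
    table : AbundanceTable or ndarray
    pseudocount : float
        Added to each count; must be > 0 whenever the table contains zeros
        that will later be log-transformed.

    Returns
    -------
    ndarray, shape (n, p)
        Each row sums to one.
    """
    counts = table.counts if isinstance(table, AbundanceTable) else np.asarray(table, dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    shifted = counts + pseudocount
    row_sums = shifted.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise ValueError("degenerate sample: all-zero row with pseudocount 0")
    return shifted / row_sums
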