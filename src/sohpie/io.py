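"""Reading, aligning and filtering count/metadata tables from TSV files."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .data import AbundanceTable

__all__ = ["AlignmentReport", "load_and_align", "read_metadata"]


@dataclass
class AlignmentReport:
    """What was dropped while aligning counts with metadata."""

    n_samples_in: int = 0
    n_samples_kept: int = 0
    n_taxa_in: int = 0
    n_taxa_kept: int = 0
    dropped_missing: list = field(default_factory=list)
    dropped_unmatched: list = field(default_factory=list)
    dropped_taxa: list = field(default_factory=list)
    transposed: bool = False


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col=0)
    md.index = md.index.astype(str)
    if md.index.duplicated().any():
        dups = md.index[md.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample identifiers in metadata: {dups}")
    return md


def load_and_align(
    counts_path,
    metadata_path,
    group: str,
    covariates=(),
    prevalence_threshold: float = 0.0,
):
    """Load a counts TSV and metadata TSV and align them on sample ID.

    Inner-joins on sample identifiers, drops (and reports) samples with
    missing group or covariate values, and applies a rare-taxon prevalence
    filter: a taxon is kept iff it is nonzero in at least
    ``prevalence_threshold`` fraction of the retained samples.  Counts in
    taxa-major orientation (rows = taxa) are auto-detected by identifier
    overlap with the metadata and transposed with a warning.

    Returns
    -------
    (AbundanceTable, metadata DataFrame, AlignmentReport)
    """
    if not 0 <= prevalence_threshold < 1:
        raise ValueError("prevalence threshold must lie in [0, 1)")
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    md = read_metadata(metadata_path)
    for c in [group, *covariates]:
        if c not in md.columns:
            raise KeyError(f"metadata is missing column {c!r}")

    report = AlignmentReport()
    row_overlap = len(set(df.index) & set(md.index))
    col_overlap = len(set(df.columns) & set(md.index))
    if col_overlap > row_overlap:
        warnings.warn("counts appear taxa-major (rows = taxa); transposing",
                      UserWarning, stacklevel=2)
        df = df.T
        report.transposed = True
    if df.index.duplicated().any():
        raise ValueError("duplicate sample identifiers in counts")
    report.n_samples_in, report.n_taxa_in = df.shape

    shared = [s for s in df.index if s in md.index]
    if not shared:
        raise ValueError("no overlapping samples between counts and metadata")
    report.dropped_unmatched = sorted(
        set(df.index).symmetric_difference(md.index))
    df = df.loc[shared]
    md = md.loc[shared]

    needed = md[[group, *covariates]]
    missing = needed.index[needed.isna().any(axis=1)].tolist()
    if missing:
        report.dropped_missing = missing
        keep = ~needed.index.isin(missing)
        df, md = df.loc[keep], md.loc[keep]

    prevalence = (df > 0).mean(axis=0)
    kept_taxa = prevalence[prevalence >= prevalence_threshold].index
    report.dropped_taxa = [t for t in df.columns if t not in set(kept_taxa)]
    df = df[kept_taxa]

    report.n_samples_kept, report.n_taxa_kept = df.shape
    return AbundanceTable.from_dataframe(df), md, report
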