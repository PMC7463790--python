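"""Post-quantification filtering of cell-free-RNA count tables.

Consumes a ready gene x sample read-count table (HTSeq-count style) and
applies, in order: (1) exclusion of a listed set of gene biotypes that
are uninformative for the cell-free mRNA analysis (immunoglobulin and
T-cell-receptor segments, small/structural RNA classes, artifacts);
(2) removal of genes whose summed counts over all samples fall below a
minimum (default 3); (3) a presence call on a pooled sample at a read
threshold (default 49 reads, with >= 49 counted as present).  A simple
abundance histogram (genes per read-count bin) supports the classic
long-tail picture of cell-free saliva RNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Annotation columns; everything else in a count table is a sample.
ANNOTATION_COLUMNS = ("gene_id", "symbol", "biotype")

#: Gene-biotype classes excluded before presence analysis.
DEFAULT_EXCLUDED_BIOTYPES = frozenset(
    {
        "IG",
        "TR",
        "artifact",
        "miRNA",
        "Mt_rRNA",
        "Mt_tRNA",
        "ncRNA",
        "piRNA",
        "pre-miRNA",
        "rRNA",
        "ribozyme",
        "sRNA",
        "scRNA",
        "scaRNA",
        "siRNA",
        "snRNA",
        "snoRNA",
        "tRNA",
        "vaultRNA",
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the count-filtering pipeline."""

    excluded_biotypes: frozenset[str] = DEFAULT_EXCLUDED_BIOTYPES
    min_total_counts: int = 3
    presence_threshold: int = 49

    def __post_init__(self) -> None:
        if self.min_total_counts < 0 or self.presence_threshold < 0:
            raise ValueError("thresholds must be >= 0")


def sample_columns(table: pd.DataFrame) -> list[str]:
    """Names of the count columns (everything except annotation)."""
    cols = [c for c in table.columns if c not in ANNOTATION_COLUMNS]
    if not cols:
        raise ValueError("count table has no sample columns")
    return cols


def _validate(table: pd.DataFrame) -> None:
    if "gene_id" not in table.columns:
        raise ValueError("count table must have a 'gene_id' column")
    if table["gene_id"].duplicated().any():
        raise ValueError("gene_ids must be unique")
    counts = table[sample_columns(table)]
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("sample columns must be numeric")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")


def exclude_biotypes(
    table: pd.DataFrame,
    excluded: frozenset[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Drop genes whose biotype is in the excluded set.

    Genes with a missing biotype annotation are retained with a warning
    — exclusion is by listed class only.
    """
    _validate(table)
    if "biotype" not in table.columns:
        raise ValueError("count table has no 'biotype' column")
    if excluded is None:
        excluded = DEFAULT_EXCLUDED_BIOTYPES
    biotype = table["biotype"]
    missing = biotype.isna() | (biotype.astype(str).str.strip() == "")
    if missing.any():
        logger.warning(
            "%d gene(s) lack a biotype annotation and are retained", int(missing.sum())
        )
    drop = biotype.isin(excluded) & ~missing
    logger.info("excluding %d gene(s) by biotype", int(drop.sum()))
    return table[~drop].reset_index(drop=True)


def filter_low_counts(table: pd.DataFrame, min_total: int = 3) -> pd.DataFrame:
    """Drop genes whose summed counts over all samples are below ``min_total``."""
    _validate(table)
    totals = table[sample_columns(table)].sum(axis=1)
    keep = totals >= min_total
    logger.info("removing %d low-count gene(s)", int((~keep).sum()))
    return table[keep].reset_index(drop=True)


def call_present(
    table: pd.DataFrame,
    threshold: int = 49,
    sample: str | None = None,
) -> pd.Index:
    """Gene ids whose count in the designated sample is >= ``threshold``.

    With a single count column (the pooled-library case) the sample is
    inferred; otherwise it must be named.  The boundary convention is
    inclusive: a gene at exactly the threshold is present.
    """
    _validate(table)
    cols = sample_columns(table)
    if sample is None:
        if len(cols) != 1:
            raise ValueError(
                f"table has {len(cols)} sample columns; name one via sample="
            )
        sample = cols[0]
    elif sample not in cols:
        raise ValueError(f"no sample column {sample!r}")
    mask = table[sample] >= threshold
    return pd.Index(table.loc[mask, "gene_id"])


def abundance_histogram(
    table: pd.DataFrame,
    bin_edges,
    sample: str | None = None,
) -> np.ndarray:
    """Number of genes per read-count bin; bins are half-open [lo, hi).

    The last bin is extended to +inf so the histogram mass always equals
    the number of genes.
    """
    _validate(table)
    if table.empty:
        raise ValueError("count table is empty")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    cols = sample_columns(table)
    if sample is None:
        if len(cols) != 1:
            raise ValueError(
                f"table has {len(cols)} sample columns; name one via sample="
            )
        sample = cols[0]
    counts = table[sample].to_numpy(dtype=float)
    work = np.append(edges, np.inf)
    hist, _ = np.histogram(counts, bins=work)
    # fold the below-range and overflow genes into the first/last bin
    below = np.sum(counts < edges[0])
    hist[0] += below
    out = hist[: edges.size - 1].copy()
    out[-1] += hist[edges.size - 1]
    return out


def apply_filters(
    table: pd.DataFrame,
    config: FilterConfig | None = None,
    sample: str | None = None,
) -> tuple[pd.DataFrame, pd.Index, dict]:
    """Biotype exclusion, then low-count filter, then presence call.

    Returns the filtered table, the present-gene index, and a stage log
    of row counts.
    """
    config = config or FilterConfig()
    n0 = len(table)
    t1 = exclude_biotypes(table, config.excluded_biotypes)
    t2 = filter_low_counts(t1, config.min_total_counts)
    present = call_present(t2, config.presence_threshold, sample)
    log = {
        "input_genes": n0,
        "after_biotype_exclusion": len(t1),
        "after_low_count_filter": len(t2),
        "present_genes": len(present),
    }
    return t2, present, log


def read_count_matrix(path) -> pd.DataFrame:
    """Read a merged TSV count matrix with annotation columns."""
    table = pd.read_csv(path, sep="\t")
    _validate(table)
    return table


def read_htseq_counts(paths, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge HTSeq-count two-column outputs into one count table.

    Each file has ``gene_id<TAB>count`` rows; HTSeq's special ``__*``
    summary rows are dropped.  Sample names come from the file stems.
    An optional annotation frame (gene_id, symbol, biotype) is joined.
    """
    import pathlib

    frames = []
    for p in paths:
        p = pathlib.Path(p)
        df = pd.read_csv(p, sep="\t", header=None, names=["gene_id", p.stem])
        df = df[~df["gene_id"].astype(str).str.startswith("__")]
        frames.append(df.set_index("gene_id"))
    merged = pd.concat(frames, axis=1).fillna(0).astype(int).reset_index()
    if annotation is not None:
        merged = annotation.merge(merged, on="gene_id", how="right")
    _validate(merged)
    return merged


def write_count_matrix(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def plot_abundance_histogram(table: pd.DataFrame, bin_edges, sample: str | None = None, ax=None):
    """Bar plot of genes per read-count bin (matplotlib Axes returned)."""
    import matplotlib.pyplot as plt

    hist = abundance_histogram(table, bin_edges, sample)
    edges = np.asarray(bin_edges, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    labels = [f"[{int(lo)}, {int(hi)})" for lo, hi in zip(edges[:-1], edges[1:])]
    ax.bar(range(len(hist)), hist, tick_label=labels)
    ax.set_xlabel("reads per gene")
    ax.set_ylabel("number of genes")
    ax.tick_params(axis="x", rotation=45)
    return ax
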