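"""Abundance-table I/O and downstream filtering.

The canonical on-disk format is the merged taxonomic-profile table produced
by abundance estimators such as Bracken: one tab-separated file with a
taxon-lineage column followed by one numeric column per sample.  City labels
travel in a separate two-column CSV (``sample_id,city``).

After profiling, low-evidence taxa are removed in two passes — a prevalence
filter (taxa seen in too few samples) followed by a total-count filter — and
the surviving counts are renormalised to per-sample relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyResultError, ParseError

logger = logging.getLogger(__name__)

LINEAGE_COLUMN = "lineage"


@dataclass
class LabeledAbundanceTable:
    """Sample x taxon abundance matrix with lineages and optional city labels.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers (rows).
    taxon_ids : list of str
        Unique taxon identifiers (columns); by convention the terminal rank
        of the lineage string.
    lineages : list of str
        Rank-delimited taxonomy strings, one per taxon.
    values : ndarray of shape (n_samples, n_taxa)
        Nonnegative counts or relative abundances.
    mode : {"counts", "relative"}
        In ``relative`` mode every row sums to 1 (within 1e-9).
    labels : list of (str or None), optional
        City label per sample; ``None`` marks an unlabeled sample.
    """

    sample_ids: list
    taxon_ids: list
    lineages: list
    values: np.ndarray
    mode: str = "counts"
    labels: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != p:
            raise ValueError("matrix shape does not match id lists")
        if len(self.lineages) != p:
            raise ValueError("one lineage required per taxon")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.taxon_ids)) != p:
            raise ValueError("taxon_ids must be unique")
        if np.any(self.values < 0):
            raise ValueError("abundance values must be nonnegative")
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "relative":
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.sample_ids[int(np.argmax(np.abs(sums - 1.0)))]
                raise ValueError(f"relative-mode row {bad!r} does not sum to 1")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("one label required per sample")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("table carries no labels")
        return np.asarray(self.labels, dtype=object)

    def to_dataframe(self) -> pd.DataFrame:
        """Samples x taxa DataFrame (taxon ids as columns)."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def subset_samples(self, indices) -> "LabeledAbundanceTable":
        indices = np.asarray(indices)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in indices],
            values=self.values[indices],
            labels=None if self.labels is None else [self.labels[i] for i in indices],
        )


def write_table(table: LabeledAbundanceTable, path, label_map_path=None) -> None:
    """Write the merged-TSV dialect (lineage column + one column per sample).

    The matrix is stored transposed on disk — taxa as rows — matching the
    merged profiler output the reader consumes.  Labels, when present and
    requested, go to a separate ``sample_id,city`` CSV.
    """
    df = pd.DataFrame(
        table.values.T, index=pd.Index(table.lineages, name=LINEAGE_COLUMN),
        columns=table.sample_ids,
    )
    df.to_csv(path, sep="\t")
    if label_map_path is not None:
        if table.labels is None:
            raise ValueError("table carries no labels to write")
        pd.DataFrame({"sample_id": table.sample_ids, "city": table.labels}).to_csv(
            label_map_path, index=False
        )


def read_table(path, label_map_path=None, mode: str | None = None) -> LabeledAbundanceTable:
    """Read a merged abundance TSV and an optional sample->city label CSV.

    Mode is auto-detected: if every sample column sums to 1 (within 1e-6) the
    table is taken as relative abundances, otherwise as counts.  Pass
    ``mode`` to override.  Samples missing from the label map get a null
    label.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse abundance table {path}: {exc}") from exc
    if df.shape[1] < 1:
        raise ParseError(f"{path}: need at least one sample column")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[int(coerced.isna().argmax())]
                raise ParseError(f"{path}: malformed numeric cell at taxon {row!r}, sample {col!r}")
            df[col] = coerced
    if (df.values < 0).any():
        i, j = np.argwhere(df.values < 0)[0]
        raise ParseError(f"{path}: negative value at taxon {df.index[i]!r}, sample {df.columns[j]!r}")
    if df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate sample id {df.columns[df.columns.duplicated()][0]!r}")
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate taxon lineage {df.index[df.index.duplicated()][0]!r}")

    lineages = [str(x) for x in df.index]
    taxon_ids = _terminal_ranks(lineages, path)
    values = df.values.T.astype(float)  # -> samples x taxa
    if mode is None:
        sums = values.sum(axis=1)
        mode = "relative" if np.allclose(sums, 1.0, atol=1e-6) else "counts"

    labels = None
    if label_map_path is not None:
        lm = pd.read_csv(label_map_path)
        if not {"sample_id", "city"} <= set(lm.columns):
            raise ParseError(f"{label_map_path}: expected columns sample_id,city")
        mapping = dict(zip(lm["sample_id"].astype(str), lm["city"].astype(str)))
        labels = [mapping.get(str(s)) for s in df.columns]
        missing = [s for s, l in zip(df.columns, labels) if l is None]
        if missing:
            logger.warning("%d samples absent from label map (null label)", len(missing))

    return LabeledAbundanceTable(
        sample_ids=[str(c) for c in df.columns],
        taxon_ids=taxon_ids,
        lineages=lineages,
        values=values,
        mode=mode,
        labels=labels,
    )


def _terminal_ranks(lineages, path) -> list:
    ids = [lin.split("|")[-1].split(";")[-1].strip() for lin in lineages]
    if len(set(ids)) != len(ids):
        # fall back to full lineages, which read_table already checked unique
        ids = list(lineages)
    return ids


def filter_and_renormalize(
    table: LabeledAbundanceTable,
    min_prevalence: float = 0.01,
    min_total_reads: int = 10,
    per_sample_reads: bool = False,
) -> LabeledAbundanceTable:
    """Drop low-evidence taxa, then renormalise rows to relative abundances.

    Two sequential filters on a counts-mode table:

    1. prevalence — taxa with nonzero counts in fewer than ``min_prevalence``
       of all samples are removed (strict less-than);
    2. read count — taxa whose count total falls below ``min_total_reads``
       are removed.  The total is summed over all samples by default; with
       ``per_sample_reads`` a taxon survives only if some single sample
       reaches the threshold.

    Samples left with an all-zero row are dropped with a warning.  The result
    is in relative mode (rows sum to 1).
    """
    if table.mode != "counts":
        raise ValueError("filtering operates on a counts-mode table")
    X = table.values
    n = table.n_samples
    prevalence = (X > 0).sum(axis=0) / n
    keep = prevalence >= min_prevalence
    if per_sample_reads:
        keep &= X.max(axis=0) >= min_total_reads
    else:
        keep &= X.sum(axis=0) >= min_total_reads
    if not keep.any():
        raise EmptyResultError("all taxa removed by filtering")
    kept_idx = np.flatnonzero(keep)
    X = X[:, kept_idx]

    row_sums = X.sum(axis=1)
    alive = row_sums > 0
    if not alive.all():
        dropped = [table.sample_ids[i] for i in np.flatnonzero(~alive)]
        logger.warning("dropping %d all-zero samples after filtering: %s", len(dropped), dropped)
    X = X[alive]
    rel = X / X.sum(axis=1, keepdims=True)
    return LabeledAbundanceTable(
        sample_ids=[s for s, a in zip(table.sample_ids, alive) if a],
        taxon_ids=[table.taxon_ids[j] for j in kept_idx],
        lineages=[table.lineages[j] for j in kept_idx],
        values=rel,
        mode="relative",
        labels=None
        if table.labels is None
        else [l for l, a in zip(table.labels, alive) if a],
    )
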