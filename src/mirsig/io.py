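"""Count-matrix I/O, housekeeping normalization and background annotation.

The on-disk dialect is a pair of CSV files (UTF-8, LF line endings):

* counts: ``probe_id,probe_class,annotated_mirnas,<sample_1>,...`` with
  ``annotated_mirnas`` semicolon-separated and counts as plain integers;
* sample metadata: ``sample_id,patient_id,tissue_class``.

Normalization rescales each sample so the geometric mean of the housekeeping
probes is constant across samples, the convention used by nSolver-style
processing of nCounter data.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DataError,
    DegenerateInputError,
    DomainError,
    FormatError,
)

PROBE_CLASSES = ("endogenous", "housekeeping", "positive_control", "negative_control")
TISSUE_CLASSES = ("primary", "metastasis")


@dataclass
class ExpressionDataset:
    """A probe x sample count matrix with probe and sample annotations.

    Attributes
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, probes as rows, samples as columns.
    probe_info : pandas.DataFrame
        Indexed by probe_id, with columns ``probe_class`` (one of
        :data:`PROBE_CLASSES`) and ``annotated_mirnas`` (tuple of miRNA
        names; non-empty only for endogenous probes).
    sample_meta : pandas.DataFrame
        Indexed by sample_id, with columns ``patient_id`` and
        ``tissue_class`` (``primary`` or ``metastasis``).
    """

    counts: pd.DataFrame
    probe_info: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ConsistencyError("duplicate probe_id in count matrix")
        if self.counts.columns.has_duplicates:
            raise ConsistencyError("duplicate sample_id in count matrix")
        if not self.counts.index.equals(self.probe_info.index):
            raise ConsistencyError("count rows and probe_info disagree")
        if not self.counts.columns.equals(self.sample_meta.index):
            raise ConsistencyError("count columns and sample_meta disagree")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise DataError("counts must be integers")
        if (vals < 0).any():
            raise DataError("counts must be non-negative")
        bad = set(self.probe_info["probe_class"]) - set(PROBE_CLASSES)
        if bad:
            raise FormatError(f"unknown probe_class values: {sorted(bad)}")
        bad = set(self.sample_meta["tissue_class"]) - set(TISSUE_CLASSES)
        if bad:
            raise FormatError(f"unknown tissue_class values: {sorted(bad)}")

    # -- convenience selectors -------------------------------------------------

    def probes_of_class(self, probe_class: str) -> pd.Index:
        if probe_class not in PROBE_CLASSES:
            raise DomainError(f"unknown probe class {probe_class!r}")
        mask = self.probe_info["probe_class"] == probe_class
        return self.probe_info.index[mask]

    @property
    def endogenous_probes(self) -> pd.Index:
        return self.probes_of_class("endogenous")

    @property
    def housekeeping_probes(self) -> pd.Index:
        return self.probes_of_class("housekeeping")

    def samples_of_class(self, tissue_class: str) -> pd.Index:
        mask = self.sample_meta["tissue_class"] == tissue_class
        return self.sample_meta.index[mask]


@dataclass
class NormalizedDataset:
    """Housekeeping-normalized expression values.

    ``values = counts * scale_factor`` column-wise; after normalization the
    geometric mean of the housekeeping probes is identical across samples.
    """

    values: pd.DataFrame
    scale_factors: pd.Series
    source: ExpressionDataset = field(repr=False)

    def __post_init__(self) -> None:
        if (self.scale_factors <= 0).any():
            raise DataError("scale factors must be positive")

    @property
    def sample_meta(self) -> pd.DataFrame:
        return self.source.sample_meta

    @property
    def probe_info(self) -> pd.DataFrame:
        return self.source.probe_info

    @property
    def endogenous_probes(self) -> pd.Index:
        return self.source.endogenous_probes


# -- CSV dialect ---------------------------------------------------------------

_META_COLUMNS = ["sample_id", "patient_id", "tissue_class"]


def write_counts(ds: ExpressionDataset, count_csv_path, sample_meta_csv_path) -> None:
    """Write a dataset in the canonical two-file CSV dialect."""
    with open(count_csv_path, "w", encoding="utf-8", newline="\n") as fh:
        header = ["probe_id", "probe_class", "annotated_mirnas", *ds.counts.columns]
        fh.write(",".join(header) + "\n")
        for probe_id, row in ds.counts.iterrows():
            info = ds.probe_info.loc[probe_id]
            mirnas = ";".join(info["annotated_mirnas"])
            cells = [probe_id, info["probe_class"], mirnas]
            cells.extend(str(int(v)) for v in row)
            fh.write(",".join(cells) + "\n")
    with open(sample_meta_csv_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(_META_COLUMNS) + "\n")
        for sample_id, row in ds.sample_meta.iterrows():
            fh.write(f"{sample_id},{row['patient_id']},{row['tissue_class']}\n")


def read_counts(count_csv_path, sample_meta_csv_path) -> ExpressionDataset:
    """Read the canonical CSV dialect back into an :class:`ExpressionDataset`.

    ``write_counts`` followed by ``read_counts`` is the identity on canonical
    files, and the reverse composition is byte-identical.
    """
    raw = pd.read_csv(count_csv_path, dtype=str, keep_default_na=False)
    expected = ["probe_id", "probe_class", "annotated_mirnas"]
    if list(raw.columns[:3]) != expected:
        raise FormatError(f"count CSV must start with columns {expected}")
    sample_ids = list(raw.columns[3:])
    if len(set(sample_ids)) != len(sample_ids):
        raise ConsistencyError("duplicate sample column in count CSV")
    if raw["probe_id"].duplicated().any():
        raise ConsistencyError("duplicate probe_id in count CSV")

    try:
        counts = raw[sample_ids].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"non-integer count value: {exc}") from exc
    if (counts.to_numpy() < 0).any():
        raise FormatError("negative count value")
    counts.index = pd.Index(raw["probe_id"], name="probe_id")
    counts.columns = pd.Index(sample_ids, name="sample_id")

    probe_info = pd.DataFrame(
        {
            "probe_class": raw["probe_class"].to_numpy(),
            "annotated_mirnas": [
                tuple(m for m in cell.split(";") if m)
                for cell in raw["annotated_mirnas"]
            ],
        },
        index=counts.index,
    )

    meta = pd.read_csv(sample_meta_csv_path, dtype=str, keep_default_na=False)
    if list(meta.columns) != _META_COLUMNS:
        raise FormatError(f"sample metadata CSV must have columns {_META_COLUMNS}")
    if meta["sample_id"].duplicated().any():
        raise ConsistencyError("duplicate sample_id in metadata CSV")
    meta = meta.set_index("sample_id")
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise ConsistencyError(f"samples missing from metadata: {missing}")
    meta = meta.loc[sample_ids]

    return ExpressionDataset(counts=counts, probe_info=probe_info, sample_meta=meta)


def write_normalized(norm: NormalizedDataset, path) -> None:
    """Write the normalized matrix as CSV with 6 decimal places."""
    buf = _stdio.StringIO()
    norm.values.to_csv(buf, float_format="%.6f", lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


# -- normalization and background ----------------------------------------------


def normalize_housekeeping(ds: ExpressionDataset) -> NormalizedDataset:
    """Rescale every sample to equalize housekeeping geometric means.

    The per-sample scale factor is ``mean_s(geomean_HK) / geomean_HK(s)``:
    the cohort arithmetic mean of the housekeeping geometric means divided by
    the sample's own housekeeping geometric mean. Any zero housekeeping count
    makes the geometric mean degenerate and raises
    :class:`~mirsig.errors.DegenerateInputError` rather than being silently
    pseudo-counted.
    """
    from .preprocessing import HousekeepingNormalizer

    hk_mask = (ds.probe_info["probe_class"] == "housekeeping").to_numpy()
    if not hk_mask.any():
        raise DegenerateInputError("no housekeeping probes in dataset")
    X = ds.counts.to_numpy().T.astype(float)  # samples x probes
    est = HousekeepingNormalizer(housekeeping_mask=hk_mask).fit(X)
    factors = est.scale_factors(X)
    values = pd.DataFrame(
        est.transform(X).T, index=ds.counts.index, columns=ds.counts.columns
    )
    scale = pd.Series(factors, index=ds.counts.columns, name="scale_factor")
    return NormalizedDataset(values=values, scale_factors=scale, source=ds)


def background_stats(ds: ExpressionDataset) -> pd.Series:
    """Per-sample background threshold: mean + 2*SD of negative controls.

    The SD is the sample standard deviation (ddof=1). The threshold is used
    only to flag probes as near-background in reports, mirroring the
    convention of nCounter QC; it gates nothing.
    """
    neg = ds.probes_of_class("negative_control")
    if len(neg) < 2:
        raise DomainError("background_stats requires >= 2 negative-control probes")
    sub = ds.counts.loc[neg].astype(float)
    thresh = sub.mean(axis=0) + 2.0 * sub.std(axis=0, ddof=1)
    thresh.name = "background_threshold"
    return thresh
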