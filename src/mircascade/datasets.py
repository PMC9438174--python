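"""Data model, file I/O and normalization for time-course expression matrices.

The central container is :class:`ExpressionDataset`: a log2 expression matrix
(transcripts x samples) for one transcript kind (``gene`` or ``mirna``)
together with per-sample metadata (differentiation day, replicate).  All
pipeline stages consume either the dataset itself or the per-transcript
:class:`TimeProfile` curves derived from it, where each day's value is the
arithmetic mean over that day's replicates.

File contract: matrices are plain TSV with a header row ``id\\t<sample ids>``
and one row per transcript; metadata is a TSV with columns ``sample_id``,
``day``, ``replicate``.  Readers and writers round-trip bit-exactly for
finite values.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "ExpressionDataset",
    "TimeProfile",
    "read_expression",
    "write_expression",
    "read_series_matrix",
    "quantile_normalize",
    "to_profiles",
]

_KINDS = ("gene", "mirna")


@dataclass(frozen=True, order=True)
class SampleMeta:
    """One array/sample: identifier, differentiation day and replicate index."""

    sample_id: str = field(compare=False)
    day: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"day must be non-negative, got {self.day}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")


@dataclass
class TimeProfile:
    """Per-transcript day-mean log2 trajectory.

    ``days`` is strictly increasing; ``mean_log2[i]`` is the replicate mean at
    ``days[i]``.  ``per_replicate`` optionally keeps the individual replicate
    values per day (a list of 1-D arrays aligned with ``days``).
    """

    transcript_id: str
    days: np.ndarray
    mean_log2: np.ndarray
    per_replicate: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.mean_log2 = np.asarray(self.mean_log2, dtype=float)
        if self.days.shape != self.mean_log2.shape:
            raise ValueError("days and mean_log2 must have equal length")
        if self.days.size >= 2 and not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")


@dataclass
class ExpressionDataset:
    """Log2 expression matrix plus sample metadata for one transcript kind."""

    kind: str
    transcript_ids: list[str]
    values: np.ndarray
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (transcripts x samples)")
        n, m = self.values.shape
        if len(self.transcript_ids) != n:
            raise ValueError("transcript_ids length does not match row count")
        if len(self.samples) != m:
            raise ValueError("sample metadata length does not match column count")
        if len(set(self.transcript_ids)) != n:
            dupes = _duplicates(self.transcript_ids)
            raise ValueError(f"duplicate transcript ids: {sorted(dupes)[:5]}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != m:
            raise ValueError(f"duplicate sample ids: {sorted(_duplicates(ids))[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/inf)")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def days(self) -> np.ndarray:
        """Sorted unique differentiation days."""
        return np.unique([s.day for s in self.samples])

    @property
    def sample_days(self) -> np.ndarray:
        return np.array([s.day for s in self.samples], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.transcript_ids, name="id"),
            columns=[s.sample_id for s in self.samples],
        )

    def subset(self, transcript_ids: Iterable[str]) -> "ExpressionDataset":
        """Row-subset in the given order; unknown ids raise KeyError."""
        index = {t: i for i, t in enumerate(self.transcript_ids)}
        keep = list(transcript_ids)
        missing = [t for t in keep if t not in index]
        if missing:
            raise KeyError(f"transcripts not in dataset: {missing[:5]}")
        rows = [index[t] for t in keep]
        return ExpressionDataset(self.kind, keep, self.values[rows], list(self.samples))


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


# -- file I/O ------------------------------------------------------------------


def read_expression(
    matrix_path: str | Path,
    meta_path: str | Path,
    kind: str,
    *,
    drop_missing: bool = False,
) -> ExpressionDataset:
    """Read a TSV expression matrix and its sample-metadata table.

    Samples are returned ordered by (day, replicate); transcripts keep file
    order.  A sample present in the matrix but absent from the metadata is an
    error naming the sample.  Rows containing missing values are rejected
    unless ``drop_missing`` is set, in which case they are dropped.
    """
    mat = pd.read_csv(
        matrix_path, sep="\t", header=0, index_col=0, dtype={0: str},
        float_precision="round_trip",
    )
    mat.index = mat.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "day", "replicate"):
        if col not in meta.columns:
            raise ValueError(f"metadata file missing required column {col!r}")
    meta_map = {
        str(r.sample_id): SampleMeta(str(r.sample_id), float(r.day), int(r.replicate))
        for r in meta.itertuples(index=False)
    }
    missing = [c for c in mat.columns if c not in meta_map]
    if missing:
        raise ValueError(f"sample(s) in matrix absent from metadata: {missing}")

    if mat.index.duplicated().any():
        dupes = mat.index[mat.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate transcript id(s): {dupes[:5]}")

    if mat.isna().any().any():
        if drop_missing:
            mat = mat.dropna(axis=0, how="any")
        else:
            bad = mat.index[mat.isna().any(axis=1)].tolist()
            raise ValueError(
                f"missing values in rows {bad[:5]}; pass drop_missing=True to drop them"
            )

    samples = sorted(
        (meta_map[c] for c in mat.columns),
        key=lambda s: (s.day, s.replicate, s.sample_id),
    )
    ordered_cols = [s.sample_id for s in samples]
    mat = mat[ordered_cols]
    return ExpressionDataset(kind, mat.index.tolist(), mat.to_numpy(float), samples)


def write_expression(
    ds: ExpressionDataset, matrix_path: str | Path, meta_path: str | Path
) -> None:
    """Write the dataset in the same TSV dialect :func:`read_expression` reads."""
    # 17 significant digits guarantee bit-exact float round trips
    ds.to_frame().to_csv(matrix_path, sep="\t", float_format="%.17g")
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in ds.samples],
            "day": [s.day for s in ds.samples],
            "replicate": [s.replicate for s in ds.samples],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_series_matrix(
    path: str | Path,
    kind: str,
    day_of_sample,
    *,
    collapse: str | None = "max-mean",
) -> ExpressionDataset:
    """Thin converter for plain-text GEO series-matrix files.

    ``day_of_sample`` maps a sample title/accession to a ``(day, replicate)``
    tuple (return None to drop the sample).  Multiple probes mapping to the
    same symbol are collapsed by keeping the probe with the highest mean
    signal (``collapse='max-mean'``) or left as-is (``collapse=None``, which
    errors on duplicates).  The pipeline contract remains TSV; this helper
    only eases one-off conversion.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration as exc:
        raise ValueError("not a series-matrix file: missing table markers") from exc
    table = "\n".join(lines[start + 1 : end])
    df = pd.read_csv(_io.StringIO(table), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [c.strip('"') for c in df.columns]

    keep_samples: list[SampleMeta] = []
    for c in df.columns:
        dr = day_of_sample(c)
        if dr is None:
            continue
        day, rep = dr
        keep_samples.append(SampleMeta(c, float(day), int(rep)))
    if not keep_samples:
        raise ValueError("day_of_sample dropped every sample")
    df = df[[s.sample_id for s in keep_samples]].dropna(axis=0, how="any")

    if collapse == "max-mean":
        order = np.argsort(-df.mean(axis=1).to_numpy(), kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
    elif collapse is not None:
        raise ValueError(f"unknown collapse rule {collapse!r}")

    samples = sorted(keep_samples, key=lambda s: (s.day, s.replicate, s.sample_id))
    df = df[[s.sample_id for s in samples]]
    return ExpressionDataset(kind, df.index.tolist(), df.to_numpy(float), samples)


# -- normalization and profiles ------------------------------------------------


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize columns so every sample shares one value distribution.

    Each rank is mapped to the across-column mean of the values at that rank;
    within-column ties receive the mean of the tied ranks' across-column means,
    making the result deterministic and idempotent.
    """
    if ds.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = ds.values
    n, m = vals.shape
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    rank_means = sorted_vals.mean(axis=1)

    out = np.empty_like(vals)
    for j in range(m):
        col_norm = np.empty(n)
        col_norm[order[:, j]] = rank_means
        # average tied ranks' means per distinct input value
        uniq, inv = np.unique(vals[:, j], return_inverse=True)
        sums = np.bincount(inv, weights=col_norm)
        counts = np.bincount(inv)
        out[:, j] = (sums / counts)[inv]
    return ExpressionDataset(ds.kind, list(ds.transcript_ids), out, list(ds.samples))


def to_profiles(ds: ExpressionDataset) -> list[TimeProfile]:
    """One :class:`TimeProfile` per transcript; day values are replicate means."""
    days = ds.days
    sample_days = ds.sample_days
    day_cols = [np.flatnonzero(sample_days == d) for d in days]
    profiles = []
    for i, tid in enumerate(ds.transcript_ids):
        row = ds.values[i]
        per_rep = [row[cols] for cols in day_cols]
        means = np.array([r.mean() for r in per_rep])
        profiles.append(TimeProfile(tid, days.copy(), means, per_rep))
    return profiles
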