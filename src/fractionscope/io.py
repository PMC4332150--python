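"""Readers and writers for the pipeline's tabular formats.

Two count-matrix dialects are supported:

* ``matrix_tsv`` — wide layout: ``prey_id  length  <purification ids...>``,
  one row per prey.
* ``triplet_tsv`` — long, SAINT-interaction-file style:
  ``purification_id  prey_id  count`` plus a companion prey-length table;
  absent (prey, purification) pairs are zero.

All pipeline outputs are TSV with ``#``-prefixed comment header lines
recording the package version and, where applicable, the configuration
hash, so every table is traceable to the run that produced it.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CountMatrix,
    DesignMismatchError,
    ExperimentDesign,
    FormatError,
)

try:  # pragma: no cover - metadata lookup
    from importlib.metadata import version as _pkg_version

    __version__ = _pkg_version("fractionscope")
except Exception:  # pragma: no cover
    __version__ = "unknown"

FLOAT_FMT = "%.12g"  # scores round-trip to 12 significant digits


# ---------------------------------------------------------------------------
# low-level TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty table: {path}") from exc


def write_table(obj, path: str | Path, *, comments: Sequence[str] = ()) -> None:
    """Write a pipeline table (DataFrame or convertible object) as TSV.

    Column order is preserved; integer columns are written exactly and
    float columns to 12 significant digits, so a read-back reproduces the
    table (bit-exact for integers).
    """
    if isinstance(obj, ExperimentDesign):
        df = obj.to_frame()
    elif isinstance(obj, CountMatrix):
        write_count_matrix(obj, path, dialect="matrix_tsv", comments=comments)
        return
    elif isinstance(obj, pd.DataFrame):
        df = obj
    else:
        raise FormatError(f"cannot write object of type {type(obj).__name__}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fractionscope {__version__}\n")
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> ExperimentDesign:
    """Read an experiment-design TSV.

    Required header columns: id, bait, fraction, pool, replicate, treatment.
    """
    df = _read_tsv(path, dtype=str, keep_default_na=False)
    if not len(df):
        raise FormatError(f"design file has no rows: {path}")
    required = ["id", "bait", "fraction", "pool", "replicate", "treatment"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"design file missing columns {missing}: {path}")
    try:
        df["replicate"] = df["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer replicate in {path}") from exc
    return ExperimentDesign.from_frame(df)


def write_design(design: ExperimentDesign, path: str | Path,
                 *, comments: Sequence[str] = ()) -> None:
    write_table(design, path, comments=comments)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(
    path: str | Path,
    dialect: str = "matrix_tsv",
    *,
    lengths_path: str | Path | None = None,
    purification_ids: Sequence[str] | None = None,
    design: ExperimentDesign | None = None,
) -> CountMatrix:
    """Read a spectral-count matrix in either dialect.

    For ``triplet_tsv`` the purification set must be declared (via
    ``purification_ids`` or ``design``) because absent pairs mean zero —
    an all-zero purification is otherwise unrepresentable — and a
    companion prey-length table is required via ``lengths_path``.
    """
    if dialect == "matrix_tsv":
        return _read_matrix_tsv(path)
    if dialect == "triplet_tsv":
        if design is not None and purification_ids is None:
            purification_ids = design.ids
        if purification_ids is None:
            raise FormatError(
                "triplet_tsv requires the declared purification ids "
                "(pass purification_ids= or design=)"
            )
        if lengths_path is None:
            raise FormatError("triplet_tsv requires a prey-length table "
                              "(pass lengths_path=)")
        return _read_triplet_tsv(path, lengths_path, purification_ids)
    raise FormatError(f"unknown count-matrix dialect {dialect!r}")


def _check_counts_numeric(df: pd.DataFrame, path) -> None:
    arr = df.to_numpy()
    if arr.size == 0:
        return
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise FormatError(f"non-numeric counts in columns {list(bad)}: {path}")
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise FormatError(
            f"non-integer count at row {df.index[i]!r} "
            f"column {df.columns[j]!r}: {path}"
        )
    if arr.min() < 0:
        i, j = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"negative count at row {df.index[i]!r} "
            f"column {df.columns[j]!r}: {path}"
        )


def _read_matrix_tsv(path: str | Path) -> CountMatrix:
    df = _read_tsv(path)
    if "prey_id" not in df.columns or "length" not in df.columns:
        raise FormatError(f"matrix_tsv needs 'prey_id' and 'length' columns: {path}")
    if df["prey_id"].duplicated().any():
        dupes = sorted(df.loc[df["prey_id"].duplicated(), "prey_id"].unique())
        raise FormatError(f"duplicate prey_id rows {dupes}: {path}")
    df = df.set_index("prey_id")
    lengths = df.pop("length")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise FormatError(f"non-positive length for prey {bad!r}: {path}")
    counts = df
    counts.columns = counts.columns.astype(str)
    _check_counts_numeric(counts, path)
    return CountMatrix(counts.astype(np.int64), lengths.astype(np.int64))


def _read_lengths(path: str | Path) -> pd.Series:
    df = _read_tsv(path, dtype={"prey_id": str})
    if "prey_id" not in df.columns or "length" not in df.columns:
        raise FormatError(f"length table needs 'prey_id' and 'length': {path}")
    if df["prey_id"].duplicated().any():
        raise FormatError(f"duplicate prey_id in length table: {path}")
    return df.set_index("prey_id")["length"].astype(np.int64)


def _read_triplet_tsv(path, lengths_path, purification_ids) -> CountMatrix:
    lengths = _read_lengths(lengths_path)
    cols = list(purification_ids)
    try:
        df = _read_tsv(path, dtype={"purification_id": str, "prey_id": str})
        empty = False
    except FormatError:
        df = pd.DataFrame(columns=["purification_id", "prey_id", "count"])
        empty = True
    if not empty:
        required = ["purification_id", "prey_id", "count"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"triplet_tsv missing columns {missing}: {path}")
        if not len(df):
            empty = True
    if not empty:
        dup = df.duplicated(subset=["purification_id", "prey_id"])
        if dup.any():
            r = df[dup].iloc[0]
            raise FormatError(
                f"duplicate triplet for purification {r['purification_id']!r}, "
                f"prey {r['prey_id']!r}: {path}"
            )
        unknown = set(df["purification_id"]) - set(cols)
        if unknown:
            raise DesignMismatchError(
                f"triplet purifications absent from design: {sorted(unknown)[:5]}"
            )
        cnt = df["count"]
        if not np.issubdtype(cnt.dtype, np.number):
            raise FormatError(f"non-numeric counts: {path}")
        bad = cnt[(cnt < 0) | (cnt != np.round(cnt))]
        if len(bad):
            r = df.loc[bad.index[0]]
            raise FormatError(
                f"invalid count {r['count']!r} for purification "
                f"{r['purification_id']!r}, prey {r['prey_id']!r}: {path}"
            )
    wide = pd.DataFrame(
        0, index=pd.Index(lengths.index, name="prey_id"),
        columns=cols, dtype=np.int64,
    )
    for r in df.itertuples(index=False):
        if r.prey_id not in wide.index:
            raise FormatError(
                f"prey {r.prey_id!r} missing from the length table: {path}"
            )
        wide.loc[r.prey_id, r.purification_id] = int(r.count)
    return CountMatrix(wide, lengths)


def write_count_matrix(
    cm: CountMatrix,
    path: str | Path,
    dialect: str = "matrix_tsv",
    *,
    lengths_path: str | Path | None = None,
    comments: Sequence[str] = (),
) -> None:
    """Write a count matrix; ``triplet_tsv`` also writes the length table."""
    path = Path(path)
    if dialect == "matrix_tsv":
        df = cm.counts.reset_index()
        df.insert(1, "length", cm.lengths.to_numpy())
        with open(path, "w") as fh:
            fh.write(f"# fractionscope {__version__}\n")
            for line in comments:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)
        return
    if dialect == "triplet_tsv":
        if lengths_path is None:
            lengths_path = path.with_suffix(".lengths.tsv")
        long = (
            cm.counts.stack()
            .rename_axis(["prey_id", "purification_id"])
            .rename("count")
            .reset_index()
        )
        long = long[long["count"] > 0]
        long = long[["purification_id", "prey_id", "count"]]
        with open(path, "w") as fh:
            fh.write(f"# fractionscope {__version__}\n")
            long.to_csv(fh, sep="\t", index=False)
        ldf = cm.lengths.rename("length").rename_axis("prey_id").reset_index()
        with open(lengths_path, "w") as fh:
            fh.write(f"# fractionscope {__version__}\n")
            ldf.to_csv(fh, sep="\t", index=False)
        return
    raise FormatError(f"unknown count-matrix dialect {dialect!r}")
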