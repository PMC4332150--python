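"""Core data model for fractionated AP-MS spectral-count experiments.

The pipeline operates on two objects: a spectral-count matrix (preys x
purifications) and an experiment design assigning each purification a bait,
a biochemical fraction (chromatin / soluble / combined) and a pool (TF
sample vs negative control).  Counts are semi-quantitative MS/MS spectrum
tallies; missing entries mean zero, never missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel bait id for vector-only control purifications
CONTROL = "CONTROL"

FRACTIONS = ("chromatin", "soluble", "combined")
POOLS = ("sample", "control")


class FormatError(ValueError):
    """A file or table violates the expected tabular format."""


class DesignMismatchError(ValueError):
    """Counts and experiment design disagree (unknown ids, wrong shapes)."""


@dataclass(frozen=True)
class Purification:
    """One affinity purification (= one MS run = one matrix column)."""

    id: str
    bait: str
    fraction: str
    pool: str
    replicate: int = 1
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise FormatError(
                f"unknown fraction {self.fraction!r} for purification "
                f"{self.id!r}; expected one of {FRACTIONS}"
            )
        if self.pool not in POOLS:
            raise FormatError(
                f"unknown pool {self.pool!r} for purification {self.id!r}; "
                f"expected one of {POOLS}"
            )
        if self.bait == CONTROL and self.pool != "control":
            raise FormatError(
                f"purification {self.id!r} has the CONTROL bait sentinel "
                "but is not in the control pool"
            )
        if self.replicate < 1:
            raise FormatError(
                f"replicate must be >= 1, got {self.replicate} "
                f"for purification {self.id!r}"
            )


class ExperimentDesign:
    """Ordered collection of purifications with sample/control bookkeeping.

    Scoring needs at least one sample and one control purification (the
    two-pool layout: the control pool estimates the false-interaction
    background).  Control purifications may carry a real bait id — the
    study's 61 unrelated-bait controls are genuine TAP experiments — or
    the ``CONTROL`` sentinel for vector-only runs.
    """

    def __init__(self, purifications: Sequence[Purification]):
        ids = [p.id for p in purifications]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate purification ids: {dupes}")
        self.purifications: tuple[Purification, ...] = tuple(purifications)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.purifications]

    @property
    def samples(self) -> list[Purification]:
        return [p for p in self.purifications if p.pool == "sample"]

    @property
    def controls(self) -> list[Purification]:
        return [p for p in self.purifications if p.pool == "control"]

    @property
    def sample_count(self) -> int:
        return len(self.samples)

    @property
    def control_count(self) -> int:
        return len(self.controls)

    def __len__(self) -> int:
        return len(self.purifications)

    def __getitem__(self, pid: str) -> Purification:
        for p in self.purifications:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ExperimentDesign)
            and self.purifications == other.purifications
        )

    def sample_baits(self) -> list[str]:
        """Distinct baits of the sample pool, in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.samples:
            seen.setdefault(p.bait, None)
        return list(seen)

    def sample_fractions(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.samples:
            seen.setdefault(p.fraction, None)
        return list(seen)

    def purifications_of(self, bait: str, fraction: str | None = None,
                         pool: str = "sample") -> list[Purification]:
        out = [p for p in self.purifications
               if p.bait == bait and p.pool == pool]
        if fraction is not None:
            out = [p for p in out if p.fraction == fraction]
        return out

    def controls_for_fraction(self, fraction: str) -> list[Purification]:
        """Control purifications matched to a fraction.

        A "combined"-fraction control was purified from unfractionated
        lysate, so it belongs to both fraction-specific control pools.
        """
        return [p for p in self.controls
                if p.fraction == fraction or p.fraction == "combined"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.id for p in self.purifications],
                "bait": [p.bait for p in self.purifications],
                "fraction": [p.fraction for p in self.purifications],
                "pool": [p.pool for p in self.purifications],
                "replicate": [p.replicate for p in self.purifications],
                "treatment": [p.treatment for p in self.purifications],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExperimentDesign":
        required = {"id", "bait", "fraction", "pool", "replicate", "treatment"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        purs = [
            Purification(
                id=str(r.id),
                bait=str(r.bait),
                fraction=str(r.fraction),
                pool=str(r.pool),
                replicate=int(r.replicate),
                treatment="" if pd.isna(r.treatment) else str(r.treatment),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(purs)


@dataclass(frozen=True)
class PreyInfo:
    """Prey protein metadata: identifier and amino-acid length."""

    prey_id: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise FormatError(
                f"prey {self.prey_id!r} has non-positive length {self.length}"
            )


class CountMatrix:
    """Spectral-count matrix X_ij: preys (rows) x purifications (columns).

    Backed by a dense integer DataFrame (the study scale, ~3,700 preys x
    190 purifications, is small); absent pairs are zeros by construction.
    """

    def __init__(self, counts: pd.DataFrame, lengths: pd.Series):
        if counts.index.has_duplicates:
            dupes = sorted(counts.index[counts.index.duplicated()].unique())
            raise FormatError(f"duplicate prey ids: {dupes}")
        if counts.columns.has_duplicates:
            dupes = sorted(counts.columns[counts.columns.duplicated()].unique())
            raise FormatError(f"duplicate purification ids: {dupes}")
        arr = counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("spectral counts must be integers")
            counts = counts.round().astype(np.int64)
            arr = counts.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at prey {counts.index[i]!r}, "
                f"purification {counts.columns[j]!r}"
            )
        missing = counts.index.difference(lengths.index)
        if len(missing):
            raise FormatError(f"preys without length metadata: {list(missing)[:5]}")
        bad = lengths.reindex(counts.index)
        if (bad <= 0).any():
            raise FormatError("prey lengths must be positive")
        self.counts: pd.DataFrame = counts.astype(np.int64)
        self.lengths: pd.Series = lengths.reindex(counts.index).astype(np.int64)

    # -- basic accessors -------------------------------------------------
    @property
    def prey_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def purification_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def tsc(self) -> pd.Series:
        """Total spectral count of every purification (column sums)."""
        return self.counts.sum(axis=0)

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.counts.equals(other.counts)
            and self.lengths.equals(other.lengths)
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.lengths.copy())

    def validate_against(self, design: ExperimentDesign) -> None:
        unknown = set(self.purification_ids) - set(design.ids)
        if unknown:
            raise DesignMismatchError(
                f"purifications absent from design: {sorted(unknown)[:5]}"
            )

    @classmethod
    def from_preys(
        cls,
        preys: Iterable[PreyInfo],
        purification_ids: Sequence[str],
        counts: np.ndarray | None = None,
    ) -> "CountMatrix":
        preys = list(preys)
        idx = pd.Index([p.prey_id for p in preys], name="prey_id")
        if counts is None:
            counts = np.zeros((len(preys), len(purification_ids)), dtype=np.int64)
        frame = pd.DataFrame(np.asarray(counts, dtype=np.int64),
                             index=idx, columns=list(purification_ids))
        lengths = pd.Series([p.length for p in preys], index=idx, name="length")
        return cls(frame, lengths)
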