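"""Domain containers: sequence records, alignments, structure templates,
landmark configurations and region annotations.

All sequence/structure coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .alphabet import ALPHABET, GAP


class Role(str, Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    HYBRID = "hybrid"
    CLONE = "clone"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence with optional group/role labels.

    ``seq`` is upper-case IUPAC DNA (U already folded to T), gap ``-``.
    """

    id: str
    seq: str
    group: str | None = None
    role: Role = Role.UNKNOWN

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.seq, start=1):
            if ch not in ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: non-IUPAC character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def with_labels(self, group: str | None, role: Role | None) -> "SequenceRecord":
        return SequenceRecord(
            self.id,
            self.seq,
            group if group is not None else self.group,
            role if role is not None else self.role,
        )


@dataclass(frozen=True)
class AlignedSet:
    """A multiple sequence alignment with per-sequence labels."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in alignment: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    @property
    def L(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def column(self, col: int) -> list[str]:
        """Characters of 1-based column ``col``."""
        if not 1 <= col <= self.L:
            raise IndexError(f"column {col} outside alignment of length {self.L}")
        return [r.seq[col - 1] for r in self.records]

    def subset(self, ids=None, groups=None) -> "AlignedSet":
        recs = [
            r
            for r in self.records
            if (ids is None or r.id in set(ids))
            and (groups is None or r.group in set(groups))
        ]
        return AlignedSet(tuple(recs))

    def groups(self) -> dict[str, list[SequenceRecord]]:
        out: dict[str, list[SequenceRecord]] = {}
        for r in self.records:
            out.setdefault(r.group or "", []).append(r)
        return out

    @staticmethod
    def from_records(records) -> "AlignedSet":
        return AlignedSet(tuple(records))


@dataclass(frozen=True)
class StructureTemplate:
    """A secondary-structure template: sequence, base pairs and region spans.

    ``pairs`` hold 1-based (i, j) with i < j; every position occurs in at
    most one pair. ``region_spans`` maps region name (ITS1, 5.8S, ITS2) to a
    1-based inclusive (start, end) span on the template sequence.
    """

    seq: str
    pairs: frozenset[tuple[int, int]]
    region_spans: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = len(self.seq)
        seen: set[int] = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"self-pair at position {i}")
            if not (1 <= i < j <= L):
                raise ValueError(f"pair ({i},{j}) out of range for length {L}")
            for p in (i, j):
                if p in seen:
                    raise ValueError(f"position {p} occurs in more than one pair")
                seen.add(p)

    @property
    def L(self) -> int:
        return len(self.seq)

    def partner_of(self, col: int) -> int | None:
        for i, j in self.pairs:
            if i == col:
                return j
            if j == col:
                return i
        return None

    def partner_map(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's 2D landmark configuration (14 fixed landmarks)."""

    id: str
    group: str
    coords: np.ndarray  # (n_landmarks, 2)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"coords must be (k, 2), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"configuration {self.id!r}: non-finite coordinates")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


REGIONS = ("ITS1", "5.8S", "ITS2")


@dataclass(frozen=True)
class RegionAnnotation:
    """ITS1 / 5.8S / ITS2 spans on alignment columns, 1-based inclusive."""

    spans: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        missing = [r for r in REGIONS if r not in self.spans]
        if missing:
            raise ValueError(f"missing region spans: {missing}")
        prev_end = 0
        for name in REGIONS:
            start, end = self.spans[name]
            if name != "5.8S" and end < start:
                raise ValueError(f"{name}: empty span ({start},{end})")
            if start <= prev_end:
                raise ValueError("region spans must be ordered ITS1 < 5.8S < ITS2 and disjoint")
            prev_end = end

    def region_of(self, col: int) -> str | None:
        for name, (start, end) in self.spans.items():
            if start <= col <= end:
                return name
        return None

    def local_coordinate(self, col: int) -> tuple[str, int] | None:
        """Map a full-template column to (region, position-within-region)."""
        region = self.region_of(col)
        if region is None:
            return None
        return region, col - self.spans[region][0] + 1
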