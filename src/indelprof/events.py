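"""Indel events, the naming grammar, and per-site profiles.

An event name follows ``[start relative to cleavage site]:[size][I|D]``,
e.g. ``-4:2D`` is a 2-nt deletion starting 4 bases 5' of the cut and
``0:1I`` is a 1-nt insertion at the cut boundary. Names are for display;
counting keys include the inserted sequence, so two distinct 1-nt
insertions at the same boundary are distinct outcomes sharing a name.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

_NAME_RE = re.compile(r"^(-?\d+):(\d+)([ID])$")


@dataclass(frozen=True)
class IndelEvent:
    """One insertion or deletion in cut-relative coordinates.

    ``start_rel`` follows the package convention (see :mod:`indelprof.sites`):
    deletions carry the coordinate of their leftmost deleted base, insertions
    the boundary immediately 3' of which the bases sit.
    """

    site_id: str
    kind: str  # "insertion" | "deletion"
    start_rel: int
    size: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"kind must be insertion/deletion, got {self.kind!r}")
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if self.kind == "insertion" and len(self.inserted_seq) != self.size:
            raise ValueError("inserted_seq length must equal size for insertions")
        if self.kind == "deletion" and self.inserted_seq:
            raise ValueError("deletions carry no inserted_seq")

    @property
    def key(self) -> tuple:
        return (self.kind, self.start_rel, self.size, self.inserted_seq)

    @property
    def name(self) -> str:
        suffix = "I" if self.kind == "insertion" else "D"
        return f"{self.start_rel}:{self.size}{suffix}"

    @property
    def is_frameshift(self) -> bool:
        return self.size % 3 != 0

    @property
    def signed_size(self) -> int:
        """Insertions positive, deletions negative."""
        return self.size if self.kind == "insertion" else -self.size


def name_indel(event: IndelEvent) -> str:
    return event.name


def parse_indel_name(name: str, site_id: str = "", inserted_seq: str = "") -> IndelEvent:
    """Parse ``-4:2D``-style names back into events.

    The inserted sequence is not encoded in the name; supply it separately
    when known (placeholder ``N``s are used otherwise so the size invariant
    holds).
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unparseable indel name: {name!r}")
    start_rel, size, suffix = int(m.group(1)), int(m.group(2)), m.group(3)
    kind = "insertion" if suffix == "I" else "deletion"
    if kind == "insertion" and not inserted_seq:
        inserted_seq = "N" * size
    return IndelEvent(
        site_id=site_id, kind=kind, start_rel=start_rel, size=size,
        inserted_seq=inserted_seq if kind == "insertion" else "",
    )


@dataclass
class SiteIndelProfile:
    """Multiset of indel events observed at one target site."""

    site_id: str
    counts: Counter = field(default_factory=Counter)  # IndelEvent -> count
    n_reads_total: int = 0
    library_size: int = 0
    replicate_id: str = ""

    def __post_init__(self) -> None:
        for event, count in self.counts.items():
            if count < 1:
                raise ValueError(f"count for {event.name} must be >= 1")
            if event.site_id != self.site_id:
                raise ValueError("event site_id does not match profile")

    @property
    def total_indel_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return len(self.counts)

    def add(self, event: IndelEvent, count: int = 1) -> None:
        self.counts[event] += count

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site_id": self.site_id,
                "name": e.name,
                "kind": e.kind,
                "start_rel": e.start_rel,
                "size": e.size,
                "inserted_seq": e.inserted_seq,
                "count": c,
                "replicate_id": self.replicate_id,
                "library_size": self.library_size,
            }
            for e, c in sorted(self.counts.items(), key=lambda kv: kv[0].key)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "site_id", "name", "kind", "start_rel", "size",
                "inserted_seq", "count", "replicate_id", "library_size",
            ],
        )


def profiles_to_frame(profiles: list[SiteIndelProfile]) -> pd.DataFrame:
    if not profiles:
        return SiteIndelProfile(site_id="").to_frame()
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)


def profiles_from_frame(df: pd.DataFrame) -> list[SiteIndelProfile]:
    out: list[SiteIndelProfile] = []
    for (site_id, rep), grp in df.groupby(["site_id", "replicate_id"], sort=True, dropna=False):
        prof = SiteIndelProfile(
            site_id=site_id,
            replicate_id="" if pd.isna(rep) else str(rep),
            library_size=int(grp["library_size"].iloc[0]) if len(grp) else 0,
        )
        for row in grp.to_dict("records"):
            ins = row["inserted_seq"]
            event = IndelEvent(
                site_id=site_id,
                kind=row["kind"],
                start_rel=int(row["start_rel"]),
                size=int(row["size"]),
                inserted_seq="" if (not isinstance(ins, str)) else ins,
            )
            prof.add(event, int(row["count"]))
        out.append(prof)
    return out
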