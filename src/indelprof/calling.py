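"""Indel identification from aligned amplicon reads.

The cascade mirrors targeted-amplicon CRISPR editing analysis: drop
duplicates and low-mapping-quality reads (MAPQ < 38), extract raw indels
from CIGAR strings, left-align them against the reference, keep only indels
starting within 5 nt of the Cas9 cleavage site, subtract events also seen in
the unedited control (probable somatic variants), and drop sites with fewer
than 10 indel reads overall.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

from .events import IndelEvent, SiteIndelProfile
from .sites import TargetSite, revcomp

DEFAULT_MIN_MAPQ = 38
DEFAULT_WINDOW = 5
DEFAULT_MIN_SITE_READS = 10

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


@dataclass(frozen=True)
class AlignedReadRecord:
    """Minimal aligned-read view (subset of a SAM record)."""

    read_id: str
    ref_name: str
    ref_start: int  # 0-based
    cigar: str
    query_seq: str
    mapq: int = 60
    is_duplicate: bool = False
    is_proper_pair: bool = True

    def __post_init__(self) -> None:
        if self.ref_start < 0:
            raise ValueError("ref_start must be >= 0")
        if not (0 <= self.mapq <= 60):
            raise ValueError("mapq must be in 0..60")


@dataclass(frozen=True)
class RawIndel:
    """An indel in absolute reference coordinates, pre-windowing.

    ``pos`` is the leftmost deleted reference base for deletions, and the
    reference boundary (number of reference bases to the left) for
    insertions.
    """

    kind: str
    pos: int
    size: int
    inserted_seq: str = ""


class RecordRejected(ValueError):
    """Raised when a record's CIGAR and query sequence disagree."""


def record_filters(
    records: list[AlignedReadRecord], min_mapq: int = DEFAULT_MIN_MAPQ
) -> list[AlignedReadRecord]:
    """Remove duplicate-flagged records and records with MAPQ below threshold."""
    return [r for r in records if not r.is_duplicate and r.mapq >= min_mapq]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise RecordRejected(f"malformed CIGAR: {cigar!r}")
    return ops


def parse_alignment_record(record: AlignedReadRecord) -> list[RawIndel]:
    """Extract one raw indel per I/D CIGAR element.

    Raises :class:`RecordRejected` when the CIGAR does not consume exactly
    the query sequence; callers keep a rejects log.
    """
    ops = parse_cigar(record.cigar)
    consumed = sum(n for n, op in ops if op in _QUERY_OPS)
    if consumed != len(record.query_seq):
        raise RecordRejected(
            f"CIGAR {record.cigar} consumes {consumed} query bases, "
            f"sequence has {len(record.query_seq)}"
        )
    out: list[RawIndel] = []
    ref_pos = record.ref_start
    q_pos = 0
    for n, op in ops:
        if op == "I":
            out.append(
                RawIndel(
                    kind="insertion",
                    pos=ref_pos,
                    size=n,
                    inserted_seq=record.query_seq[q_pos : q_pos + n],
                )
            )
        elif op == "D":
            out.append(RawIndel(kind="deletion", pos=ref_pos, size=n))
        if op in _REF_OPS:
            ref_pos += n
        if op in _QUERY_OPS:
            q_pos += n
    return out


def left_align_indel(indel: RawIndel, ref_seq: str) -> RawIndel:
    """Shift an indel to its leftmost reference-equivalent placement.

    Aligners arbitrarily place indels inside repeats; normalizing to the
    leftmost placement makes equivalent calls identical. Idempotent.
    """
    if indel.kind == "deletion":
        pos = indel.pos
        while pos > 0 and ref_seq[pos - 1] == ref_seq[pos + indel.size - 1]:
            pos -= 1
        return replace(indel, pos=pos)
    pos, seq = indel.pos, indel.inserted_seq
    while pos > 0 and ref_seq[pos - 1] == seq[-1]:
        seq = ref_seq[pos - 1] + seq[:-1]
        pos -= 1
    return replace(indel, pos=pos, inserted_seq=seq)


def project_to_guide_strand(indel: RawIndel, site: TargetSite) -> RawIndel:
    """Re-express a reference-strand indel on the protospacer strand."""
    if site.strand == "+":
        return indel
    n = len(site)
    if indel.kind == "deletion":
        return replace(indel, pos=n - (indel.pos + indel.size))
    return replace(indel, pos=n - indel.pos, inserted_seq=revcomp(indel.inserted_seq))


def to_cut_relative(indel: RawIndel, guide_cut: int) -> int:
    """Cut-relative start: bases 5' of the cut are -1, -2, ...; 3' are +1, ...

    Deletions use their leftmost deleted base; insertions the boundary, with
    0 the cut itself.
    """
    if indel.kind == "insertion":
        return indel.pos - guide_cut
    return indel.pos - guide_cut if indel.pos < guide_cut else indel.pos - guide_cut + 1


def window_filter(
    raw_indels: list[RawIndel],
    site: TargetSite,
    window: int = DEFAULT_WINDOW,
    membership: str = "start",
) -> list[IndelEvent]:
    """Convert left-aligned guide-strand indels to events within the cut window.

    ``membership='start'`` (default) keeps indels whose left-aligned start is
    within ``window`` nt of the cut; ``'overlap'`` keeps any indel whose span
    touches the window.
    """
    if membership not in ("start", "overlap"):
        raise ValueError(f"unknown membership mode {membership!r}")
    events: list[IndelEvent] = []
    for indel in raw_indels:
        start_rel = to_cut_relative(indel, site.guide_strand_cut)
        if membership == "start" or indel.kind == "insertion":
            keep = abs(start_rel) <= window
        else:
            # deletion span vs window in guide coordinates (no 0 position for bases)
            end_rel = start_rel + indel.size - 1
            if start_rel < 0 <= end_rel:
                end_rel += 1  # span crosses the cut; skip the nonexistent 0
            keep = start_rel <= window and end_rel >= -window
        if not keep:
            continue
        events.append(
            IndelEvent(
                site_id=site.site_id,
                kind=indel.kind,
                start_rel=start_rel,
                size=indel.size,
                inserted_seq=indel.inserted_seq,
            )
        )
    return events


def call_read(
    record: AlignedReadRecord,
    site: TargetSite,
    window: int = DEFAULT_WINDOW,
    membership: str = "start",
) -> list[IndelEvent]:
    """Raw CIGAR indels -> guide-strand projection -> left-align -> window."""
    guide_ref = site.guide_strand_seq
    raw = [project_to_guide_strand(i, site) for i in parse_alignment_record(record)]
    raw = [left_align_indel(i, guide_ref) for i in raw]
    return window_filter(raw, site, window=window, membership=membership)


def read_overlaps_window(
    record: AlignedReadRecord, site: TargetSite, window: int = DEFAULT_WINDOW
) -> bool:
    """Whether the aligned span covers the full cut +/- window region."""
    ops = parse_cigar(record.cigar)
    ref_len = sum(n for n, op in ops if op in _REF_OPS)
    lo = site.guide_to_ref_boundary(site.guide_strand_cut - window)
    hi = site.guide_to_ref_boundary(site.guide_strand_cut + window)
    lo, hi = min(lo, hi), max(lo, hi)
    return record.ref_start <= lo and record.ref_start + ref_len >= hi


def call_site_profile(
    records: list[AlignedReadRecord],
    site: TargetSite,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    window: int = DEFAULT_WINDOW,
    membership: str = "start",
    replicate_id: str = "",
    rejects_log: list | None = None,
) -> SiteIndelProfile:
    """Full per-site cascade: filters, per-read calls, event counting.

    Reads with no windowed indel count toward the library size (unedited)
    but contribute nothing to the profile.
    """
    kept = record_filters(records, min_mapq=min_mapq)
    counts: Counter = Counter()
    for record in kept:
        try:
            events = call_read(record, site, window=window, membership=membership)
        except RecordRejected as exc:
            if rejects_log is not None:
                rejects_log.append((record.read_id, str(exc)))
            continue
        for event in events:
            counts[event] += 1
    return SiteIndelProfile(
        site_id=site.site_id,
        counts=counts,
        n_reads_total=len(kept),
        library_size=len(kept),
        replicate_id=replicate_id,
    )


def subtract_control(
    profile: SiteIndelProfile, control_profile: SiteIndelProfile
) -> SiteIndelProfile:
    """Drop events also present in the unedited control (probable somatic)."""
    if profile.site_id != control_profile.site_id:
        raise ValueError(
            f"site mismatch: {profile.site_id!r} vs {control_profile.site_id!r}"
        )
    control_keys = {e.key for e in control_profile.counts}
    counts = Counter(
        {e: c for e, c in profile.counts.items() if e.key not in control_keys}
    )
    return SiteIndelProfile(
        site_id=profile.site_id,
        counts=counts,
        n_reads_total=profile.n_reads_total,
        library_size=profile.library_size,
        replicate_id=profile.replicate_id,
    )


def filter_low_count_sites(
    profiles: list[SiteIndelProfile], min_reads: int = DEFAULT_MIN_SITE_READS
) -> list[SiteIndelProfile]:
    """Drop sites whose indel reads summed across replicates fall below threshold."""
    totals: dict[str, int] = {}
    for p in profiles:
        totals[p.site_id] = totals.get(p.site_id, 0) + p.total_indel_reads
    return [p for p in profiles if totals[p.site_id] >= min_reads]


def background_estimate(
    profile_on: SiteIndelProfile, profiles_off: list[SiteIndelProfile]
) -> dict:
    """Sequencing-error background from experiments where the site was untargeted.

    Off-pool amplicons see no Cas9 activity, so any windowed indels there
    estimate the error floor; the mean count across off-pool experiments is
    reported beside the on-pool count.
    """
    if not profiles_off:
        raise ValueError("at least one off-pool profile is required")
    off_counts = [p.total_indel_reads for p in profiles_off]
    return {
        "site_id": profile_on.site_id,
        "on_pool_indels": profile_on.total_indel_reads,
        "background_indels": float(np.mean(off_counts)),
    }
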