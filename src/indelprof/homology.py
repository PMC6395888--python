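"""Microhomology and insertion-homology analysis.

Deletion microhomology (MH): for each candidate length n, the 5' n bases of
the deleted sequence are compared with the first n bases downstream of the
3' join, and the 3' n bases of the deleted sequence with the last n bases
upstream of the 5' join. A match on either side counts; the MH length is the
largest matching n, capped at 50 or the deletion length.

Insertion homology: the (first) inserted base compared with the protospacer
-4 base, the base immediately 5' of the cut — templated insertions copy it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import IndelEvent, SiteIndelProfile
from .sites import TargetSite

MAX_MH = 50

_BASES = "ACGT"


@dataclass(frozen=True)
class MicrohomologyAnnotation:
    event: IndelEvent | None
    mh_len: int
    matched_side: str  # five_prime | three_prime | both | none

    def __post_init__(self) -> None:
        if (self.mh_len >= 1) != (self.matched_side != "none"):
            raise ValueError("mh_len >= 1 iff a side matched")


@dataclass(frozen=True)
class InsertionHomologyCall:
    event: IndelEvent
    minus4_base: str
    inserted_first_base: str

    @property
    def is_homologous(self) -> bool:
        return self.minus4_base == self.inserted_first_base


def deletion_mh(
    deleted_seq: str,
    upstream_flank: str,
    downstream_flank: str,
    max_n: int = MAX_MH,
    require_both_sides: bool = False,
    event: IndelEvent | None = None,
) -> MicrohomologyAnnotation:
    """Score a deletion for flanking microhomology.

    ``upstream_flank`` is the sequence immediately 5' of the deleted span and
    ``downstream_flank`` immediately 3', both on the protospacer strand.
    With ``require_both_sides`` the stricter both-tests-match rule is applied
    (sensitivity analysis only; either-side is the default semantics).
    """
    if not deleted_seq:
        raise ValueError("deleted_seq must be non-empty")
    best_n = 0
    best_side = "none"
    for n in range(1, min(max_n, len(deleted_seq)) + 1):
        five = (
            len(downstream_flank) >= n and deleted_seq[:n] == downstream_flank[:n]
        )
        three = (
            len(upstream_flank) >= n and deleted_seq[-n:] == upstream_flank[-n:]
        )
        matched = (five and three) if require_both_sides else (five or three)
        if matched:
            best_n = n
            best_side = "both" if (five and three) else ("five_prime" if five else "three_prime")
    return MicrohomologyAnnotation(event=event, mh_len=best_n, matched_side=best_side)


def annotate_deletion(
    event: IndelEvent, site: TargetSite, max_n: int = MAX_MH,
    require_both_sides: bool = False,
) -> MicrohomologyAnnotation:
    """Locate a called deletion in the site window and score its MH."""
    if event.kind != "deletion":
        raise ValueError("annotate_deletion requires a deletion event")
    seq = site.guide_strand_seq
    cut = site.guide_strand_cut
    start = cut + event.start_rel if event.start_rel < 0 else cut + event.start_rel - 1
    if start < 0 or start + event.size > len(seq):
        raise ValueError("deletion extends outside the site window")
    deleted = seq[start : start + event.size]
    return deletion_mh(
        deleted, seq[:start], seq[start + event.size :],
        max_n=max_n, require_both_sides=require_both_sides, event=event,
    )


def insertion_homology(event: IndelEvent, site: TargetSite) -> InsertionHomologyCall:
    """Compare the first inserted base with the site's -4 base."""
    if event.kind != "insertion":
        raise ValueError("insertion_homology requires an insertion event")
    return InsertionHomologyCall(
        event=event,
        minus4_base=site.minus4_base,
        inserted_first_base=event.inserted_seq[0],
    )


def mh_null_expectation(
    k: int,
    base_probs: dict[str, float],
    deletion_size_dist: dict[int, float],
    n_sim: int = 20000,
    seed: int = 0,
    max_n: int = MAX_MH,
) -> float:
    """Monte-Carlo chance expectation: fraction of random deletions with MH >= k.

    Random deleted sequences and flanks are drawn i.i.d. from ``base_probs``,
    deletion sizes from ``deletion_size_dist``; the same either-side MH rule
    used for observed deletions is applied.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list(_BASES))
    p = np.array([base_probs[b] for b in _BASES], dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("base_probs must sum to 1")
    sizes = np.array(sorted(deletion_size_dist), dtype=int)
    sp = np.array([deletion_size_dist[s] for s in sizes], dtype=float)
    sp = sp / sp.sum()
    if k > sizes.max():
        return 0.0  # MH cannot exceed the deletion length
    flank_len = min(max_n, int(sizes.max()))
    hits = 0
    drawn_sizes = rng.choice(sizes, size=n_sim, p=sp)
    for size in drawn_sizes:
        deleted = "".join(rng.choice(bases, size=size, p=p))
        up = "".join(rng.choice(bases, size=flank_len, p=p))
        down = "".join(rng.choice(bases, size=flank_len, p=p))
        ann = deletion_mh(deleted, up, down, max_n=max_n)
        if ann.mh_len >= k:
            hits += 1
    return hits / n_sim


def site_homology_summary(
    profile: SiteIndelProfile,
    site: TargetSite,
    min_insertions: int = 5,
    max_n: int = MAX_MH,
) -> dict:
    """Count-weighted homology percentages for one site.

    The commonest insertion is reported only when the site carries at least
    ``min_insertions`` insertion reads, to obviate low-count bias.
    """
    del_reads = mh_reads = ins_reads = hom_reads = 0
    ins_counts: dict[IndelEvent, int] = {}
    for event, count in profile.counts.items():
        if event.kind == "deletion":
            del_reads += count
            if annotate_deletion(event, site, max_n=max_n).mh_len >= 1:
                mh_reads += count
        else:
            ins_reads += count
            ins_counts[event] = ins_counts.get(event, 0) + count
            if insertion_homology(event, site).is_homologous:
                hom_reads += count
    commonest_ins = None
    if ins_reads >= min_insertions and ins_counts:
        commonest_ins = max(
            ins_counts.items(), key=lambda kv: (kv[1], kv[0].size, kv[0].inserted_seq)
        )[0]
    return {
        "site_id": profile.site_id,
        "n_deletion_reads": del_reads,
        "pct_mh_deletions": 100.0 * mh_reads / del_reads if del_reads else float("nan"),
        "n_insertion_reads": ins_reads,
        "pct_homologous_insertions": (
            100.0 * hom_reads / ins_reads if ins_reads else float("nan")
        ),
        "commonest_insertion": commonest_ins.name if commonest_ins else None,
        "commonest_insertion_seq": commonest_ins.inserted_seq if commonest_ins else None,
        "commonest_insertion_homologous": (
            insertion_homology(commonest_ins, site).is_homologous
            if commonest_ins
            else None
        ),
    }


def homology_summary_table(
    profiles: list[SiteIndelProfile], sites: dict[str, TargetSite],
    min_insertions: int = 5, max_n: int = MAX_MH,
) -> pd.DataFrame:
    rows = [
        site_homology_summary(p, sites[p.site_id], min_insertions=min_insertions, max_n=max_n)
        for p in profiles
    ]
    return pd.DataFrame(rows)
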