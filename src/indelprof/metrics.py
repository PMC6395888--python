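"""Site-level indel-profile statistics.

Precision is the relative frequency of a site's commonest indel:
imprecise <= 0.25 < middle <= 0.5 < precise. Ties for commonest are broken
by prioritizing insertions over deletions, then the longest deletion (and,
symmetrically, the longest then lexicographically-smallest insertion).
Frameshift potential is divisibility of indel size by 3; under a null with
sizes equidistributed across residue classes mod 3, 2/3 of indels frameshift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .calling import (
    DEFAULT_MIN_MAPQ,
    DEFAULT_WINDOW,
    AlignedReadRecord,
    RecordRejected,
    call_read,
    read_overlaps_window,
    record_filters,
)
from .events import IndelEvent, SiteIndelProfile
from .sites import TargetSite

PRECISION_IMPRECISE_MAX = 0.25
PRECISION_MIDDLE_MAX = 0.5

SIZE_SPECTRUM_BINS = (
    ["insertion_gt1", "insertion_1"]
    + [f"deletion_{k}" for k in range(1, 11)]
    + ["deletion_gt10"]
)

#: Expected frameshift fraction when indel sizes are equidistributed mod 3.
FRAMESHIFT_NULL_FRACTION = 2.0 / 3.0


def indel_frequency_table(profile: SiteIndelProfile) -> dict[IndelEvent, float]:
    total = profile.total_indel_reads
    if total == 0:
        raise ValueError(f"profile for {profile.site_id!r} is empty")
    return {e: c / total for e, c in profile.counts.items()}


def _tie_key(event: IndelEvent) -> tuple:
    # insertion beats deletion; then larger size; then lexicographic sequence
    return (event.kind == "insertion", event.size, event.inserted_seq)


def commonest_indel(profile: SiteIndelProfile) -> tuple[IndelEvent, float]:
    freqs = indel_frequency_table(profile)
    best = max(freqs, key=lambda e: (freqs[e],) + _tie_key(e))
    return best, freqs[best]


def precision_class(frequency: float) -> str:
    if not (0.0 < frequency <= 1.0):
        raise ValueError(f"commonest frequency must be in (0,1], got {frequency}")
    if frequency <= PRECISION_IMPRECISE_MAX:
        return "imprecise"
    if frequency <= PRECISION_MIDDLE_MAX:
        return "middle"
    return "precise"


def frameshift_stats(profile: SiteIndelProfile) -> tuple[float, bool]:
    """(count-weighted frameshift fraction, commonest-is-frameshift flag)."""
    total = profile.total_indel_reads
    if total == 0:
        raise ValueError("empty profile")
    shifted = sum(c for e, c in profile.counts.items() if e.is_frameshift)
    commonest, _ = commonest_indel(profile)
    return shifted / total, commonest.is_frameshift


def size_spectrum(profile: SiteIndelProfile) -> pd.Series:
    """Frequencies over the 13 signed-size bins (sums to 1)."""
    total = profile.total_indel_reads
    if total == 0:
        raise ValueError("empty profile")
    values = pd.Series(0.0, index=SIZE_SPECTRUM_BINS, name=profile.site_id)
    for event, count in profile.counts.items():
        if event.kind == "insertion":
            bin_name = "insertion_1" if event.size == 1 else "insertion_gt1"
        elif event.size > 10:
            bin_name = "deletion_gt10"
        else:
            bin_name = f"deletion_{event.size}"
        values[bin_name] += count / total
    return values


def size_spectrum_matrix(profiles: list[SiteIndelProfile]) -> pd.DataFrame:
    return pd.DataFrame([size_spectrum(p) for p in profiles])


def cluster_size_spectra(
    spectra: pd.DataFrame, k: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Ward-D2 hierarchical clustering of size spectra, tree cut at ``k``.

    Returns (labels in 1..k, scipy linkage matrix). The partition depends
    only on pairwise Euclidean distances, so input order does not matter.
    """
    if len(spectra) < k:
        raise ValueError(f"need at least k={k} spectra, got {len(spectra)}")
    Z = linkage(spectra.to_numpy(dtype=float), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


def editing_efficiency(
    records: list[AlignedReadRecord],
    site: TargetSite,
    window: int = DEFAULT_WINDOW,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    apply_filters: bool = True,
) -> float:
    """Fraction of window-spanning reads carrying >= 1 valid windowed indel.

    Substitution-only reads count as unedited (single-nucleotide variants
    are non-variants for efficiency purposes).
    """
    kept = record_filters(records, min_mapq=min_mapq) if apply_filters else records
    n_overlap = n_edited = 0
    for record in kept:
        try:
            if not read_overlaps_window(record, site, window=window):
                continue
            n_overlap += 1
            if call_read(record, site, window=window):
                n_edited += 1
        except RecordRejected:
            continue
    if n_overlap == 0:
        raise ValueError(f"no reads overlap the cut window at {site.site_id!r}")
    return n_edited / n_overlap


@dataclass(frozen=True)
class PrecisionSummary:
    site_id: str
    commonest_event: IndelEvent
    commonest_freq: float
    n_distinct: int
    precision_class: str
    frameshift_fraction: float
    insertion_fraction: float
    median_abs_size: float


def summarize_profile(profile: SiteIndelProfile) -> PrecisionSummary:
    freqs = indel_frequency_table(profile)
    commonest, cfreq = commonest_indel(profile)
    frameshift_frac, _ = frameshift_stats(profile)
    ins_frac = sum(f for e, f in freqs.items() if e.kind == "insertion")
    sizes = np.repeat(
        [e.size for e in profile.counts], [profile.counts[e] for e in profile.counts]
    )
    return PrecisionSummary(
        site_id=profile.site_id,
        commonest_event=commonest,
        commonest_freq=cfreq,
        n_distinct=profile.n_distinct,
        precision_class=precision_class(cfreq),
        frameshift_fraction=frameshift_frac,
        insertion_fraction=ins_frac,
        median_abs_size=float(np.median(sizes)),
    )


def precision_summary_table(profiles: list[SiteIndelProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        s = summarize_profile(p)
        rows.append(
            {
                "site_id": s.site_id,
                "commonest_name": s.commonest_event.name,
                "commonest_inserted_seq": s.commonest_event.inserted_seq,
                "commonest_freq": s.commonest_freq,
                "n_distinct": s.n_distinct,
                "normalized_n_distinct": s.n_distinct / p.total_indel_reads,
                "precision_class": s.precision_class,
                "frameshift_fraction": s.frameshift_fraction,
                "insertion_fraction": s.insertion_fraction,
                "median_abs_size": s.median_abs_size,
            }
        )
    return pd.DataFrame(rows)


def external_profile_filters(
    profiles: list[SiteIndelProfile],
    efficiencies: dict[str, float],
    min_indel_freq: float = 0.01,
    min_efficiency: float = 0.10,
) -> list[SiteIndelProfile]:
    """Filters for externally generated profiles (time-course style data).

    Events below ``min_indel_freq`` (of the site's indel reads) are removed,
    then sites with efficiency below ``min_efficiency`` are dropped entirely.
    Frequencies are NOT recomputed after event removal, so applying the
    filter twice can remove further events; callers apply it once.
    """
    out = []
    for profile in profiles:
        if efficiencies[profile.site_id] < min_efficiency:
            continue
        freqs = indel_frequency_table(profile)
        kept = {e: c for e, c in profile.counts.items() if freqs[e] >= min_indel_freq}
        if not kept:
            continue
        out.append(
            SiteIndelProfile(
                site_id=profile.site_id,
                counts=type(profile.counts)(kept),
                n_reads_total=profile.n_reads_total,
                library_size=profile.library_size,
                replicate_id=profile.replicate_id,
            )
        )
    return out
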