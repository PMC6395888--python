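"""Synthetic target sites, repair-outcome truth models, and aligned reads.

The generator emulates pooled CRISPR amplicon sequencing: most reads at a
site come from unedited cells; edited reads carry one indel near the cut.
Outcome structure follows the repair biology the analysis assumes:

* 1-nt insertions at the cut are templated on the protospacer -4 base (the
  base immediately 5' of the blunt cut) with high probability, and the
  per-site insertion mass depends on which base sits at -4;
* deletions overlap the cut and are weighted toward spans with flanking
  microhomology, ``(1 + mh_len) ** mh_weight_exponent``, with geometric
  size decay;
* a small per-read noise-indel rate and per-base substitution rate stand in
  for sequencing error.

Outcome tables are canonicalized with the same left-alignment used by the
caller, so with error rates at zero, called profiles match realized truth
counts exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import pysam

from .calling import AlignedReadRecord, RawIndel, left_align_indel
from .events import IndelEvent
from .homology import deletion_mh
from .sites import TargetSite, read_site_table, revcomp, write_site_table

_BASES = ("A", "C", "G", "T")

#: Per-site probability that repair yields insertions, by the -4 base.
#: T and A strongly favour templated insertions; G strongly favours deletions.
DEFAULT_INSERTION_RATE_BY_MINUS4 = {"T": 0.91, "A": 0.77, "C": 0.45, "G": 0.21}

#: Fraction of 1-nt insertions that copy the -4 base (insertion homology).
DEFAULT_P_HOMOLOGOUS_INSERTION = 0.82


@dataclass
class RepairTruthParams:
    insertion_rate_by_minus4: dict = field(
        default_factory=lambda: dict(DEFAULT_INSERTION_RATE_BY_MINUS4)
    )
    p_homologous_insertion: float = DEFAULT_P_HOMOLOGOUS_INSERTION
    mh_weight_exponent: float = 2.0
    deletion_size_decay: float = 0.75
    edited_fraction: float = 0.3
    noise_indel_rate: float = 1e-4
    substitution_error_rate: float = 1e-3

    def __post_init__(self) -> None:
        for b in _BASES:
            rate = self.insertion_rate_by_minus4.get(b)
            if rate is None or not (0.0 <= rate <= 1.0):
                raise ValueError(f"insertion_rate_by_minus4[{b}] must be in [0,1]")
        for name in ("p_homologous_insertion", "edited_fraction",
                     "noise_indel_rate", "substitution_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.mh_weight_exponent < 0:
            raise ValueError("mh_weight_exponent must be >= 0")
        if not (0.0 < self.deletion_size_decay < 1.0):
            raise ValueError("deletion_size_decay must be in (0,1)")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RepairTruthParams":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class RepairTruth:
    """Ground-truth outcome distribution for one site."""

    site_id: str
    outcomes: list  # list[(IndelEvent, probability)]
    params: RepairTruthParams
    mh_lens: dict = field(default_factory=dict)  # deletion event -> mh_len

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.outcomes)
        if self.outcomes and abs(total - 1.0) > 1e-9:
            raise ValueError(f"outcome probabilities sum to {total}, not 1")

    @property
    def insertion_mass(self) -> float:
        return sum(p for e, p in self.outcomes if e.kind == "insertion")


def make_target_sites(
    n: int,
    base_probs: dict[str, float] | None = None,
    seed: int = 0,
    flank_len: int = 200,
    gene_prefix: str = "GENE",
) -> list[TargetSite]:
    """Draw ``n`` synthetic target sites with i.i.d. random protospacers/flanks.

    Strands alternate so that minus-strand projection is always exercised.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if base_probs is None:
        base_probs = {b: 0.25 for b in _BASES}
    p = np.array([base_probs.get(b, 0.0) for b in _BASES], dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("base_probs must be nonnegative and sum to 1")
    if flank_len < 50:
        raise ValueError("flank_len must be >= 50")
    rng = np.random.default_rng(seed)
    bases = np.array(_BASES)
    sites = []
    for i in range(n):
        protospacer = "".join(rng.choice(bases, size=20, p=p))
        pam = str(rng.choice(bases, p=p)) + "GG"
        upstream = "".join(rng.choice(bases, size=flank_len, p=p))
        downstream = "".join(rng.choice(bases, size=flank_len, p=p))
        strand = "+" if i % 2 == 0 else "-"
        sites.append(
            TargetSite.from_guide_window(
                site_id=f"site_{i:05d}",
                gene=f"{gene_prefix}{i // 3:04d}",
                protospacer=protospacer,
                pam=pam,
                strand=strand,
                ref_name=f"amplicon_{i:05d}",
                upstream_flank=upstream,
                downstream_flank=downstream,
            )
        )
    return sites


def enumerate_mh_candidates(
    window_seq: str, cut_index: int, max_del: int, max_mh: int = 50
) -> list[tuple[tuple[int, int], int]]:
    """All deletion spans touching the cut boundary, with their MH lengths.

    Returns ``((start, size), mh_len)`` in ``window_seq`` coordinates for
    every span of size 1..max_del satisfying start <= cut_index <= start+size,
    scored with the same microhomology rule used for observed deletions.
    """
    if not (1 <= max_del <= len(window_seq) // 2):
        raise ValueError("max_del must be in [1, len(window_seq)/2]")
    if not (max_del <= cut_index <= len(window_seq) - max_del):
        raise ValueError("cut_index too close to the window edge")
    out = []
    for size in range(1, max_del + 1):
        for start in range(cut_index - size, cut_index + 1):
            deleted = window_seq[start : start + size]
            ann = deletion_mh(
                deleted, window_seq[:start], window_seq[start + size :], max_n=max_mh
            )
            out.append(((start, size), ann.mh_len))
    return out


def _canonical_deletion_event(
    site: TargetSite, start: int, size: int
) -> tuple[IndelEvent, int, int]:
    """Left-align a guide-strand deletion span and express it cut-relative."""
    guide = site.guide_strand_seq
    cut = site.guide_strand_cut
    raw = left_align_indel(RawIndel(kind="deletion", pos=start, size=size), guide)
    start_rel = raw.pos - cut if raw.pos < cut else raw.pos - cut + 1
    event = IndelEvent(
        site_id=site.site_id, kind="deletion", start_rel=start_rel, size=size
    )
    return event, raw.pos, size


def _canonical_insertion_event(site: TargetSite, inserted: str) -> IndelEvent:
    """1-nt (or longer) insertion at the cut, left-aligned like the caller does."""
    guide = site.guide_strand_seq
    cut = site.guide_strand_cut
    raw = left_align_indel(
        RawIndel(kind="insertion", pos=cut, size=len(inserted), inserted_seq=inserted),
        guide,
    )
    return IndelEvent(
        site_id=site.site_id,
        kind="insertion",
        start_rel=raw.pos - cut,
        size=len(inserted),
        inserted_seq=raw.inserted_seq,
    )


def build_truth_model(
    site: TargetSite,
    params: RepairTruthParams | None = None,
    seed: int = 0,
    max_del: int = 15,
    window: int = 5,
) -> RepairTruth:
    """Forward model of repair outcomes at one site.

    Insertion mass is set by the -4 base; within it, the templated (-4-copying)
    insertion takes ``p_homologous_insertion`` and the three other bases share
    the rest. Deletion mass is spread over cut-overlapping spans that remain
    within the detection window after left alignment, weighted by
    ``(1+mh_len)**mh_weight_exponent * decay**(size-1)``.
    """
    params = params if params is not None else RepairTruthParams()
    del seed  # the truth table is deterministic; kept for interface symmetry
    guide = site.guide_strand_seq
    cut = site.guide_strand_cut
    if cut < max_del or len(guide) - cut < max_del:
        raise ValueError("site flanks too short to enumerate deletions")

    ins_mass = params.insertion_rate_by_minus4[site.minus4_base]
    outcomes: dict[IndelEvent, float] = {}
    if ins_mass > 0:
        p_hom = params.p_homologous_insertion
        # left alignment can push an insertion out of the detection window at
        # long homopolymers; renormalize over the detectable insertions
        raw_ins: dict[IndelEvent, float] = {}
        for base in _BASES:
            p = p_hom if base == site.minus4_base else (1 - p_hom) / 3
            if p > 0:
                event = _canonical_insertion_event(site, base)
                if abs(event.start_rel) <= window:
                    raw_ins[event] = raw_ins.get(event, 0.0) + p
        kept = sum(raw_ins.values())
        if kept > 0:
            for event, p in raw_ins.items():
                outcomes[event] = outcomes.get(event, 0.0) + ins_mass * p / kept
        else:
            ins_mass = 0.0  # no detectable insertion; all mass to deletions

    mh_lens: dict[IndelEvent, int] = {}
    del_mass = 1.0 - ins_mass
    if del_mass > 0:
        weights: dict[IndelEvent, float] = {}
        seen: set[tuple[int, int]] = set()
        for (start, size), mh_len in enumerate_mh_candidates(
            guide, cut, max_del=max_del, max_mh=50
        ):
            event, canon_start, _ = _canonical_deletion_event(site, start, size)
            if (canon_start, size) in seen:
                continue
            seen.add((canon_start, size))
            if abs(event.start_rel) > window:
                continue  # would be dropped by the caller's window rule
            canon_deleted = guide[canon_start : canon_start + size]
            ann = deletion_mh(
                canon_deleted, guide[:canon_start], guide[canon_start + size :]
            )
            w = (1.0 + ann.mh_len) ** params.mh_weight_exponent
            w *= params.deletion_size_decay ** (size - 1)
            weights[event] = w
            mh_lens[event] = ann.mh_len
        total_w = sum(weights.values())
        if total_w <= 0:
            raise ValueError("no deletion candidates within the window")
        for event, w in weights.items():
            outcomes[event] = outcomes.get(event, 0.0) + del_mass * w / total_w

    table = sorted(outcomes.items(), key=lambda kv: kv[0].key)
    return RepairTruth(site_id=site.site_id, outcomes=table, params=params,
                       mh_lens=mh_lens)


@dataclass
class SimulatedReadBundle:
    site_id: str
    records: list  # list[AlignedReadRecord]
    truth_labels: list  # per read: "unedited" | "noise" | outcome index (int as str)
    seed: int
    site: TargetSite | None = None
    truth: RepairTruth | None = None

    def __post_init__(self) -> None:
        if len(self.records) != len(self.truth_labels):
            raise ValueError("one truth label per record required")


def _event_to_ref_raw(event: IndelEvent, site: TargetSite) -> RawIndel:
    """Express a canonical guide-strand event as a reference-strand raw indel."""
    cut = site.guide_strand_cut
    if event.kind == "insertion":
        guide_pos = cut + event.start_rel
        if site.strand == "+":
            return RawIndel("insertion", guide_pos, event.size, event.inserted_seq)
        return RawIndel(
            "insertion", len(site) - guide_pos, event.size, revcomp(event.inserted_seq)
        )
    guide_pos = cut + event.start_rel if event.start_rel < 0 else cut + event.start_rel - 1
    if site.strand == "+":
        return RawIndel("deletion", guide_pos, event.size)
    return RawIndel("deletion", len(site) - (guide_pos + event.size), event.size)


def simulate_reads(
    site: TargetSite,
    truth: RepairTruth,
    n_reads: int,
    seed: int = 0,
    read_half_span: int = 75,
    start_jitter: int = 10,
) -> SimulatedReadBundle:
    """Emit pre-aligned reads realizing the truth distribution.

    Each read spans the cut by ``read_half_span`` on both sides (with a small
    uniform start jitter), is unedited with probability ``1 - edited_fraction``
    and otherwise carries one sampled outcome. Unedited reads acquire a
    spurious 1-nt indel at ``noise_indel_rate``; substitution errors hit every
    read at ``substitution_error_rate`` per base. MAPQ is 60 and no read is
    duplicate-flagged.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    params = truth.params
    ref = site.ref_seq
    cut_ref = site.cut_coord
    probs = np.array([p for _, p in truth.outcomes])
    ref_raws = [_event_to_ref_raw(e, site) for e, _ in truth.outcomes]

    records: list[AlignedReadRecord] = []
    labels: list[str] = []
    for i in range(n_reads):
        jitter = int(rng.integers(-start_jitter, start_jitter + 1))
        a = max(0, cut_ref - read_half_span + jitter)
        b = min(len(ref), cut_ref + read_half_span + jitter)
        label = "unedited"
        raw: RawIndel | None = None
        if len(probs) and rng.random() < params.edited_fraction:
            idx = int(rng.choice(len(probs), p=probs))
            label = str(idx)
            raw = ref_raws[idx]
        elif rng.random() < params.noise_indel_rate:
            label = "noise"
            # spurious 1-nt indel near the cut
            offset = int(rng.integers(-5, 6))
            if rng.random() < 0.5:
                pos = min(max(a + 1, cut_ref + offset), b - 2)
                raw = RawIndel("deletion", pos, 1)
            else:
                pos = min(max(a + 1, cut_ref + offset), b - 1)
                raw = RawIndel("insertion", pos, 1, str(rng.choice(list(_BASES))))

        if raw is None:
            query = ref[a:b]
            cigar = f"{b - a}M"
        elif raw.kind == "deletion":
            query = ref[a : raw.pos] + ref[raw.pos + raw.size : b]
            cigar = f"{raw.pos - a}M{raw.size}D{b - raw.pos - raw.size}M"
        else:
            query = ref[a : raw.pos] + raw.inserted_seq + ref[raw.pos : b]
            cigar = f"{raw.pos - a}M{raw.size}I{b - raw.pos}M"

        if params.substitution_error_rate > 0:
            n_err = rng.binomial(len(query), params.substitution_error_rate)
            if n_err:
                q = list(query)
                for pos in rng.choice(len(q), size=n_err, replace=False):
                    alternatives = [x for x in _BASES if x != q[pos]]
                    q[pos] = str(rng.choice(alternatives))
                query = "".join(q)

        records.append(
            AlignedReadRecord(
                read_id=f"{site.site_id}_read_{i:06d}",
                ref_name=site.ref_name,
                ref_start=a,
                cigar=cigar,
                query_seq=query,
                mapq=60,
                is_duplicate=False,
                is_proper_pair=True,
            )
        )
        labels.append(label)
    return SimulatedReadBundle(
        site_id=site.site_id, records=records, truth_labels=labels,
        seed=seed, site=site, truth=truth,
    )


def realized_truth_counts(bundle: SimulatedReadBundle) -> dict[IndelEvent, int]:
    """Counts of truth outcomes actually carried by the bundle's reads."""
    assert bundle.truth is not None
    counts: dict[IndelEvent, int] = {}
    for label in bundle.truth_labels:
        if label in ("unedited", "noise"):
            continue
        event = bundle.truth.outcomes[int(label)][0]
        counts[event] = counts.get(event, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# fixtures: SAM + FASTA + TSV round trip


def write_fixture(bundles: SimulatedReadBundle | list, directory) -> None:
    """Write bundles as reads.sam / reference.fa / truth.tsv / sites.tsv."""
    import os

    if isinstance(bundles, SimulatedReadBundle):
        bundles = [bundles]
    os.makedirs(directory, exist_ok=True)
    sites = [b.site for b in bundles]
    if any(s is None for s in sites):
        raise ValueError("bundles must carry their TargetSite to be written")

    with open(os.path.join(directory, "reference.fa"), "w") as fh:
        for s in sites:
            fh.write(f">{s.ref_name}\n{s.ref_seq}\n")
    write_site_table(sites, os.path.join(directory, "sites.tsv"))

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": s.ref_name, "LN": len(s)} for s in sites],
    }
    tid = {s.ref_name: i for i, s in enumerate(sites)}
    with pysam.AlignmentFile(
        os.path.join(directory, "reads.sam"), "wh", header=header
    ) as sam:
        for bundle in bundles:
            for rec in bundle.records:
                seg = pysam.AlignedSegment(sam.header)
                seg.query_name = rec.read_id
                seg.query_sequence = rec.query_seq
                seg.reference_id = tid[rec.ref_name]
                seg.reference_start = rec.ref_start
                seg.cigarstring = rec.cigar
                seg.mapping_quality = rec.mapq
                seg.is_duplicate = rec.is_duplicate
                seg.is_paired = rec.is_proper_pair
                seg.is_proper_pair = rec.is_proper_pair
                sam.write(seg)

    rows = []
    for bundle in bundles:
        for rec, label in zip(bundle.records, bundle.truth_labels):
            name = ""
            if label not in ("unedited", "noise"):
                name = bundle.truth.outcomes[int(label)][0].name if bundle.truth else ""
            rows.append(
                {"read_id": rec.read_id, "site_id": bundle.site_id,
                 "label": label, "indel_name": name, "seed": bundle.seed}
            )
    pd.DataFrame(
        rows, columns=["read_id", "site_id", "label", "indel_name", "seed"]
    ).to_csv(os.path.join(directory, "truth.tsv"), sep="\t", index=False)


def read_sam_records(path) -> dict[str, list[AlignedReadRecord]]:
    """Load a SAM/BAM file into per-reference AlignedReadRecord lists."""
    out: dict[str, list[AlignedReadRecord]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for seg in sam.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            rec = AlignedReadRecord(
                read_id=seg.query_name,
                ref_name=seg.reference_name,
                ref_start=seg.reference_start,
                cigar=seg.cigarstring,
                query_seq=seg.query_sequence,
                mapq=seg.mapping_quality,
                is_duplicate=seg.is_duplicate,
                is_proper_pair=seg.is_proper_pair,
            )
            out.setdefault(seg.reference_name, []).append(rec)
    return out


def read_fixture(directory) -> list[SimulatedReadBundle]:
    """Inverse of :func:`write_fixture` (truth tables are not reconstructed)."""
    import os

    sam_path = os.path.join(directory, "reads.sam")
    sites_path = os.path.join(directory, "sites.tsv")
    truth_path = os.path.join(directory, "truth.tsv")
    for p in (sam_path, sites_path, truth_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    sites = read_site_table(sites_path)
    by_ref = read_sam_records(sam_path)
    truth_df = pd.read_csv(truth_path, sep="\t", dtype={"label": str})
    labels_by_read = dict(zip(truth_df["read_id"], truth_df["label"]))
    seed_by_site = dict(zip(truth_df["site_id"], truth_df["seed"]))
    bundles = []
    for site in sites:
        records = by_ref.get(site.ref_name, [])
        labels = [labels_by_read[r.read_id] for r in records]
        bundles.append(
            SimulatedReadBundle(
                site_id=site.site_id,
                records=records,
                truth_labels=labels,
                seed=int(seed_by_site.get(site.site_id, 0)),
                site=site,
            )
        )
    return bundles
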