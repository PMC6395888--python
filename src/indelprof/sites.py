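"""Target-site model and coordinate conventions.

A SpCas9 target is a 20-nt protospacer followed by an NGG PAM. Protospacer
positions are numbered -20..-1, with -1 adjacent to the PAM. The blunt cut
falls between positions -4 and -3 (3 nt upstream of the PAM); position -4 is
therefore the base immediately 5' of the cut on the protospacer strand.

Cut-relative coordinates used throughout the package: the cut boundary is 0;
bases 5' of the cut (on the protospacer strand) are -1, -2, ...; bases 3' are
+1, +2, .... A deletion's coordinate is its leftmost deleted base; an
insertion's coordinate is the boundary at which bases are inserted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: offset of the cut boundary from the protospacer start: the cut lies after
#: protospacer index 16 (position -4), i.e. 17 bases into the protospacer.
CUT_OFFSET_IN_PROTOSPACER = 17

_PAM_RE = re.compile(r"^[ACGT]GG$")
_DNA_RE = re.compile(r"^[ACGT]*$")


def revcomp(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetSite:
    """One CRISPR target: protospacer + PAM with flanking reference sequence.

    ``cut_coord`` is a 0-based boundary coordinate on the reference window
    (half-open convention): the cut lies between reference positions
    ``cut_coord - 1`` and ``cut_coord``. For minus-strand sites the
    protospacer reads off the reverse complement of the reference window.
    """

    site_id: str
    gene: str
    protospacer: str
    pam: str
    strand: str
    ref_name: str
    cut_coord: int
    upstream_flank: str
    downstream_flank: str

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError(f"protospacer must be 20 nt, got {len(self.protospacer)}")
        if not _PAM_RE.match(self.pam):
            raise ValueError(f"PAM must match NGG, got {self.pam!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not _DNA_RE.match(self.protospacer):
            raise ValueError("protospacer contains non-ACGT characters")
        if len(self.upstream_flank) < 50 or len(self.downstream_flank) < 50:
            raise ValueError("flanks must be at least 50 nt")
        # the -4 base sits immediately 5' of the cut on the protospacer strand;
        # cut_coord must agree with that boundary projected onto the reference
        expected = self.guide_to_ref_boundary(self.guide_strand_cut)
        if self.cut_coord != expected:
            raise ValueError(
                f"cut_coord {self.cut_coord} inconsistent with flanks/strand "
                f"(expected {expected})"
            )

    @property
    def minus4_base(self) -> str:
        """Reference base at protospacer position -4 (index 16)."""
        return self.protospacer[16]

    @property
    def guide_strand_seq(self) -> str:
        """Full window sequence read on the protospacer strand."""
        return self.upstream_flank + self.protospacer + self.pam + self.downstream_flank

    @property
    def guide_strand_cut(self) -> int:
        """Cut boundary within :attr:`guide_strand_seq`."""
        return len(self.upstream_flank) + CUT_OFFSET_IN_PROTOSPACER

    @property
    def ref_seq(self) -> str:
        """Reference window on the reference (+) strand."""
        s = self.guide_strand_seq
        return s if self.strand == "+" else revcomp(s)

    def __len__(self) -> int:
        return len(self.guide_strand_seq)

    @classmethod
    def from_guide_window(
        cls,
        site_id: str,
        gene: str,
        protospacer: str,
        pam: str,
        strand: str,
        ref_name: str,
        upstream_flank: str,
        downstream_flank: str,
    ) -> "TargetSite":
        """Build a site from its protospacer-strand window, deriving cut_coord."""
        guide_cut = len(upstream_flank) + CUT_OFFSET_IN_PROTOSPACER
        total = len(upstream_flank) + 23 + len(downstream_flank)
        cut_coord = guide_cut if strand == "+" else total - guide_cut
        return cls(
            site_id=site_id,
            gene=gene,
            protospacer=protospacer,
            pam=pam,
            strand=strand,
            ref_name=ref_name,
            cut_coord=cut_coord,
            upstream_flank=upstream_flank,
            downstream_flank=downstream_flank,
        )

    def guide_to_ref_boundary(self, boundary: int) -> int:
        """Map a boundary coordinate on the protospacer strand to the reference."""
        return boundary if self.strand == "+" else len(self) - boundary


SITE_TABLE_COLUMNS = [
    "site_id",
    "gene",
    "protospacer",
    "pam",
    "strand",
    "ref_name",
    "cut_coord",
    "upstream_flank",
    "downstream_flank",
]


def write_site_table(sites: list[TargetSite], path) -> None:
    pd.DataFrame(
        [{c: getattr(s, c) for c in SITE_TABLE_COLUMNS} for s in sites]
    ).to_csv(path, sep="\t", index=False)


def read_site_table(path) -> list[TargetSite]:
    df = pd.read_csv(path, sep="\t", dtype={"protospacer": str, "pam": str})
    missing = set(SITE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    return [
        TargetSite(**{c: row[c] for c in SITE_TABLE_COLUMNS})
        for row in df.to_dict("records")
    ]
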