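"""Reference sequence and target-region handling.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open — the same convention SAM/BAM
records use in memory.  1-based inclusive coordinates appear only at I/O
boundaries: the ``chr:start-end`` region text accepted on the command line
and the VCF output.  BED input is already 0-based half-open and is taken
as-is.

The built-in default region is the FLT3 locus on GRCh37
(``chr13:28577000-28676800``), but every operation takes the region as an
explicit parameter — nothing in the caller is FLT3-specific.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

from Bio import SeqIO

__all__ = [
    "TargetRegion",
    "ReferenceContig",
    "FLT3_REGION_GRCH37",
    "load_reference",
    "resolve_region",
    "window",
]

_REGION_RE = re.compile(r"^(?P<contig>[^:\s]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


@dataclass(frozen=True)
class TargetRegion:
    """A genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("region contig name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end (0-based half-open)"
            )

    @classmethod
    def from_text(cls, text: str) -> "TargetRegion":
        """Parse ``chr:start-end`` text (1-based inclusive, commas allowed)."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(
                f"cannot parse region {text!r}; expected 'chr:start-end' "
                "with 1-based inclusive coordinates"
            )
        start1 = int(m.group("start").replace(",", ""))
        end1 = int(m.group("end").replace(",", ""))
        if start1 < 1 or end1 < start1:
            raise ValueError(f"invalid region coordinates in {text!r}")
        return cls(m.group("contig"), start1 - 1, end1)

    @classmethod
    def from_bed_line(cls, line: str) -> "TargetRegion":
        """Parse the first three columns of a BED line (0-based half-open)."""
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line needs >= 3 tab-separated fields: {line!r}")
        return cls(fields[0], int(fields[1]), int(fields[2]))

    def to_text(self) -> str:
        """Render as 1-based inclusive ``chr:start-end`` text."""
        return f"{self.contig}:{self.start + 1}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


#: Default target: the FLT3 locus, GRCh37 (1-based 28577000-28676800).
FLT3_REGION_GRCH37 = TargetRegion("chr13", 28576999, 28676800)


@dataclass(frozen=True)
class ReferenceContig:
    """One reference sequence held in memory, uppercase A/C/G/T/N."""

    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end); bounds are checked, not clamped."""
        if not (0 <= start <= end <= len(self.sequence)):
            raise IndexError(
                f"fetch [{start}, {end}) outside contig {self.name!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start:end]


def load_reference(fasta_source: str | os.PathLike, contig: str) -> ReferenceContig:
    """Load one contig from a FASTA file, normalising to uppercase.

    Raises ``FileNotFoundError`` for a missing file and ``LookupError``
    (naming the contigs that are present) for a missing record.
    """
    if not os.path.exists(fasta_source):
        raise FileNotFoundError(f"reference FASTA not found: {fasta_source}")
    names = []
    for record in SeqIO.parse(str(fasta_source), "fasta"):
        if record.id == contig:
            return ReferenceContig(contig, str(record.seq).upper())
        names.append(record.id)
    raise LookupError(
        f"contig {contig!r} not found in {fasta_source}; available: {names}"
    )


def resolve_region(
    spec: str | None,
    default: TargetRegion = FLT3_REGION_GRCH37,
) -> TargetRegion:
    """Resolve a region given as text, a BED line/file, or nothing.

    ``spec`` may be ``None`` (returns ``default``), a ``chr:start-end``
    string (1-based inclusive), a single tab-separated BED line, or a path
    to a BED file whose first interval is used.
    """
    if spec is None or spec == "":
        return default
    if "\t" in spec:
        return TargetRegion.from_bed_line(spec)
    if os.path.exists(spec):
        with open(spec) as handle:
            for line in handle:
                if line.strip() and not line.startswith(("#", "track", "browser")):
                    return TargetRegion.from_bed_line(line)
        raise ValueError(f"BED file {spec!r} contains no intervals")
    return TargetRegion.from_text(spec)


def window(ref: ReferenceContig, center: int, flank: int) -> tuple[str, int]:
    """Return ``(subsequence, offset)`` for [center-flank, center+flank).

    The window is clamped to the contig; ``offset`` is the contig
    coordinate of the first returned base, so a match at position ``p``
    inside the subsequence sits at ``offset + p`` on the contig.
    """
    if not (0 <= center <= len(ref)):
        raise ValueError(
            f"window center {center} outside contig {ref.name!r} "
            f"of length {len(ref)}"
        )
    if flank < 0:
        raise ValueError("flank must be non-negative")
    start = max(0, center - flank)
    end = min(len(ref), center + flank)
    return ref.sequence[start:end], start
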