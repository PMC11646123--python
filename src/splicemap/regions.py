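"""Composite RNA-map coordinate system and strand-aware sequence extraction.

Around each cassette exon eight segments are cut, in transcript order:

    up_exon_3p | up_intron_5p ... up_intron_3p | cassette_5p ... cassette_3p
               | dn_intron_5p ... dn_intron_3p | dn_exon_5p

Exonic ends take up to ``exon_end_len`` (cassette) / ``const_exon_len``
(flanking constitutive exons) nucleotides; each flanking intron
contributes up to ``intron_end_len`` from both of its ends.  Features
shorter than twice the requested length are split at their midpoint
between the 5'- and 3'-end segments with no overlap (the 5' half gets
the extra base when the length is odd).  All sequences are reported in
transcript sense (reverse-complemented for minus-strand events) and
uppercased; IUPAC ambiguity codes other than N are mapped to N.
"""

from __future__ import annotations

from dataclasses import dataclass

from .events import SplicingEvent

#: transcript-order segment labels with (feature, anchored end) metadata.
SEGMENT_LABELS = (
    "up_exon_3p", "up_intron_5p", "up_intron_3p",
    "cassette_5p", "cassette_3p",
    "dn_intron_5p", "dn_intron_3p", "dn_exon_5p",
)

_SEGMENT_ANCHOR = {
    "up_exon_3p": "3p", "up_intron_5p": "5p", "up_intron_3p": "3p",
    "cassette_5p": "5p", "cassette_3p": "3p",
    "dn_intron_5p": "5p", "dn_intron_3p": "3p", "dn_exon_5p": "5p",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MapLayout:
    """Maximum segment lengths of the composite RNA-map axis.

    Defaults: 135 nt exon ends, 250 nt intron ends, 135 nt constitutive
    exon ends, 31 nt sliding window.
    """

    exon_end_len: int = 135
    intron_end_len: int = 250
    const_exon_len: int = 135
    window_len: int = 31

    def __post_init__(self) -> None:
        if self.window_len % 2 != 1:
            raise ValueError("window_len must be odd")
        if min(self.exon_end_len, self.intron_end_len, self.const_exon_len) \
                < self.window_len:
            raise ValueError("segment lengths must be >= window_len")

    def slot_len(self, label: str) -> int:
        if label in ("cassette_5p", "cassette_3p"):
            return self.exon_end_len
        if label in ("up_exon_3p", "dn_exon_5p"):
            return self.const_exon_len
        return self.intron_end_len

    @property
    def slot_starts(self) -> dict[str, int]:
        starts, pos = {}, 0
        for lab in SEGMENT_LABELS:
            starts[lab] = pos
            pos += self.slot_len(lab)
        return starts

    @property
    def axis_len(self) -> int:
        return sum(self.slot_len(lab) for lab in SEGMENT_LABELS)

    def anchor(self, label: str) -> str:
        return _SEGMENT_ANCHOR[label]


@dataclass(frozen=True)
class Segment:
    """One extracted map segment: transcript-sense sequence + genomic interval."""

    label: str
    seq: str
    genomic_start: int
    genomic_end: int

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RegionSet:
    """All eight segments of one event, in transcript order."""

    event_id: str
    chrom: str
    strand: str
    segments: tuple[Segment, ...]

    def segment(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def composite_len(self) -> int:
        return sum(len(s) for s in self.segments)

    def composite_position(self, segment_label: str, offset: int) -> int:
        """Map (segment, within-segment offset) to the event's concatenated axis."""
        pos = 0
        for s in self.segments:
            if s.label == segment_label:
                if not 0 <= offset < len(s):
                    raise ValueError(
                        f"offset {offset} outside segment {segment_label} "
                        f"of length {len(s)}")
                return pos + offset
            pos += len(s)
        raise KeyError(segment_label)

    def from_composite(self, position: int) -> tuple[str, int]:
        """Inverse of :meth:`composite_position`."""
        pos = position
        for s in self.segments:
            if pos < len(s):
                return s.label, pos
            pos -= len(s)
        raise ValueError(f"composite position {position} beyond axis "
                         f"length {self.composite_len}")


def _split_lengths(feature_len: int, requested: int) -> tuple[int, int]:
    """(5' segment, 3' segment) lengths for a double-ended feature."""
    if feature_len >= 2 * requested:
        return requested, requested
    five = (feature_len + 1) // 2
    return five, feature_len - five


def segment_intervals(event: SplicingEvent, layout: MapLayout) -> dict[str, tuple[int, int]]:
    """Genomic half-open interval of every map segment of an event.

    Shared between extraction and the synthetic-genome planter so that
    planted motif positions and extracted sequences agree by
    construction.
    """
    plus = event.strand == "+"
    if plus:
        up_exon = (event.upstream_exon_start, event.upstream_exon_end)
        dn_exon = (event.downstream_exon_start, event.downstream_exon_end)
        up_intron = (event.upstream_exon_end, event.cassette_start)
        dn_intron = (event.cassette_end, event.downstream_exon_start)
    else:
        up_exon = (event.upstream_exon_start, event.upstream_exon_end)
        dn_exon = (event.downstream_exon_start, event.downstream_exon_end)
        up_intron = (event.cassette_end, event.upstream_exon_start)
        dn_intron = (event.downstream_exon_end, event.cassette_start)
    cassette = (event.cassette_start, event.cassette_end)

    def five_slice(iv: tuple[int, int], length: int) -> tuple[int, int]:
        s, e = iv
        return (s, s + length) if plus else (e - length, e)

    def three_slice(iv: tuple[int, int], length: int) -> tuple[int, int]:
        s, e = iv
        return (e - length, e) if plus else (s, s + length)

    out: dict[str, tuple[int, int]] = {}
    out["up_exon_3p"] = three_slice(
        up_exon, min(layout.const_exon_len, up_exon[1] - up_exon[0]))
    out["dn_exon_5p"] = five_slice(
        dn_exon, min(layout.const_exon_len, dn_exon[1] - dn_exon[0]))
    for feat, iv, req in (("up_intron", up_intron, layout.intron_end_len),
                          ("cassette", cassette, layout.exon_end_len),
                          ("dn_intron", dn_intron, layout.intron_end_len)):
        l5, l3 = _split_lengths(iv[1] - iv[0], req)
        prefix = {"up_intron": "up_intron", "cassette": "cassette",
                  "dn_intron": "dn_intron"}[feat]
        out[f"{prefix}_5p"] = five_slice(iv, l5)
        out[f"{prefix}_3p"] = three_slice(iv, l3)
    return out


def _clean(seq: str) -> str:
    seq = seq.upper()
    if any(c not in "ACGTN" for c in seq):
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
    return seq


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] padding out-of-bounds bases with N."""
    try:
        record = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} absent from genome FASTA") from None
    chrom_len = len(record)
    lo, hi = max(start, 0), min(end, chrom_len)
    core = str(record[lo:hi]) if hi > lo else ""
    return "N" * (lo - start) + _clean(core) + "N" * (end - hi)


def extract_regions(event: SplicingEvent, genome, layout: MapLayout | None = None
                    ) -> RegionSet:
    """Extract all eight transcript-sense map segments for an event.

    ``genome`` is any mapping of chromosome name to a sliceable
    sequence record (a ``pyfaidx.Fasta`` or a plain dict of strings).
    """
    layout = layout or MapLayout()
    intervals = segment_intervals(event, layout)
    segments = []
    for label in SEGMENT_LABELS:
        gstart, gend = intervals[label]
        seq = _fetch(genome, event.chrom, gstart, gend)
        if event.strand == "-":
            seq = reverse_complement(seq)
        segments.append(Segment(label=label, seq=seq,
                                genomic_start=gstart, genomic_end=gend))
    return RegionSet(event_id=event.event_id, chrom=event.chrom,
                     strand=event.strand, segments=tuple(segments))


def export_segments_bed(region_sets: list[RegionSet], path) -> None:
    """BED6 export of every segment for inspection in a genome browser."""
    with open(path, "w") as fh:
        for rs in region_sets:
            for seg in rs.segments:
                fh.write(f"{rs.chrom}\t{seg.genomic_start}\t{seg.genomic_end}\t"
                         f"{rs.event_id}|{seg.label}\t0\t{rs.strand}\n")
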