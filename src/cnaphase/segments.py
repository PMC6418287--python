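"""Copy-number segments: validity thresholds, shared-CNA candidates and
breakpoint concordance.

Two tumors that inherited a CNA from a common ancestral clone carry the
event on the same homolog *and* with the same breakpoints (identity by
descent); independently acquired events on the same arm typically differ
in at least one breakpoint.  This module finds candidate shared events by
reciprocal overlap of same-state segments and compares their breakpoints
at a configurable tolerance.  A segment end that reaches a telomere
(coordinate 0 or the chromosome end) is treated as automatically
concordant at that end: terminal events are bounded by the chromosome,
not by where the mutational break occurred.

Internal coordinates are 0-based half-open; SEG files on disk are 1-based
inclusive and converted only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

STATES = ("loss", "gain")


@dataclass(frozen=True)
class CNASegment:
    """One copy-number segment call (0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: str
    n_probes: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must precede end")
        if self.n_probes < 0:
            raise ValueError("n_probes must be >= 0")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentMatch:
    """A candidate shared CNA: one segment from each of two samples."""

    seg_a: CNASegment
    seg_b: CNASegment
    reciprocal_overlap: float
    state_equal: bool
    breakpoint_verdict: str | None = None  # "concordant" | "discordant"

    @property
    def cna_id(self) -> str:
        lo = min(self.seg_a.start, self.seg_b.start)
        hi = max(self.seg_a.end, self.seg_b.end)
        return f"{self.seg_a.chrom}:{lo + 1}-{hi}:{self.seg_a.state}"


def validate_segment(seg: CNASegment, min_length: int = 50_000,
                     min_probes: int = 21) -> str:
    """'valid' iff the segment is strictly longer than ``min_length`` bp
    and supported by at least ``min_probes`` probes."""
    ok = seg.length > min_length and seg.n_probes >= min_probes
    return "valid" if ok else "invalid"


def reciprocal_overlap(a: CNASegment, b: CNASegment) -> float:
    """Intersection length over the longer segment's length (0 if on
    different chromosomes)."""
    if a.chrom != b.chrom:
        return 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    return inter / max(a.length, b.length)


def find_candidate_shared_cnas(segs_a: list[CNASegment],
                               segs_b: list[CNASegment],
                               min_reciprocal_overlap: float = 0.5,
                               ) -> list[SegmentMatch]:
    """Pairs of same-chromosome, same-state segments whose reciprocal
    overlap meets the threshold — the candidates for identity by descent."""
    matches = []
    for a in segs_a:
        for b in segs_b:
            if a.chrom != b.chrom or a.state != b.state:
                continue
            ro = reciprocal_overlap(a, b)
            if ro >= min_reciprocal_overlap:
                matches.append(SegmentMatch(a, b, ro, state_equal=True))
    return matches


def compare_breakpoints(match: SegmentMatch, tolerance: int = 1_000_000,
                        chrom_length: int | None = None) -> str:
    """Concordant iff both breakpoints agree within ``tolerance`` bp.

    An end that reaches the p-telomere (start 0 in both segments) or the
    q-telomere (end equal to ``chrom_length`` in both, when known) is
    compared as automatically concordant at that end.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    a, b = match.seg_a, match.seg_b
    if a.chrom != b.chrom:
        raise ValueError("breakpoint comparison requires the same chromosome")
    start_ok = abs(a.start - b.start) <= tolerance or (a.start == 0 and b.start == 0)
    end_ok = abs(a.end - b.end) <= tolerance or (
        chrom_length is not None and a.end == chrom_length and b.end == chrom_length)
    return "concordant" if (start_ok and end_ok) else "discordant"


# --------------------------------------------------------------------------
# SEG I/O (1-based inclusive on disk)


def read_seg(path: str) -> list[CNASegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [CNASegment(r.sample, r.chrom, int(r.start) - 1, int(r.end),
                       r.state, int(r.n_probes))
            for r in df.itertuples()]


def write_seg(segments: list[CNASegment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_probes\tstate\n")
        for seg in segments:
            fh.write(f"{seg.sample_id}\t{seg.chrom}\t{seg.start + 1}\t{seg.end}"
                     f"\t{seg.n_probes}\t{seg.state}\n")


def write_bed(segments: list[CNASegment], path: str) -> None:
    """BED export (0-based half-open, name = state)."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}"
                     f"\t{seg.sample_id}:{seg.state}\n")
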