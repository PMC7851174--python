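"""Alternative-splicing / alternative-termini event classification.

Given the exon structures of two transcript isoforms of the same gene, the
classifier aligns their splice-site chains between the outermost shared
coordinates and labels every variable region with an event category:
cassette (skipped) exons, alternative 5'/3' splice sites, intron retention,
mutually exclusive exons, alternative or tandem transcript termini, and
"complex" catch-alls for patterns that do not reduce to a simple event. A
single isoform pair can carry several events at once.

All comparisons are exact on genomic coordinates; classification is done in
transcript (5'->3') orientation so that labels are strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EVENT_LABELS = (
    "exon_skipping",
    "alt_5ss",
    "alt_3ss",
    "intron_retention",
    "mutually_exclusive_exons",
    "alt_first_exon",
    "alt_last_exon",
    "alt_5utr",
    "alt_3utr",
    "tandem_5utr",
    "tandem_3utr",
    "complex_internal",
    "complex_5p",
    "complex_3p",
)


@dataclass(frozen=True)
class TranscriptStructure:
    """Ordered, non-overlapping exon intervals of one transcript.

    Exons are (start, end) 0-based half-open genomic intervals, sorted by
    start regardless of strand.
    """

    transcript_id: str
    strand: str
    exons: list

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        exons = [(int(s), int(e)) for s, e in self.exons]
        if not exons:
            raise ValueError(f"{self.transcript_id}: at least one exon required")
        for s, e in exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: overlapping or unsorted exons")
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


def _oriented_exons(tx: TranscriptStructure) -> list[tuple[int, int]]:
    """Exons in transcript orientation: coordinates increase 5'->3'.

    On the minus strand each exon (s, e) maps to (-e, -s) and the order is
    reversed, so downstream logic can treat exon starts as acceptors and exon
    ends as donors throughout.
    """
    if tx.strand == "+":
        return list(tx.exons)
    return [(-e, -s) for s, e in reversed(tx.exons)]


def _sites(exons: list[tuple[int, int]]) -> list[tuple[int, str]]:
    """Splice-site chain: alternating acceptor ('a', exon start) and donor
    ('d', exon end) coordinates, excluding the transcript termini."""
    sites: list[tuple[int, str]] = []
    for i, (s, e) in enumerate(exons):
        if i > 0:
            sites.append((s, "a"))
        if i < len(exons) - 1:
            sites.append((e, "d"))
    return sites


def _exons_between(exons, lo, hi) -> list[tuple[int, int]]:
    return [(s, e) for s, e in exons if s >= lo and e <= hi]


def _classify_internal(region_a, region_b, exons_a, exons_b, lo, hi) -> str:
    """Label one internal variable region (site chains differ, flanks shared)."""
    kinds_a = "".join(k for _, k in region_a)
    kinds_b = "".join(k for _, k in region_b)
    full_a = _exons_between(exons_a, lo, hi)
    full_b = _exons_between(exons_b, lo, hi)
    # cassette exon: one isoform has exactly one exon in the region, the other none
    if {kinds_a, kinds_b} == {"ad", ""}:
        return "exon_skipping"
    # intron retention: one isoform's exon spans the other's exon-intron-exon
    if {kinds_a, kinds_b} == {"da", ""}:
        return "intron_retention"
    # single differing donor / acceptor
    if kinds_a == kinds_b == "d":
        return "alt_5ss"
    if kinds_a == kinds_b == "a":
        return "alt_3ss"
    # mutually exclusive exons: one full exon each, non-overlapping
    if kinds_a == kinds_b == "ad" and len(full_a) == 1 and len(full_b) == 1:
        (sa, ea), (sb, eb) = full_a[0], full_b[0]
        if ea <= sb or eb <= sa:
            return "mutually_exclusive_exons"
    return "complex_internal"


def _classify_terminus(exons_a, exons_b, first: bool) -> set[str]:
    """Label a differing 5' (first=True) or 3' terminus, in oriented coords."""
    ex_a = exons_a[0] if first else exons_a[-1]
    ex_b = exons_b[0] if first else exons_b[-1]
    if ex_a == ex_b:
        return set()
    inner_a = ex_a[1] if first else ex_a[0]  # splice-site side of terminal exon
    inner_b = ex_b[1] if first else ex_b[0]
    outer_a = ex_a[0] if first else ex_a[1]
    outer_b = ex_b[0] if first else ex_b[1]
    single_a = len(exons_a) == 1
    single_b = len(exons_b) == 1
    if inner_a == inner_b and outer_a != outer_b and not (single_a or single_b):
        # same terminal exon body, shifted transcript start/end
        return {"tandem_5utr" if first else "tandem_3utr"}
    if inner_a != inner_b and not (single_a or single_b):
        # distinct terminal exons with their own splice sites
        if first:
            return {"alt_first_exon", "alt_5utr"}
        return {"alt_last_exon", "alt_3utr"}
    return {"complex_5p" if first else "complex_3p"}


def classify_events(a: TranscriptStructure, b: TranscriptStructure) -> set[str]:
    """Event labels distinguishing two isoforms of the same gene.

    Returns the empty set iff the exon structures are identical; symmetric in
    its arguments; raises on strand mismatch.
    """
    if a.strand != b.strand:
        raise ValueError("isoforms on different strands cannot be compared")
    exons_a = _oriented_exons(a)
    exons_b = _oriented_exons(b)
    if exons_a == exons_b:
        return set()

    sites_a = _sites(exons_a)
    sites_b = _sites(exons_b)
    # anchors: shared internal splice sites plus shared transcript termini —
    # variable regions are the maximal stretches between consecutive anchors
    anchors = sorted({pos for pos, kind in set(sites_a) & set(sites_b)})
    if exons_a[0][0] == exons_b[0][0]:
        anchors.insert(0, exons_a[0][0])
    if exons_a[-1][1] == exons_b[-1][1]:
        anchors.append(exons_a[-1][1])
    anchors = sorted(set(anchors))

    events: set[str] = set()

    if not anchors:
        # no shared coordinate at all: compare termini; anything beyond a
        # clean terminal difference is a complex change of the structure
        ev5 = _classify_terminus(exons_a, exons_b, first=True)
        ev3 = _classify_terminus(exons_a, exons_b, first=False)
        events |= ev5 | ev3
        if not events:
            events.add("complex_internal")
        return events

    lo, hi = anchors[0], anchors[-1]

    # --- termini outside the outermost anchors -----------------------------
    if exons_a[0][0] != exons_b[0][0]:
        head_a = [s for s in sites_a if s[0] < lo]
        head_b = [s for s in sites_b if s[0] < lo]
        if len(head_a) <= 1 and len(head_b) <= 1:
            events |= _classify_terminus(exons_a, exons_b, first=True)
        else:
            events.add("complex_5p")
    if exons_a[-1][1] != exons_b[-1][1]:
        tail_a = [s for s in sites_a if s[0] > hi]
        tail_b = [s for s in sites_b if s[0] > hi]
        if len(tail_a) <= 1 and len(tail_b) <= 1:
            events |= _classify_terminus(exons_a, exons_b, first=False)
        else:
            events.add("complex_3p")

    # --- internal variable regions between consecutive anchors -------------
    for left, right in zip(anchors, anchors[1:]):
        region_a = [s for s in sites_a if left < s[0] < right]
        region_b = [s for s in sites_b if left < s[0] < right]
        if region_a == region_b:
            continue
        events.add(_classify_internal(region_a, region_b, exons_a, exons_b, left, right))

    if not events:
        # structures differ but every local comparison matched: conservative
        events.add("complex_internal")
    return events


def select_isoform_pair(
    group_means: np.ndarray, transcript_ids: list[str]
) -> tuple[str, str]:
    """Pick the two isoforms changing the most, in opposite directions.

    ``group_means`` is genotype-groups x transcripts (mean adjusted relative
    expression). Over the group pair realising the gene's MD (the largest
    absolute mean difference across transcripts), returns the transcript with
    the largest positive change and the one with the largest negative change.
    """
    gm = np.asarray(group_means, dtype=float)
    if gm.ndim != 2 or gm.shape[0] < 2 or gm.shape[1] < 2:
        raise ValueError("need >=2 genotype groups and >=2 transcripts")
    if gm.shape[1] != len(transcript_ids):
        raise ValueError("transcript_ids length mismatch")
    best = None
    for i in range(gm.shape[0]):
        for j in range(i + 1, gm.shape[0]):
            diff = gm[j] - gm[i]
            md = np.max(np.abs(diff))
            if best is None or md > best[0]:
                best = (md, diff)
    diff = best[1]
    up, down = int(np.argmax(diff)), int(np.argmin(diff))
    if diff[down] >= 0 or diff[up] <= 0:
        raise ValueError(
            "no opposite-direction pair: compositional group means expected"
        )
    return transcript_ids[up], transcript_ids[down]
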