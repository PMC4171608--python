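"""Microsatellite target-set construction.

Detects maximal perfect tandem repeats (unit size 1–6) in a reference
sequence and applies the locus-selection filters: minimum tract length
(12 nt, relaxed to 10 nt inside exons), uniqueness of the concatenated
10 nt flanks in the reference (both strands), and exclusion of repeat
pairs separated by fewer than 5 non-repeat bases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FLANK_SIZE = 10
MIN_TRACT_LEN = 12
MIN_TRACT_LEN_EXON = 10
PROXIMITY_WINDOW = 200
MIN_INTER_TRACT_GAP = 5


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MicrosatLocus:
    """A catalogued tandem-repeat locus.

    Coordinates are 0-based half-open; ``locus_id`` renders them 1-based
    inclusive (``chrom:start-end``) for human-readable output.
    """

    chrom: str
    start: int
    end: int
    motif: str
    region_class: str = "intergenic"
    gene: Optional[str] = None
    left_flank: str = ""
    right_flank: str = ""

    @property
    def ref_length(self) -> int:
        return self.end - self.start

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    @property
    def unit_size(self) -> int:
        return len(self.motif)

    def min_length(self) -> int:
        return MIN_TRACT_LEN_EXON if self.region_class == "exon" else MIN_TRACT_LEN


def _minimal_period(s: str) -> int:
    """Smallest p such that s[i] == s[i - p] for all i >= p."""
    n = len(s)
    for p in range(1, n):
        if all(s[i] == s[i - p] for i in range(p, n)):
            return p
    return n


def detect_repeats(
    sequence: str,
    chrom: str,
    min_unit: int = 1,
    max_unit: int = 6,
    max_impurity: float = 0.0,
) -> list[MicrosatLocus]:
    """Find maximal perfect tandem runs of unit sizes ``min_unit``..``max_unit``.

    A run of period ``p`` is reported only when ``p`` is the minimal period
    of the run, so e.g. a poly-A stretch appears once as a mononucleotide
    locus rather than again at period 2. Runs must contain at least two
    full motif units; runs containing ``N`` are dropped.

    ``max_impurity`` > 0 greedily extends each pure run left/right through
    single-base interruptions as long as the number of bases mismatching
    the periodic template stays within ``floor(max_impurity * length)``.
    The default (0) reports pure runs only.

    Raises ``ValueError`` for characters outside ``ACGTN``; an empty
    sequence yields an empty list.
    """
    if not 1 <= min_unit <= max_unit <= 6:
        raise ValueError(f"invalid unit range [{min_unit}, {max_unit}]")
    if not sequence:
        return []
    if not _VALID_BASES.issuperset(sequence):
        bad = sorted(set(sequence) - _VALID_BASES)
        raise ValueError(f"sequence contains invalid characters: {bad!r}")

    n = len(sequence)
    loci: list[MicrosatLocus] = []
    for p in range(min_unit, max_unit + 1):
        # eq[i] marks s[i] == s[i+p]; a maximal True run [u, v) is the
        # tract [u, v + p). Runs of the same period may overlap by up to
        # p - 1 bases, so every maximal run is enumerated.
        i = 0
        limit = n - p
        while i < limit:
            if sequence[i + p] != sequence[i]:
                i += 1
                continue
            u = i
            while i < limit and sequence[i + p] == sequence[i]:
                i += 1
            run_start, run_end = u, i + p  # tract interval
            if run_end - run_start < 2 * p:
                continue
            tract = sequence[run_start:run_end]
            if "N" in tract:
                continue
            if _minimal_period(tract) != p:
                continue  # already reported at a smaller period
            loci.append(
                MicrosatLocus(
                    chrom=chrom, start=run_start, end=run_end, motif=tract[:p]
                )
            )
    if max_impurity > 0:
        loci = [_extend_impure(l, sequence, max_impurity) for l in loci]
        loci = _dedupe_overlaps(loci)
    loci.sort(key=lambda l: (l.start, l.unit_size))
    return loci


def _extend_impure(locus: MicrosatLocus, sequence: str, max_impurity: float) -> MicrosatLocus:
    """Greedy extension of a pure run allowing template mismatches.

    The tract is compared against the continuation of its own periodicity;
    extension stops when the mismatch budget floor(max_impurity * length)
    would be exceeded or the sequence ends.
    """
    p = locus.unit_size
    anchor = locus.start  # phase reference for the pure-motif template
    motif = locus.motif

    def template(j: int) -> str:
        return motif[(j - anchor) % p]

    start, end = locus.start, locus.end
    mismatches = 0
    n = len(sequence)
    extended = True
    while extended:
        extended = False
        if end < n and sequence[end] != "N":
            cost = 0 if sequence[end] == template(end) else 1
            if mismatches + cost <= int(max_impurity * (end - start + 1)):
                mismatches += cost
                end += 1
                extended = True
                continue
        if start > 0 and sequence[start - 1] != "N":
            cost = 0 if sequence[start - 1] == template(start - 1) else 1
            if mismatches + cost <= int(max_impurity * (end - start + 1)):
                mismatches += cost
                start -= 1
                extended = True
    # trim so the tract starts and ends on template-matching bases
    while end - start > 2 * p and sequence[end - 1] != template(end - 1):
        end -= 1
    while end - start > 2 * p and sequence[start] != template(start):
        start += 1
    return replace(locus, start=start, end=end, motif=sequence[start : start + p])


def _dedupe_overlaps(loci: Sequence[MicrosatLocus]) -> list[MicrosatLocus]:
    """Collapse identical-interval calls to the smallest period."""
    best: dict[tuple[int, int], MicrosatLocus] = {}
    for l in loci:
        key = (l.start, l.end)
        if key not in best or l.unit_size < best[key].unit_size:
            best[key] = l
    return list(best.values())


def _count_occurrences(haystack: str, needle: str) -> int:
    """Count (possibly overlapping) exact occurrences."""
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


MAX_PROBE_GAP = 100


def count_flank_context(
    reference: Mapping[str, str],
    left: str,
    right: str,
    max_gap: int = MAX_PROBE_GAP,
    _rc_cache: Optional[Mapping[str, str]] = None,
) -> int:
    """Occurrences of the left/right flank pair with <= max_gap bases between.

    The 20 nt context (tract elided) is searched as an anchored pair:
    each occurrence of the left 10-mer followed by the right 10-mer
    within ``max_gap`` bases counts once, on both strands of every
    sequence. A catalogued locus contributes exactly one occurrence via
    its own site.
    """
    total = 0
    strands = []
    for chrom, seq in reference.items():
        strands.append(seq)
        strands.append(_rc_cache[chrom] if _rc_cache else reverse_complement(seq))
    for seq in strands:
        start = 0
        while True:
            i = seq.find(left, start)
            if i < 0:
                break
            window = seq[i + len(left) : i + len(left) + max_gap + len(right)]
            if right in window:
                total += 1
            start = i + 1
    return total


@dataclass
class ExonIntervals:
    """Exon intervals grouped per chromosome with gene spans for intron calls."""

    exons: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    gene_spans: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, str]]) -> "ExonIntervals":
        obj = cls()
        for chrom, start, end, gene in records:
            obj.exons.setdefault(chrom, []).append((start, end, gene))
            spans = obj.gene_spans.setdefault(chrom, {})
            lo, hi = spans.get(gene, (start, end))
            spans[gene] = (min(lo, start), max(hi, end))
        for chrom in obj.exons:
            obj.exons[chrom].sort()
        return obj

    def classify(self, chrom: str, start: int, end: int) -> tuple[str, Optional[str]]:
        for ex_start, ex_end, gene in self.exons.get(chrom, []):
            if start < ex_end and end > ex_start:
                return "exon", gene
        for gene, (lo, hi) in self.gene_spans.get(chrom, {}).items():
            if start < hi and end > lo:
                return "intron", gene
        return "intergenic", None


def apply_catalog_filters(
    candidates: Sequence[MicrosatLocus],
    reference: Mapping[str, str],
    exons: Optional[ExonIntervals] = None,
    min_len: int = MIN_TRACT_LEN,
    min_len_exon: int = MIN_TRACT_LEN_EXON,
    flank_size: int = FLANK_SIZE,
) -> list[MicrosatLocus]:
    """Apply the locus-selection filters and annotate region class and gene.

    Retains loci that (a) meet the length minimum for their region class
    (``min_len`` generally, ``min_len_exon`` inside exons); (b) have 10 nt
    left and right flanks whose 20 nt context (tract elided; searched as
    an anchored flank pair with a bounded inter-flank gap, see
    :func:`count_flank_context`) occurs exactly once in the reference
    counting both strands; (c) are not
    within ``PROXIMITY_WINDOW`` bases of another catalogued tract with
    fewer than ``MIN_INTER_TRACT_GAP`` non-repeat bases in between (both
    members of such a pair are discarded).

    Loci too close to a sequence boundary for full flanks are excluded
    with a logged warning. The operation is idempotent.
    """
    # both-strand search corpus, built once
    rc_cache = {chrom: reverse_complement(seq) for chrom, seq in reference.items()}

    annotated: list[MicrosatLocus] = []
    for locus in candidates:
        seq = reference.get(locus.chrom)
        if seq is None:
            log.warning("locus %s on unknown sequence %s; excluded", locus.locus_id, locus.chrom)
            continue
        if locus.start < flank_size or locus.end + flank_size > len(seq):
            log.warning("locus %s flanks exceed sequence bounds; excluded", locus.locus_id)
            continue
        region_class, gene = ("intergenic", None)
        if exons is not None:
            region_class, gene = exons.classify(locus.chrom, locus.start, locus.end)
        threshold = min_len_exon if region_class == "exon" else min_len
        if locus.ref_length < threshold:
            continue
        left = seq[locus.start - flank_size : locus.start]
        right = seq[locus.end : locus.end + flank_size]
        if count_flank_context(reference, left, right, _rc_cache=rc_cache) != 1:
            continue
        annotated.append(
            replace(
                locus,
                region_class=region_class,
                gene=gene,
                left_flank=left,
                right_flank=right,
            )
        )

    return _proximity_filter(annotated)


def _proximity_filter(loci: list[MicrosatLocus]) -> list[MicrosatLocus]:
    """Drop both members of any pair of tracts separated by < 5 bases.

    The documented reading of the pair-exclusion rule: two catalogued
    tracts within ``PROXIMITY_WINDOW`` bases of each other whose
    inter-tract gap is below ``MIN_INTER_TRACT_GAP`` are both removed
    (a sub-5-base gap is necessarily within the 200-base window).
    """
    ordered = sorted(loci, key=lambda l: (l.chrom, l.start, l.end))
    drop: set[int] = set()
    for i, a in enumerate(ordered):
        for j in range(i + 1, len(ordered)):
            b = ordered[j]
            if b.chrom != a.chrom or b.start - a.end > PROXIMITY_WINDOW:
                break
            gap = b.start - a.end
            if gap < MIN_INTER_TRACT_GAP:
                drop.add(i)
                drop.add(j)
    return [l for i, l in enumerate(ordered) if i not in drop]


def build_catalog(
    reference: Mapping[str, str],
    exons: Optional[ExonIntervals] = None,
    min_unit: int = 1,
    max_unit: int = 6,
    min_len: int = MIN_TRACT_LEN,
    min_len_exon: int = MIN_TRACT_LEN_EXON,
    max_impurity: float = 0.0,
) -> list[MicrosatLocus]:
    """Detect and filter repeats over every sequence in ``reference``."""
    candidates: list[MicrosatLocus] = []
    for chrom, seq in reference.items():
        candidates.extend(
            detect_repeats(seq, chrom, min_unit=min_unit, max_unit=max_unit, max_impurity=max_impurity)
        )
    return apply_catalog_filters(
        candidates, reference, exons=exons, min_len=min_len, min_len_exon=min_len_exon
    )
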