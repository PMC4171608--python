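"""Flank-anchored microsatellite genotyping from aligned reads.

A read contributes an allele observation at a locus only when it fully
spans the repeat tract plus at least 5 bases on each side and both 5 nt
flank windows match the reference flanks. Mapping position is used only
to shortlist candidate loci; the flank match is the authoritative
filter. Observations are binned by identical tract sequence; genotypes
are allele-length pairs with stutter suppression via a minimum allele
fraction and a hard coverage gate.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from caml.catalog import MicrosatLocus

FLANK_PROBE = 5
DEFAULT_COVERAGE_MIN = 15
DEFAULT_MIN_ALLELE_FRACTION = 0.2

STATUS_CALLED = "called"
STATUS_LOW_COVERAGE = "low_coverage"
STATUS_MULTI_ALLELIC = "multi_allelic"
STATUS_NO_READS = "no_reads"


@dataclass(frozen=True)
class AlleleObservation:
    """One binned allele: reads sharing an identical tract sequence."""

    locus_id: str
    allele_length: int
    repeat_sequence: str
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")
        if self.allele_length != len(self.repeat_sequence):
            raise ValueError("allele_length inconsistent with repeat_sequence")


@dataclass(frozen=True)
class GenotypeCall:
    locus_id: str
    sample_id: str
    allele_a: Optional[int]
    allele_b: Optional[int]
    depth: int
    status: str

    @property
    def genotype(self) -> Optional[tuple[int, int]]:
        if self.status != STATUS_CALLED:
            return None
        return (self.allele_a, self.allele_b)


def _find_with_mismatches(haystack: str, needle: str, start: int, max_mismatches: int) -> int:
    """Leftmost index >= start where needle matches with <= max_mismatches."""
    n, m = len(haystack), len(needle)
    if max_mismatches == 0:
        idx = haystack.find(needle, start)
        return idx
    for i in range(start, n - m + 1):
        mism = 0
        for a, b in zip(haystack[i : i + m], needle):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        if mism <= max_mismatches:
            return i
    return -1


def _matches_with_mismatches(haystack: str, needle: str, at: int, max_mismatches: int) -> bool:
    if at < 0 or at + len(needle) > len(haystack):
        return False
    mism = 0
    for a, b in zip(haystack[at : at + len(needle)], needle):
        if a != b:
            mism += 1
            if mism > max_mismatches:
                return False
    return True


def _query_offset(read: pysam.AlignedSegment, ref_pos: int) -> Optional[int]:
    """Query index aligned to ref_pos, walking the CIGAR (None if unaligned)."""
    q = 0
    r = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):  # M/=/X consume both
            if r <= ref_pos < r + length:
                return q + (ref_pos - r)
            q += length
            r += length
        elif op in (1, 4):  # I/S consume query
            q += length
        elif op in (2, 3):  # D/N consume reference
            if r <= ref_pos < r + length:
                return None  # ref position deleted from the read
            r += length
        # 5 (H) and 6 (P) consume neither
    return None


class _LocusIndex:
    """Per-chromosome locus lookup by reference span."""

    def __init__(self, catalog: Sequence[MicrosatLocus]):
        self._by_chrom: dict[str, tuple[list[int], list[MicrosatLocus]]] = {}
        grouped: dict[str, list[MicrosatLocus]] = {}
        for locus in catalog:
            grouped.setdefault(locus.chrom, []).append(locus)
        for chrom, loci in grouped.items():
            loci.sort(key=lambda l: l.start)
            self._by_chrom[chrom] = ([l.start for l in loci], loci)

    def candidates(self, chrom: str, ref_start: int, ref_end: int) -> Iterable[MicrosatLocus]:
        """Loci whose tract plus 5 nt flanks lie within [ref_start, ref_end)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return ()
        starts, loci = entry
        lo = bisect_left(starts, ref_start + FLANK_PROBE)
        hi = bisect_right(starts, ref_end)
        return (
            l
            for l in loci[lo:hi]
            if l.start - FLANK_PROBE >= ref_start and l.end + FLANK_PROBE <= ref_end
        )


def extract_observations(
    alignments: str | pysam.AlignmentFile,
    catalog: Sequence[MicrosatLocus],
    max_flank_mismatches: int = 0,
) -> dict[str, list[AlleleObservation]]:
    """Collect per-locus allele observations from one sample's alignments.

    Unmapped, secondary, supplementary and duplicate-flagged reads are
    skipped. Base substitutions inside the tract produce distinct bins
    (distinct tract sequences) but do not change the binned length, so
    downstream length-based genotyping ignores them.

    Returns a mapping locus_id -> observation bins (loci with no
    validated reads are absent).
    """
    own = False
    if isinstance(alignments, str):
        alignments = pysam.AlignmentFile(alignments, check_sq=False)
        own = True
    index = _LocusIndex(catalog)
    bins: dict[str, Counter[str]] = {}
    try:
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            seq = read.query_sequence
            if not seq:
                continue
            chrom = read.reference_name
            ref_start = read.reference_start
            ref_end = read.reference_end
            if ref_end is None:
                continue
            for locus in index.candidates(chrom, ref_start, ref_end):
                left5 = locus.left_flank[-FLANK_PROBE:]
                right5 = locus.right_flank[:FLANK_PROBE]
                if len(left5) < FLANK_PROBE or len(right5) < FLANK_PROBE:
                    continue
                # the alignment locates the left flank window; the exact
                # 5-mer match there (and downstream for the right flank)
                # is the authoritative validation
                i = _query_offset(read, locus.start - FLANK_PROBE)
                if i is None or not _matches_with_mismatches(
                    seq, left5, i, max_flank_mismatches
                ):
                    continue
                j = _find_with_mismatches(seq, right5, i + FLANK_PROBE, max_flank_mismatches)
                if j < 0:
                    continue
                tract = seq[i + FLANK_PROBE : j]
                bins.setdefault(locus.locus_id, Counter())[tract] += 1
    finally:
        if own:
            alignments.close()
    return {
        locus_id: [
            AlleleObservation(locus_id, len(tract), tract, count)
            for tract, count in sorted(counter.items())
        ]
        for locus_id, counter in bins.items()
    }


def call_genotype(
    observations: Sequence[AlleleObservation],
    sample_id: str = "",
    locus_id: Optional[str] = None,
    coverage_min: int = DEFAULT_COVERAGE_MIN,
    min_allele_fraction: float = DEFAULT_MIN_ALLELE_FRACTION,
) -> GenotypeCall:
    """Call an allele-length-pair genotype from one locus's observations.

    Observation bins are aggregated by tract length; lengths supported by
    at least ``min_allele_fraction`` of the validated depth are retained.
    One retained length gives a homozygous call, two a heterozygous call;
    more than two marks the locus multi-allelic (excluded). Depth below
    ``coverage_min`` yields ``low_coverage``; no observations yield
    ``no_reads``.
    """
    if not observations:
        return GenotypeCall(locus_id or "", sample_id, None, None, 0, STATUS_NO_READS)
    ids = {o.locus_id for o in observations}
    if len(ids) > 1:
        raise ValueError(f"observations span multiple loci: {sorted(ids)}")
    lid = locus_id or observations[0].locus_id

    by_length: Counter[int] = Counter()
    for obs in observations:
        by_length[obs.allele_length] += obs.read_count
    depth = sum(by_length.values())
    if depth < coverage_min:
        return GenotypeCall(lid, sample_id, None, None, depth, STATUS_LOW_COVERAGE)
    retained = sorted(
        length for length, count in by_length.items() if count >= min_allele_fraction * depth
    )
    if len(retained) == 1:
        a = retained[0]
        return GenotypeCall(lid, sample_id, a, a, depth, STATUS_CALLED)
    if len(retained) == 2:
        return GenotypeCall(lid, sample_id, retained[0], retained[1], depth, STATUS_CALLED)
    # 0 retained (diffuse noise) is treated like >2: no coherent allele pair
    return GenotypeCall(lid, sample_id, None, None, depth, STATUS_MULTI_ALLELIC)


CALL_COLUMNS = ["sample_id", "locus_id", "allele_a", "allele_b", "depth", "status"]


@dataclass
class CohortGenotypeTable:
    """Genotype calls for all sample x locus pairs plus cohort labels.

    ``calls`` has one row per (sample_id, locus_id) with allele_a/allele_b
    (nullable Int64), depth and status. ``cohorts`` maps sample_id to its
    cohort label.
    """

    calls: pd.DataFrame
    cohorts: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CALL_COLUMNS if c not in self.calls.columns]
        if missing:
            raise ValueError(f"calls missing columns: {missing}")
        self.calls = self.calls.reset_index(drop=True)
        for col in ("allele_a", "allele_b"):
            self.calls[col] = self.calls[col].astype("Int64")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.cohorts)

    def samples_in(self, label: str) -> list[str]:
        return sorted(s for s, c in self.cohorts.items() if c == label)

    def called(self) -> pd.DataFrame:
        return self.calls[self.calls["status"] == STATUS_CALLED]

    def called_loci_per_sample(self) -> pd.Series:
        counts = self.called().groupby("sample_id").size()
        return counts.reindex(self.sample_ids, fill_value=0)

    def genotype_lookup(self) -> dict[tuple[str, str], tuple[int, int]]:
        """(sample_id, locus_id) -> (allele_a, allele_b) for called rows."""
        called = self.called()
        return {
            (s, l): (int(a), int(b))
            for s, l, a, b in zip(
                called["sample_id"], called["locus_id"], called["allele_a"], called["allele_b"]
            )
        }

    def subset_samples(self, sample_ids: Iterable[str]) -> "CohortGenotypeTable":
        keep = set(sample_ids)
        return CohortGenotypeTable(
            self.calls[self.calls["sample_id"].isin(keep)].copy(),
            {s: c for s, c in self.cohorts.items() if s in keep},
        )

    def subset_loci(self, locus_ids: Iterable[str]) -> "CohortGenotypeTable":
        keep = set(locus_ids)
        return CohortGenotypeTable(
            self.calls[self.calls["locus_id"].isin(keep)].copy(), dict(self.cohorts)
        )


def genotype_sample(
    alignment_path: str,
    sample_id: str,
    catalog: Sequence[MicrosatLocus],
    coverage_min: int = DEFAULT_COVERAGE_MIN,
    min_allele_fraction: float = DEFAULT_MIN_ALLELE_FRACTION,
    max_flank_mismatches: int = 0,
) -> list[GenotypeCall]:
    observations = extract_observations(
        alignment_path, catalog, max_flank_mismatches=max_flank_mismatches
    )
    calls = []
    for locus in catalog:
        obs = observations.get(locus.locus_id, [])
        calls.append(
            call_genotype(
                obs,
                sample_id=sample_id,
                locus_id=locus.locus_id,
                coverage_min=coverage_min,
                min_allele_fraction=min_allele_fraction,
            )
        )
    return calls


def genotype_cohort(
    manifest: pd.DataFrame,
    catalog: Sequence[MicrosatLocus],
    coverage_min: int = DEFAULT_COVERAGE_MIN,
    min_allele_fraction: float = DEFAULT_MIN_ALLELE_FRACTION,
    max_flank_mismatches: int = 0,
) -> CohortGenotypeTable:
    """Genotype every sample in a manifest (sample_id, cohort, path)."""
    required = {"sample_id", "cohort", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    rows = []
    cohorts: dict[str, str] = {}
    for rec in manifest.itertuples(index=False):
        cohorts[rec.sample_id] = rec.cohort
        for call in genotype_sample(
            rec.path,
            rec.sample_id,
            catalog,
            coverage_min=coverage_min,
            min_allele_fraction=min_allele_fraction,
            max_flank_mismatches=max_flank_mismatches,
        ):
            rows.append(
                (call.sample_id, call.locus_id, call.allele_a, call.allele_b, call.depth, call.status)
            )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return CohortGenotypeTable(calls, cohorts)
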