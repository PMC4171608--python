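"""Regulatory-element proximity and driver-mutation cross-tabulation."""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from caml.catalog import MicrosatLocus
from caml.genotyper import CohortGenotypeTable

CPG_WINDOW = 10_000
TFBS_WINDOW = 40

# driver / mismatch-repair panel as configured by default; two published
# symbols have no HGNC entry, so documented aliases are provided
DEFAULT_DRIVER_PANEL = (
    "IDH1",
    "PTEN",
    "PIK3CA",
    "RB1",
    "MSH2",
    "MSH3",
    "MSH4",
    "MSH5",
    "MSF6",
    "MLH1",
    "MLH2",
)
DRIVER_PANEL_ALIASES = {"MSF6": "MSH6", "MLH2": "PMS2"}

Interval = tuple[str, int, int]  # chrom, start, end (0-based half-open)


@dataclass(frozen=True)
class LocusAnnotation:
    locus_id: str
    nearest_cpg_distance: float  # gap distance in bases; 0 when overlapping; inf if none
    nearest_tfbs_distance: float
    cpg_within_10kb: bool
    tfbs_within_40bp: bool


class _TrackIndex:
    """Sorted per-chromosome intervals for nearest-feature queries."""

    def __init__(self, intervals: Iterable[Interval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end < start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._by_chrom = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = [s for s, _ in ivs]
            # running max of ends handles contained intervals
            max_ends = list(np.maximum.accumulate([e for _, e in ivs]))
            self._by_chrom[chrom] = (starts, ivs, max_ends)

    def nearest_distance(self, chrom: str, start: int, end: int) -> float:
        """Gap distance from [start, end) to the nearest interval (0 on overlap)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return float("inf")
        starts, ivs, max_ends = entry
        idx = bisect_left(starts, end)  # ivs[idx:] start at/after the locus end
        best = float("inf")
        if idx < len(starts):
            best = ivs[idx][0] - end
        if idx > 0:
            # ivs[:idx] all start before the locus end; overlap iff the
            # furthest-reaching of them extends past the locus start
            if max_ends[idx - 1] > start:
                return 0.0
            best = min(best, start - max_ends[idx - 1])
        return float(max(best, 0.0))


def annotate_proximity(
    loci: Sequence[MicrosatLocus],
    cpg_track: Iterable[Interval],
    tfbs_track: Iterable[Interval],
    cpg_window: int = CPG_WINDOW,
    tfbs_window: int = TFBS_WINDOW,
) -> list[LocusAnnotation]:
    """Gap distance from each locus tract to the nearest feature per track.

    Overlap gives distance 0; a chromosome with no features gives inf.
    Window thresholds (defaults 10,000 and 40 bases) set the booleans.
    """
    cpg = _TrackIndex(cpg_track)
    tfbs = _TrackIndex(tfbs_track)
    out = []
    for locus in loci:
        d_cpg = cpg.nearest_distance(locus.chrom, locus.start, locus.end)
        d_tfbs = tfbs.nearest_distance(locus.chrom, locus.start, locus.end)
        out.append(
            LocusAnnotation(
                locus_id=locus.locus_id,
                nearest_cpg_distance=d_cpg,
                nearest_tfbs_distance=d_tfbs,
                cpg_within_10kb=d_cpg <= cpg_window,
                tfbs_within_40bp=d_tfbs <= tfbs_window,
            )
        )
    return out


def annotations_frame(annotations: Sequence[LocusAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": a.locus_id,
                "nearest_cpg_distance": a.nearest_cpg_distance,
                "nearest_tfbs_distance": a.nearest_tfbs_distance,
                "cpg_within_10kb": a.cpg_within_10kb,
                "tfbs_within_40bp": a.tfbs_within_40bp,
            }
            for a in annotations
        ]
    )


def signature_gene_carriers(
    table: CohortGenotypeTable,
    signature_genotypes: Sequence[tuple[str, tuple[int, int]]],
    locus_genes: Mapping[str, str],
) -> dict[str, set[str]]:
    """Per gene, the samples whose call matches a signature genotype there."""
    lookup = table.genotype_lookup()
    carriers: dict[str, set[str]] = {}
    for locus_id, genotype in signature_genotypes:
        gene = locus_genes.get(locus_id)
        if gene is None:
            continue
        for sample_id in table.sample_ids:
            if lookup.get((sample_id, locus_id)) == genotype:
                carriers.setdefault(gene, set()).add(sample_id)
    return carriers


def methylation_contrast(
    methylation: pd.DataFrame,
    carriers: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Per-site mean methylation among carrier vs non-carrier samples.

    ``methylation`` needs columns site, gene, sample_id, beta; only sites
    whose gene appears in ``carriers`` are reported.
    """
    required = {"site", "gene", "sample_id", "beta"}
    if not required.issubset(methylation.columns):
        raise ValueError(f"methylation table must have columns {sorted(required)}")
    rows = []
    for (site, gene), sub in methylation.groupby(["site", "gene"], sort=True):
        if gene not in carriers:
            continue
        with_mask = sub["sample_id"].isin(carriers[gene])
        mean_with = float(sub.loc[with_mask, "beta"].mean())
        mean_without = float(sub.loc[~with_mask, "beta"].mean())
        rows.append(
            {
                "site": site,
                "gene": gene,
                "mean_with_signature": mean_with,
                "mean_without_signature": mean_without,
                "difference": mean_with - mean_without,
                "n_with": int(with_mask.sum()),
                "n_without": int((~with_mask).sum()),
            }
        )
    return pd.DataFrame(rows)


FRACTION_BIN_EDGES = (0, 20, 40, 60, 80, 100)  # percent
MAX_DRIVER_COUNT = 5


@dataclass
class DriverMutationProfile:
    sample_id: str
    driver_count: int
    genes_hit: list[str]
    caml_fraction: float


def profile_drivers(
    mutations: pd.DataFrame,
    fractions: Mapping[str, float],
    panel: Sequence[str] = DEFAULT_DRIVER_PANEL,
    use_aliases: bool = False,
) -> list[DriverMutationProfile]:
    """Build per-sample driver profiles from mutation calls (sample_id, gene).

    Genes outside the configured panel are ignored; ``use_aliases``
    additionally accepts the documented symbol aliases.
    """
    accepted = set(panel)
    if use_aliases:
        accepted |= {DRIVER_PANEL_ALIASES[g] for g in panel if g in DRIVER_PANEL_ALIASES}
    profiles = []
    grouped = mutations.groupby("sample_id")["gene"].apply(set) if len(mutations) else {}
    for sample_id, fraction in sorted(fractions.items()):
        genes = sorted((grouped.get(sample_id, set()) if len(mutations) else set()) & accepted)
        profiles.append(
            DriverMutationProfile(
                sample_id=sample_id,
                driver_count=min(len(genes), MAX_DRIVER_COUNT),
                genes_hit=genes,
                caml_fraction=fraction,
            )
        )
    return profiles


def driver_caml_crosstab(
    profiles: Sequence[DriverMutationProfile],
) -> pd.DataFrame:
    """Percent of samples per (driver count, detection-fraction bin) cell.

    Fraction bins are (0,20], (20,40], ... (80,100] percent, with 0%
    assigned to the first bin; rows are driver counts 0..5. The table
    total sums to 100 (within rounding). Empty input warns and returns
    an empty table.
    """
    bin_labels = [
        f"{lo}-{hi}%" for lo, hi in zip(FRACTION_BIN_EDGES[:-1], FRACTION_BIN_EDGES[1:])
    ]
    if not profiles:
        warnings.warn("driver_caml_crosstab: empty input", stacklevel=2)
        return pd.DataFrame(columns=bin_labels)
    counts = np.zeros((MAX_DRIVER_COUNT + 1, len(bin_labels)), dtype=int)
    for prof in profiles:
        pct = 100.0 * prof.caml_fraction
        idx = int(np.searchsorted(FRACTION_BIN_EDGES[1:-1], pct, side="left"))
        row = min(prof.driver_count, MAX_DRIVER_COUNT)
        counts[row, idx] += 1
    pct_table = 100.0 * counts / len(profiles)
    return pd.DataFrame(
        pct_table, index=pd.Index(range(MAX_DRIVER_COUNT + 1), name="driver_count"),
        columns=bin_labels,
    )
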