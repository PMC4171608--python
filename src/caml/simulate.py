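"""Synthetic references, cohorts and aligned reads for pipeline testing.

Generates (a) a random reference with planted perfect repeats separated
by unique spacer sequence, (b) case/control genotype tables in which a
configurable subset of loci carries a case-enriched genotype, and
(c) per-sample SAM alignments with Poisson depth, optional PCR stutter
(single ±1-unit step) and base errors. Every source of randomness flows
from one seed, so repeated runs are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from caml.catalog import MicrosatLocus, detect_repeats
from caml.genotyper import CohortGenotypeTable, CALL_COLUMNS, STATUS_CALLED, STATUS_NO_READS

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedCaml:
    """A case-enriched genotype at one locus.

    ``case_carrier_freq``/``control_carrier_freq`` give the probability
    that a sample of each cohort carries ``genotype`` (an allele-length
    pair in nucleotides); their ratio is the planted relative risk.
    """

    locus_index: int
    genotype: tuple[int, int]
    case_carrier_freq: float
    control_carrier_freq: float

    @property
    def relative_risk(self) -> float:
        return self.case_carrier_freq / self.control_carrier_freq


@dataclass
class SimulationConfig:
    seed: int = 0
    n_loci: int = 50
    n_case: int = 20
    n_control: int = 20
    case_label: str = "CASE"
    control_label: str = "CONTROL"
    motif_set: tuple[str, ...] = ("A", "AC", "AT", "AAG", "AGC", "ACT")
    min_units: int = 6
    max_units: int = 10
    spacer_length: int = 300
    # probabilities for [predominant (L,L), (L-u,L), (L,L+u), (L-u,L-u)]
    control_genotype_freqs: tuple[float, ...] = (0.70, 0.15, 0.10, 0.05)
    planted_caml: list[PlantedCaml] = field(default_factory=list)
    depth_mean: float = 30.0
    read_length: int = 100
    base_error_rate: float = 0.0
    stutter_rate: float = 0.0
    dropout_rate: float = 0.0
    # samples listed here get an elevated per-locus dropout, producing
    # callable-locus counts that straddle the per-sample inclusion filter
    low_call_samples: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.control_genotype_freqs) - 1.0) > 1e-9:
            raise ValueError("control_genotype_freqs must sum to 1")
        for rate in (self.base_error_rate, self.stutter_rate, self.dropout_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


def _random_spacer(rng: np.random.Generator, length: int, max_repeat: int = 7) -> str:
    """Random sequence rejected until free of tandem runs >= max_repeat+1 nt."""
    while True:
        seq = "".join(rng.choice(BASES, size=length))
        runs = detect_repeats(seq, "tmp")
        if all(l.ref_length <= max_repeat for l in runs):
            return seq


def _tract(motif: str, length: int) -> str:
    reps = -(-length // len(motif))
    return (motif * reps)[:length]


def simulate_reference(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], list[MicrosatLocus]]:
    """Random single-chromosome reference with planted perfect repeats.

    Tracts are separated by >= ``spacer_length`` bases of repeat-free
    unique sequence and are maximal by construction (the bases abutting
    each tract break its periodicity).
    """
    rng = rng or np.random.default_rng(config.seed)
    chrom = "chr1"

    motifs: list[str] = []
    tracts: list[str] = []
    for _ in range(config.n_loci):
        motif = config.motif_set[int(rng.integers(len(config.motif_set)))]
        units = int(rng.integers(config.min_units, config.max_units + 1))
        # keep tracts >= 12 nt so they survive the default length filter
        while units * len(motif) < 12:
            units += 1
        motifs.append(motif)
        tracts.append(_tract(motif, units * len(motif)))

    # a tract is left-maximal when the preceding base differs from the
    # motif's last character, and right-maximal when the following base
    # differs from the motif's first character
    parts: list[str] = []
    loci: list[MicrosatLocus] = []
    pos = 0
    for i in range(config.n_loci + 1):
        spacer = _random_spacer(rng, config.spacer_length)
        if i > 0:
            while spacer[0] == motifs[i - 1][0]:
                spacer = str(rng.choice(BASES)) + spacer[1:]
        if i < config.n_loci:
            while spacer[-1] == motifs[i][-1]:
                spacer = spacer[:-1] + str(rng.choice(BASES))
        parts.append(spacer)
        pos += len(spacer)
        if i < config.n_loci:
            start = pos
            parts.append(tracts[i])
            pos += len(tracts[i])
            loci.append(
                MicrosatLocus(chrom=chrom, start=start, end=pos, motif=motifs[i])
            )
    sequence = "".join(parts)

    # reconcile against an actual scan: adopt the detected interval with
    # the greatest overlap so truth coordinates always match the catalog
    reference = {chrom: sequence}
    detected = detect_repeats(sequence, chrom)
    truth = []
    for locus in loci:
        overlapping = [
            d
            for d in detected
            if d.start < locus.end and d.end > locus.start
        ]
        best = max(
            overlapping,
            key=lambda d: min(d.end, locus.end) - max(d.start, locus.start),
            default=locus,
        )
        truth.append(best)
    return reference, truth


def _genotype_options(locus: MicrosatLocus) -> list[tuple[int, int]]:
    L, u = locus.ref_length, locus.unit_size
    return [(L, L), (L - u, L), (L, L + u), (L - u, L - u)]


def planted_genotype_default(locus: MicrosatLocus) -> tuple[int, int]:
    """Default case-enriched genotype: homozygous one unit longer than reference."""
    L, u = locus.ref_length, locus.unit_size
    return (L + u, L + u)


def make_planted_caml(
    truth_catalog: Sequence[MicrosatLocus],
    locus_indices: Sequence[int],
    case_carrier_freq: float = 0.6,
    control_carrier_freq: float = 0.2,
) -> list[PlantedCaml]:
    return [
        PlantedCaml(
            locus_index=i,
            genotype=planted_genotype_default(truth_catalog[i]),
            case_carrier_freq=case_carrier_freq,
            control_carrier_freq=control_carrier_freq,
        )
        for i in locus_indices
    ]


def simulate_cohort_genotypes(
    config: SimulationConfig,
    truth_catalog: Sequence[MicrosatLocus],
    rng: Optional[np.random.Generator] = None,
) -> CohortGenotypeTable:
    """Draw truth genotypes for both cohorts.

    Controls draw from ``control_genotype_freqs`` over four candidate
    genotypes per locus. At planted loci the case-enriched genotype is
    carried with the configured cohort-specific probabilities, with the
    residual mass distributed over the standard candidates; all other
    loci are distributionally identical across cohorts. Dropout makes a
    sample x locus pair uncallable (status no_reads in the truth table).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    planted_by_locus = {p.locus_index: p for p in config.planted_caml}
    sample_ids = [f"case_{i:04d}" for i in range(config.n_case)] + [
        f"ctrl_{i:04d}" for i in range(config.n_control)
    ]
    cohorts = {
        s: (config.case_label if s.startswith("case_") else config.control_label)
        for s in sample_ids
    }

    base_freqs = np.asarray(config.control_genotype_freqs, dtype=float)
    rows = []
    for idx, locus in enumerate(truth_catalog):
        options = _genotype_options(locus)
        planted = planted_by_locus.get(idx)
        if planted is not None:
            case_options = options + [planted.genotype]
            case_freqs = np.append(base_freqs * (1 - planted.case_carrier_freq), planted.case_carrier_freq)
            ctrl_freqs = np.append(
                base_freqs * (1 - planted.control_carrier_freq), planted.control_carrier_freq
            )
        else:
            case_options = options
            case_freqs = ctrl_freqs = base_freqs
        for sample_id in sample_ids:
            is_case = cohorts[sample_id] == config.case_label
            freqs = case_freqs if is_case else ctrl_freqs
            opts = case_options if planted is not None else options
            dropout = config.dropout_rate + config.low_call_samples.get(sample_id, 0.0)
            if rng.random() < dropout:
                rows.append((sample_id, locus.locus_id, None, None, 0, STATUS_NO_READS))
                continue
            choice = opts[int(rng.choice(len(opts), p=freqs / freqs.sum()))]
            a, b = sorted(choice)
            rows.append((sample_id, locus.locus_id, a, b, 0, STATUS_CALLED))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return CohortGenotypeTable(calls, cohorts)


def _apply_base_errors(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alternatives = BASES[BASES != seq[i]]
        seq[i] = alternatives[int(rng.integers(3))]
    return seq


def simulate_reads(
    config: SimulationConfig,
    reference: Mapping[str, str],
    truth_catalog: Sequence[MicrosatLocus],
    truth_table: CohortGenotypeTable,
    out_dir: str,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Write one SAM per sample; returns the manifest (sample_id, cohort, path).

    Per sample x callable locus, depth ~ Poisson(depth_mean) reads each
    drawn uniformly from the two alleles, placed uniformly among start
    positions spanning the tract plus 5 bases of flank. Stutter shifts a
    read's tract by ±1 unit with probability ``stutter_rate``; base
    errors are uniform substitutions. CIGARs carry the tract indel.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    os.makedirs(out_dir, exist_ok=True)
    chrom = truth_catalog[0].chrom
    seq = reference[chrom]
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": chrom, "LN": len(seq)}],
        }
    )
    lookup = truth_table.genotype_lookup()
    read_len = config.read_length

    manifest_rows = []
    for sample_id in truth_table.sample_ids:
        path = os.path.join(out_dir, f"{sample_id}.sam")
        records = []
        n_read = 0
        for locus in truth_catalog:
            genotype = lookup.get((sample_id, locus.locus_id))
            if genotype is None:
                continue
            depth = int(rng.poisson(config.depth_mean))
            u = locus.unit_size
            for _ in range(depth):
                allele = genotype[int(rng.integers(2))]
                if config.stutter_rate > 0 and rng.random() < config.stutter_rate:
                    step = u if rng.random() < 0.5 else -u
                    if allele + step >= 2 * u:
                        allele += step
                rec = _make_read(
                    seq, locus, allele, read_len, rng, config.base_error_rate
                )
                if rec is None:
                    continue
                pos, cigar, read_seq = rec
                records.append((pos, cigar, read_seq, f"{sample_id}:{locus.locus_id}:{n_read}"))
                n_read += 1
        records.sort(key=lambda r: r[0])
        with pysam.AlignmentFile(path, "wh", header=header) as out:
            for pos, cigar, read_seq, name in records:
                aln = pysam.AlignedSegment(header)
                aln.query_name = name
                aln.query_sequence = read_seq
                aln.flag = 0
                aln.reference_id = 0
                aln.reference_start = pos
                aln.mapping_quality = 60
                aln.cigarstring = cigar
                aln.query_qualities = pysam.qualitystring_to_array("I" * len(read_seq))
                out.write(aln)
        manifest_rows.append(
            {
                "sample_id": sample_id,
                "cohort": truth_table.cohorts[sample_id],
                "path": path,
            }
        )
    return pd.DataFrame(manifest_rows)


def _make_read(
    seq: str,
    locus: MicrosatLocus,
    allele: int,
    read_len: int,
    rng: np.random.Generator,
    base_error_rate: float,
) -> Optional[tuple[int, str, str]]:
    """One read spanning the tract with ``allele`` nt of repeat.

    Returns (0-based reference position, CIGAR, sequence), or None when
    the geometry cannot accommodate a spanning read.
    """
    ref_len = locus.ref_length
    delta = allele - ref_len
    tract = _tract(locus.motif, allele)
    window = read_len  # flanking sequence available on each side
    left_ctx = seq[max(0, locus.start - window) : locus.start]
    right_ctx = seq[locus.end : locus.end + window]
    hap = left_ctx + tract + right_ctx
    ts = len(left_ctx)  # tract start within hap
    te = ts + allele
    h_min = max(0, te + 5 - read_len)
    h_max = ts - 5
    if h_min > h_max or len(hap) < read_len:
        return None
    h = int(rng.integers(h_min, h_max + 1))
    if h + read_len > len(hap):
        return None
    read = np.array(list(hap[h : h + read_len]))
    read = _apply_base_errors(read, base_error_rate, rng)
    read_seq = "".join(read)

    genome_left_start = max(0, locus.start - window)
    pos = genome_left_start + h  # read starts in the left context (h <= ts - 5)
    left_m = ts - h
    right_m = read_len - left_m - allele
    if delta == 0:
        cigar = f"{read_len}M"
    elif delta > 0:
        cigar = f"{left_m + ref_len}M{delta}I{right_m}M"
    else:
        cigar = f"{left_m + allele}M{-delta}D{right_m}M"
    return pos, cigar, read_seq


def make_tracks(
    truth_catalog: Sequence[MicrosatLocus],
    rng: np.random.Generator,
    cpg_fraction: float = 0.3,
    tfbs_fraction: float = 0.3,
) -> tuple[list[tuple[str, int, int]], list[tuple[str, int, int]]]:
    """CpG-island and TFBS tracks with a subset of loci in range."""
    cpg, tfbs = [], []
    for locus in truth_catalog:
        if rng.random() < cpg_fraction:
            offset = int(rng.integers(0, 9000))
            start = locus.end + offset
            cpg.append((locus.chrom, start, start + 200))
        if rng.random() < tfbs_fraction:
            offset = int(rng.integers(0, 35))
            start = locus.end + offset
            tfbs.append((locus.chrom, start, start + 12))
    cpg.sort()
    tfbs.sort()
    return cpg, tfbs


def make_exons(
    truth_catalog: Sequence[MicrosatLocus],
    rng: np.random.Generator,
    exon_fraction: float = 0.25,
) -> list[tuple[str, int, int, str]]:
    """Exon intervals covering a subset of loci, one synthetic gene each."""
    exons = []
    for i, locus in enumerate(truth_catalog):
        if rng.random() < exon_fraction:
            exons.append(
                (locus.chrom, max(0, locus.start - 30), locus.end + 30, f"GENE{i:03d}")
            )
    return exons


def end_to_end_fixture(config: SimulationConfig, out_dir: str) -> dict[str, object]:
    """Generate every pipeline input from one seed.

    Writes reference FASTA, exon/CpG/TFBS BED tracks, per-sample SAMs,
    manifest TSV and truth tables under ``out_dir``; returns the paths
    together with the in-memory objects.
    """
    from caml import io as caml_io

    rng = np.random.default_rng(config.seed)
    os.makedirs(out_dir, exist_ok=True)
    reference, truth_catalog = simulate_reference(config, rng)
    truth_table = simulate_cohort_genotypes(config, truth_catalog, rng)
    manifest = simulate_reads(
        config, reference, truth_catalog, truth_table, os.path.join(out_dir, "reads"), rng
    )
    cpg, tfbs = make_tracks(truth_catalog, rng)
    exons = make_exons(truth_catalog, rng)

    paths = {
        "reference": os.path.join(out_dir, "reference.fa"),
        "manifest": os.path.join(out_dir, "manifest.tsv"),
        "exons": os.path.join(out_dir, "exons.bed"),
        "cpg": os.path.join(out_dir, "cpg.bed"),
        "tfbs": os.path.join(out_dir, "tfbs.bed"),
        "truth_catalog": os.path.join(out_dir, "truth_catalog.tsv"),
        "truth_genotypes": os.path.join(out_dir, "truth_genotypes.tsv"),
    }
    caml_io.write_fasta(reference, paths["reference"])
    portable = manifest.copy()  # relative paths keep the fixture relocatable
    portable["path"] = [os.path.relpath(p, out_dir) for p in portable["path"]]
    portable.to_csv(paths["manifest"], sep="\t", index=False)
    caml_io.write_bed(
        [(c, s, e, g) for c, s, e, g in exons], paths["exons"]
    )
    caml_io.write_bed(cpg, paths["cpg"])
    caml_io.write_bed(tfbs, paths["tfbs"])
    caml_io.write_catalog(truth_catalog, paths["truth_catalog"])
    caml_io.write_genotype_table(truth_table, paths["truth_genotypes"])

    return {
        "paths": paths,
        "reference": reference,
        "truth_catalog": truth_catalog,
        "truth_table": truth_table,
        "manifest": manifest,
        "cpg": cpg,
        "tfbs": tfbs,
        "exons": exons,
    }
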