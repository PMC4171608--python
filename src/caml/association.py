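"""Case/control genotype association and signature assembly.

Per locus, each non-predominant genotype is tested against "any other
genotype" in a 2x2 table over callable samples (two-sided Fisher exact
by hypergeometric enumeration). Multiple testing is controlled by
Benjamini–Hochberg step-up at level q* = 1/X, where X is the number of
tested hypotheses with p < 1; the signature keeps members that pass
both the BH cutoff and a raw significance level (default 0.01).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from caml.genotyper import CohortGenotypeTable, STATUS_CALLED

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_LOCI_PER_SAMPLE = 15_000
DEFAULT_MIN_SAMPLES_PER_LOCUS = 10

# relative tolerance for "table at least as extreme as observed"; matches
# the convention of R's fisher.test for floating-point pmf ties
_PMF_TIE_TOLERANCE = 1 + 1e-7


Genotype = tuple[int, int]


def genotype_str(genotype: Genotype) -> str:
    return f"{genotype[0]}/{genotype[1]}"


def parse_genotype(text: str) -> Genotype:
    a, b = text.split("/")
    return (int(a), int(b))


@dataclass
class LocusAssociation:
    """One (locus, genotype) hypothesis with its contingency evidence."""

    locus_id: str
    genotype: Genotype
    a: int  # cases carrying the genotype
    b: int  # cases callable, not carrying
    c: int  # controls carrying
    d: int  # controls callable, not carrying
    p_value: float
    relative_risk: float
    relative_risk_haldane: float
    predominant_control_genotype: Optional[Genotype] = None
    q_pass: bool = False

    @property
    def case_frequency(self) -> float:
        return self.a / (self.a + self.b) if self.a + self.b else float("nan")

    @property
    def control_frequency(self) -> float:
        return self.c / (self.c + self.d) if self.c + self.d else float("nan")


@dataclass
class Signature:
    """FDR-surviving (locus, genotype) members distinguishing two cohorts."""

    label: str
    caml_genotypes: list[tuple[str, Genotype]]
    alpha: float = DEFAULT_ALPHA
    fdr_rule: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.caml_genotypes)

    def genotype_at(self, locus_id: str) -> Optional[Genotype]:
        for lid, gt in self.caml_genotypes:
            if lid == locus_id:
                return gt
        return None

    @property
    def locus_ids(self) -> list[str]:
        return [lid for lid, _ in self.caml_genotypes]


def apply_cohort_filters(
    table: CohortGenotypeTable,
    min_loci_per_sample: int = DEFAULT_MIN_LOCI_PER_SAMPLE,
    min_samples_per_locus: int = DEFAULT_MIN_SAMPLES_PER_LOCUS,
) -> tuple[CohortGenotypeTable, dict]:
    """Apply the inclusion filters and return (filtered table, report).

    Samples with fewer called loci than ``min_loci_per_sample`` are
    dropped; then loci called in fewer than ``min_samples_per_locus``
    samples of *either* cohort are dropped.
    """
    labels = sorted(set(table.cohorts.values()))
    if len(labels) < 2:
        raise ValueError("cohort filters require at least two cohorts")

    per_sample = table.called_loci_per_sample()
    kept_samples = [s for s in table.sample_ids if per_sample[s] >= min_loci_per_sample]
    dropped_samples = [s for s in table.sample_ids if s not in set(kept_samples)]
    filtered = table.subset_samples(kept_samples)

    called = filtered.called()
    all_loci = sorted(filtered.calls["locus_id"].unique())
    counts = {}
    for label in labels:
        members = set(filtered.samples_in(label))
        sub = called[called["sample_id"].isin(members)]
        counts[label] = sub.groupby("locus_id").size()
    kept_loci = [
        lid
        for lid in all_loci
        if all(counts[label].get(lid, 0) >= min_samples_per_locus for label in labels)
    ]
    dropped_loci = [lid for lid in all_loci if lid not in set(kept_loci)]
    filtered = filtered.subset_loci(kept_loci)

    report = {
        "min_loci_per_sample": min_loci_per_sample,
        "min_samples_per_locus": min_samples_per_locus,
        "samples_dropped": dropped_samples,
        "n_samples_dropped": len(dropped_samples),
        "loci_dropped": dropped_loci,
        "n_loci_dropped": len(dropped_loci),
        "n_samples_kept": len(kept_samples),
        "n_loci_kept": len(kept_loci),
    }
    return filtered, report


def predominant_genotype(
    table: CohortGenotypeTable,
    locus_id: str,
    control_label: str,
    ref_length: Optional[int] = None,
) -> Genotype:
    """Modal genotype among control calls at a locus.

    Ties break toward the genotype equal to (ref_length, ref_length) when
    a reference length is known, then toward the lexicographically
    smallest pair.
    """
    controls = set(table.samples_in(control_label))
    called = table.called()
    rows = called[(called["locus_id"] == locus_id) & called["sample_id"].isin(controls)]
    if rows.empty:
        raise ValueError(f"no control calls at locus {locus_id}")
    tally: Counter[Genotype] = Counter(
        (int(a), int(b)) for a, b in zip(rows["allele_a"], rows["allele_b"])
    )
    top = max(tally.values())
    tied = [gt for gt, n in tally.items() if n == top]

    def rank(gt: Genotype):
        matches_ref = ref_length is not None and gt == (ref_length, ref_length)
        return (0 if matches_ref else 1, gt)

    return min(tied, key=rank)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with a small
    relative tolerance for floating-point ties).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1 = a + b
    c1 = a + c
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * _PMF_TIE_TOLERANCE].sum())
    return min(p, 1.0)


def relative_risk(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """(RR, Haldane-corrected RR). RR is +inf when controls have no carriers."""
    if a + b == 0 or c + d == 0:
        return float("nan"), float("nan")
    haldane = ((a + 0.5) / (a + b + 1.0)) / ((c + 0.5) / (c + d + 1.0))
    if c == 0:
        return (float("inf") if a > 0 else math.nan, haldane)
    return ((a / (a + b)) / (c / (c + d)), haldane)


def _carrier_counts(
    table: CohortGenotypeTable, locus_id: str, genotype: Genotype, samples: set[str]
) -> tuple[int, int]:
    called = table.called()
    rows = called[(called["locus_id"] == locus_id) & called["sample_id"].isin(samples)]
    carriers = int(
        ((rows["allele_a"] == genotype[0]) & (rows["allele_b"] == genotype[1])).sum()
    )
    return carriers, len(rows) - carriers


def fisher_association(
    table: CohortGenotypeTable,
    locus_id: str,
    genotype: Genotype,
    case_label: str,
    control_label: str,
    predominant: Optional[Genotype] = None,
) -> LocusAssociation:
    """Test one genotype's carrier frequency between the two cohorts.

    The 2x2 table counts carriers vs non-carriers among *callable*
    (status == called) samples per cohort. Raises on a cohort with zero
    callable samples at the locus.
    """
    cases = set(table.samples_in(case_label))
    controls = set(table.samples_in(control_label))
    a, b = _carrier_counts(table, locus_id, genotype, cases)
    c, d = _carrier_counts(table, locus_id, genotype, controls)
    if a + b == 0 or c + d == 0:
        raise ValueError(f"no callable samples in one cohort at locus {locus_id}")
    p = fisher_two_sided(a, b, c, d)
    rr, rr_h = relative_risk(a, b, c, d)
    return LocusAssociation(
        locus_id=locus_id,
        genotype=genotype,
        a=a,
        b=b,
        c=c,
        d=d,
        p_value=p,
        relative_risk=rr,
        relative_risk_haldane=rr_h,
        predominant_control_genotype=predominant,
    )


def discover_associations(
    table: CohortGenotypeTable,
    case_label: str,
    control_label: str,
    ref_lengths: Optional[Mapping[str, int]] = None,
) -> list[LocusAssociation]:
    """Test every observed non-predominant genotype at every locus.

    For each locus the control-side predominant genotype is established;
    every other genotype observed among called samples of either cohort
    becomes one hypothesis. Loci without control calls or case calls are
    skipped.
    """
    ref_lengths = ref_lengths or {}
    cases = set(table.samples_in(case_label))
    controls = set(table.samples_in(control_label))
    called = table.called()
    relevant = called[called["sample_id"].isin(cases | controls)]

    associations: list[LocusAssociation] = []
    for locus_id, rows in relevant.groupby("locus_id", sort=True):
        case_rows = rows[rows["sample_id"].isin(cases)]
        control_rows = rows[rows["sample_id"].isin(controls)]
        if case_rows.empty or control_rows.empty:
            continue
        tally: Counter[Genotype] = Counter(
            (int(x), int(y)) for x, y in zip(control_rows["allele_a"], control_rows["allele_b"])
        )
        ref_length = ref_lengths.get(locus_id)
        top = max(tally.values())
        tied = [gt for gt, v in tally.items() if v == top]
        predominant = min(
            tied,
            key=lambda gt: (
                0 if (ref_length is not None and gt == (ref_length, ref_length)) else 1,
                gt,
            ),
        )
        observed: set[Genotype] = {
            (int(x), int(y)) for x, y in zip(rows["allele_a"], rows["allele_b"])
        }
        n_case = len(case_rows)
        n_control = len(control_rows)
        case_tally: Counter[Genotype] = Counter(
            (int(x), int(y)) for x, y in zip(case_rows["allele_a"], case_rows["allele_b"])
        )
        for genotype in sorted(observed - {predominant}):
            a = case_tally.get(genotype, 0)
            b = n_case - a
            c = tally.get(genotype, 0)
            d = n_control - c
            p = fisher_two_sided(a, b, c, d)
            rr, rr_h = relative_risk(a, b, c, d)
            associations.append(
                LocusAssociation(
                    locus_id=locus_id,
                    genotype=genotype,
                    a=a,
                    b=b,
                    c=c,
                    d=d,
                    p_value=p,
                    relative_risk=rr,
                    relative_risk_haldane=rr_h,
                    predominant_control_genotype=predominant,
                )
            )
    return associations


def bh_pass(p_values: Sequence[float], q_star: float) -> np.ndarray:
    """Benjamini–Hochberg step-up at level ``q_star``; boolean pass mask."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0 or q_star <= 0:
        return np.zeros(m, dtype=bool)
    order = np.argsort(p, kind="stable")
    thresholds = q_star * (np.arange(1, m + 1) / m)
    below = p[order] <= thresholds
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.nonzero(below)[0].max())
        mask[order[: k + 1]] = True
    return mask


def bh_signature_cutoff(
    associations: Sequence[LocusAssociation],
    alpha: float = DEFAULT_ALPHA,
    label: str = "case-vs-control",
) -> Signature:
    """Assemble the signature from tested associations.

    The BH level is q* = 1/X with X = number of tested hypotheses whose
    p is strictly below 1. Step-up runs over *all* tested hypotheses;
    members must also satisfy p <= alpha. ``q_pass`` is set on each
    association as a side effect.
    """
    p_values = [assoc.p_value for assoc in associations]
    x = sum(1 for p in p_values if p < 1.0)
    q_star = 1.0 / x if x > 0 else 0.0
    mask = bh_pass(p_values, q_star)
    members = []
    for assoc, passed in zip(associations, mask):
        assoc.q_pass = bool(passed)
        if passed and assoc.p_value <= alpha:
            members.append((assoc.locus_id, assoc.genotype))
    return Signature(
        label=label,
        caml_genotypes=members,
        alpha=alpha,
        fdr_rule={"X": x, "q_star": q_star, "n_hypotheses": len(associations)},
    )


def associations_frame(associations: Sequence[LocusAssociation]) -> pd.DataFrame:
    rows = [
        {
            "locus_id": assoc.locus_id,
            "genotype": genotype_str(assoc.genotype),
            "a": assoc.a,
            "b": assoc.b,
            "c": assoc.c,
            "d": assoc.d,
            "p_value": assoc.p_value,
            "relative_risk": assoc.relative_risk,
            "relative_risk_haldane": assoc.relative_risk_haldane,
            "predominant_control_genotype": (
                genotype_str(assoc.predominant_control_genotype)
                if assoc.predominant_control_genotype
                else ""
            ),
            "q_pass": assoc.q_pass,
        }
        for assoc in associations
    ]
    return pd.DataFrame(rows)
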