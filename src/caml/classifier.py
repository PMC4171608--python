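"""Signature detection-fraction scoring and ROC thresholding.

Each sample is scored by the fraction of its callable signature loci
whose called genotype equals the signature genotype. A cutoff on that
fraction is chosen by maximizing Youden's J over all observed
thresholds; sensitivity and specificity are reported at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from caml.association import Signature, fisher_two_sided, genotype_str
from caml.genotyper import CohortGenotypeTable


@dataclass
class ClassificationResult:
    sample_id: str
    detectable: int
    matched: int
    true_label: Optional[str] = None
    predicted_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.matched <= self.detectable:
            raise ValueError("matched must lie in [0, detectable]")

    @property
    def scorable(self) -> bool:
        return self.detectable > 0

    @property
    def fraction(self) -> float:
        if not self.scorable:
            return float("nan")
        return self.matched / self.detectable


@dataclass
class RocSummary:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    points: pd.DataFrame  # threshold, sensitivity, specificity per candidate
    positive_label: str
    negative_label: str
    n_unscorable: int = 0


def score_samples(
    table: CohortGenotypeTable, signature: Signature
) -> list[ClassificationResult]:
    """Score every sample in the table against the signature.

    "Detectable" means status == called at the signature locus; samples
    with zero detectable signature loci are flagged unscorable
    (fraction NaN) and must be excluded from ROC analysis.
    """
    if len(signature) == 0:
        raise ValueError("signature is empty")
    lookup = table.genotype_lookup()
    results = []
    for sample_id in table.sample_ids:
        detectable = matched = 0
        for locus_id, genotype in signature.caml_genotypes:
            call = lookup.get((sample_id, locus_id))
            if call is None:
                continue
            detectable += 1
            if call == genotype:
                matched += 1
        results.append(
            ClassificationResult(
                sample_id=sample_id,
                detectable=detectable,
                matched=matched,
                true_label=table.cohorts.get(sample_id),
            )
        )
    return results


def fraction_histogram(
    results: Sequence[ClassificationResult], n_bins: int = 10
) -> pd.DataFrame:
    """Percentage of scorable samples per detection-fraction bin, per label."""
    scorable = [r for r in results if r.scorable]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for label in sorted({r.true_label for r in scorable}):
        fractions = np.array([r.fraction for r in scorable if r.true_label == label])
        counts, _ = np.histogram(fractions, bins=edges)
        # top bin is closed so fraction == 1.0 lands in the last bin
        pct = 100.0 * counts / len(fractions)
        for lo, hi, value in zip(edges[:-1], edges[1:], pct):
            rows.append(
                {"label": label, "bin_low": lo, "bin_high": hi, "percent_samples": value}
            )
    return pd.DataFrame(rows)


def roc_cutoff(
    results: Sequence[ClassificationResult],
    positive_label: str,
    negative_label: str,
) -> RocSummary:
    """Choose the detection-fraction cutoff maximizing Youden's J.

    Candidate thresholds are every observed fraction (a sample is
    predicted positive when fraction >= threshold). Ties on J break
    toward higher specificity, then toward the higher threshold.
    Raises when either class has no scorable samples.
    """
    scorable = [r for r in results if r.scorable]
    pos = np.array([r.fraction for r in scorable if r.true_label == positive_label])
    neg = np.array([r.fraction for r in scorable if r.true_label == negative_label])
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC requires scorable samples from both classes")

    thresholds = np.unique(np.concatenate([pos, neg]))
    rows = []
    best = None
    for t in thresholds:
        tp = int((pos >= t).sum())
        fn = len(pos) - tp
        fp = int((neg >= t).sum())
        tn = len(neg) - fp
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        rows.append(
            {"threshold": t, "sensitivity": sens, "specificity": spec, "youden_j": j}
        )
        key = (j, spec, t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec, j)

    _, cutoff, sens, spec, j = best
    for r in results:
        if r.scorable:
            r.predicted_label = positive_label if r.fraction >= cutoff else negative_label
        else:
            r.predicted_label = None
    return RocSummary(
        cutoff=float(cutoff),
        sensitivity=float(sens),
        specificity=float(spec),
        youden_j=float(j),
        points=pd.DataFrame(rows),
        positive_label=positive_label,
        negative_label=negative_label,
        n_unscorable=len(results) - len(scorable),
    )


def cross_signature_comparison(
    positive_table: CohortGenotypeTable,
    negative_table: CohortGenotypeTable,
    signature: Signature,
    positive_label: str,
    negative_label: str,
) -> tuple[list[ClassificationResult], RocSummary]:
    """Score one case cohort against another (grade-vs-grade design).

    Both tables are scored against the shared signature; samples keep
    their own cohort labels, and the ROC treats ``positive_label`` as
    the detection target.
    """
    merged = CohortGenotypeTable(
        pd.concat([positive_table.calls, negative_table.calls], ignore_index=True),
        {**positive_table.cohorts, **negative_table.cohorts},
    )
    results = score_samples(merged, signature)
    summary = roc_cutoff(results, positive_label, negative_label)
    return results, summary


def tumor_germline_concordance(
    germline: CohortGenotypeTable,
    tumor: CohortGenotypeTable,
    signature: Signature,
    flag_alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-signature-locus agreement between matched compartments.

    For samples present in both tables: the per-locus genotype agreement
    rate over pairs called in both compartments, and a two-sided Fisher
    test of signature-genotype carrier frequency between compartments
    (germline carriers vs tumor carriers among called samples). Loci
    with p below ``flag_alpha`` are flagged.
    """
    paired = sorted(set(germline.cohorts) & set(tumor.cohorts))
    if not paired:
        raise ValueError("no matched sample_ids between germline and tumor tables")
    g_lookup = germline.genotype_lookup()
    t_lookup = tumor.genotype_lookup()

    rows = []
    for locus_id, genotype in signature.caml_genotypes:
        both = [
            (g_lookup[(s, locus_id)], t_lookup[(s, locus_id)])
            for s in paired
            if (s, locus_id) in g_lookup and (s, locus_id) in t_lookup
        ]
        g_called = [g_lookup[(s, locus_id)] for s in paired if (s, locus_id) in g_lookup]
        t_called = [t_lookup[(s, locus_id)] for s in paired if (s, locus_id) in t_lookup]
        agree = sum(1 for g, t in both if g == t)
        concordance = agree / len(both) if both else float("nan")
        a = sum(1 for g in g_called if g == genotype)
        b = len(g_called) - a
        c = sum(1 for t in t_called if t == genotype)
        d = len(t_called) - c
        p = fisher_two_sided(a, b, c, d) if (a + b > 0 and c + d > 0) else float("nan")
        rows.append(
            {
                "locus_id": locus_id,
                "genotype": genotype_str(genotype),
                "n_pairs_called_both": len(both),
                "concordance": concordance,
                "germline_carriers": a,
                "germline_called": a + b,
                "tumor_carriers": c,
                "tumor_called": c + d,
                "p_value": p,
                "flagged": bool(p == p and p < flag_alpha),
            }
        )
    return pd.DataFrame(rows)
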