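"""Readers and writers for the pipeline's plain-text formats.

FASTA via Biopython; BED (0-based half-open, optional name column);
catalog BED+ TSV; manifest TSV; genotype table TSV; signature JSON.
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from caml.association import Signature, genotype_str, parse_genotype
from caml.catalog import ExonIntervals, MicrosatLocus
from caml.genotyper import CALL_COLUMNS, CohortGenotypeTable


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(reference: Mapping[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in reference.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_bed(path: str) -> list[tuple]:
    """BED rows as (chrom, start, end[, name]) tuples."""
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 4:
                rows.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
            else:
                rows.append((fields[0], int(fields[1]), int(fields[2])))
    return rows


def write_bed(intervals: Iterable[tuple], path: str) -> None:
    with open(path, "w") as handle:
        for row in intervals:
            handle.write("\t".join(str(x) for x in row) + "\n")


def read_exons(path: str) -> ExonIntervals:
    records = []
    for row in read_bed(path):
        if len(row) < 4:
            raise ValueError(f"exon BED needs a gene symbol in column 4: {row}")
        records.append((row[0], row[1], row[2], row[3]))
    return ExonIntervals.from_records(records)


CATALOG_COLUMNS = [
    "chrom",
    "start",
    "end",
    "locus_id",
    "motif",
    "ref_length",
    "region_class",
    "gene",
    "left_flank",
    "right_flank",
]


def write_catalog(catalog: Sequence[MicrosatLocus], path: str) -> None:
    rows = [
        {
            "chrom": l.chrom,
            "start": l.start,
            "end": l.end,
            "locus_id": l.locus_id,
            "motif": l.motif,
            "ref_length": l.ref_length,
            "region_class": l.region_class,
            "gene": l.gene or ".",
            "left_flank": l.left_flank or ".",
            "right_flank": l.right_flank or ".",
        }
        for l in catalog
    ]
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog(path: str) -> list[MicrosatLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    loci = []
    for rec in df.itertuples(index=False):
        loci.append(
            MicrosatLocus(
                chrom=rec.chrom,
                start=int(rec.start),
                end=int(rec.end),
                motif=rec.motif,
                region_class=rec.region_class,
                gene=None if rec.gene in (".", "") or pd.isna(rec.gene) else rec.gene,
                left_flank="" if rec.left_flank == "." else rec.left_flank,
                right_flank="" if rec.right_flank == "." else rec.right_flank,
            )
        )
    return loci


def read_manifest(path: str) -> pd.DataFrame:
    """Read a sample manifest; relative alignment paths resolve against it."""
    import os

    manifest = pd.read_csv(path, sep="\t")
    required = {"sample_id", "cohort", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = os.path.dirname(os.path.abspath(path))
    manifest["path"] = [
        p if os.path.isabs(p) else os.path.join(base, p) for p in manifest["path"]
    ]
    return manifest


def write_genotype_table(table: CohortGenotypeTable, path: str) -> None:
    out = table.calls.copy()
    out["cohort"] = out["sample_id"].map(table.cohorts)
    out.to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str) -> CohortGenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    cohorts = dict(zip(df["sample_id"], df["cohort"]))
    return CohortGenotypeTable(df[CALL_COLUMNS].copy(), cohorts)


def write_signature(signature: Signature, path: str) -> None:
    payload = {
        "label": signature.label,
        "alpha": signature.alpha,
        "fdr_rule": signature.fdr_rule,
        "caml_genotypes": [
            {"locus_id": lid, "genotype": genotype_str(gt)}
            for lid, gt in signature.caml_genotypes
        ],
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_signature(path: str) -> Signature:
    with open(path) as handle:
        payload = json.load(handle)
    return Signature(
        label=payload["label"],
        alpha=payload["alpha"],
        fdr_rule=payload.get("fdr_rule", {}),
        caml_genotypes=[
            (item["locus_id"], parse_genotype(item["genotype"]))
            for item in payload["caml_genotypes"]
        ],
    )
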