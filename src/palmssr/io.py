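"""File-format readers and writers.

Conventions: internal coordinates are 0-based half-open everywhere. BED
output keeps that convention; GFF3 is converted to/from its native 1-based
closed intervals. Genotype tables use a GenAlEx-style CSV layout:

    line 1: n_loci,n_samples,n_groups
    line 2: sample,group,<locus1>,,<locus2>,, ...   (two columns per locus)
    then one row per sample: id, group, allele1, allele2, ...  (0 = missing)

Malformed records raise :class:`palmssr.repeat_mining.InputError` naming the
file, line and reason.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .marker_design import ExonModel, MarkerCandidate
from .ordination import DistanceMatrix, PCoAResult
from .popgen_stats import GenotypeTable, TransferMatrix
from .repeat_mining import InputError, SSRLocus, SSRSummary

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_bed",
    "read_gff3_exons",
    "write_gff3_exons",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_transfer_tsv",
    "write_transfer_tsv",
    "write_distance_tsv",
    "read_distance_tsv",
    "write_pcoa_tsv",
    "write_summary_tsv",
    "write_panel_tsv",
    "write_locus_stats_tsv",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA → {id: uppercase sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_bed(path: str | Path, loci: Iterable[SSRLocus]) -> None:
    """BED6: chrom, start, end, name=(motif)xrepeats, score=0, strand=+."""
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.sequence_id}\t{locus.start}\t{locus.end}\t"
                f"{locus.label}\t0\t+\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED → list of (chrom, start, end, name); 0-based half-open kept as is."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise InputError(f"{path}:{lineno}: empty interval {start}-{end}")
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], start, end, name))
    return out


def read_gff3_exons(path: str | Path) -> list[ExonModel]:
    """Extract exon features from a GFF3 file, grouped by Parent transcript.

    GFF3 1-based closed intervals become 0-based half-open internally.
    """
    exons: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise InputError(f"{path}:{lineno}: GFF3 line has {len(parts)} columns, expected 9")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype.lower() != "exon":
                continue
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer coordinate") from exc
            if e < s:
                raise InputError(f"{path}:{lineno}: end < start")
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    key, val = item.split("=", 1)
                    attr_map[key.strip()] = val.strip()
            parent = attr_map.get("Parent") or attr_map.get("ID")
            if not parent:
                raise InputError(f"{path}:{lineno}: exon without Parent/ID attribute")
            exons.setdefault((chrom, parent, strand), []).append((s - 1, e))
    models = []
    for (chrom, parent, strand), intervals in exons.items():
        models.append(
            ExonModel(
                chromosome=chrom,
                transcript_id=parent,
                strand=strand,
                exons=tuple(sorted(intervals)),
            )
        )
    models.sort(key=lambda m: (m.chromosome, m.exons[0][0], m.transcript_id))
    return models


def write_gff3_exons(path: str | Path, models: Sequence[ExonModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for model in models:
            for i, (start, end) in enumerate(model.exons, 1):
                fh.write(
                    f"{model.chromosome}\tpalmssr\texon\t{start + 1}\t{end}\t.\t"
                    f"{model.strand}\t.\tID={model.transcript_id}.exon{i};"
                    f"Parent={model.transcript_id}\n"
                )


def write_genotype_csv(path: str | Path, table: GenotypeTable) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([table.n_loci, table.n_samples, len(table.group_names())])
        header = ["sample", "group"]
        for locus in table.loci:
            header += [locus, ""]
        writer.writerow(header)
        for i, sample in enumerate(table.sample_ids):
            row: list = [sample, table.groups[i]]
            for j in range(table.n_loci):
                row += [int(table.calls[i, j, 0]), int(table.calls[i, j, 1])]
            writer.writerow(row)


def read_genotype_csv(path: str | Path) -> GenotypeTable:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise InputError(f"{path}: genotype CSV needs header rows plus samples")
    try:
        n_loci, n_samples, n_groups = (int(x) for x in rows[0][:3])
    except (ValueError, IndexError) as exc:
        raise InputError(f"{path}:1: header must be n_loci,n_samples,n_groups") from exc
    header = rows[1]
    loci = [header[2 + 2 * j] for j in range(n_loci)]
    if any(not name for name in loci):
        raise InputError(f"{path}:2: empty locus name in header")
    sample_ids, groups = [], []
    calls = np.zeros((n_samples, n_loci, 2), dtype=np.int64)
    if len(rows) - 2 != n_samples:
        raise InputError(
            f"{path}: expected {n_samples} sample rows, found {len(rows) - 2}"
        )
    for i, row in enumerate(rows[2:]):
        lineno = i + 3
        if len(row) < 2 + 2 * n_loci:
            raise InputError(f"{path}:{lineno}: row has too few columns")
        sample_ids.append(row[0])
        groups.append(row[1])
        for j in range(n_loci):
            try:
                a = int(row[2 + 2 * j])
                b = int(row[3 + 2 * j])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: non-integer allele size") from exc
            if a < 0 or b < 0:
                raise InputError(f"{path}:{lineno}: negative allele size")
            # a half-missing call is treated as fully missing
            if a == 0 or b == 0:
                a = b = 0
            calls[i, j] = (a, b)
    del n_groups
    return GenotypeTable(sample_ids=sample_ids, groups=groups, loci=loci, calls=calls)


def write_transfer_tsv(path: str | Path, matrix: TransferMatrix) -> None:
    out = matrix.data.copy()
    out.index.name = "species"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_transfer_tsv(path: str | Path) -> TransferMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise InputError(f"{path}: cannot parse transfer TSV: {exc}") from exc
    if df.shape[1] < 1:
        raise InputError(f"{path}: transfer matrix has no marker columns")
    bad = df.stack().dropna()
    if not bad.isin([0, 1]).all():
        raise InputError(f"{path}: transfer entries must be 0, 1 or NA")
    return TransferMatrix(data=df)


def write_distance_tsv(path: str | Path, dist: DistanceMatrix) -> None:
    df = pd.DataFrame(dist.matrix, index=dist.ids, columns=dist.ids)
    df.index.name = "unit"
    df.to_csv(path, sep="\t")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise InputError(f"{path}: distance matrix rows and columns disagree")
    return DistanceMatrix(ids=list(df.index), matrix=df.to_numpy(dtype=float))


def write_pcoa_tsv(path: str | Path, result: PCoAResult) -> None:
    k = result.coordinates.shape[1]
    with open(path, "w") as fh:
        pct = "\t".join(f"{p:.4f}" for p in result.percent_variance)
        fh.write(f"# percent variance per axis: {pct}\n")
        fh.write("unit\t" + "\t".join(f"axis{i + 1}" for i in range(k)) + "\n")
        for i, unit in enumerate(result.ids):
            coords = "\t".join(f"{c:.6f}" for c in result.coordinates[i])
            fh.write(f"{unit}\t{coords}\n")


def write_summary_tsv(path: str | Path, summary: SSRSummary) -> None:
    """Three-block summary table: SSR type, repeat number, motif tallies."""
    with open(path, "w") as fh:
        fh.write("block\tcategory\tcount\tpercent_of_total\n")

        def block(name: str, items: dict) -> None:
            for key, count in items.items():
                pct = 100.0 * count / summary.total if summary.total else 0.0
                fh.write(f"{name}\t{key}\t{count}\t{pct:.2f}\n")

        block("ssr_type", summary.by_type)
        block("n_repeats", summary.by_n_repeats)
        block("raw_motif", summary.by_raw_motif)
        block("canonical_motif", summary.by_canonical_motif)
        if summary.by_tissue_category:
            block("tissue", summary.by_tissue_category)
        fh.write(f"total\tall\t{summary.total}\t100.00\n")


def write_panel_tsv(path: str | Path, panel: Sequence[MarkerCandidate]) -> None:
    """Marker panel table: id, placement, motif, repeats, primers, Tm, GC, product."""
    cols = (
        "marker_id\tchrom\tamplicon_start\tamplicon_end\tssr_start\tssr_end\t"
        "motif\tn_repeats\tforward_primer\treverse_primer\ttm_forward\t"
        "tm_reverse\tgc_forward\tgc_reverse\tproduct_size\tsource_individuals\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for cand in panel:
            p = cand.primers
            fh.write(
                f"{cand.marker_id}\t{cand.chromosome}\t{cand.start}\t{cand.end}\t"
                f"{cand.locus.start}\t{cand.locus.end}\t"
                f"{cand.locus.motif or cand.locus.label}\t{cand.locus.n_repeats}\t"
                f"{p.forward_seq if p else ''}\t{p.reverse_seq if p else ''}\t"
                f"{p.tm_forward:.2f}\t{p.tm_reverse:.2f}\t"
                f"{p.gc_forward:.1f}\t{p.gc_reverse:.1f}\t"
                f"{p.product_size}\t{','.join(sorted(cand.source_individuals))}\n"
                if p
                else f"{cand.marker_id}\t{cand.chromosome}\t{cand.start}\t{cand.end}\t"
                f"{cand.locus.start}\t{cand.locus.end}\t"
                f"{cand.locus.motif or cand.locus.label}\t{cand.locus.n_repeats}\t"
                "\t\t\t\t\t\t\t\n"
            )


def write_locus_stats_tsv(path: str | Path, stats: dict) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tNa\tNe\tHe\tHo\tI\tPIC\tPI\tcategory\tn_typed\n")
        for locus, s in stats.items():
            fh.write(
                f"{locus}\t{s.na}\t{s.ne:.4f}\t{s.he:.4f}\t{s.ho:.4f}\t"
                f"{s.shannon:.4f}\t{s.pic:.4f}\t{s.pi:.4f}\t{s.category}\t{s.n_typed}\n"
            )
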