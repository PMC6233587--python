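"""Hand-transcribed published marker tables, shipped as package data.

These small TSVs hold the printed summary numbers of the marker-development
study this toolkit re-implements (locus tallies by tissue, repeat number and
motif type; the private-allele table; per-species transfer counts; headline
pipeline counts). They serve as inputs to the arithmetic/classification
layer — the underlying raw sequence reads and the 17-sample genotype matrix
were never deposited, so these tables are the only recomputable anchors.

Each file is integrity-checked against ``data/SHA256SUMS`` at load time.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass
from importlib import resources

from .popgen_stats import TransferMatrix
from .repeat_mining import InputError

import pandas as pd

__all__ = [
    "PaperTableFixture",
    "load_paper_fixtures",
    "private_allele_summary",
    "reconstruct_tissue_sets",
    "reconstruct_transfer_matrix",
]

_FILES = {
    "table1_tissue": "table1_tissue.tsv",
    "table1_repeats": "table1_repeats.tsv",
    "table1_motifs": "table1_motifs.tsv",
    "table2_private_alleles": "table2_private_alleles.tsv",
    "results_counts": "results_counts.tsv",
    "transfer_counts": "transfer_counts.tsv",
}


@dataclass
class PaperTableFixture:
    table_id: str
    records: list[dict[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError(f"fixture {self.table_id} is empty")


def _data_dir():
    return resources.files("palmssr") / "data"


def _checksums() -> dict[str, str]:
    text = (_data_dir() / "SHA256SUMS").read_text()
    out = {}
    for line in text.strip().splitlines():
        digest, name = line.split()
        out[name] = digest
    return out


def load_paper_fixtures() -> dict[str, PaperTableFixture]:
    """Load and verify all transcribed tables; raises on checksum mismatch."""
    sums = _checksums()
    out: dict[str, PaperTableFixture] = {}
    for table_id, filename in _FILES.items():
        raw = (_data_dir() / filename).read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        if sums.get(filename) != digest:
            raise InputError(f"checksum mismatch for fixture {filename}")
        rows = list(csv.DictReader(raw.decode().splitlines(), delimiter="\t"))
        out[table_id] = PaperTableFixture(table_id=table_id, records=rows)
    return out


def private_allele_summary(
    fixture: PaperTableFixture,
) -> tuple[int, int, str, int]:
    """(total private alleles, markers carrying one, top marker, its count)."""
    per_marker: dict[str, int] = {}
    for rec in fixture.records:
        per_marker[rec["marker"]] = per_marker.get(rec["marker"], 0) + 1
    top = max(per_marker, key=lambda m: (per_marker[m], m))
    return len(fixture.records), len(per_marker), top, per_marker[top]


def reconstruct_tissue_sets(
    fixture: PaperTableFixture,
) -> dict[str, set[int]]:
    """Rebuild three tissue locus-id sets realizing the published category
    counts, so the exclusivity tally can be recomputed from set operations."""
    sets: dict[str, set[int]] = {"vegetative": set(), "flower": set(), "fruit": set()}
    next_id = 0
    for rec in fixture.records:
        members = rec["category"].split("/")
        count = int(rec["count"])
        ids = range(next_id, next_id + count)
        next_id += count
        for tissue in members:
            sets[tissue].update(ids)
    return sets


def reconstruct_transfer_matrix(fixture: PaperTableFixture) -> TransferMatrix:
    """Rebuild a binary species × marker matrix with the published per-species
    amplification counts over the fixed marker universe."""
    totals = {int(rec["total"]) for rec in fixture.records}
    if len(totals) != 1:
        raise InputError("transfer fixture species disagree on marker total")
    total = totals.pop()
    markers = [f"M{i + 1:03d}" for i in range(total)]
    rows = {}
    for rec in fixture.records:
        amplified = int(rec["amplified"])
        rows[rec["species"]] = [1.0] * amplified + [0.0] * (total - amplified)
    return TransferMatrix(data=pd.DataFrame(rows, index=markers).T)
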