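"""From mined SSR loci to a non-redundant, genomically spaced marker panel.

The filters mirror a standard EST-SSR marker-development protocol:

1. primer scan — exhaustive enumeration of forward/reverse primer windows
   flanking the repeat tract under length (16-22 nt), GC (40-60 %), melting
   temperature (50-60 °C) and product-size (100-500 bp) constraints;
2. exon containment — the amplicon must lie inside a single exon, so the
   genomic PCR product has the size predicted from the transcript;
3. redundancy removal — candidates from different individuals whose genomic
   placements overlap collapse to one representative locus;
4. genomic spacing — a minimum inter-marker distance (default 1 Mbp) per
   chromosome, to avoid validating linked loci;
5. validation-panel selection — a pure predicate on motif type, product
   size and primer Tm.

Melting temperatures use the basic GC-fraction formula
``Tm = 64.9 + 41 * (n_GC - 16.4) / length`` (°C); full nearest-neighbour
thermodynamics is intentionally out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .repeat_mining import ContractError, SSRLocus, reverse_complement

__all__ = [
    "ExonModel",
    "PrimerPair",
    "PrimerConstraints",
    "MarkerCandidate",
    "primer_tm",
    "gc_percent",
    "scan_primer_candidates",
    "amplicon_within_single_exon",
    "deduplicate_loci",
    "enforce_min_spacing",
    "select_validation_panel",
    "assign_marker_ids",
    "design_panel",
    "MOTIF_TYPE_PRIORITY",
]

# tri/hexa repeats preserve reading frame in genic sequence, hence preferred
MOTIF_TYPE_PRIORITY = {
    "tri": 0,
    "hexa": 1,
    "di": 2,
    "tetra": 3,
    "penta": 4,
    "mono": 5,
    "compound": 6,
}


@dataclass(frozen=True)
class ExonModel:
    """Exon structure of one transcript on a chromosome.

    Exons are 0-based half-open genomic intervals, sorted and non-overlapping.
    """

    chromosome: str
    transcript_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ContractError(f"strand must be + or -, got {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if start < prev_end:
                raise ContractError("exons must be sorted and non-overlapping")
            if end <= start:
                raise ContractError(f"empty exon interval {start}-{end}")
            prev_end = end


@dataclass(frozen=True)
class PrimerPair:
    forward_seq: str
    reverse_seq: str
    forward_start: int  # template offset of forward primer 5' end
    reverse_start: int  # template offset of reverse primer binding-site start
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    product_size: int

    @property
    def mean_tm(self) -> float:
        return 0.5 * (self.tm_forward + self.tm_reverse)


@dataclass(frozen=True)
class PrimerConstraints:
    min_length: int = 16
    max_length: int = 22
    min_gc: float = 40.0
    max_gc: float = 60.0
    min_tm: float = 50.0
    max_tm: float = 60.0
    min_product: int = 100
    max_product: int = 500


@dataclass
class MarkerCandidate:
    """An SSR locus with genomic placement, primer pair and panel metadata.

    ``start``/``end`` delimit the amplicon on ``chromosome``; flags are
    monotone: ``validation_panel`` implies ``spaced`` implies ``unique``.
    """

    marker_id: str
    locus: SSRLocus
    chromosome: str
    start: int
    end: int
    primers: PrimerPair | None = None
    source_individuals: frozenset[str] = frozenset()
    unique: bool = False
    in_exon: bool = False
    spaced: bool = False
    validation_panel: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ContractError("amplicon interval is empty")


def gc_percent(seq: str) -> float:
    if not seq:
        raise ContractError("empty sequence")
    gc = sum(1 for b in seq.upper() if b in "GC")
    return 100.0 * gc / len(seq)


def primer_tm(seq: str) -> float:
    """Basic GC-count melting temperature, °C."""
    seq = seq.upper()
    gc = sum(1 for b in seq if b in "GC")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def _windows(template: str, lo: int, hi: int, constraints: PrimerConstraints):
    """All (start, length, seq, gc, tm) windows within template[lo:hi] passing
    the per-primer constraints."""
    out = []
    for length in range(constraints.min_length, constraints.max_length + 1):
        for start in range(lo, hi - length + 1):
            win = template[start : start + length]
            if "N" in win:
                continue
            gc = gc_percent(win)
            if not (constraints.min_gc <= gc <= constraints.max_gc):
                continue
            tm = primer_tm(win)
            if not (constraints.min_tm <= tm <= constraints.max_tm):
                continue
            out.append((start, length, win, gc, tm))
    return out


def scan_primer_candidates(
    template: str,
    locus: SSRLocus,
    constraints: PrimerConstraints | None = None,
) -> list[PrimerPair]:
    """Enumerate every primer pair bracketing the SSR tract that satisfies all
    constraint bounds.

    The forward primer lies entirely left of the tract, the reverse primer
    (given as its reverse complement, ready for synthesis) entirely right of
    it. Pairs are ranked by |Tm_f - Tm_r| ascending, then |product - 300|
    ascending, then leftmost. Returns an empty list when no window qualifies.
    """
    constraints = constraints or PrimerConstraints()
    template = template.upper()
    n = len(template)
    if locus.start < 0 or locus.end > n:
        raise ContractError("locus does not lie within template")
    if n < constraints.min_product:
        return []
    # product <= max_product bounds how far primers can sit from the tract
    fwd_lo = max(0, locus.end - constraints.max_product)
    rev_hi = min(n, locus.start + constraints.max_product)
    fwd = _windows(template, fwd_lo, locus.start, constraints)
    rev = _windows(template, locus.end, rev_hi, constraints)
    pairs: list[PrimerPair] = []
    for fs, flen, fseq, fgc, ftm in fwd:
        for rs, rlen, rwin, rgc, rtm in rev:
            product = rs + rlen - fs
            if not (constraints.min_product <= product <= constraints.max_product):
                continue
            pairs.append(
                PrimerPair(
                    forward_seq=fseq,
                    reverse_seq=reverse_complement(rwin),
                    forward_start=fs,
                    reverse_start=rs,
                    tm_forward=ftm,
                    tm_reverse=rtm,
                    gc_forward=fgc,
                    gc_reverse=rgc,
                    product_size=product,
                )
            )
    pairs.sort(
        key=lambda p: (
            abs(p.tm_forward - p.tm_reverse),
            abs(p.product_size - 300),
            p.forward_start,
            p.reverse_start,
        )
    )
    return pairs


def amplicon_within_single_exon(
    amplicon: tuple[int, int], model: ExonModel
) -> bool:
    """True iff one exon fully contains the amplicon (touching boundaries
    allowed)."""
    start, end = amplicon
    return any(es <= start and end <= ee for es, ee in model.exons)


def _dedup_sort_key(cand: MarkerCandidate):
    tract_len = cand.locus.end - cand.locus.start
    if cand.primers is not None:
        tm_crit = abs(cand.primers.mean_tm - 55.0)
    else:
        tm_crit = float("inf")
    return (
        -tract_len,
        tm_crit,
        MOTIF_TYPE_PRIORITY.get(cand.locus.ssr_type, 99),
        cand.marker_id,
    )


def deduplicate_loci(candidates: Sequence[MarkerCandidate]) -> list[MarkerCandidate]:
    """Collapse candidates with overlapping genomic placements to one
    representative per overlap cluster.

    Clusters are the connected components of the interval-overlap graph per
    chromosome (any shared base). The representative is chosen by tract
    length descending, then mean primer Tm closest to 55 °C, then motif-type
    priority, then stable id order; it records the union of the cluster's
    source individuals. Idempotent: output intervals are pairwise disjoint.
    """
    by_chrom: dict[str, list[MarkerCandidate]] = {}
    for cand in candidates:
        by_chrom.setdefault(cand.chromosome, []).append(cand)
    out: list[MarkerCandidate] = []
    for chrom in sorted(by_chrom):
        cands = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end, c.marker_id))
        cluster: list[MarkerCandidate] = []
        cluster_end = -1
        for cand in cands:
            if cluster and cand.start >= cluster_end:
                out.append(_cluster_representative(cluster))
                cluster = []
                cluster_end = -1
            cluster.append(cand)
            cluster_end = max(cluster_end, cand.end)
        if cluster:
            out.append(_cluster_representative(cluster))
    out.sort(key=lambda c: (c.chromosome, c.start, c.marker_id))
    return out


def _cluster_representative(cluster: list[MarkerCandidate]) -> MarkerCandidate:
    rep = min(cluster, key=_dedup_sort_key)
    sources = frozenset().union(*(c.source_individuals for c in cluster))
    return replace_flags(rep, source_individuals=sources, unique=True)


def replace_flags(cand: MarkerCandidate, **kwargs) -> MarkerCandidate:
    return replace(cand, **kwargs)


def enforce_min_spacing(
    candidates: Sequence[MarkerCandidate], min_distance: int = 1_000_000
) -> list[MarkerCandidate]:
    """Greedy left-to-right per-chromosome spacing filter.

    A candidate is kept iff its start is at least ``min_distance`` from the
    start of the previously kept candidate on the same chromosome, so all
    retained pairs satisfy the distance. Output order: chromosome, start.
    """
    by_chrom: dict[str, list[MarkerCandidate]] = {}
    for cand in candidates:
        by_chrom.setdefault(cand.chromosome, []).append(cand)
    kept: list[MarkerCandidate] = []
    for chrom in sorted(by_chrom):
        last_start: int | None = None
        for cand in sorted(by_chrom[chrom], key=lambda c: (c.start, c.marker_id)):
            if last_start is None or cand.start - last_start >= min_distance:
                kept.append(replace_flags(cand, spaced=True))
                last_start = cand.start
    return kept


def select_validation_panel(
    candidates: Sequence[MarkerCandidate],
    trinucleotide_only: bool = True,
    product_range: tuple[int, int] = (100, 500),
    tm_range: tuple[float, float] = (50.0, 60.0),
) -> list[MarkerCandidate]:
    """Pure element-wise predicate selecting the wet-lab validation subset:
    motif type (trinucleotide by default), amplicon size and primer Tm."""

    def keep(cand: MarkerCandidate) -> bool:
        if cand.primers is None:
            return False
        if trinucleotide_only and cand.locus.ssr_type != "tri":
            return False
        lo, hi = product_range
        if not (lo <= cand.primers.product_size <= hi):
            return False
        tlo, thi = tm_range
        return (
            tlo <= cand.primers.tm_forward <= thi
            and tlo <= cand.primers.tm_reverse <= thi
        )

    return [replace_flags(c, validation_panel=True) for c in candidates if keep(c)]


def assign_marker_ids(
    candidates: Sequence[MarkerCandidate], prefix: str = "Acro"
) -> list[MarkerCandidate]:
    """Assign ids by genomic order (chromosome, start), zero-padded."""
    ordered = sorted(candidates, key=lambda c: (c.chromosome, c.start))
    width = max(2, len(str(len(ordered))))
    return [
        replace_flags(c, marker_id=f"{prefix}{i + 1:0{width}d}")
        for i, c in enumerate(ordered)
    ]


def design_panel(
    chromosomes: dict[str, str],
    exon_models: Sequence[ExonModel],
    loci: Sequence[SSRLocus],
    constraints: PrimerConstraints | None = None,
    min_spacing: int = 1_000_000,
    flank: int = 600,
    id_prefix: str = "Acro",
    source_individual: str = "i1",
) -> list[MarkerCandidate]:
    """End-to-end design: primer scan, exon filter, dedup, spacing, ids.

    ``loci`` carry genomic placements (sequence_id = chromosome). Loci with
    no qualifying primer pair or whose best amplicon crosses an exon boundary
    are dropped. The exon filter runs before spacing.
    """
    constraints = constraints or PrimerConstraints()
    models_by_chrom: dict[str, list[ExonModel]] = {}
    for model in exon_models:
        models_by_chrom.setdefault(model.chromosome, []).append(model)

    candidates: list[MarkerCandidate] = []
    for i, locus in enumerate(loci):
        chrom = locus.sequence_id
        seq = chromosomes[chrom]
        lo = max(0, locus.start - flank)
        hi = min(len(seq), locus.end + flank)
        template = seq[lo:hi]
        local = replace(
            locus, start=locus.start - lo, end=locus.end - lo, sequence_id=chrom
        )
        pairs = scan_primer_candidates(template, local, constraints)
        best: PrimerPair | None = None
        amplicon: tuple[int, int] | None = None
        for pair in pairs:
            a = (lo + pair.forward_start, lo + pair.reverse_start + len(pair.reverse_seq))
            if any(
                amplicon_within_single_exon(a, m)
                for m in models_by_chrom.get(chrom, [])
            ):
                best, amplicon = pair, a
                break
        if best is None or amplicon is None:
            continue
        candidates.append(
            MarkerCandidate(
                marker_id=f"cand{i:05d}",
                locus=locus,
                chromosome=chrom,
                start=amplicon[0],
                end=amplicon[1],
                primers=best,
                source_individuals=frozenset({source_individual}),
                in_exon=True,
            )
        )
    unique = deduplicate_loci(candidates)
    spaced = enforce_min_spacing(unique, min_spacing)
    return assign_marker_ids(spaced, prefix=id_prefix)
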