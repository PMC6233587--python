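"""Perfect and compound microsatellite (SSR) detection in nucleotide sequences.

Perfect SSRs are uninterrupted tandem repeats of a primitive 1-6 bp motif.
Detection follows the MISA-style convention used for EST-SSR mining in
transcriptome assemblies: per motif length a minimum repeat number
(defaults 10, 6, 5, 5, 5, 5 for mono- through hexanucleotides), and two or
more tracts separated by at most ``max_gap`` bases (default 100) are merged
into a single *compound* SSR.

Coordinates are 0-based half-open throughout; only whole motif copies count
toward ``n_repeats`` (a trailing partial copy is not part of the tract).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SSRLocus",
    "MiningThresholds",
    "SSRSummary",
    "ContractError",
    "InputError",
    "find_perfect_ssrs",
    "merge_compound",
    "canonical_motif",
    "is_primitive",
    "reverse_complement",
    "tissue_exclusivity_tally",
    "summarize_loci",
    "mine_sequence",
    "TISSUE_CATEGORIES",
]

_SSR_TYPES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TISSUE_CATEGORIES = (
    "vegetative",
    "flower",
    "fruit",
    "vegetative/flower",
    "vegetative/fruit",
    "flower/fruit",
    "vegetative/flower/fruit",
)


class ContractError(ValueError):
    """An operation was called with arguments violating its preconditions."""


class InputError(ValueError):
    """Malformed user input (bad characters, bad file records)."""


@dataclass(frozen=True)
class SSRLocus:
    """A detected repeat tract on one sequence.

    ``start``/``end`` are 0-based half-open offsets. For perfect loci
    ``end - start == len(motif) * n_repeats`` and ``motif`` is primitive.
    Compound loci carry their constituents in ``members`` (ordered,
    non-overlapping) with ``motif == ""`` and ``n_repeats == 0``.
    """

    sequence_id: str
    start: int
    end: int
    motif: str
    n_repeats: int
    ssr_type: str
    tract: str = ""
    members: tuple["SSRLocus", ...] = ()

    def __post_init__(self) -> None:
        if self.ssr_type == "compound":
            if not self.members:
                raise ContractError("compound locus requires members")
        else:
            if self.members:
                raise ContractError("non-compound locus must not have members")
            if self.end - self.start != len(self.motif) * self.n_repeats:
                raise ContractError(
                    f"span {self.start}-{self.end} inconsistent with "
                    f"{self.n_repeats} x {self.motif!r}"
                )
            if not is_primitive(self.motif):
                raise ContractError(f"motif {self.motif!r} is not primitive")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        """Human-readable name, e.g. ``(AT)6`` or ``(GA)5+(TTG)5``."""
        if self.ssr_type == "compound":
            return "+".join(f"({m.motif}){m.n_repeats}" for m in self.members)
        return f"({self.motif}){self.n_repeats}"


@dataclass(frozen=True)
class MiningThresholds:
    """Minimum repeat number per motif length, and compound merge distance."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    )
    max_gap: int = 100

    def __post_init__(self) -> None:
        if set(self.min_repeats) != set(range(1, 7)):
            raise ContractError("min_repeats must cover motif lengths 1-6")
        if any(v < 2 for v in self.min_repeats.values()):
            raise ContractError("all min_repeats must be >= 2")
        if self.max_gap < 0:
            raise ContractError("max_gap must be >= 0")


@dataclass
class SSRSummary:
    """Tallies of a mined locus set: by type, repeat number, motif and tissue.

    ``by_raw_motif`` counts the reported motif phases as-is; ``by_canonical_motif``
    groups rotations and reverse complements (CT and AG fall in one class).
    Compound loci contribute to ``by_type`` and the tissue tallies but carry no
    single repeat number or motif, so ``by_n_repeats`` sums to
    ``total - by_type["compound"]``.
    """

    total: int
    by_type: dict[str, int]
    by_n_repeats: dict[int, int]
    by_raw_motif: dict[str, int]
    by_canonical_motif: dict[str, int]
    by_tissue_category: dict[str, int] = field(default_factory=dict)


def _validate_sequence(seq: str) -> str:
    up = seq.upper()
    for off, ch in enumerate(up):
        if ch not in "ACGTN":
            raise InputError(f"non-nucleotide character {ch!r} at offset {off}")
    return up


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a whole-number repetition of a shorter string."""
    n = len(motif)
    if n == 0:
        return False
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Canonical class label of a primitive motif.

    The label is the lexicographically smallest string among all cyclic
    rotations of the motif and of its reverse complement, so every member of
    a motif class (e.g. GAG/AGG/GGA/CTC/CCT/TCC) maps to the same label.
    """
    motif = motif.upper()
    if not (1 <= len(motif) <= 6) or not is_primitive(motif):
        raise ContractError(f"motif {motif!r} must be primitive, length 1-6")
    rc = reverse_complement(motif)
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    rotations += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rotations)


def find_perfect_ssrs(
    seq: str,
    thresholds: MiningThresholds | None = None,
    sequence_id: str = "seq",
) -> list[SSRLocus]:
    """Detect every maximal perfect SSR meeting the per-motif-length threshold.

    A tract is a maximal run with period L (1-6) whose starting L-mer is a
    primitive motif; ``n_repeats`` counts whole motif copies from the run
    start (leftmost phase). N bases terminate runs and never match. Loci are
    returned sorted by start, then by motif length.
    """
    thresholds = thresholds or MiningThresholds()
    seq = _validate_sequence(seq)
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = arr != ord("N")
    loci: list[SSRLocus] = []
    for length in range(1, 7):
        min_rep = thresholds.min_repeats[length]
        if n < length * min_rep:
            continue
        # eq[j] true iff seq[j] == seq[j+L] and both are real bases
        eq = (arr[length:] == arr[:-length]) & valid[length:] & valid[:-length]
        if not eq.any():
            continue
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.nonzero(diff == 1)[0]
        run_ends = np.nonzero(diff == -1)[0]  # exclusive, in eq coordinates
        for s, e in zip(run_starts, run_ends):
            region_len = (e - s) + length  # seq[s : s + region_len] has period L
            k = region_len // length
            if k < min_rep:
                continue
            motif = seq[s : s + length]
            if not is_primitive(motif):
                continue  # reported at its primitive period instead
            end = s + k * length
            loci.append(
                SSRLocus(
                    sequence_id=sequence_id,
                    start=int(s),
                    end=int(end),
                    motif=motif,
                    n_repeats=int(k),
                    ssr_type=_SSR_TYPES[length],
                    tract=seq[s:end],
                )
            )
    loci.sort(key=lambda l: (l.start, len(l.motif)))
    return loci


def merge_compound(
    loci: Sequence[SSRLocus],
    max_gap: int = 100,
    seq: str | None = None,
    on_overlap: str = "error",
) -> list[SSRLocus]:
    """Merge runs of >=2 loci whose successive gaps are <= ``max_gap`` into
    compound loci; isolated loci pass through unchanged.

    Inputs must be sorted by start, non-compound, and on one sequence.
    Overlapping inputs raise :class:`ContractError` unless
    ``on_overlap="merge"``, in which case overlapping tracts (different
    motifs interleaving) join the same compound cluster.
    """
    loci = list(loci)
    if not loci:
        return []
    seq_ids = {l.sequence_id for l in loci}
    if len(seq_ids) > 1:
        raise ContractError(f"loci span multiple sequences: {sorted(seq_ids)}")
    for prev, cur in itertools.pairwise(loci):
        if cur.ssr_type == "compound" or prev.ssr_type == "compound":
            raise ContractError("inputs must be non-compound loci")
        if cur.start < prev.start:
            raise ContractError("loci must be sorted by start")
        if cur.start < prev.end and on_overlap != "merge":
            raise ContractError(
                f"overlapping loci at {prev.start}-{prev.end} / {cur.start}-{cur.end}"
            )

    groups: list[list[SSRLocus]] = [[loci[0]]]
    for cur in loci[1:]:
        gap = cur.start - groups[-1][-1].end
        if gap <= max_gap:
            groups[-1].append(cur)
        else:
            groups.append([cur])

    out: list[SSRLocus] = []
    for group in groups:
        if len(group) == 1:
            out.append(group[0])
            continue
        start, end = group[0].start, max(l.end for l in group)
        out.append(
            SSRLocus(
                sequence_id=group[0].sequence_id,
                start=start,
                end=end,
                motif="",
                n_repeats=0,
                ssr_type="compound",
                tract=seq[start:end] if seq is not None else "",
                members=tuple(group),
            )
        )
    return out


def mine_sequence(
    seq: str,
    thresholds: MiningThresholds | None = None,
    sequence_id: str = "seq",
) -> list[SSRLocus]:
    """Full per-sequence pipeline: perfect-SSR scan followed by compound merge."""
    thresholds = thresholds or MiningThresholds()
    seq = _validate_sequence(seq)
    perfect = find_perfect_ssrs(seq, thresholds, sequence_id)
    return merge_compound(perfect, thresholds.max_gap, seq=seq, on_overlap="merge")


def tissue_exclusivity_tally(
    locus_ids_by_tissue_class: Mapping[str, set],
) -> dict[str, int]:
    """Partition the union of the three tissue locus-id sets into the seven
    membership categories (each tissue alone, each pair, all three) and count.

    Keys must be exactly {"vegetative", "flower", "fruit"}. The seven counts
    sum to the size of the union.
    """
    expected = {"vegetative", "flower", "fruit"}
    if set(locus_ids_by_tissue_class) != expected:
        raise ContractError(f"tissue classes must be exactly {sorted(expected)}")
    veg = set(locus_ids_by_tissue_class["vegetative"])
    flo = set(locus_ids_by_tissue_class["flower"])
    fru = set(locus_ids_by_tissue_class["fruit"])
    counts = dict.fromkeys(TISSUE_CATEGORIES, 0)
    for locus in veg | flo | fru:
        members = (locus in veg, locus in flo, locus in fru)
        key = "/".join(
            name for name, inside in zip(("vegetative", "flower", "fruit"), members) if inside
        )
        counts[key] += 1
    return counts


def summarize_loci(
    loci: Iterable[SSRLocus],
    locus_ids_by_tissue_class: Mapping[str, set] | None = None,
) -> SSRSummary:
    """Tally a locus set by SSR type, repeat number, raw motif and canonical
    motif class; optionally add the tissue-exclusivity partition."""
    by_type: dict[str, int] = {}
    by_reps: dict[int, int] = {}
    by_raw: dict[str, int] = {}
    by_canon: dict[str, int] = {}
    total = 0
    for locus in loci:
        total += 1
        by_type[locus.ssr_type] = by_type.get(locus.ssr_type, 0) + 1
        if locus.ssr_type == "compound":
            continue
        by_reps[locus.n_repeats] = by_reps.get(locus.n_repeats, 0) + 1
        by_raw[locus.motif] = by_raw.get(locus.motif, 0) + 1
        canon = canonical_motif(locus.motif)
        by_canon[canon] = by_canon.get(canon, 0) + 1
    tissue = (
        tissue_exclusivity_tally(locus_ids_by_tissue_class)
        if locus_ids_by_tissue_class is not None
        else {}
    )
    return SSRSummary(
        total=total,
        by_type=by_type,
        by_n_repeats=dict(sorted(by_reps.items())),
        by_raw_motif=dict(sorted(by_raw.items())),
        by_canonical_motif=dict(sorted(by_canon.items())),
        by_tissue_category=tissue,
    )
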