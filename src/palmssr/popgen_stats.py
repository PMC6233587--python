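"""Per-locus codominant marker statistics and transferability rates.

Given diploid allele-size genotypes (GenAlEx-style), computes the classic
marker-informativeness panel: observed allele count Na, effective alleles
Ne = 1/Σp², expected heterozygosity He = 1 − Σp², observed heterozygosity
Ho, Shannon's information index I = −Σ p ln p, Botstein's polymorphism
information content PIC = 1 − Σp² − Σ_{i<j} 2 p_i² p_j², and the probability
of identity PI = Σp⁴ + Σ_{i<j} (2 p_i p_j)².

PIC categories follow Botstein: high ≥ 0.50, medium 0.25–0.50, low < 0.25,
null for monomorphic loci. Private alleles are alleles segregating in
exactly one group. Transfer rates summarise binary cross-species
amplification matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repeat_mining import ContractError

__all__ = [
    "GenotypeTable",
    "FreqRecord",
    "AlleleFrequencies",
    "LocusStats",
    "TransferMatrix",
    "TransferRate",
    "PrivateAllele",
    "allele_frequencies",
    "locus_stats",
    "classify_pic",
    "private_alleles",
    "transfer_rates",
    "round_half_up",
]

MISSING = 0  # allele-size code for a missing call


@dataclass
class GenotypeTable:
    """Samples × loci diploid allele-size calls with group labels.

    ``calls`` has shape (n_samples, n_loci, 2) with positive integer allele
    sizes in bp; 0 encodes missing. A call is treated as missing when either
    allele is 0.
    """

    sample_ids: list[str]
    groups: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.sample_ids), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ContractError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2)"
            )
        if len(self.groups) != n:
            raise ContractError("one group label per sample required")
        if any(not g for g in self.groups):
            raise ContractError("group labels must be non-empty")
        if (self.calls < 0).any():
            raise ContractError("allele sizes must be positive (0 = missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """(n_samples, n_loci) boolean; True where the call is missing."""
        return (self.calls == MISSING).any(axis=2)

    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g)
        return list(seen)


@dataclass
class FreqRecord:
    """Allele frequencies at one locus within one unit (population or all)."""

    freqs: dict[int, float]
    n_typed: int

    @property
    def defined(self) -> bool:
        return self.n_typed > 0


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequencies, overall and optionally per group."""

    loci: list[str]
    overall: dict[str, FreqRecord]
    by_group: dict[str, dict[str, FreqRecord]] = field(default_factory=dict)

    def undefined_loci(self) -> list[str]:
        return [l for l in self.loci if not self.overall[l].defined]


@dataclass
class LocusStats:
    locus: str
    na: int
    ne: float
    he: float
    ho: float
    shannon: float
    pic: float
    pi: float
    category: str
    n_typed: int


@dataclass
class TransferMatrix:
    """Species × markers binary amplification outcomes (NaN = missing)."""

    data: pd.DataFrame  # index: species, columns: marker ids, values 0/1/NaN

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise ContractError("transfer matrix needs at least one marker")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class TransferRate:
    species: str
    amplified: int
    total: int
    percent_1dp: float
    percent_int: int


@dataclass(frozen=True)
class PrivateAllele:
    locus: str
    allele: int
    group: str
    frequency: float


def _freqs_for(calls: np.ndarray) -> FreqRecord:
    """calls: (n, 2) integer array for one locus; 0 = missing."""
    typed = calls[(calls != MISSING).all(axis=1)]
    n_typed = typed.shape[0]
    if n_typed == 0:
        return FreqRecord(freqs={}, n_typed=0)
    alleles, counts = np.unique(typed.ravel(), return_counts=True)
    denom = 2.0 * n_typed
    return FreqRecord(
        freqs={int(a): c / denom for a, c in zip(alleles, counts)},
        n_typed=n_typed,
    )


def allele_frequencies(table: GenotypeTable, by_group: bool = False) -> AlleleFrequencies:
    """Estimate p_i = allele count / (2 × n_typed) per locus; missing calls
    are excluded from the denominator (listwise per locus).

    Loci with no typed individual get an empty, flagged-undefined record and
    must be excluded from downstream statistics.
    """
    if table.n_samples == 0 or table.n_loci == 0:
        raise ContractError("genotype table is empty")
    overall = {
        locus: _freqs_for(table.calls[:, j, :]) for j, locus in enumerate(table.loci)
    }
    by_grp: dict[str, dict[str, FreqRecord]] = {}
    if by_group:
        groups = np.asarray(table.groups)
        for g in table.group_names():
            idx = np.nonzero(groups == g)[0]
            by_grp[g] = {
                locus: _freqs_for(table.calls[idx, j, :])
                for j, locus in enumerate(table.loci)
            }
    return AlleleFrequencies(loci=list(table.loci), overall=overall, by_group=by_grp)


def classify_pic(pic: float) -> str:
    """Botstein informativeness category: high ≥ 0.50 > medium ≥ 0.25 > low > null (0)."""
    if not (0.0 <= pic < 1.0):
        raise ContractError(f"PIC must lie in [0, 1), got {pic}")
    if pic >= 0.50:
        return "high"
    if pic >= 0.25:
        return "medium"
    if pic > 0.0:
        return "low"
    return "null"


def _stats_from_freqs(p: np.ndarray) -> tuple[float, float, float, float, float]:
    """(Ne, He, I, PIC, PI) from a frequency vector."""
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    ne = 1.0 / s2
    he = 1.0 - s2
    shannon = float(-np.sum(p * np.log(p))) or 0.0  # avoid -0.0 at monomorphism
    # Σ_{i<j} 2 p_i² p_j² = s2² − s4 ; Σ_{i<j} (2 p_i p_j)² = 2 (s2² − s4)
    pic = 1.0 - s2 - (s2 * s2 - s4)
    pi = 2.0 * s2 * s2 - s4
    return ne, he, shannon, pic, pi


def locus_stats(
    freqs: AlleleFrequencies,
    table: GenotypeTable,
    unbiased_he: bool = False,
) -> dict[str, LocusStats]:
    """Full per-locus statistics panel.

    Ho comes from the raw calls (fraction heterozygous among typed); all
    other quantities from the overall allele frequencies. ``unbiased_he``
    applies the 2n/(2n−1) small-sample correction to He (off by default,
    matching the plain 1 − Σp² definition). Undefined loci are skipped.
    """
    out: dict[str, LocusStats] = {}
    for j, locus in enumerate(table.loci):
        rec = freqs.overall[locus]
        if not rec.defined:
            continue
        p = np.array(sorted(rec.freqs.values(), reverse=True), dtype=float)
        ne, he, shannon, pic, pi = _stats_from_freqs(p)
        if unbiased_he:
            he *= (2 * rec.n_typed) / (2 * rec.n_typed - 1)
        calls = table.calls[:, j, :]
        typed = calls[(calls != MISSING).all(axis=1)]
        ho = float(np.mean(typed[:, 0] != typed[:, 1])) if typed.size else 0.0
        out[locus] = LocusStats(
            locus=locus,
            na=len(rec.freqs),
            ne=ne,
            he=he,
            ho=ho,
            shannon=shannon,
            pic=pic,
            pi=pi,
            category=classify_pic(min(pic, math.nextafter(1.0, 0.0))),
            n_typed=rec.n_typed,
        )
    return out


def private_alleles(freqs: AlleleFrequencies) -> list[PrivateAllele]:
    """Alleles whose frequency is positive in exactly one group.

    Requires per-group frequencies over at least two groups; each private
    allele is reported with its frequency within the owning group. The
    result is invariant to group relabelling (up to the labels themselves).
    """
    if len(freqs.by_group) < 2:
        raise ContractError("private alleles require >= 2 groups")
    out: list[PrivateAllele] = []
    for locus in freqs.loci:
        support: dict[int, list[str]] = {}
        for group, per_locus in freqs.by_group.items():
            rec = per_locus[locus]
            for allele, p in rec.freqs.items():
                if p > 0:
                    support.setdefault(allele, []).append(group)
        for allele in sorted(support):
            owners = support[allele]
            if len(owners) == 1:
                g = owners[0]
                out.append(
                    PrivateAllele(
                        locus=locus,
                        allele=allele,
                        group=g,
                        frequency=freqs.by_group[g][locus].freqs[allele],
                    )
                )
    return out


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero upward)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def transfer_rates(matrix: TransferMatrix) -> dict[str, TransferRate]:
    """Per-species amplification count and percentage over the fixed marker
    universe (columns); missing entries count as not amplified.

    Both a 1-decimal and an integer-rounded percentage are reported, since
    published tables mix the two conventions.
    """
    total = len(matrix.markers)
    if total == 0:
        raise ContractError("empty marker set")
    out: dict[str, TransferRate] = {}
    for species in matrix.species:
        row = matrix.data.loc[species]
        amplified = int((row == 1).sum())
        pct = 100.0 * amplified / total
        out[species] = TransferRate(
            species=species,
            amplified=amplified,
            total=total,
            percent_1dp=round_half_up(pct, 1),
            percent_int=int(round_half_up(pct, 0)),
        )
    return out
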