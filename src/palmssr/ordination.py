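"""Nei (1972) standard genetic distance and principal coordinate analysis.

For two units (populations, or individuals treated as populations of one)
with allele frequencies p, q over shared loci:

    J_ab = mean over loci of Σ_i p_i q_i
    J_a  = mean over loci of Σ_i p_i²          (J_b analogous)
    I    = J_ab / sqrt(J_a · J_b)              (normalized gene identity)
    D    = −ln I                               (Nei standard distance)

Loci undefined in either unit are dropped pairwise; I = 0 (no shared allele
at any locus) yields D = +inf with a warning. PCoA is classical (Gower)
metric scaling: double-centre −½ D², eigendecompose, scale eigenvectors by
the square roots of the positive eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .popgen_stats import AlleleFrequencies, FreqRecord, GenotypeTable, MISSING
from .repeat_mining import ContractError

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "nei_distance",
    "unit_frequencies",
    "nei_distance_matrix",
    "cap_infinite",
    "pcoa",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ContractError("distance matrix must be square over ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ContractError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ContractError("distance matrix diagonal must be zero")
        if (self.matrix[np.isfinite(self.matrix)] < 0).any():
            raise ContractError("distances must be non-negative")


@dataclass
class PCoAResult:
    """Classical-scaling ordination of a distance matrix.

    ``coordinates`` holds one row per unit over the returned axes (ordered by
    decreasing eigenvalue); ``percent_variance`` is each returned axis's
    share of the sum of *positive* eigenvalues; ``eigenvalues`` stores the
    full spectrum (negative values included, reported but never used in the
    variance denominator).
    """

    ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    percent_variance: np.ndarray


def nei_distance(
    freqs_a: dict[str, FreqRecord], freqs_b: dict[str, FreqRecord]
) -> float:
    """Nei (1972) standard genetic distance between two frequency profiles.

    ``freqs_a``/``freqs_b`` map locus → FreqRecord; loci undefined in either
    profile are dropped pairwise. Raises if no locus remains.
    """
    shared = [
        l
        for l in freqs_a
        if l in freqs_b and freqs_a[l].defined and freqs_b[l].defined
    ]
    if not shared:
        raise ContractError("no shared locus with defined frequencies")
    jab = ja = jb = 0.0
    for locus in shared:
        pa, pb = freqs_a[locus].freqs, freqs_b[locus].freqs
        jab += sum(p * pb.get(a, 0.0) for a, p in pa.items())
        ja += sum(p * p for p in pa.values())
        jb += sum(q * q for q in pb.values())
    n = len(shared)
    jab, ja, jb = jab / n, ja / n, jb / n
    if jab == 0.0:
        warnings.warn("no shared alleles at any locus; Nei distance is infinite")
        return float("inf")
    identity = jab / np.sqrt(ja * jb)
    # Cauchy-Schwarz bounds identity <= 1; clamp float fuzz so D >= 0 exactly
    identity = min(identity, 1.0)
    return float(-np.log(identity))


def unit_frequencies(
    table: GenotypeTable, unit: str = "individual"
) -> dict[str, dict[str, FreqRecord]]:
    """Frequency profiles per unit.

    ``unit="individual"`` treats each sample as a population of one (allele
    frequencies 0, 0.5 or 1 per locus — the individual-by-distance
    convention); ``unit="group"`` pools samples by group label.
    """
    from .popgen_stats import allele_frequencies

    if unit == "group":
        freqs = allele_frequencies(table, by_group=True)
        return {g: freqs.by_group[g] for g in freqs.by_group}
    if unit != "individual":
        raise ContractError("unit must be 'individual' or 'group'")
    out: dict[str, dict[str, FreqRecord]] = {}
    for i, sample in enumerate(table.sample_ids):
        per_locus: dict[str, FreqRecord] = {}
        for j, locus in enumerate(table.loci):
            a, b = table.calls[i, j]
            if a == MISSING or b == MISSING:
                per_locus[locus] = FreqRecord(freqs={}, n_typed=0)
            elif a == b:
                per_locus[locus] = FreqRecord(freqs={int(a): 1.0}, n_typed=1)
            else:
                per_locus[locus] = FreqRecord(
                    freqs={int(a): 0.5, int(b): 0.5}, n_typed=1
                )
        out[sample] = per_locus
    return out


def nei_distance_matrix(
    table: GenotypeTable, unit: str = "individual"
) -> DistanceMatrix:
    """Pairwise Nei distances between all units of a genotype table."""
    profiles = unit_frequencies(table, unit)
    ids = list(profiles)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = nei_distance(profiles[ids[i]], profiles[ids[j]])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids=ids, matrix=mat)


def cap_infinite(dist: DistanceMatrix) -> DistanceMatrix:
    """Replace infinite entries with (max finite entry + 1), warning once."""
    mat = dist.matrix.copy()
    inf_mask = np.isinf(mat)
    if inf_mask.any():
        cap = float(mat[~inf_mask].max()) + 1.0
        warnings.warn(
            f"capping {int(inf_mask.sum())} infinite distance entries at {cap}"
        )
        mat[inf_mask] = cap
    return DistanceMatrix(ids=list(dist.ids), matrix=mat)


def pcoa(dist: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical metric scaling of a distance matrix.

    Double-centres −½ D², eigendecomposes, and returns coordinates on the
    first ``n_axes`` positive axes (fewer if the positive spectrum is
    smaller). Eigenvector signs are fixed so each axis's first nonzero
    coordinate is positive. Requires >= 3 units and finite distances
    (cap infinities first with :func:`cap_infinite`).
    """
    n = len(dist.ids)
    if n < 3:
        raise ContractError("PCoA requires at least 3 units")
    if not np.isfinite(dist.matrix).all():
        raise ContractError("distances must be finite; use cap_infinite first")
    d2 = dist.matrix**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    b = 0.5 * (b + b.T)  # symmetrize against float drift
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = float(np.abs(eigvals).max()) or 1.0
    positive = eigvals > 1e-12 * scale
    pos_vals = eigvals[positive]
    k = min(n_axes, pos_vals.size)
    coords = eigvecs[:, positive][:, :k] * np.sqrt(pos_vals[:k])
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    total_pos = float(pos_vals.sum())
    percent = 100.0 * pos_vals[:k] / total_pos if total_pos > 0 else np.zeros(k)
    return PCoAResult(
        ids=list(dist.ids),
        coordinates=coords,
        eigenvalues=eigvals,
        percent_variance=percent,
    )
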