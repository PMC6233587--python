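"""Synthetic inputs with known ground truth for every pipeline stage.

The generators stand in for the study system this toolkit targets — a palm
transcriptome/genotyping survey whose raw sequence data are not public:

* ``generate_genome`` — chromosomes of random background sequence with SSR
  tracts of known motif/repeat number planted at known positions, exon
  models around the exonic ones, and a truth table. The background is
  rejection-sampled so it contains no above-threshold SSR other than the
  planted ones, making the truth unambiguous.
* ``simulate_genotypes`` — diploid allele-size genotypes for grouped samples
  under the Balding–Nichols model: ancestral frequencies ~ Dirichlet(α),
  group frequencies ~ Dirichlet(p_anc (1−F)/F), Hardy–Weinberg sampling
  within groups, sizes = base + step × allele index, missing-at-random
  masking. Defaults emulate a 17-plant, 6-location validation design with
  145 loci (allele counts cycling 1–8, mean ≈ 3.3).
* ``simulate_transfer`` — independent Bernoulli amplification per
  species × marker; defaults emulate a six-species palm transfer panel.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .marker_design import ExonModel
from .popgen_stats import GenotypeTable, TransferMatrix
from .repeat_mining import (
    ContractError,
    MiningThresholds,
    SSRLocus,
    find_perfect_ssrs,
    is_primitive,
)

__all__ = [
    "ConfigError",
    "PlantedSSR",
    "GenomeConfig",
    "LocusPlan",
    "GenotypeConfig",
    "TransferConfig",
    "SimulationConfig",
    "SyntheticGenome",
    "generate_genome",
    "simulate_genotypes",
    "simulate_transfer",
    "default_genotype_config",
    "default_transfer_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    n_repeats: int
    exonic: bool = True
    chromosome: str | None = None  # None: assigned round-robin
    position: int | None = None  # None: evenly slotted with jitter

    def __post_init__(self) -> None:
        if not is_primitive(self.motif.upper()) or not (1 <= len(self.motif) <= 6):
            raise ConfigError(f"motif {self.motif!r} must be primitive, length 1-6")
        if self.n_repeats < 2:
            raise ConfigError("n_repeats must be >= 2")

    @property
    def tract(self) -> str:
        return self.motif.upper() * self.n_repeats


@dataclass
class GenomeConfig:
    n_chromosomes: int = 2
    chromosome_length: int = 50_000
    ssr_plan: list[PlantedSSR] = field(default_factory=list)
    exon_flank: tuple[int, int] = (200, 400)  # exon extends this far past a tract
    intron_length: int = 300
    second_exon_length: int = 200
    thresholds: MiningThresholds = field(default_factory=MiningThresholds)
    max_scrub_rounds: int = 1000


@dataclass(frozen=True)
class LocusPlan:
    """One simulated marker locus.

    ``divergence`` is the Balding–Nichols F (0 = panmixia); allele sizes are
    ``base_size + step * i`` for allele index i (step = motif length in bp).
    """

    n_alleles: int
    base_size: int = 150
    step: int = 3
    alpha: float = 1.0
    divergence: float = 0.15

    def __post_init__(self) -> None:
        if self.n_alleles < 1:
            raise ConfigError("n_alleles must be >= 1")
        if not (0.0 <= self.divergence < 1.0):
            raise ConfigError("divergence F must lie in [0, 1)")
        if self.base_size <= 0 or self.step <= 0:
            raise ConfigError("base_size and step must be positive")


@dataclass
class GenotypeConfig:
    group_sizes: dict[str, int]
    loci: list[LocusPlan]
    missing_rate: float = 0.03

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if not self.group_sizes or not self.loci:
            raise ConfigError("need at least one group and one locus")


@dataclass
class TransferConfig:
    amplification_probability: dict[str, float]
    n_markers: int = 145
    marker_prefix: str = "Acro"

    def __post_init__(self) -> None:
        for sp, p in self.amplification_probability.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability for {sp} outside [0, 1]")
        if self.n_markers < 1:
            raise ConfigError("n_markers must be >= 1")


@dataclass
class SimulationConfig:
    seed: int
    genome: GenomeConfig | None = None
    genotypes: GenotypeConfig | None = None
    transfer: TransferConfig | None = None


@dataclass
class SyntheticGenome:
    chromosomes: dict[str, str]
    exon_models: list[ExonModel]
    truth: list[SSRLocus]  # planted tracts, exact coordinates
    truth_exonic: list[bool]


def default_genotype_config(
    n_loci: int = 145, divergence: float = 0.15, missing_rate: float = 0.03
) -> GenotypeConfig:
    """The default validation-study design: 17 samples in 6 geographic
    groups (3,3,3,3,3,2) and ``n_loci`` markers whose allele counts cycle
    through 1-8 (mean ≈ 3.3, with monomorphic loci included)."""
    cycle = [3, 5, 2, 4, 1, 3, 6, 2, 3, 4, 8, 2, 3, 5, 1, 4]
    loci = [
        LocusPlan(
            n_alleles=cycle[i % len(cycle)],
            base_size=100 + 10 * (i % 30),
            step=3,
            divergence=divergence,
        )
        for i in range(n_loci)
    ]
    groups = {
        "Rifaina": 3,
        "Jaguariuna": 3,
        "Itapira": 3,
        "SerraDaCanastra": 3,
        "Luz": 3,
        "Capitolio": 2,
    }
    return GenotypeConfig(group_sizes=groups, loci=loci, missing_rate=missing_rate)


def default_transfer_config() -> TransferConfig:
    """Six-species palm panel at the amplification rates observed in the
    motivating survey (145-marker universe)."""
    probs = {
        "Acrocomia_intumescens": 144 / 145,
        "Acrocomia_totai": 143 / 145,
        "Elaeis_guineensis": 117 / 145,
        "Bactris_gasipaes": 117 / 145,
        "Euterpe_edulis": 102 / 145,
        "Sabal_causiarum": 104 / 145,
    }
    return TransferConfig(amplification_probability=probs, n_markers=145)


def _random_background(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _assign_positions(cfg: GenomeConfig) -> list[tuple[str, int, PlantedSSR]]:
    """Resolve chromosome/position for every planted SSR; validate spacing."""
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    per_chrom: dict[str, list[PlantedSSR]] = {c: [] for c in chrom_names}
    for i, plant in enumerate(cfg.ssr_plan):
        chrom = plant.chromosome or chrom_names[i % cfg.n_chromosomes]
        if chrom not in per_chrom:
            raise ConfigError(f"unknown chromosome {chrom!r}")
        per_chrom[chrom].append(plant)

    margin = max(cfg.exon_flank) + cfg.intron_length + cfg.second_exon_length + 50
    min_sep = cfg.thresholds.max_gap + 1
    placed: list[tuple[str, int, PlantedSSR]] = []
    for chrom, plants in per_chrom.items():
        if not plants:
            continue
        explicit = [p for p in plants if p.position is not None]
        auto = [p for p in plants if p.position is None]
        slots: list[tuple[int, PlantedSSR]] = [(p.position, p) for p in explicit]  # type: ignore[misc]
        if auto:
            usable = cfg.chromosome_length - 2 * margin
            slot = usable // len(auto)
            for k, plant in enumerate(auto):
                pos = margin + k * slot + slot // 3
                slots.append((pos, plant))
        slots.sort(key=lambda t: t[0])
        prev_end = None
        for pos, plant in slots:
            end = pos + len(plant.tract)
            if pos < 0 or end > cfg.chromosome_length:
                raise ConfigError(
                    f"tract at {chrom}:{pos} does not fit the chromosome"
                )
            if prev_end is not None and pos - prev_end < min_sep:
                raise ConfigError(
                    f"planted tracts on {chrom} closer than max_gap+1 ({min_sep})"
                )
            prev_end = end
            placed.append((chrom, pos, plant))
    return placed


def _scrub_stray_ssrs(
    rng: np.random.Generator,
    arr: np.ndarray,
    planted: list[tuple[int, int]],
    cfg: GenomeConfig,
) -> np.ndarray:
    """Re-randomize background until the detectable SSR set equals the
    planted spans exactly.

    Any detected tract whose span is not a planted span (a stray background
    repeat, or a planted tract extended by lucky flanking bases) has the
    non-planted bases of its neighbourhood redrawn. Planted bases are never
    touched, so the loop converges unless a planted tract itself embeds a
    second above-threshold repeat, which is reported as an infeasible plan.
    """
    planted_set = set(planted)
    protected = np.zeros(arr.size, dtype=bool)
    for ps, pe in planted:
        protected[ps:pe] = True
    for _ in range(cfg.max_scrub_rounds):
        seq = arr.tobytes().decode("ascii")
        loci = find_perfect_ssrs(seq, cfg.thresholds)
        stray = [l for l in loci if (l.start, l.end) not in planted_set]
        if not stray:
            return arr
        progressed = False
        for l in stray:
            lo = max(0, l.start - 2)
            hi = min(arr.size, l.end + 2)
            free = np.nonzero(~protected[lo:hi])[0]
            if free.size:
                arr[lo + free] = _random_background(rng, free.size)
                progressed = True
        if not progressed:
            raise ConfigError(
                "planted tract embeds a second above-threshold SSR; "
                "choose a different motif/repeat plan"
            )
    raise ConfigError("could not scrub stray SSRs within max_scrub_rounds")


def generate_genome(
    cfg: GenomeConfig, rng: np.random.Generator
) -> SyntheticGenome:
    """Build chromosomes with planted SSR tracts, exon models and truth loci.

    Planted tracts are pairwise separated by more than ``max_gap`` so the
    miner's compound rule cannot merge distinct truths. Each exonic tract
    gets a two-exon transcript whose first exon contains the tract with
    clean primer-compatible flanks; non-exonic tracts get no enclosing exon.
    """
    placed = _assign_positions(cfg)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chromosomes: dict[str, str] = {}
    exon_models: list[ExonModel] = []
    truth: list[SSRLocus] = []
    truth_exonic: list[bool] = []

    for chrom in chrom_names:
        arr = _random_background(rng, cfg.chromosome_length)
        spans: list[tuple[int, int]] = []
        for c, pos, plant in placed:
            if c != chrom:
                continue
            tract = np.frombuffer(plant.tract.encode("ascii"), dtype=np.uint8)
            arr[pos : pos + tract.size] = tract
            spans.append((pos, pos + tract.size))
        arr = _scrub_stray_ssrs(rng, arr, spans, cfg)
        chromosomes[chrom] = arr.tobytes().decode("ascii")

    tcounter = 0
    for chrom, pos, plant in sorted(placed, key=lambda t: (t[0], t[1])):
        end = pos + len(plant.tract)
        truth.append(
            SSRLocus(
                sequence_id=chrom,
                start=pos,
                end=end,
                motif=plant.motif.upper(),
                n_repeats=plant.n_repeats,
                ssr_type={1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}[
                    len(plant.motif)
                ],
                tract=plant.tract,
            )
        )
        truth_exonic.append(plant.exonic)
        if plant.exonic:
            tcounter += 1
            lo_f, hi_f = cfg.exon_flank
            exon1 = (max(0, pos - hi_f), min(cfg.chromosome_length, end + hi_f))
            e2s = exon1[1] + cfg.intron_length
            exon2 = (e2s, min(cfg.chromosome_length, e2s + cfg.second_exon_length))
            exons = [exon1]
            if exon2[1] > exon2[0]:
                exons.append(exon2)
            exon_models.append(
                ExonModel(
                    chromosome=chrom,
                    transcript_id=f"t{tcounter:04d}",
                    strand="+",
                    exons=tuple(exons),
                )
            )
    return SyntheticGenome(
        chromosomes=chromosomes,
        exon_models=exon_models,
        truth=truth,
        truth_exonic=truth_exonic,
    )


def simulate_genotypes(
    cfg: GenotypeConfig, rng: np.random.Generator
) -> tuple[GenotypeTable, dict]:
    """Draw a structured diploid genotype table; returns (table, truth).

    truth = {"ancestral": {locus: {size: p}}, "group": {group: {locus: {size: p}}}}
    """
    loci_names = [f"L{j + 1:03d}" for j in range(len(cfg.loci))]
    sample_ids: list[str] = []
    groups: list[str] = []
    for g, size in cfg.group_sizes.items():
        for k in range(size):
            sample_ids.append(f"{g}_{k + 1}")
            groups.append(g)
    n = len(sample_ids)
    calls = np.zeros((n, len(cfg.loci), 2), dtype=np.int64)
    truth_anc: dict[str, dict[int, float]] = {}
    truth_grp: dict[str, dict[str, dict[int, float]]] = {
        g: {} for g in cfg.group_sizes
    }

    group_of = np.asarray(groups)
    for j, plan in enumerate(cfg.loci):
        k = plan.n_alleles
        sizes = plan.base_size + plan.step * np.arange(k)
        if k == 1:
            p_anc = np.array([1.0])
        else:
            p_anc = rng.dirichlet(np.full(k, plan.alpha))
            # keep every planned allele representable
            p_anc = np.clip(p_anc, 1e-3, None)
            p_anc /= p_anc.sum()
        truth_anc[loci_names[j]] = {int(s): float(p) for s, p in zip(sizes, p_anc)}
        for g in cfg.group_sizes:
            if plan.divergence == 0.0 or k == 1:
                p_g = p_anc.copy()
            else:
                f = plan.divergence
                p_g = rng.dirichlet(p_anc * (1.0 - f) / f)
            truth_grp[g][loci_names[j]] = {
                int(s): float(p) for s, p in zip(sizes, p_g)
            }
            idx = np.nonzero(group_of == g)[0]
            draws = rng.choice(k, size=(idx.size, 2), p=p_g)
            calls[idx, j, :] = sizes[draws]

    if cfg.missing_rate > 0:
        mask = rng.random((n, len(cfg.loci))) < cfg.missing_rate
        calls[mask] = 0

    table = GenotypeTable(
        sample_ids=sample_ids, groups=groups, loci=loci_names, calls=calls
    )
    return table, {"ancestral": truth_anc, "group": truth_grp}


def simulate_transfer(
    cfg: TransferConfig, rng: np.random.Generator
) -> tuple[TransferMatrix, dict[str, float]]:
    """Independent Bernoulli amplification per species × marker; returns the
    matrix and the truth probabilities."""
    markers = [f"{cfg.marker_prefix}{i + 1:03d}" for i in range(cfg.n_markers)]
    rows = {}
    species = list(cfg.amplification_probability)
    for sp in species:
        p = cfg.amplification_probability[sp]
        rows[sp] = (rng.random(cfg.n_markers) < p).astype(float)
    data = pd.DataFrame(rows, index=markers).T
    return TransferMatrix(data=data), dict(cfg.amplification_probability)
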