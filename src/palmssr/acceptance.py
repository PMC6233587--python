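"""Recompute the pipeline's headline quantities from scratch.

Two kinds of quantities are produced:

* arithmetic/classification results over the transcribed published tables
  (tissue-exclusivity tallies, motif-class percentages, amplification and
  transfer rates, private-allele structure) — each number is pushed through
  the corresponding pipeline operation, never copied;
* end-to-end measurements on synthetic data with known ground truth
  (planted-tract recovery, allele-frequency estimation error, PCoA group
  separation), seeded for reproducibility.

Percentages are reported on the 0-100 scale.
"""

from __future__ import annotations

import numpy as np

from .fixtures import (
    load_paper_fixtures,
    private_allele_summary,
    reconstruct_tissue_sets,
    reconstruct_transfer_matrix,
)
from .ordination import cap_infinite, nei_distance, nei_distance_matrix, pcoa
from .popgen_stats import (
    FreqRecord,
    allele_frequencies,
    round_half_up,
    transfer_rates,
)
from .repeat_mining import mine_sequence, tissue_exclusivity_tally
from .synthetic_data import (
    GenomeConfig,
    GenotypeConfig,
    LocusPlan,
    PlantedSSR,
    default_genotype_config,
    generate_genome,
    simulate_genotypes,
)

__all__ = ["run_acceptance"]


def _fixture_quantities() -> dict[str, dict[str, float]]:
    fixtures = load_paper_fixtures()
    out: dict[str, dict[str, float]] = {}

    # Tissue-exclusivity tally recomputed from reconstructed locus-id sets
    tissue_fixture = fixtures["table1_tissue"]
    sets = reconstruct_tissue_sets(tissue_fixture)
    tally = tissue_exclusivity_tally(sets)
    total = sum(tally.values())
    out["nonredundant_est_ssr_total"] = {"value": float(total), "n": total}
    out["tissue_triple_category_pct"] = {
        "value": round_half_up(100.0 * tally["vegetative/flower/fruit"] / total, 2),
        "n": total,
    }
    out["vegetative_exclusive_pct"] = {
        "value": round_half_up(100.0 * tally["vegetative"] / total, 2),
        "n": total,
    }

    # Motif-type percentages on the published 418-locus denominator
    motif_counts = {
        rec["motif_type"]: int(rec["count"])
        for rec in fixtures["table1_motifs"].records
    }
    for motif_type in ("tri", "di", "hexa", "compound"):
        out[f"{motif_type}nucleotide_motif_pct" if motif_type != "compound" else "compound_motif_pct"] = {
            "value": round_half_up(100.0 * motif_counts[motif_type] / total, 2),
            "n": total,
        }

    # Most frequent repeat number share
    rep_counts = {
        int(rec["n_repeats"]): int(rec["count"])
        for rec in fixtures["table1_repeats"].records
    }
    out["five_repeat_pct"] = {
        "value": round_half_up(100.0 * rep_counts[5] / total, 2),
        "n": total,
    }

    # Validation amplification success rate
    counts = {
        rec["key"]: int(rec["value"]) for rec in fixtures["results_counts"].records
    }
    out["validation_amplification_pct"] = {
        "value": round_half_up(
            100.0 * counts["amplified"] / counts["validation_panel"], 1
        ),
        "n": counts["validation_panel"],
    }

    # Cross-species transfer rates through the counting operation
    matrix = reconstruct_transfer_matrix(fixtures["transfer_counts"])
    rates = transfer_rates(matrix)
    for species, rate in rates.items():
        out[f"transfer_pct_{species.lower()}"] = {
            "value": rate.percent_1dp,
            "n": rate.total,
        }

    # Private-allele structure of the published table
    total_pa, n_markers, _, top_count = private_allele_summary(
        fixtures["table2_private_alleles"]
    )
    out["private_allele_total"] = {"value": float(total_pa), "n": total_pa}
    out["markers_with_private_alleles"] = {"value": float(n_markers), "n": total_pa}
    out["max_private_alleles_one_marker"] = {"value": float(top_count), "n": total_pa}
    return out


def _synthetic_quantities(seed: int) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    rng = np.random.default_rng(seed)

    # Planted-tract recovery: mine a synthetic genome against its truth
    plan = [
        PlantedSSR(motif=m, n_repeats=r)
        for m, r in [
            ("AGG", 6), ("AT", 8), ("GAG", 5), ("A", 12), ("TTG", 7),
            ("CCT", 5), ("ACGT", 5), ("GGA", 9), ("CAG", 5), ("AAG", 6),
        ]
    ]
    genome = generate_genome(
        GenomeConfig(n_chromosomes=2, chromosome_length=40_000, ssr_plan=plan), rng
    )
    mined = [
        locus
        for chrom, seq in genome.chromosomes.items()
        for locus in mine_sequence(seq, sequence_id=chrom)
    ]
    mined_spans = {(l.sequence_id, l.start, l.end) for l in mined}
    truth_spans = {(t.sequence_id, t.start, t.end) for t in genome.truth}
    recovered = len(mined_spans & truth_spans)
    out["planted_ssr_recovery_pct"] = {
        "value": round_half_up(100.0 * recovered / len(truth_spans), 1),
        "n": len(truth_spans),
    }

    # Allele-frequency estimation error at large n
    cfg = GenotypeConfig(
        group_sizes={"G1": 500},
        loci=[LocusPlan(n_alleles=4, divergence=0.0) for _ in range(30)],
        missing_rate=0.0,
    )
    table, truth = simulate_genotypes(cfg, rng)
    est = allele_frequencies(table)
    errs = []
    for locus in table.loci:
        for allele, p_true in truth["ancestral"][locus].items():
            errs.append(abs(est.overall[locus].freqs.get(allele, 0.0) - p_true))
    out["allele_frequency_mae_n500"] = {
        "value": round(float(np.mean(errs)), 5),
        "n": 500,
    }

    # Group separation in PCoA under the emulated 17-sample design
    table17, _ = simulate_genotypes(default_genotype_config(n_loci=60), rng)
    dist = cap_infinite(nei_distance_matrix(table17, unit="individual"))
    result = pcoa(dist, n_axes=2)
    groups = np.asarray(
        [g for g in table17.groups]
    )
    coords = result.coordinates
    within, between = [], []
    n = len(table17.sample_ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            (within if groups[i] == groups[j] else between).append(d)
    out["pcoa_within_between_ratio"] = {
        "value": round(float(np.mean(within) / np.mean(between)), 4),
        "n": n,
    }
    out["pcoa_axis1_pct_synthetic"] = {
        "value": round_half_up(float(result.percent_variance[0]), 2),
        "n": n,
    }

    # Worked two-locus Nei-distance example (closed form: ln(4/3)/2)
    fa = {
        "L1": FreqRecord(freqs={100: 1.0}, n_typed=10),
        "L2": FreqRecord(freqs={200: 1.0}, n_typed=10),
    }
    fb = {
        "L1": FreqRecord(freqs={100: 0.5, 103: 0.5}, n_typed=10),
        "L2": FreqRecord(freqs={200: 1.0}, n_typed=10),
    }
    out["nei_distance_two_locus_example"] = {
        "value": round(nei_distance(fa, fb), 4),
        "n": 2,
    }
    return out


def run_acceptance(seed: int) -> dict[str, dict[str, float]]:
    out = _fixture_quantities()
    out.update(_synthetic_quantities(seed))
    return out
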