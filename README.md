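# palmssr

EST-SSR marker development and codominant marker statistics for palm
transcriptomes, built around the macaúba palm (*Acrocomia aculeata*), a
South American oil palm of growing agronomic interest whose genomic
resources are still sparse. The package is aimed at plant geneticists who
need to go from assembled transcript sequences to a validated, non-redundant
microsatellite marker panel, and then to the standard diversity statistics
computed from the genotypes those markers produce.

## What it does

**SSR mining.** Perfect microsatellites are uninterrupted tandem repeats of
a primitive 1–6 bp motif. The miner reports every maximal tract meeting
MISA-style minimum repeat counts (10, 6, 5, 5, 5, 5 for mono- through
hexanucleotide motifs), and merges tracts separated by ≤ 100 bp into
compound SSRs. Motifs can be tallied raw or by canonical class (rotations ∪
reverse complements, e.g. CT/AG).

**Marker panel design.** Mined loci are flanked with primer pairs under
PRIMER3-like bounds (length 16–22 nt, GC 40–60 %, Tm 50–60 °C via the basic
formula Tm = 64.9 + 41·(GC − 16.4)/ℓ, product 100–500 bp), filtered to
amplicons inside a single exon, deduplicated across individuals by genomic
overlap, spaced ≥ 1 Mbp per chromosome, and filtered to a trinucleotide
validation panel.

**Marker statistics.** From diploid allele-size genotypes: Na, effective
alleles Ne = 1/Σp², He = 1 − Σp², Ho, Shannon's I = −Σp ln p, Botstein's
PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j² with the high/medium/low/null categories
(0.50 and 0.25 boundaries), probability of identity PI = Σp⁴ + Σ_{i<j}(2p_ip_j)²,
private alleles per group, and cross-species transfer rates.

**Ordination.** Nei (1972) standard genetic distance D = −ln I between
frequency profiles (individuals-as-units or pooled groups) and classical
PCoA of the resulting matrix.

**Synthetic data.** Ground-truthed generators for every input: genomes with
planted SSR tracts and exon models, Balding–Nichols structured genotype
tables (defaulting to a 17-sample, 6-location, 145-locus design), and
Bernoulli transfer matrices.

## Worked example

```python
import numpy as np
import palmssr as ps

seq = "GC" + "GAG" * 5 + "ACGGTCA" * 8 + "AT" * 6 + "ACGGTCA" * 18 + "TTG" * 7
for l in ps.mine_sequence(seq, sequence_id="transcript1"):
    print(l.sequence_id, l.start, l.end, l.ssr_type, l.label)

table, truth = ps.simulate_genotypes(ps.default_genotype_config(n_loci=5),
                                     np.random.default_rng(1))
freqs = ps.allele_frequencies(table, by_group=True)
for s in ps.locus_stats(freqs, table).values():
    print(f"{s.locus} Na={s.na} Ne={s.ne:.3f} He={s.he:.3f} Ho={s.ho:.3f} "
          f"I={s.shannon:.3f} PIC={s.pic:.3f} PI={s.pi:.3f} {s.category}")
print("private alleles:", len(ps.private_alleles(freqs)))
```

prints

```
transcript1 2 85 compound (GAG)5+(AT)6
transcript1 211 232 tri (TTG)7
L001 Na=2 Ne=1.192 He=0.161 Ho=0.176 I=0.298 PIC=0.148 PI=0.717 low
L002 Na=4 Ne=2.651 He=0.623 Ho=0.824 I=1.097 PIC=0.555 PI=0.211 high
L003 Na=2 Ne=1.192 He=0.161 Ho=0.176 I=0.298 PIC=0.148 PI=0.717 low
L004 Na=3 Ne=2.072 He=0.517 Ho=0.235 I=0.794 PIC=0.411 PI=0.340 medium
L005 Na=1 Ne=1.000 He=0.000 Ho=0.000 I=0.000 PIC=0.000 PI=1.000 null
private alleles: 2
```

The first two lines are mined loci: the GAG and AT tracts sit 56 bp apart,
so they merge into one compound SSR, while the TTG tract stands alone. The
statistics table shows one highly informative locus (PIC ≥ 0.50), one
monomorphic locus (PIC = 0, PI = 1), and two private alleles — alleles seen
in exactly one sampling location.

The same functionality is exposed as a CLI:

```
palmssr mine --fasta transcripts.fa --out-prefix mined
palmssr design --genome genome.fa --gff exons.gff3 --loci mined.bed --out-prefix panel
palmssr stats --genotypes genotypes.csv --by-group --out-prefix stats
palmssr dist --genotypes genotypes.csv --unit individual --out dist.tsv
palmssr pcoa --dist dist.tsv --axes 2 --out pcoa.tsv
palmssr transfer --matrix transfer.tsv --out rates.tsv
palmssr simulate genome --seed 1 --out-prefix sim
```

Genotype CSVs use a GenAlEx-style layout (header rows with locus/sample/
group counts, then one row per sample with two allele-size columns per
locus, 0 = missing); see `palmssr/io.py` for all format conventions.

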