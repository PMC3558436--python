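# nanochromkit

Analysis toolkit for genomes built from telomere-capped, gene-sized
"nanochromosomes", together with a synthetic genome/read simulator that
provides ground truth for every analysis stage.

The package covers the bespoke parts of a nanochromosome genome project:

| module | what it does |
| --- | --- |
| `nanochromkit.simgenome` | Simulates telomere-capped loci (truncated-lognormal lengths, mean ~3.2 kb), homozygous/heterozygous allele structure (~4% SNP heterozygosity), alternative-fragmentation isoforms, right-skewed relative copy number, PE reads (outer distance 362 ± 52 bp), an optional subtelomeric coverage gap, telomeric reads and a telomere-paired library — all with truth tables. |
| `nanochromkit.telomere` | Finds/masks `[AC]*CCCCAAAACCCC`-style telomeric repeats (configurable degeneracy), classifies contigs as 0/1/2/multi-telomere and computes assembly stats (N50, per-class counts). |
| `nanochromkit.metasm` | Contig finishing: quality trimming (longest Q≥20 run), anchored 100 bp end extension from prioritised sources (≥94% identity), greedy overlap merging, chimera detection from unspanned paired-read intervals and split-and-trim. |
| `nanochromkit.mapkit` | Minimal seed-and-verify read mapper (exact 21-mers + ungapped identity, ≥94% floor), contig–contig matcher (≥100 bp, ≥90%), cross-mapping counts and minimal SAM import/export. |
| `nanochromkit.hetvar` | Pileup variant calling (≥20×, ≥5%, ≥40 bp from ends), heterozygous/homozygous classification at the 0.5% threshold, variant-frequency profiles, pairwise-alignment heterozygosity, 4-fold synonymous diversity under the ciliate nuclear code and Ne = π4S/(4μ). |
| `nanochromkit.fragsites` | Telomere-addition-site calling in 200 bp windows, strong/weak support at 10 reads, alternative-fragmentation detection, isoform prediction from telomere-paired reads and inter-/intra-CDS enrichment. |
| `nanochromkit.copynum` | Relative copy number from interior read depth (600 bp margins, ≥1,800 bp contigs) and telomeric-read counts, estimator cross-validation, one-sided two-sample K–S comparisons and genome-size helpers. |
| `nanochromkit.pipeline` / `cli` | YAML-configured end-to-end runs with a checksummed manifest; byte-identical reruns under a fixed seed. |

## CLI

Everything is under one entry point (module groups also install as
standalone scripts `simgenome`, `telomere`, `metasm`, `hetvar`,
`fragsites`, `copynum`):

```sh
# simulate a genome + reads + truth tables
nanochromkit simulate --n-loci 200 --coverage 30 --seed 42 --outdir sim/

# telomere scanning / masking / assembly stats
nanochromkit telomere scan sim/contigs.fasta --out telomeres.bed
nanochromkit telomere stats sim/contigs.fasta

# map reads (telomere-masked by default), then downstream analyses
nanochromkit map sim/contigs.fasta sim/reads_se.fastq --out aln.sam
nanochromkit hetvar classify sim/contigs.fasta aln.sam --out het.tsv
nanochromkit fragsites call sim/contigs.fasta aln.sam --out tas.bed
nanochromkit copynum estimate sim/contigs.fasta aln.sam --out cn.tsv

# or the whole pipeline in one go (deterministic under --seed)
nanochromkit run --n-loci 200 --seed 42 --outdir run/
```

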