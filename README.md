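# offpop

Population-aware CRISPR/Cas9 off-target audit for a single sgRNA:

* **bulge-aware alignment** of 21–25 nt candidate sites to a 20 nt spacer +
  NGG PAM (banded DP minimizing indels, then mismatches; predictor-declared
  gaps `-` and lowercase insertion markup are honored when present);
* **CFD scoring** with the published per-position mismatch/PAM activity
  fractions plus an indel extension (insertion/deletion activity fractions),
  combined multiplicatively into a final cleavage probability with the
  0.2 / 0.023 tiers;
* **candidate filtering** (≤6 mismatches, ≤2 indels, conserved 5 nt SEED,
  canonical PAM), genic/intergenic/pseudogene annotation, multi-locus
  duplicate detection, repeat-overlap flagging (inside / within ±200 bp);
* **population-variant overlay**: VCF (1000 Genomes-style INFO AF keys) and
  long-format TSV frequency ingestion, the ≥1 % polymorphic-site rule over
  configurable populations, per-variant re-alignment and re-scoring with
  effect classes (mismatch increase/decrease, indel increase, SEED/PAM
  disruption, PAM creation), and private/shared privacy summaries;
* **PAM discovery**: exhaustive scan of desk-scale genomes for NNG/NGN
  near-matches and detection of variants converting them to NGG;
* **synthetic fixtures**: deterministic genomes with planted off-targets,
  annotations, and VCFs whose truth is known exactly.

A demonstration dataset (the IDUA W402X guide `GCTCTAGGCCGAAGTGTCGC` and its
published candidate sites and site variants) ships with the package
(`offpop.datasets`). Coordinates are real hg19 loci where the source tables
print them; rows without printed loci carry placeholder coordinates on
`chrU` and support sequence-level analyses only.

## CLI

```bash
offpop fixtures --seed 1 --length 100000 --spacer GCTCTAGGCCGAAGTGTCGC --out fx/
offpop filter  fx/candidates.tsv --spacer GCTCTAGGCCGAAGTGTCGC
offpop score   fx/candidates.tsv --spacer GCTCTAGGCCGAAGTGTCGC
offpop overlay fx/candidates.tsv pop.vcf --spacer GCTCTAGGCCGAAGTGTCGC
offpop pamscan fx/genome.fa --spacer GCTCTAGGCCGAAGTGTCGC --variants pop.vcf
offpop audit   config.yaml
```

`audit` runs the whole pipeline from a YAML config (guide, input paths,
policy, thresholds, output dir) and writes deterministic TSV/JSON reports
(scores at 3 dp, `-` for absent indel scores, `**`/`*` tier markers,
frequencies as percentages). Exit codes: 0 success, 2 validation error,
3 data-integrity error.

Unified candidate TSV schema (0-based half-open coordinates, sequence in
guide orientation): `id  chrom  start  end  strand  sequence  source
annotation`.

## Penalty resource

`src/offpop/resources/cfd_penalties.tsv` holds the mismatch/PAM activity
fractions from the published SpCas9 off-target activity dataset (Doench et
al. 2016, as redistributed in the CRISPRme/CRISPRitz score files) together
with the single-base insertion/deletion activity fractions from the same
dataset. Conventions (insertion keyed by inserted target base and its
position in the candidate; deletion keyed by the deleted guide base and
guide position; mismatch scores computed on guide coordinates, equivalently
on the insertion-removed sequence) are pinned by golden tests against
published per-site scores. The file's SHA-256 is recorded alongside and
logged at load time.
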