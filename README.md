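# phyllotig

Post-assembly analysis of long-read (PacBio-style) plant-microbiome
metagenomes. Given assembled contigs, per-contig read depths, gene annotations
with best-hit taxonomy, and a full-length 16S rRNA reference set, the package

1. **summarises and filters the assembly** — contig counts, total bases, N50,
   large-contig tallies; removal of low-complexity artifact contigs; a
   high-quality set defined by mean read depth > 5;
2. **detects circular contigs** — closed replicons appear as linear strings
   whose start is duplicated at the end; the detector finds the longest
   prefix/suffix overlap within a substitution tolerance and emits trimmed
   circular forms;
3. **assigns tiered 16S taxonomy and profiles the community** — the reference
   set is curated (length > 1400 bp, greedy clustering at ≥ 97% identity),
   full-length 16S genes are aligned to it (hits covering < 95% of the gene
   are dropped), and the top-hit identity is mapped to rank tiers
   (≥ 97% species, ≥ 94.5% genus, ≥ 86.5% family, ≥ 82% order, ≥ 78% class;
   below a tier the gene flags a candidate novel taxon one rank up).
   Abundances are depth-weighted per contig, so multi-copy rRNA operons do
   not inflate a species;
4. **classifies replicons** — an ordered decision list sorts contigs into
   chromosome, megaplasmid, repABC plasmid, putative plasmid, bacteriophage,
   or unclassified from circularity, size (1 Mbp chromosome/megaplasmid
   boundary), DnaA/RepA/repC/RepAB/TraY/partitioning markers, and an external
   viral score (> 0.8); contig-level taxonomy uses the conservative
   one-fourth/single-phylum rule; the VirB/VirD4 type-IV secretion system is
   scored for completeness (all 12 components / 10–11 / partial) and operon
   arrangement.

A first-class synthetic-community generator plants all of this structure with
a full truth table (replicon classes, circular overlaps, 16S copies at
controlled divergence, marker genes, log-normal depths), so every stage is
tested against known ground truth without any downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
community (seed 42, 20 taxa, 80 contigs) and write their tables under
`results/`:

```bash
python analysis/01_simulate_community.py   # inputs + truth table
python analysis/02_assembly_qc.py          # assembly summary table
python analysis/03_circularity.py          # circular contig list + trimmed FASTA
python analysis/04_ssu_profile.py          # 16S tiers + community profile
python analysis/05_classify_replicons.py   # replicon classes + T4SS report
```

Step 02 prints the assembly summary (all vs high-quality contigs):

```
0 low-complexity artifact contigs removed; 47 of 80 contigs have depth > 5
                                      Total contigs  High quality contigs
Number of the contigs                            80                    47
Total nucleotides (bp)                     35505383              17893825
...
high-quality contigs hold 50.4% of assembled bases
```

Step 03 recovers every planted circular contig exactly:

```
68 circular contigs detected, trimmed sizes 10.2 kbp to 4.52 Mbp
sensitivity vs planted truth: 1.000 (68 planted); false positives: 0; trimmed lengths all exact: True
```

Step 04 prints the 16S identity-tier table — 5 of 21 full-length genes on
depth-eligible contigs match a known species at ≥ 97% identity, the other 16
are candidate novel taxa at lower ranks — and the depth-weighted species
profile. Step 05 closes the loop against the truth table:

```
class accuracy vs truth: 1.000; genus-call accuracy: 1.000
VirB/VirD4 T4SS status counts: {'nearly_complete': 7, 'partial': 3, 'complete': 2}
```

The same stages are available as a CLI (`phyllotig simulate | qc | circular |
ssu | classify | t4ss | run | demo`); `phyllotig run --config config.yaml`
executes the whole pipeline from a YAML config with byte-identical outputs for
identical inputs.

## Documentation

`docs/methods.md` describes the model and procedure behind each stage, the
synthetic data generator and its limits, parameter defaults, and numerical
choices.
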