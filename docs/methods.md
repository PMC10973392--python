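# Methods

## Scope and model

phyllotig implements the analytical core that sits *after* long-read
metagenome assembly: quality filtering and summary of contigs, circularity
detection, full-length 16S taxonomy and community profiling, and rule-based
replicon classification. Everything upstream (read filtering, assembly, read
mapping, gene calling, functional annotation, viral/completeness screens) is
consumed as input: depths arrive as a per-contig table, gene annotations as a
labelled feature table, and viral scores / genome completeness as optional
per-contig columns.

## Assembly QC

* **Summary statistics.** N50 is the largest-first cumulative definition: the
  contig length `L` at which contigs of length ≥ `L` first hold at least half
  of all assembled bases; when the cumulative sum hits exactly half, the
  current (boundary) length is reported. The summary also counts bases in
  contigs ≥ 50 kbp, contigs ≥ 1 Mbp, circular contigs, and carries a CDS count
  through if supplied.
* **High-quality filter.** Contigs with mean read depth strictly `> 5` (the
  headline filter) form the high-quality set. 16S eligibility elsewhere uses
  an inclusive `>= 5`; the two thresholds are deliberately separate parameters
  because depth-filter conventions differ between the assembly-QC and
  16S-screening contexts, and both are configurable.
* **Artifact screen.** Artificial contigs dominated by one nucleotide are
  flagged when a single-base run reaches 1000 bp or one base exceeds 50% of
  the sequence. No published run-length convention exists for this screen, so
  both knobs are parameters; the defaults are conservative enough that a
  uniform-random 10 kbp contig is essentially never flagged (the expected
  count of ≥ 1 kb homopolymer runs is astronomically small).

## Circularity by terminal overlap

An assembler emits a closed replicon as a linear string whose start is
repeated at its end. The detector scans candidate overlap lengths from
`max_overlap` (default 50 kbp) down to `min_overlap` (default 1 kbp) and calls
the contig circular at the longest length whose prefix/suffix Hamming mismatch
fraction is at most `max_mismatch_frac` (default 2%, conservative for
HiFi-grade consensus accuracy). The comparison is substitution-only by design:
assembler-produced terminal repeats are copies of the same consensus, so
indels between them are rare; an indel-bearing overlap shifts the register and
will be missed (documented limitation).

The naive scan is quadratic in `max_overlap`. Implementation: per-length match
counts for all candidate lengths are obtained at once by FFT cross-correlation
of one-hot base tracks of the two terminal windows (exact integers up to FFT
rounding ≪ 0.5), and every candidate within one mismatch of tolerance is then
re-verified with an exact vectorised byte comparison — so float rounding can
never change a call, and the result equals the naive scan by construction
(property-tested against it). Trimming removes the trailing copy of the
overlap and leaves the rotation start unchanged; both raw and trimmed lengths
are reported, since conventions differ on which one a study quotes.

## Pairwise identity and coverage

All 16S comparisons use one pinned alignment definition (module
`phyllotig.align`): overlap alignment (terminal gaps on either sequence are
free) with match +1, mismatch −1, linear gap −5; endpoint and traceback
tie-breaks are fixed and documented. Identity is matches over aligned core
columns (internal gaps count, terminal free gaps do not); query coverage is
the fraction of query bases inside the core. Pinning the tie-breaks makes
identity a well-defined function of the two sequences, which is what lets the
test suite demand *exact* agreement with an independently written scalar DP
oracle.

Two numerical choices matter:

* **Gap penalty −5.** With weak gap penalties, co-optimal gappy paths pair
  random matches and inflate identity at high divergence (observed drift above
  one percentage point at ~72% target identity). At −5 the realized identity
  of substitution-mutated sequences tracks the planted value to within ~0.03
  points across the whole tier range, which is what identity-threshold
  taxonomy needs.
* **Coverage gating.** The optimal overlap alignment of two *unrelated*
  sequences can be a handful of terminal columns that match perfectly —
  formally 100% identity at ~0% coverage. Wherever identity is used without
  an explicit coverage filter (greedy clustering absorption, reference-set
  rejection sampling), it is therefore gated: pairs whose alignment covers
  < 90% of the query are treated as unalignable. Top-hit search carries its
  own 95% coverage filter.

## 16S taxonomy and profiling

* **Curation.** Records ≤ 1400 bp are removed; survivors are sorted by length
  descending (ties by id) and clustered greedily first-fit at ≥ 97%
  coverage-gated identity, keeping representatives — the classic behaviour of
  greedy incremental clusterers for rRNA databases.
* **Assignment.** Each full-length gene (≥ 1400 bp, contig depth ≥ 5) is
  aligned to every representative; hits covering < 95% of the gene are
  discarded; the best identity wins (ties to higher coverage, then smaller
  id). Identity maps to lower-inclusive half-open tiers: ≥ 97 species
  (known species), [94.5, 97) genus (novel species), [86.5, 94.5) family
  (novel genus), [82, 86.5) order (novel family), [78, 82) class (novel
  order), < 78 unresolved (novel class). Boundary inclusivity follows the
  convention that "≥ 97% identity" defines a known species and "< 78%" a
  candidate novel class.
* **Profiling.** The species-level profile uses only species-tier genes and
  weights by contig mean depth. Default weighting is *per contig*: a contig
  contributes its depth once per taxon regardless of how many 16S copies of
  that taxon it carries, so multi-copy operons (up to 9 copies on one replicon
  have been observed in real assemblies) do not inflate abundance. Per-gene
  weighting is available for comparison. Abundances are normalised to 100 and
  are invariant under rescaling all depths.
* **Profile comparison.** Given a companion profile (e.g. amplicon-derived),
  the comparison reports the taxa above an abundance threshold (default 1%)
  in the companion, how many occur in the metagenome profile, and the
  combined abundance of that taxon set evaluated in each profile.

## Replicon classification

An ordered decision list, first match wins, every contig gets exactly one
class and the fired rule's satisfied predicates as evidence:

1. circular ∧ ≥ 1 Mbp ∧ (DnaA ∨ genome completeness ≥ 50%) ∧ no plasmid-type
   replication (RepA/repC/RepAB) → **chromosome**
2. circular ∧ ≥ 1 Mbp ∧ plasmid-type replication → **megaplasmid**
3. viral score > 0.8 → **bacteriophage**
4. repC present → **repABC plasmid**
5. RepAB ∨ RepA ∨ TraY ∨ (partitioning genes without phage structural genes)
   ∨ (≥ 1 VirB component without phage structural genes) → **putative
   plasmid**
6. otherwise → **unclassified**

The 1 Mbp size boundary and the 50% completeness fallback operationalise the
standard chromosome/megaplasmid criteria (essential replication machinery and
gene content, not size alone); both are parameters. Precedence
(chromosome/megaplasmid > phage > repABC > putative) encodes evidence
strength and is fixed in code to keep calls reproducible. A DnaA gene on a
small circular contig is *not* sufficient for a chromosome call — such
contigs (known from plasmids of *Rickettsia* and others) fall through to the
later rules.

**Contig taxonomy (one-fourth rule).** Genes whose best hit has ≥ 80%
identity and ≥ 80% coverage qualify; a genus is assigned only when its
qualifying genes strictly exceed one fourth of *all* annotated genes on the
contig (the stricter denominator) and every qualifying hit comes from a
single phylum. "Exceeding" is strict: 25 of 100 genes is not enough, 26 is.

**T4SS scoring.** Components are VirB1–VirB11 plus VirD4. Status: complete
with all 12 distinct components, nearly complete with 10–11, partial with
1–9, absent with 0. The 10–11 convention for "nearly complete" is this
package's own numerical definition of an otherwise qualitative label.
Arrangement comparison de-duplicates the observed gene order (first
occurrences, by start coordinate) and asks whether it is a subsequence of the
canonical operon order under any rotation on either strand — the natural
equivalence for circular replicons; duplicated and missing components are
reported alongside.

## Synthetic communities (what the generator emulates, and what not)

The generator produces the inputs the pipeline consumes, with full truth:

* **Reference taxa.** 6-rank lineages sampled from a nested hierarchy (shared
  genus ⇒ shared family, and so on up). 16S templates are random sequences
  with fixed conserved 100-bp blocks at both ends so alignments anchor
  end-to-end; secondary structure and real conserved-region layout are not
  modelled — identity arithmetic, not biology, is what downstream stages
  consume. Inter-species identity is kept < 97% by rejection.
* **Contigs.** Classes are drawn from a configurable mix whose default echoes
  the observed composition of classified circular elements in long-read
  phyllosphere assemblies (repABC : putative plasmid : phage : unclassified
  ≈ 41 : 59 : 29 : 6) plus chromosomes/megaplasmids as 16S carriers. Sizes:
  chromosomes 1–5 Mbp, megaplasmids 1–2.5 Mbp, repABC plasmids 8–500 kbp,
  putative plasmids 8–300 kbp, phages 10–80 kbp — within the 8.5 kbp–4.3 Mbp
  range reported for circular contigs in such assemblies. Chromosomes and
  megaplasmids are always circular (their definitions require closure); other
  classes are circular with probability `circular_fraction` (default 0.8).
  Circular contigs are emitted with the first `terminal_overlap_len` (default
  2 kbp) bases duplicated at the end.
* **Markers.** Chromosomes carry DnaA and a high external genome
  completeness; megaplasmids RepA/RepAB; repABC plasmids 1–3 repC genes
  (echoing the ~1.5 repC genes per repABC contig seen in real data, and
  keeping the signal robust to moderate annotation loss); putative plasmids
  one of RepAB/RepA/TraY/Par/partial-VirB; phages structural genes plus an
  external viral score in (0.85, 0.99). A quarter of plasmid-class contigs
  additionally carry a T4SS (complete, nearly complete, or partial, sometimes
  with a duplicated component). Marker and filler gene rows are
  annotation-level truth only — their coordinates do not correspond to real
  gene sequence, which is irrelevant to the label-driven classifier. Only the
  16S rows are real planted sequence.
* **16S copies.** Chromosome-scale replicons get 1–4 copies, each
  substitution-mutated to a divergence level drawn from the configured tier
  targets (defaults span 99.5% down to 76.5%, deliberately off the tier
  boundaries so each target maps to one tier). Substitution-only divergence
  makes realized identity exactly controllable; indel robustness is exercised
  separately in the aligner tests.
* **Depths.** Log-normal (μ = 2, σ = 1), floored at 0.1 — a standard
  skewed-abundance stand-in; no published depth distribution exists for these
  assemblies, so the parameters are config knobs. About a third of contigs
  fall below the depth-5 filter, which exercises the QC path.
* **Taxonomy hits.** 35–60% of each contig's genes receive best-hit taxonomy
  from the source taxon at 85–100% identity/coverage, so the one-fourth rule
  is recoverable; the fraction is per-contig random.

Determinism: every output is a pure function of (config, reference set,
seed); the global seed is split into independent per-purpose streams, so
identical configs give byte-identical files.

What passing tests on this generator do **not** show: robustness to chimeric
contigs, indel-rich terminal overlaps, mis-annotated labels (only dropout is
modelled), multi-taxon contigs, or real 16S conservation structure. The
generator is a contract on the pipeline's logic, not a sequencing simulator.

## Problem sizes and degenerate inputs

The bundled analyses and the acceptance script use communities of 20 taxa and
30–200 contigs (tens of Mbp) — large enough for every class and tier to be
populated while keeping a full run in tens of seconds on one core. Degenerate
inputs are defined behaviours, not crashes: an empty annotation table yields
an empty profile (with a warning) and score-only classification; a reference
set emptied by the length filter returns an empty curated set with a warning;
contigs shorter than twice the minimum overlap are reported linear without a
scan; a missing depth entry aborts the run naming the stage and contig.

## Known limitations

* Hamming-based overlap detection misses indel-bearing terminal repeats.
* 16S genes are taken from the annotation table (`SSU_RRNA` rows); there is
  no built-in rRNA detector.
* Identity is matches over aligned columns under one pinned scoring scheme;
  BLAST-style local identity on the same pair can differ slightly.
* The classifier consumes external viral scores and completeness values; it
  does not recompute them.
* Secondary 16S hits are retained in the output table but do not influence
  taxonomy, which uses the top hit only.
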