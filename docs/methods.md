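# Methods

`pedimpute` phases and imputes biallelic SNP genotypes for every member
of a pedigree — densely genotyped, sparsely genotyped, or ungenotyped —
and emits phased alleles, per-gamete allele probabilities, and dosages
(the expected count of allele 1, in [0, 2]).  This note documents the
model, the algorithmic choices, the tunable parameters, and what the
synthetic benchmark does and does not demonstrate.

## Model and coding conventions

Genotypes are coded 0/1/2 with 3 for missing; phased alleles 0/1 with
−1 (9 on disk) for unresolved.  Each individual's genotype is treated
as an *ordered* pair of alleles (paternal gamete, maternal gamete),
giving four states (0,0), (0,1), (1,0), (1,1).  Imputation resolves
each gamete separately, so the output doubles as a parent-of-origin
haplotyping of the whole pedigree.

The pipeline has three stages:

1. **Single-locus segregation analysis (peeling).**  For every locus
   independently, posterior ordered-genotype probabilities for every
   individual are computed by sum-product message passing on the
   pedigree: one trio factor per offspring encodes Mendelian
   transmission (each parent transmits its paternal or maternal allele
   with probability ½), base animals carry a Hardy–Weinberg prior at
   the allele frequency estimated from the high-density animals, and
   observed genotypes enter as penetrance factors.  Messages are
   iterated to a fixed point: on loop-free pedigrees this is exact (the
   test suite checks equality with brute-force enumeration to 1e-6); on
   looped (inbred) pedigrees it is the usual iterative-peeling
   approximation, stabilized by message damping from iteration 12.
   Loci whose messages have converged are compacted out of the
   iteration, so whole-chromosome peeling costs little more than the
   few slow-mixing columns.  An allele is hard-called when its
   probability exceeds `call_threshold` (default 0.99).

2. **Long-range phasing and haplotype libraries.**  High-density
   animals (fraction of non-missing SNP ≥ `hd_threshold`, default 0.9)
   are phased core by core (`core_length` 100 SNP, `n_rounds` 4 rounds
   with shifted core boundaries).  Within a core, heterozygous loci are
   phased by the unanimous vote of *surrogate relatives*: genotyped
   animals connected through exactly one parental side of the target
   (shared pedigree ancestor with the sire but not the dam, or vice
   versa) and sharing no opposing homozygotes with the target across
   the declaration region.  Surrogacy is declared on the core extended
   by `surrogate_flank` (default 200 SNP) on each side: on a bare
   100-SNP window, unrelated-haplotype candidates too often show zero
   opposing homozygotes by chance, and the flank restores the
   long-range character of the test (measured on the standard fixture,
   the flank cuts phase disagreements with simulated truth from ~1% to
   ~0.15%).  Fully resolved gametes populate a per-core haplotype
   library; partially resolved gametes are completed against the
   library when exactly one entry matches (completions that would
   contradict an observed genotype are reverted); animals still
   unresolved — base animals in particular, which have no surrogates —
   receive the unique pair of library haplotypes compatible with their
   genotype, left unordered until stitching.  Rounds are merged
   conservatively: inter-round disagreements are treated as phasing
   errors and reset to unresolved.

3. **Imputation hierarchy.**  Four *minor* rules run to a fixed point
   after every major step: (1) a homozygous-phased parent fills the
   offspring's corresponding gamete; (2) known genotype plus one known
   allele gives the complement; (3) a parent with one known allele
   gains the other when an offspring demonstrably received a different
   one; (4) two known alleles give the genotype.  The *major* steps,
   cycled `n_outer_iterations` (default 3) times: hard-call peeled
   probabilities; label base animals' gametes by anchoring an arbitrary
   paternal/maternal labeling at the central core and extending it
   through overlapping cores of other rounds; vote unresolved alleles
   against the haplotype libraries, against the two haplotypes of each
   HD parent, against the animal's own haplotype pair, against
   libraries rebuilt internally from the partially imputed phase at
   several core lengths (`internal_core_lengths` 50/100/200), and
   against parents' *imputed* phase; then a recombination scan (below).
   Every write is monotone (first writer wins) and genotype-coherent:
   a proposal contradicting the observed genotype or the resolved
   opposite allele is dropped and counted as a conflict.

   **Vote thresholds.**  A vote step accepts an allele when its
   accumulated count across cores and rounds reaches the iteration's
   accept threshold while the opposite allele's count stays at or below
   `vote_reject` (default 0).  The default accept schedule
   (deferred, 6, 4) runs the first outer iteration without consensus
   votes at all, so that the exact Mendelian machinery (minor rules,
   recombination scan) lays down anchors before any library consensus
   is trusted.  This matters at sparse densities: a low-density
   animal's gamete is a *novel recombinant* that is usually absent from
   the library, and early unanimous votes from surviving non-identical
   haplotypes write wrong alleles that monotone fill can never retract.
   Measured on the standard fixture at 1% retained SNP, immediate
   voting (accept 1–2 from the first iteration) yields ~8% wrong hard
   calls and a mean accuracy of 0.81; the deferred schedule yields
   ~3% and 0.90.

   **Recombination scan.**  Wherever a parent is heterozygous and
   phased and the child's transmitted allele is resolved, the allele
   identifies the parental strand of origin.  (Any resolved transmitted
   allele is an anchor, including loci where the child is homozygous —
   a deliberate widening of the classical double-heterozygote rule that
   roughly doubles anchor density at no cost in correctness.)  Forward
   and backward scans interpolate origin between anchors, assuming no
   double crossover in between; imputation from the identified strand
   is subject to per-iteration restrictions that relax across the
   scan's schedule: total recombination count (`max_recombinations`
   10/20/40), minimum spacing of double crossovers
   (`min_double_crossover_gap` 100/50/25 SNP), and maximum distance to
   the nearest anchor (`anchor_distance_cap` 50/100/200 SNP) — the last
   keeps long anchor-free chromosome ends as probabilities rather than
   coin-flip hard calls.

   **Final probabilities.**  Peeling is re-run on the updated genotypes
   with every resolved allele folded into the penetrance; resolved
   alleles keep their 0/1, unresolved ones take the recalculated
   probability.  When `origin_aware_probs` is on (default), unresolved
   alleles of animals with a known parent are sharpened further: the
   probability that the origin at distance *d* from an anchor matches
   the anchor is the Haldane no-net-crossover probability
   (1 + e^(−2rd))/2, with the per-SNP recombination rate *r* estimated
   from the origin switches observed across all gametes in the run;
   the refined allele probability mixes the parent's two strand
   probabilities with these weights.  This leaves hard calls untouched
   and replaces only uninformative 50/50 origin guesses; at 1% retained
   SNP it raises mean dosage accuracy by roughly a point of
   correlation.

Unmapped SNP (no map position) take a peeling-only path — hard calls
plus minor rules plus recalculation, no haplotype information — which
is also available for whole runs as `--unmapped-only`.

## Synthetic data

The generator reproduces the study design the tool targets: a
discrete-generation livestock pedigree (default 100 founders, 6
generations, ~1500 animals), founder haplotypes over 1000 SNP on a
1 Morgan chromosome with blocky LD (per-SNP frequencies uniform on
[0.1, 0.5]; adjacent SNP share their latent uniform with probability
`ld_decay` = 0.95, so marginals are exact and LD decays geometrically),
gene dropping with Poisson(`morgans`) crossovers per meiosis, and
masking scenarios that keep 1/5/10/15% of SNP on the test cohort (the
500 youngest animals), choosing the retained SNP as the max-MAF member
of evenly spaced 5-SNP windows.  HD assignment rules mirror the
designs seen in practice: all parents, sires only, a random subset of
parents, or everyone.

What the simulation does *not* contain: genotyping error (the
opposing-homozygote Mendelian check is exercised only by constructed
fixtures), mutation, selection, assortative mating, and map error.
Accuracy figures from the benchmark therefore show the machinery works
as designed, not what to expect on error-prone real data; with real
genotypes the `max_mismatch` surrogate allowance and the
`library_mismatch_threshold` should be opened up.

## Numerical and degenerate-input choices

Peeling messages are normalized per locus and clipped at 1e-12 before
division (exclusion of a child's own contribution), which bounds the
error of the division trick well below the 1e-6 exactness target;
fixed-point tolerance 1e-7, at most 30 sweeps.  Allele-frequency
estimates are clipped to [1e-4, 1−1e-4] so founder priors never
degenerate.  Zero-probability deadlocks (inconsistent observations
surviving the Mendelian clean) reset the offending penetrance to
uniform with a warning.  Ties in the max-MAF panel choice go to the
lower SNP index; all traversals are in pedigree (oldest-first) and SNP
order, so runs are bit-reproducible — the only arbitrary choice, the
paternal label of a base animal's first haplotype, is fixed by
convention.  An empty pedigree, a single-core chromosome
(n_snp < core_length), and `n_outer_iterations = 0` (peeling +
phasing only) are all defined, tested degenerate cases.

## Known limitations

- Accuracy at very sparse panels is anchor-limited: at 10 retained SNP
  per Morgan roughly 3 origin anchors per gamete exist, and stretches
  beyond the last anchor or containing an undetected double crossover
  are irrecoverable by deterministic rules; the origin-aware
  probabilities mitigate but cannot eliminate this.
- Iterative peeling is approximate on looped (inbred) pedigrees; no
  loop-cutting is attempted.
- One chromosome per run; multi-chromosome data are processed
  chromosome by chromosome.
- No genotyping-error model beyond conflict detection and the
  configurable mismatch allowances.
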