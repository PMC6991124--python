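# Methods

urfkit asks one question of an unidentified reading frame (URF) found in a
small genome sequenced from several individuals of one species: does it
behave like a protein-coding gene? Two independent lines of evidence are
computed — a population-genetic one (is the ORF under purifying selection?)
and a compositional one (does its codon usage look like that of known
genes?) — plus the supporting statistics around them.

## Nucleotide diversity

`calculate_pi` computes Nei–Li nucleotide diversity: for every pair of
sequences the per-site mismatch fraction over the columns comparable for
that pair (both bases in A/C/G/T), averaged over all C(n,2) pairs.
Gap/N-containing columns are excluded *pairwise*, not listwise, which
matters when only three individuals are available. No n/(n−1) sample-size
correction is applied by default, matching the "Pi" statistic of DnaSP;
`sample_size_correction=True` enables it. For n = 2 the statistic is
exactly the Hamming mismatch fraction.

## Synonymous and nonsynonymous diversity (NG86)

`ng86_pairwise` implements Nei–Gojobori (1986) counting. Per codon, each of
the nine single-nucleotide neighbours contributes 1/3 of a site, synonymous
or nonsynonymous according to the genetic code; site counts of the two
sequences are averaged. Codon pairs differing at k positions are scored by
averaging the per-step synonymous/nonsynonymous counts over all k!
single-step pathways. Proportions are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − (4/3)·p), reported as NA (NaN) with a warning when
p ≥ 3/4.

Mutations that create stop codons are governed by `stop_policy`:

* `"exclude"` (default): changes to stops contribute no sites (so S+N < 3
  for stop-adjacent codons), pathways through stops are dropped and the
  remaining ones reweighted, and codon pairs that are stops or whose
  pathways are all blocked are skipped entirely. This is what lets the
  permutation null — whose simulants freely acquire stops — be scored.
* `"nonsynonymous"`: stop-bound changes count as nonsynonymous and sites
  renormalise to S+N = 3, reproducing Biopython's `calculate_dn_ds`
  convention; kept as an externally cross-checkable reference behaviour.

The whole method is reduced at load time to 64- and 64×64-element lookup
tables per genetic code, so one dN/dS evaluation is a few vectorised
gathers; a permutation run needing ~10⁵ evaluations takes milliseconds.

`pinpis` reports πN = mean pairwise dN and πS = mean pairwise dS and their
ratio as the **ratio of means**, not the mean of pairwise ratios — stable
when individual pairs have dS = 0. Degenerate cases: ratio = 0 when
πN = 0; ratio = NA when πN > 0 but πS = 0 (never infinity).

`classify_sites` labels each codon column invariant / synonymous /
nonsynonymous / both using the same pathway-averaged difference tables, so
a column is labelled (non)synonymous exactly when it contributes to πS
(πN) — including codon pairs whose endpoints encode the same amino acid
but whose pathways pass through a different one.

## The neutral permutation null (NDPS)

A πN/πS below 1 is not by itself evidence of selection: with a handful of
mutations the ratio estimate is extremely noisy. The nucleotide diversity
permutation simulation converts the observed ratio into a Monte-Carlo
p-value against an explicit neutral null that preserves the data's
diversity structure:

1. **Ancestor and lineage counts.** The ancestor is the column-wise
   majority consensus (≥3 sequences required; ties broken by a seeded
   random choice and counted). Each sequence's mutation count is its
   Hamming distance to that ancestor — minimal parsimony on a star tree.
2. **Neutral replicates.** Each replicate re-places every lineage's
   mutations at uniformly random distinct positions, each changed to a
   uniformly random different base (no transition/transversion bias, no
   coding constraint — simulants may gain internal stops, handled by the
   NG86 stop policy). Per-lineage mutation counts are preserved exactly by
   construction, and replicate π tracks observed π closely.
3. **p-value.** mc_p = #(valid simulated ratios < observed) / #valid,
   where a replicate is valid iff its πS > 0. Replicates with undefined
   ratios are excluded from numerator and denominator alike; if no
   replicate is valid the p-value is NA with a warning.

Given a seed, `ndps_run` is bit-reproducible. Default 1,000 replicates
(configurable) gives p-value resolution ~10⁻³.

**Calibration and power.** When the observed alignment is itself a neutral
draw, mc_p is uniform on (0,1) (KS test over 200 outer draws × 500
replicates; exercised in the acceptance suite). Power depends strongly on
the number of segregating mutations: at π ≈ 0.005 a ~1 kb locus carries
only ~8–10 mutations, and measured power at omega = 0.1 is ≈ 0.83 at the
0.05 level — some replicates simply draw too few mutations, or a
by-chance-high ratio, for any test to call. A 189-nt locus with 3
segregating sites is essentially untestable (p ≈ 0.4 regardless of the
truth), which is why short loci should be judged by the codon-usage test
instead.

**Ratio-estimator bias.** The mean of per-replicate πN/πS ratios over
neutral replicates exceeds 1 at low diversity (≈1.26 at ~1 kb, π ≈ 0.02)
purely because E[X/Y] > E[X]/E[Y] for noisy Y; the pooled ratio
mean(πN)/mean(πS) is 1.00 within sampling error. The permutation test is
immune to this (observed and null share the bias), but raw mean-of-ratio
summaries at low diversity should be read with care.

## The codon-usage Bayes factor

The codon (3-mer) spectrum of a query ORF is modelled as a multinomial
over the 62 sense codons of the genetic code (NCBI table 4 by default:
TGA = Trp, stops TAA/TAG). Conditioning a symmetric Dirichlet(1) prior on
the summed spectra of known coding genes gives a Dirichlet posterior with
α_coding = 1 + Σcounts, and likewise for known noncoding (intergenic)
sequence read in-frame. The test statistic is

    log BF = log DM(x | α_coding) − log DM(x | α_noncoding)

where DM is the Dirichlet-multinomial (multivariate Pólya) marginal,
computed with log-gamma functions (stable to ≥10⁵ codons; normalization
verified by exhaustive enumeration and Monte-Carlo integration in the
tests). log BF > 0 ⇒ coding-like. The prior is uniform over the simplex
because nothing stronger is defensible a priori; it is overridable and
recorded in output metadata.

**Preprocessing** prevents the classifier from keying on start/stop
codons: the leading start codon is stripped from every sequence, true ORFs
lose their terminal stop, and noncoding sequences lose every in-frame stop
triplet, keeping the model strictly 62-dimensional.

**LOOCV protocol.** Each trial picks one (locus, individual) query
uniformly at random; noncoding queries also draw a uniform reading frame
on the gene strand (only same-strand intergenic sequence is used at all,
to avoid the compositional shadow of the antisense strand). The held-out
locus is removed from conditioning for *all* individuals (no leakage
through sister copies), and each remaining locus contributes exactly one
randomly chosen individual's copy — conditioning sequences are never
pseudo-replicated across individuals. Noncoding conditioning spectra are
drawn at a random frame per locus per trial. Power = fraction of coding
queries with log BF > 0, specificity = fraction of noncoding queries with
log BF < 0; log BF = 0 counts as a misclassification for both
(conservative). The default 100,001 trials run in seconds (the loop is
vectorised over trials); estimates stabilise far below that.

`classify_urf` scores a candidate ORF per individual against posteriors
conditioned on every known locus (all copies) — the deterministic summary
used once cross-validation has established the classifier's operating
characteristics.

## The synthetic-data generator

`synth` produces the study system with known truth: an AT-rich (GC target
0.173) circular genome, ~11 unidirectional coding loci with gene-like
length spread (189–1,800 nt) separated by intergenic stretches ≥ 50 bp,
sampled from 3 individuals at neutral pairwise divergence 2 × rate with
default rate 0.011/site/lineage (the 2.2% scale of the motivating system).
Lineages radiate independently from one ancestor (star phylogeny — the
natural model for a few conspecific individuals); each draws
Poisson(rate × length) mutation proposals; a proposal changing an amino
acid inside a coding locus is accepted with probability omega (synonymous
and noncoding proposals always). Acceptance-rejection gives direct control
of the expected πN/πS, so omega is recoverable by `pinpis` (recovery
within ±0.04 at omega = 0.1, 500 replicates, ~1 kb loci).

The default coding codon distribution is an independent-base measure at
the GC target *tilted by amino-acid weights* favouring hydrophobic
residues (F/L/I/V/M…), mimicking the membrane-protein-rich composition of
organelle genomes; intergenic sequence is a Markov chain (i.i.d. by
default) at the same base composition. The tilt is what makes coding and
noncoding spectra distinguishable — with a plain product measure the two
classes would be identical by construction and no codon-usage classifier
could work, which would misrepresent real genomes.

Presets: `beroe-like` (13.3 kb, 11 genes at omega 0.05 plus two unlabeled
test ORFs of 1,065 and 669 nt at omega 0.3 and 1.0), `neutral-null`
(everything omega = 1; calibration), `separable-toy` (A/T-only coding
codons vs G/C-only noncoding — disjoint supports, so a correct classifier
must reach power and specificity ≈ 1).

What the generator does **not** emulate: rRNA loci, indels (off by
default, matching the indel-free coding loci of the motivating data; a
flagless design — alignments are trivially columnar), recombination,
demography, transition/transversion bias, within-genome rate variation,
and the highly divergent noncoding tracts that can dominate genome-wide
divergence in real organelles. Passing tests therefore demonstrate
correctness of the statistics under a clean star-tree model, not
robustness to alignment error or rate heterogeneity. Realized whole-genome
divergence on `beroe-like` is ~0.7–0.8% (selection removes most proposals
in the ~90%-coding genome) while gene-level π lands at the realistic
~0.005; intergenic stretches are short (50–200 bp), which caps LOOCV
specificity on this preset near 0.7–0.8 — short queries are genuinely hard,
consistent with the classifier's length dependence.

## Numerical and interface choices

* Internal coordinates 0-based half-open; GFF3 written/read 1-based
  closed; BED native. Sense codons ordered lexicographically so count
  vectors are comparable across runs.
* ORF discovery: ATG starts by default (alternative starts by flag); one
  ORF per start codon, `longest_per_stop` collapses nested ORFs;
  circularity handled by scanning the doubled sequence, keeping starts in
  the first copy and rejecting spans longer than the genome. Conserved
  ORFs require identical aligned span, intact start and no internal stop
  in every individual; nested conserved ORFs sharing a stop report the
  largest, exact ties going to the leftmost start.
* Every stochastic entry point takes an explicit seed (the CLI refuses to
  run without one) and is bit-reproducible given it; tie-breaks are drawn
  from the same generator and logged with counts.
* Tables are TSV with `.` for NA; every CLI run writes a JSON manifest
  (subcommand, parameters, seed, input SHA-256 checksums, version,
  timestamp).

## Limitations

Three individuals give three sequence pairs: π and πN/πS are point
estimates with large sampling error, lineage assignment is
majority-parsimony (recurrent mutation at a site is collapsed to one
event), and no outgroup means no divergence-based tests
(McDonald–Kreitman is out of scope by design). The Bayes factor compares
exactly two composition hypotheses; an ORF unlike *both* training classes
gets whichever is less unlike it. Maximum-likelihood codon models over
phylogenies are deliberately not implemented.
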