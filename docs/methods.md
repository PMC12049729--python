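# Methods

`immunoedit` implements five per-sample statistics of cancer
immunoediting — the immune-mediated negative selection that removes
immunogenic tumour clones and leaves a genomic footprint of "missing"
neoantigens — together with their permutation nulls, the
edited/unedited/unassigned classification rules, and a tumour-mutation
simulator under graded immune selection used to benchmark them against
each other.

## Mutation contexts and consequences

All scores operate on coding single-nucleotide variants in CDS space
(0-based positions on the spliced coding sequence).  Each SNV is
classified by its trinucleotide mutation context — the substituted base
with one flanking base on each side, `X[R>A]Y` — giving 192 raw
coding-strand classes, or 96 after pyrimidine collapsing
(reverse-complementing contexts whose reference base is a purine).  The
96-class scheme is used only by HBMR; everything else uses 192.
Consequences come from standard-genetic-code translation of the mutated
codon; stop gain/loss counts as nonsynonymous, since every statistic
here dichotomizes synonymous versus non-synonymous.  Contexts are
undefined at the two CDS edge positions; such records are kept in raw
counts but excluded from context-dependent expectations.

A `SubstitutionSpace` enumerates all three possible substitutions at
every internal CDS position with context and consequence annotations.
This single enumeration backs four different quantities: the
per-context synonymous probabilities P̄_s of the codon OE-ratio, the
substitution-class probabilities P_t and expected counts of HBMR, the
context-weighted site counts of immune dN/dS, and the simulator's
context-to-site placement map.

## The five statistics

**OEratio, reference-sample method.**  From a reference cohort assumed
free of immune selection, per-context rates N̄_s (nonsynonymous per
synonymous) and B̄_s (neoantigens per nonsynonymous) are estimated as
count ratios.  A sample's synonymous mutations S_s then predict
Npred = Σ_s N̄_s S_s and Bpred = Σ_s B̄_s N̄_s S_s, and the score is
(Bobs/Nobs)/(Bpred/Npred).  Contexts with a zero reference denominator
are undefined (NaN), never zero; sample terms falling on undefined
contexts are dropped and counted, with an optional +0.5 pseudocount
mode behind a flag.  Scores below 1 indicate neoantigen depletion.

**OEratio, codon method.**  Identical observed side, but
Npred = Σ_s (1−P̄_s) C_s over all coding mutations, where P̄_s is the
probability that a substitution with context s is synonymous —
concretized here as the synonymous fraction among all enumerated
substitutions of context s over the supplied coding-region set (the
genome-enumerated rather than codon-table-theoretical definition) —
and Bpred = B̄_coding · |C| ignores context.

**HBMR.**  Positions are HLA-binding when their aggregated affinity
(harmonic mean over alleles of each allele's minimum affinity across
the ≤9 peptide windows covering the position's codon) is strictly
below 500 nM.  HBMRobs = (Nb/Sb)/(Nn/Sn); HBMRexp applies the same
ratio to the enumerated substitution counts weighted per 96-class by
P_t; the reported score is obs/exp.  P_t defaults to the class
frequencies of the enumeration itself (cohort-independent), with a
cohort-spectrum mode behind a flag.

**Immune dN/dS.**  The immunopeptidome (ON) is the union of 9-mer
windows whose best %rank is strictly below 0.5.  Per region,
dN/dS = (Nobs/Nsite)/(Sobs/Ssite) with Nsite/Ssite the context-weighted
counts of possible substitutions (each enumerated substitution
contributes its 192-context weight); the statistic is ON/OFF.  Weights
default to the cohort's observed 192-context spectrum, with per-sample
and uniform modes available.

**ES-CCF.**  The CCF range (0,1] is split into L=100 intervals
traversed from high CCF to low, so interval r carries rank weight
R_r = |L/2−r|+1 (largest at both extremes).  Within each class
(antigenic / non-antigenic) the interval masses a_r = m_r R_r / Σ m_r R_r
cumulate into F_N and F_M; with D = F_N − F_M,
ES = max(0, max D) − |min(0, min D)|.  The high-to-low traversal is the
orientation under which neoantigens shifted toward low CCF accumulate
late and drive ES negative; it is switchable, as is the bin edge
convention (left-open right-closed, CCF 1 in the first traversed bin).
CCF = 0 records are excluded with a warning count.

## Permutation nulls and classification

* OE-ratios: mutations are reassigned across samples uniformly,
  preserving per-sample counts; p is the fraction of a sample's
  permuted scores strictly below its real score (ties count as not
  below; an optional (k+1)/(n+1) estimator avoids p = 0).
* HBMR: binding flags are shuffled over CDS positions preserving the
  number of binding positions; observed and expected HBMR are both
  recomputed under each permuted annotation.
* Immune dN/dS: no published construction exists for this p-value, so
  it is a documented stand-in: each observed mutation is reassigned
  ON/OFF with its consequence-specific weighted-site fraction and the
  statistic recomputed.  The consequence-specific probabilities (rather
  than a shared total-sites probability) are what make the permuted
  statistic center at 1 exactly where the neutral real statistic does,
  giving a uniform null p.
* ES-CCF: class labels are shuffled over the pooled CCFs; p is the
  fraction of permuted ES ≤ the real ES (one-sided toward editing).

Classification: the four ratio scores call a sample edited when the
score is below 1; ES-CCF requires ES < 0 and p < 0.05 (the `without_p`
variant drops the p requirement).  A sample is unassigned exactly when
the method's assignability predicate fails (e.g. no synonymous
mutation in a region, vanished denominator); failures are isolated per
method and never abort the panel.  Cohort-level eligibility requires
at least one nonsynonymous mutation, one synonymous mutation and one
neoantigen per sample.

## The simulator

`build_synthetic_coding_set` draws a random in-frame CDS (internal
stops rejected) and lays down binder positions in contiguous 27-nt
runs (one 9-mer peptide window each) until the requested fraction
(default 0.3) of positions binds; binder positions get aggregated
affinities log-uniform on [1, 500) nM, the rest log-uniform on
[500, 50000) nM.  Log-uniform IC50 is the conventional shape for
binding-affinity distributions; it concentrates immunogenicity
a = (500−affinity)/499 near 1 for binders, so strong selection removes
most neoantigens.  The synthetic strong-binder runs stand in for both
the HLA-binding regions (HBMR) and the immunopeptidome (immune dN/dS);
real annotations distinguish the two, and both flags are carried
separately.

Baseline cohorts draw each mutation's context from a 192-context
spectrum (default: a transition-dominated stand-in with C>T/G>A at ~42%
of mass, flanks uniform; any cohort-estimated spectrum can be passed),
place it uniformly on a matching trinucleotide site, translate for the
consequence, and flag neoantigens as nonsynonymous changes at binder
positions.  CCFs come from a mixture of 60% clonal mass (normal around
1, sd 0.08, truncated to ≤1) and 40% subclonal mass (Beta(2, 2.857),
mode ≈ 0.35), conditioned on detectability: draws below the 0.2
detection threshold are rejected, because an observed baseline cannot
contain undetectable mutations (and selection at s = 0 must be the
identity).  Within a sample, duplicate (position, alt) draws are
rejected and resampled.

Selection of strength s ∈ [0,1] depresses each neoantigen's CCF by
CCF_s = CCF − s·a and removes it when CCF_s < 0.2.  `combined` keeps
survivors at the depressed CCF (the alternative — reverting survivors —
is a flag); `remove_only` reverts survivors to their original CCF;
`ccf_only` depresses without removing, flooring retained CCFs at 0.01
so they stay inside the ES-CCF binning domain.  Synonymous mutations
are untouched in every mode.

### What the generator does and does not emulate

It reproduces the features the five statistics actually consume:
a realistic context spectrum over real codon structure, real
synonymous/nonsynonymous consequences, binder regions with an affinity
gradient, and a clonal/subclonal CCF mixture.  It does not emulate
gene-level mutation-rate heterogeneity, transcription-coupled strand
asymmetry, driver selection, copy-number-driven CCF error, expression
filtering of neoantigens, or inter-patient HLA diversity (one shared
annotation stands in for patient-specific immunopeptidomes).  Passing
tests therefore demonstrate internal consistency and sensitivity of
the statistics under controlled selection, not calibration on real
tumour cohorts.

## Problem sizes and numerical choices

The benchmark experiments run at desk scale: the selection gradient
uses 120 samples × 400 mutations on a 9,999-nt synthetic CDS with
binder fraction 0.3 (s ∈ {0, 0.25, 0.5, 0.75, 1}); the null
calibration uses 200 samples × 300 mutations with 200 permutations per
test.  These sizes keep every experiment within a few seconds while
leaving all group tests massively powered (the s = 0 vs s = 1 Wilcoxon
adjusted p is ~1e-40).  The s = 0 cohort is the OE reference in all
simulator experiments.

Ties in permutation p-values follow each null's stated convention
(strictly below for OE and HBMR, ≤ for ES-CCF and immune dN/dS's
editing tail).  ES-CCF bin indices round CCF·L to 9 decimals before
the ceiling to keep values like 0.28 in their closed-right bin.
Group comparisons use two-sided Mann–Whitney U (Wilcoxon rank-sum)
with Benjamini–Hochberg adjustment within each emitted family;
correlations are Spearman over pairwise-assignable samples, not
multiplicity-adjusted.

## Known limitations

* ES-CCF under removal-only selection is *anti*-conservative in the
  unedited direction: removal preferentially deletes low-CCF
  neoantigens, clonally enriching the survivors and pushing the median
  score positive (~+0.28 at s = 0.8 under the defaults).  The statistic
  is therefore blind to pure neoantigen removal, while the four
  count-based scores are blind to pure CCF depression — the central
  complementarity the benchmark demonstrates.
* The immune dN/dS p-value construction is this package's own
  permutation scheme, not a reimplementation of a published one.
* Reference rates from small cohorts leave many of the 192 contexts
  undefined; the dropped-term accounting makes this visible but a
  sparse reference still biases per-sample predictions.
* One transcript per mutation is trusted from the input; no
  multi-transcript re-mapping is attempted.
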