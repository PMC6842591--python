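# Methods

## Model

### State space and parameters

Sequences are modeled at the codon level over the 61 sense codons of the
standard genetic code (lexicographic order, A<C<G<T, stops removed; the
ordering is frozen so serialized matrices are reproducible). The
instantaneous rate of a single-nucleotide change from codon *a* to codon
*b* at codon position *p* under HLP19 is

    q_ab = kappa^[transition] * omega_r^[nonsynonymous]
           * max(1 + sum_m h_m e(a, p, m), 1e-9)

where `omega_r` is `omega_fwr` or `omega_cdr` according to the site's
region label, and `h_m` is the rate offset of SHM motif *m* in
{WRC, GYW, WA, TW, SYC, GRS}. Multi-nucleotide changes have rate zero.
Motif target bases: WRC targets the C, GYW the G, WA the A, TW the T,
SYC the C, GRS the G — the canonical AID and polymerase-eta hot/cold
spots; this choice preserves the reverse-complement pairing
(WRC,GYW), (WA,TW), (SYC,GRS). `h` is an additive offset with multiplier
`1 + h`, so `h = -1` is the zero-rate limit and the fitted cold spots
(~ -0.6) correspond to a 0.4x rate; the `1e-9` floor guards pathological
combinations of several negative offsets.

HLP17 multiplies every entry additionally by the target-codon frequency
`pi_b`; GY94 is `pi_b * kappa^[ts] * omega^[nonsyn]` with a single
omega. Fitted GY94 constrains `omega_fwr = omega_cdr` (2 free
parameters); the HLP models have 9.

### Mean-field motif context

`e(a, p, m)` is the probability that position *p* of source codon *a* is
the target base of an occurrence of motif *m*. Motif positions falling
inside the codon are evaluated on the codon's own (pre-mutation) bases,
so fully in-codon contexts are exactly 0 or 1. Positions reaching across
the codon boundary are replaced by position-specific nucleotide
marginals of the frequency vector `pi`: a flank one base to the left
uses the marginal of codon position 3, two bases left uses position 2,
and symmetrically (positions 1 and 2) on the right. This keeps the
likelihood site-independent while capturing the average cross-boundary
context. Two consequences worth knowing:

- marginals are derived from a 61-codon distribution, so even a uniform
  `pi` gives slightly non-uniform nucleotide marginals (stop-codon
  exclusion skews them; e.g. P(third base in {A,T}) = 30/61 under
  uniform `pi`);
- exact reverse-complement symmetry of the rate matrix holds only for
  fully in-codon contexts, for the same reason.

### Nonstationarity, rooting and normalization

The germline is the known state of the root: by default the root partial
likelihood is evaluated at the germline codon with no frequency term,
which is what makes the nonreversible model's root identifiable. An
alternative "pi" root mode (germline attached as a zero-length tip and
root partials summed against `pi`) exists solely to make AIC comparable
with reversible-model conventions; `compare_models_aic` uses it for all
models.

Q matrices are normalized so that the expected number of substitutions
per codon per unit time is 1 under the normalizing frequencies, making
branch lengths "expected substitutions per codon site". For HLP19 the
normalizing frequencies are the predicted codon frequencies at the
midpoint of the phylogeny: a fixed-point iteration starts at the
germline codon frequencies, builds the HLP19 Q under the current guess,
propagates the germline frequencies for half the mean root-to-tip
distance with the matrix exponential, renormalizes, and repeats until
the vector changes by less than 1e-8 (cap 100 iterations, warning on
non-convergence). Propagation uses the FWR matrix, since most of a
V region is framework. GY94 and HLP17 use empirical codon frequencies
(counts over all sequences plus germlines, pseudocount 0.5 so no sense
codon has frequency zero).

## Likelihood evaluation

Felsenstein pruning with per-node rescaling (log-scale accumulators), so
trees of hundreds of tips and sites do not underflow. Identical site
patterns (germline codon, tip codons, region label) are collapsed and
weighted — a large saving on low-diversity B-cell data. Codons
containing gaps, ambiguity characters or stops are missing data
(all-ones partials); sites whose germline codon is missing, and sites
labelled IGNORED (the CDR3, whose germline junction is unreliable), are
excluded from scoring. `P(t) = exp(Qt)` is evaluated through a cached
eigendecomposition of Q (complex in general; reconstruction error is
checked and the code falls back to scipy's scaling-and-squaring `expm`
if Q is numerically defective).

## Fitting

Two-stage protocol: topologies are fixed first (user-supplied trees,
simulated truth, or parsimony via stepwise addition + NNI on non-IGNORED
sites followed by GY94 ML branch refinement), then shared parameters and
branch lengths are maximized by coordinate ascent:

1. L-BFGS-B over the shared parameters on a log scale (`log kappa`,
   `log omega`, `log(1+h)`), bounds kappa in [0.01, 20], omega in
   [0.001, 20], h in (-0.999, 20];
2. per-lineage L-BFGS-B over that lineage's branch-length vector,
   bounds [0, 10], rejecting steps that worsen the lineage likelihood;
3. for HLP19, refresh the midpoint frequencies from the current branch
   lengths;

until the repertoire log-likelihood improves by less than `tol`
(default 1e-3; cap 50 rounds — typical fits converge in 3–6). Starting
values are kappa=2, omega=0.4, h=0; branch lengths come from the input
trees when present, otherwise from per-tip divergence counts. Fits are
deterministic given the data; the optimizer and tolerances are package
choices, validated against dense grid searches on single-branch
problems (agreement to ~1e-3).

Profile CIs bracket outward from the MLE by step doubling and then
bisect for the value where the re-optimized log-likelihood has dropped
by `chi2.ppf(0.95, 1)/2 = 1.9207`, re-fitting all other parameters
(warm-started) at each probe; a profile that stays above the threshold
all the way to a parameter bound reports that endpoint as open-ended.

## Synthetic data

The generator emulates the repertoire features that matter for
repertoire-wide inference; its defaults are the validation conditions
used throughout:

- **Clone sizes**: truncated power law P(k) ~ k^-3.95, k <= 100, giving
  ~92% singleton lineages (the empirically observed 88–96% band);
  `("fixed", n)` for controlled experiments.
- **Germlines**: uniform random sense codons, 100 codons by default.
  Real V genes have biased codon usage; uniform germlines are harsher
  for the midpoint-frequency machinery, not easier.
- **Masks**: two contiguous CDR blocks (~25% of sites, at 30% and 60%
  of the region) and a trailing 5% IGNORED block standing in for the
  removed CDR3.
- **Trees**: Kingman coalescent over exchangeable tips, germline trunk
  drawn Exp(1) in coalescent units, all branches rescaled so each tree
  totals `branch_scale` (default 0.3) expected substitutions per codon.
- **Sequence evolution**: exact Gillespie simulation. Rates are
  recomputed from the *current* sequence after every substitution, with
  motif hits evaluated on the actual flanking bases — deliberately
  richer than the estimator's mean-field context, so recovery
  experiments probe the estimator under the realistic mismatch.
  Substitutions creating stops have rate zero. Branch lengths are
  interpreted as expected substitutions per codon under the h=0 rate
  scale at the germline composition; with hot spots active the realized
  substitution count per codon is higher by a roughly constant factor,
  which uniformly rescales fitted branch lengths and leaves
  kappa/omega/h recovery unaffected.
- **S5F mode**: per-base rates proportional to a 5-mer mutability table
  with substitution identities drawn from its profiles. The published
  table is not redistributable here, so a clearly-labelled *synthetic*
  table ships instead: mutability of a 5-mer is the product of (1+h)
  over motifs targeting its center, which reproduces the qualitative
  hot/cold ranking GYW > WRC ~ WA > TW > SYC ~ GRS. Tests that check
  the published motif means activate only when a user provides the real
  table at `data/s5f_mutability.tsv`.

What the simulator does *not* emulate: V(D)J recombination and real
germline usage, indels, clonal birth–death dynamics, sequencing error,
and lineage-to-lineage parameter heterogeneity. Passing recovery tests
therefore demonstrate statistical correctness of the estimator under
context-dependent SHM, not robustness to every feature of real
repertoires.

## Validation problem sizes

The reference recovery experiment is 50 lineages x 6 tips x 100 codons
(~1,800 informative substitutions), which recovers kappa and omegas
within a few percent and motif offsets within ~15%. The
repertoire-wide vs mean-individual comparison runs at 5 replicates of
15 lineages x 4 tips x 60 codons, and profile-CI coverage at 6
replicates of 3 lineages x 3 tips x 36 codons — sizes chosen so the
full suite runs in minutes on one CPU while leaving the compared
effects (variance ratios of ~50x, nominal 95% coverage) far larger than
the Monte-Carlo noise. AIC model comparison uses a 20-lineage subset of
the reference fixture.

## Known limitations

- Mean-field context is an approximation; strongly skewed repertoire
  compositions could make cross-boundary motif probabilities less
  accurate (the recovery experiments bound the effect at the few-percent
  level under uniform germlines).
- HLP17's codon frequencies are fixed at empirical values rather than
  ML-estimated (the original formulation's 60 extra free parameters are
  deliberately not re-implemented); its AIC uses 9 + branches free
  parameters accordingly.
- No rate variation across sites beyond the FWR/CDR omega split, no
  indels, no ancestral-state output.
- Repertoire-wide estimates mask lineage-level heterogeneity by
  construction; per-lineage fits are provided but overfit badly on
  small clones (a 2-sequence clone with only nonsynonymous CDR changes
  drives omega_CDR to its upper bound — this is demonstrated in the
  test suite, not a bug).
- Topology search is heuristic parsimony + NNI, adequate for the
  shallow trees of BCR clones; it is not a full ML tree search.
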