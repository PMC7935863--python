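# Methods

`sgdrive` models the population genetics of *split gene drives* (sGDs) in
*Drosophila melanogaster*: a gRNA + recoded-rescue cassette inserted into an
essential gene, driving by homing only when a separately inherited static
Cas9 transgene is present. This note records the model, its parameters, the
numerical choices, what the synthetic data do and do not emulate, and the
known limitations.

## The inheritance model

**Alleles.** The target locus has four states: `W` (wildtype, the only
cleavable state), `D` (the drive cassette with a recoded rescue), `R`
(in-frame, functional resistant) and `B` (out-of-frame, loss-of-function
resistant). A haplotype pairs a target-locus allele with Cas9 carriage;
phase matters only when Cas9 is genetically linked to the target.

**Activity.** An individual can cleave iff it carries at least one `D`
(the gRNA source) together with either a Cas9 allele or — for females —
maternally deposited Cas9 protein (`maternal_exposure`). Exposure is set
for all offspring of an active mother and therefore chains through
consecutively active females, but it always requires the female's own `D`.

**Germline cleavage and repair.** In an active parent each `W` allele is
cut with probability `q_sex`; a cut allele resolves by HDR to `D` with
probability `h_sex` *provided the homolog carries `D`* (copying needs the
drive as repair template), otherwise by NHEJ to `R` with probability
`fR_sex` or `B` otherwise. For a `D/W` active parent the drive-gamete
probability is therefore `1/2 + q h / 2`, i.e. transmission
`T = (1 + q h)/2`.

**Shadow drive.** Cas9-less but exposed females cleave at `sigma_shadow *
q_f`. The default `sigma_shadow = 0.3` reproduces the observed one-extra-
generation transmission bias (~64% vs the ~50% Mendelian expectation);
males transmit no protein, so exposed males are inactive.

**Maternal deposition (lethal/sterile mosaicism).** Each zygotic `W`
allele of an active mother's offspring is independently converted to `B`
with probability `d_dep` — deposition is mutagenic only (no embryonic
HDR), and mosaicism is approximated as whole-individual allele conversion.
Viability-target configurations then remove `B/B` zygotes at the egg stage
and weight active offspring by `1 - cost_eggviability`; fecundity-target
configurations cull nothing at the egg stage but make `B/B` adults
completely sterile.

**Cas9 transmission.** Three architectures: freely assorting autosome
(recombination fraction 0.5), linked autosome (female recombination
`r_linked`, default 0.02 from the ~2 cM map distance; males are
achiasmatic), and X-linked (daughters receive the father's X; males
hemizygous). The linked configuration adds `chrom_loss`: the probability
that a cut, non-HDR-repaired receiver chromatid is destroyed in meiosis
(renormalised gamete pool), the mechanism behind sub-Mendelian
transmission of a receiver-linked Cas9 marker.

**Fitness costs.** Costs act only on *active* genotypes.
Fecundity-target: `1 - cost_fecundity_sex` multiplies egg output.
Viability-target: `1 - cost_mating_m` multiplies male mating weight and
`1 - cost_eggviability` multiplies egg survival of active zygotes. The
published per-construct fitted cost is a single number while the model has
two channels per configuration; this package assigns it to the
female-fecundity channel (fecundity targets — the egg-production channel
of the stochastic formulation) or the egg-viability channel (viability
targets — the phenotype the hatchability assays measure), leaving the
other channel at zero unless set explicitly.

## Deterministic dynamics

Discrete, non-overlapping generations; sexes as separate frequency
vectors with a 1:1 birth ratio; random union of gametes with mothers
weighted by fecundity and fathers by mating competitiveness; viability
selection inside the zygote distribution; renormalisation each generation
(the cage protocol controls census, not density, so the cage is treated
as resource-saturated). The recursion runs on a precomputed inheritance
cube `cube[mother, father, offspring]` built per parameter set from
per-parent gamete vectors (a few ms for the ≤144-state spaces); the test
suite verifies the cube against a direct summation over
`zygote_distribution` for random parameters in all four architectures.

## Stochastic cage simulator

Exactly the distributional cascade of the discrete-generation stochastic
model: multinomial mate choice over male genotypes (weighted by mating
competitiveness), Poisson egg production per mated female (mean
`eggs_per_female x` maternal `x` paternal fecundity; default 50 — any
value far above census/females is equivalent after census sampling),
multinomial offspring genotypes with a joint egg-death class, binomial
sex (folded into the sexed genotype classes), and multivariate
hypergeometric sampling of the next adults and of the scored pool, each
of `census/2` females and `census/2` males. Default protocol: 15+15
double-heterozygote and 45+45 wildtype seeded adults (25% carriers, 12.5%
allele frequency), census 120, 20 generations. Replicates are seeded by
`SeedSequence` spawning: trajectories are bitwise reproducible.

A consequence worth stating: at census 120 the *mean* of stochastic
trajectories runs systematically below the deterministic recursion after
many generations, because replicates that lose Cas9 by drift before the
drive completes freeze at low carrier frequency and can never catch up
(the nonlinearity makes the Jensen gap one-sided). The
stochastic-mean-vs-recursion equivalence test therefore runs at a
400-adult census over the first generations, where the gap is within
sampling error.

## Likelihood and MCMC

The likelihood treats each scored generation as a multinomial draw of the
four fluorescence classes (sGD+Cas9+, sGD+ only, Cas9+ only, neither)
around the deterministic trajectory propagated from the seeded
composition, pooling replicates. Because genotype drift through `g`
census bottlenecks adds variance of order `3 g p(1-p)/N` on top of
scoring noise `p(1-p)/n` — one part census sampling plus roughly two
parts family-size variance from monogamous mating at ~`N/2` mated
females, a decomposition consistent with the simulator's measured
replicate dispersion — the per-generation log-probability is tempered to
an effective sample size `n_eff = 1/(1/n + 3g/N)` (with `N` taken equal
to the scored census); the uncorrected multinomial is available via
`drift_adjusted=False`. This pseudo-likelihood is a reconstruction — the
original fitting's exact likelihood is not part of this package's scope —
and it remains approximate: the realized drift of a given cage is shared
across its generations, so fits to long, small-census trajectories can
still be overconfident about selection-strength parameters. Parameter-
recovery tests therefore simulate short trajectories at a 400-adult
census, where the correction is adequate; fitted costs from long
census-120 cages should be read as conditional on the mean-field
approximation.

Sampling: adaptive random-walk Metropolis-Hastings, component-at-a-time
on logit-transformed coordinates, uniform [0, 1] priors (the Jacobian
`theta(1-theta)` is included in the logit-scale target), proposal scales
adapted toward ~0.3 acceptance during burn-in only. The MAP is the
highest-posterior retained draw; intervals are central quantiles;
convergence is flagged by split-R-hat (> 1.1 = not converged, reported,
not fatal).

## Allele auditing

Reads are globally aligned to the reference amplicon with affine gaps
(match +2, mismatch -3, open -8, extend -1 — one long gap is preferred
over scattered short ones, so contiguous indels are recovered as single
events); both strands are tried and the better alignment used, making
calls strand-invariant. Only indels intersecting a +/-20 bp window around
the cut site count; the net length decides frame (|net| mod 3), the sign
decides deletion vs insertion. Reads containing the recoded diagnostic
subsequence are `drive`; identity < 70% or > 5% ambiguous bases is
`unalignable`. Substitution-only reads classify as `WT`: category is
decided by indels alone, so single-base sequencing errors inside the
window cannot inflate the in-frame class (a read with an indel *and*
substitutions is still categorised by its net indel). The cost of this
choice is that pure-substitution resistant alleles are invisible — at
these loci resistance is indel-driven, and the round-trip accuracy bound
below depends on it. For in-frame calls, critical codons (e.g. the
carboxy-terminal prenylation cysteines of Rab proteins) are checked by
mapping the alignment and comparing translated codons.

## Synthetic data: what it emulates, and what not

The generators produce every input the pipeline consumes: cage trajectory
CSVs with ground-truth sidecars, per-vial F2 scoring tables (binomial
counts from the zygote marker probabilities of master x wildtype
crosses), and FASTQ amplicon reads from an allele mixture with
independent per-base substitution errors. The bundled demonstration locus
is fully synthetic (a constructed 180-bp amplicon), not a deposited
construct sequence.

The four library scenarios mirror the four studied architectures. Their
efficacies are derived from printed single-cross statistics: `q h` from
the transmission midpoint and `q(1-h)` from the resistant-allele load
(in-frame indel fraction of total F2 alleles / of NHEJ events), giving
e.g. rab5-like `q_f=0.994, h_f=0.930, q_m=0.666, h_m=0.895`. Functional
NHEJ fractions: 0.345 (rab5-like), 0.55 (rab11-like; 63% in-frame minus
the 13% cysteine-altering share), 0.10 (spo11-like — most in-frame indels
at a catalytic site are non-functional and behave as `B`), 0.5
(prosalpha2-like, where NHEJ is nearly absent). The prosalpha2-cis truth
solves `h` and `chrom_loss` jointly from the two printed observables
(~99.5% drive transmission, 35.6% receiver-marker transmission), giving
`h=0.55`, `chrom_loss=0.98`. Deposition strengths (`d_dep` 0.9/0.9/0.95/
0.5) are not separately printed; they encode the qualitative ordering of
mosaic-culling intensity (prosalpha2 > rab5 ~ spo11 > rab11) and the
drive outcomes are only weakly sensitive to them.

What the synthetic data do *not* emulate: mating-order or density biases
(the observed early cage ascent exceeds any random-union model at these
efficacies — the fitted literature model shows the same under-prediction),
variable per-generation cage sizes (census fixed at 120 unless
configured), PCR chimeras/UMI structure in reads, and Sanger trace
deconvolution. Passing tests therefore certify the pipeline against its
own stated stochastic model, not against unmodelled behavioural biology.

## Problem sizes used in the checks

Reproduction runs use 100 stochastic replicates of 20 generations at
census 120 (the seeded cage size). The test suite uses 40-replicate
versions of the same simulations, 300-replicate equivalence checks at
census 400 over 3 generations, 10 MCMC refits (8-10 replicates x 2-4
generations, census 400, ~450-700 draws after short burn-in) for coverage
and cost-recovery checks, and 10^4 reads for the audit round trip. These
sizes keep every check inside a desktop run while leaving the acceptance
quantities dominated by model, not Monte Carlo, error.

## Known limitations

- Mean-field likelihood vs drifting truth (above): selection-strength
  estimates from long small-census cages are approximate.
- The observed cage data rise faster and purge Cas9 faster than the
  reconstructed model at printed single-cross efficacies; reproduction of
  printed cage summary numbers is correspondingly partial (the simulated
  spo11-like plateau and rab5-like G10 means run ~10 points low, and
  simulated Cas9 extinction is slower than observed).
- Mosaicism as whole-individual allele conversion ignores cell-lineage
  structure; `R` alleles are fully functional and costless by
  construction.
- No age structure, density dependence, remating or overlapping
  generations.
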