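# Methods

## The measurement being modelled

A five-codon NNK saturation library (N = A/C/G/T at codon positions 1–2,
K = G/T at position 3; 32 codons encoding all 20 residues plus the single
stop TAG) randomizes the first five residues of a reporter's neo-N-terminus.
Cells are sorted by reporter fluorescence into four bins and each bin is
amplicon-sequenced. A motif's Protein Stability Index is the read-weighted
mean bin index, `PSI = Σ R_i·i`, bounded in [1, 4] with B4 the most stable
bin. Contrasting PSI tables between wild-type, ClpS-deficient, and
LFTR-deficient hosts attributes sequence effects to pathway components:
ClpS recognizes bulky P1 residues (F/L/W/Y) and initiates degradation;
LFTR converts basic P1 residues (R/K) into ClpS substrates by appending
Leu/Phe.

## Synthetic data generator

The simulator exists so that every downstream stage can be validated
against known ground truth without any sequencing data. Its layers:

**Effect model.** A motif's true stability is `baseline + Σ residue effects
+ Σ pair effects`, clamped to [1, 4]. Effects carry genotype masks: a
ClpS-dependent effect vanishes in the ClpS knockout, an LFTR-dependent one
in the LFTR knockout (R/K effects are masked in both, since their pathway
runs through both proteins). The shipped preset (`example_effect_model`)
encodes the qualitative grammar of the pathway — P1 F/R strongest
destabilizers, then L/W/Y/K; P2 Pro/Gly stabilizing; P2 Gln destabilizing;
downstream bulky residues destabilizing and acidic residues stabilizing —
with plausible round-number magnitudes. It is an injectable ground truth
for recovery tests, not a set of measured values.

**Sorting model.** A cell's latent log-fluorescence is Gaussian around its
motif's true stability with SD `noise_sd`; three ascending thresholds
partition the axis into bins. Defaults: thresholds at the PSI quartiles
(1.75, 2.5, 3.25) and `noise_sd = 0.8`. That SD was chosen so the map from
latent stability s to expected PSI, `1 + Σ_k Φ((s − t_k)/σ)`, is
approximately the identity over the central stability range (verified to
within ~0.05 for s ∈ [2.0, 3.5] in the test suite). This calibration is
what makes parameter recovery meaningful on the PSI scale: an injected
−1.0 stability effect should appear as a ≈ −1.0 PSI shift. Smaller SDs
make bins nearly deterministic (the ≥99%-mass-at-the-extremes property is
tested at SD 0.1) but exaggerate mid-range PSI differences; larger SDs
compress them.

**Read allocation.** By default each sequenced read draws its motif from a
log-normal abundance distribution (dispersion 0.5, reflecting uneven NNK
cloning) and then its bin from the motif's bin probabilities. This is the
physical sorting process, and it makes the raw read fractions R_i unbiased
estimators of the bin probabilities; sorted-bin depths then emerge in
proportion to the latent bin masses, which under the stability-skewed
default preset approximate the strongly B4-weighted depth profile real
sorts produce. A fixed-depth mode (`allocation="bin"`, per-bin multinomial
over motifs at preset depths, default 400,000 reads split ≈ 9.5/11/19/60%
across B1–B4) is provided for emulating experiments with externally fixed
per-bin sequencing budgets; note that with fixed depths raw-mode PSI is
biased whenever the depths disagree with the latent bin masses, which is
why it is not the default.

**Reads.** Each read is the assembled amplicon — upstream flank carrying a
3-nt bin barcode, the 15-nt mutagenized region, a 15-nt anchor, downstream
flank (69 nt total in the default template) — with i.i.d. substitution
errors at 0.001/base by default. Indels are not simulated: the downstream
filters are exact-match, so an indel read would simply be discarded; the
substitution rate already exercises every discard rule. Quality strings
are a constant placeholder (the pipeline applies no quality filtering).
Output is byte-identical for identical seeds.

What the generator does **not** emulate: FACS gating and debris,
GFP-inactivating mutants, autofluorescence, the long sub-population tail
real reporter distributions show (the latent distribution here is a single
Gaussian), PCR amplification bias, paired-end structure, or indels.
Passing recovery tests therefore demonstrates correctness of the
estimators under a well-specified generative model, not robustness to
every artifact of real sorted-library data.

## Read processing

Filters run in a fixed order — exact 3-nt barcode lookup, zero-mismatch
consensus check outside the barcode slot and the mutagenized region,
first-exact-occurrence anchor search (the template forbids anchor
collisions upstream, making first-match unambiguous), then codon-wise
translation rejecting stop codons (TAG/TAA/TGA) and ambiguous bases. Each
read is charged to exactly the first rule it fails, so the discard ledger
partitions the input; this identity is asserted in the pipeline and the
tests. A read whose region contains an N passes the consensus check (the
region is excluded from it) and is rejected at translation as
`ambiguous-base`; an N in the checked consensus is a `consensus-mismatch`.
Coordinates are 0-based half-open throughout. No mismatch tolerance is
exposed by default.

## PSI

`compute_psi` implements the literal read-fraction definition (`raw`,
default). A `depth` mode divides each bin count by the bin's total depth
before renormalizing, the standard correction when bins are sequenced to
very unequal depths; which convention a given study used is often
unstated, so the database records which mode produced it. All-zero count
vectors are undefined and excluded rather than propagated as NaN; motifs
below the read threshold are absent, not zero rows. PSI is kept at full
float precision.

## Statistics

Group contrasts use the two-sided Mann-Whitney U test: exact enumeration
when min(n1, n2) ≤ 8 and the pooled sample is tie-free, otherwise the
normal approximation with midranks and tie correction (PSI values tie
heavily at low read counts). Cliff's delta is derived from the midrank U
as `2U/(n1·n2) − 1`, which equals the all-pairs definition
`P(X>Y) − P(X<Y)` with ties split evenly; the test suite checks this
equivalence against a brute-force all-pairs oracle on hundreds of random
tied instances. Effect sizes are reported signed and as magnitude; star
annotations are gated on p < 0.05 and tiered by magnitude
(0–0.25 `*`, 0.25–0.50 `**`, 0.50–0.75 `***`, 0.75–1.0 `****`). No
multiple-testing correction is applied — raw p-values are shown next to
effect sizes, and interpretation should lean on the latter.

Net charge counts +1 for R/K and −1 for D/E with His neutral (the
convention fixed by the worked example motifs FDEDE = −4, FRKAA = +2);
termini contribute nothing, and analyses can restrict the sum to P2–P5.
Dipeptide enrichment normalizes each PSI stratum by its size (deterministic
frequency normalization) rather than subsampling; the low-PSI dipeptide
ranking defaults to mean PSI per pair with an enrichment-ranked
alternative. The Met-aminopeptidase comparison matches four-residue
windows exactly: mean PSI of M+w motifs versus mean PSI of motifs whose
P1–P4 equal w, aggregated per first residue of w, dropping windows present
on only one side. Analyses that exclude P1 Pro (whose upstream fusion is
incompletely cleaved in the source assay) take an exclusion mask at the
call site.

## Stability predictor

Motifs are one-hot encoded into 100 binary columns, position-major with
residues alphabetical within each position block; the column order is
frozen in the model artifact and checked at load. The regressor is an
XGBoost tree ensemble with defaults n_estimators 986, max_depth 11,
learning_rate 0.085, subsample 0.904, colsample_bytree 0.810,
squared-error objective, `hist` tree method, after a minimum read-count
filter of 20 and a seeded 80/20 split. Early stopping is disabled.
Reported predictions are clamped to [1, 4] (the target is bounded);
attributions decompose the *unclamped* output, using the ensemble's exact
additive tree-path decomposition (TreeSHAP via XGBoost's
`pred_contribs`), whose baseline-plus-contributions identity is asserted
to 1e-5. Candidate selection enumerates a constrained space (a fixed
residue at one position leaves 160,000 motifs) or samples an unconstrained
one (100,000 random motifs by default, uniform over residues with an
NNK-multiplicity weighting behind a flag), ranks by predicted PSI with
lexicographic tie-breaks, and warns when fewer than k motifs pass the
threshold. Splits and training are seeded; repeated runs on one machine
configuration reproduce the training report exactly.

## Problem sizes

The analysis scripts run a 2,000-motif shared library at 200,000 reads per
genotype — enough for per-motif PSI standard errors near 0.06 and clean
qualitative recovery of every preset effect. Recovery tests and the
acceptance self-check use 20,000 motifs at ~200 reads/motif (4M reads,
counts-level simulation), at which the genotype-difference matrix recovers
a single injected −1.0 effect within ±0.1 and the predictor reaches
validation R² ≥ 0.95 on purely additive ground truth. The FASTQ-level
round trip is exercised at smaller scale where per-read processing cost
matters.

## Known limitations

* The latent-Gaussian sorting model is a deliberate simplification; real
  fluorescence distributions are heavier-tailed and asymmetric.
* PSI compresses near its bounds: effects acting on motifs already near
  stability 4 (or 1) are attenuated in PSI units, so recovery guarantees
  hold in the central range only.
* The exact-match filter cascade discards any read with a consensus error
  (~6% at 0.1%/base over the checked 54 nt); substitution errors *inside*
  the region survive filtering and register as spurious low-count motifs,
  which the read-count threshold is the intended defence against.
* Validation metrics on simulated data reflect the simulation's
  signal-to-noise, not the performance attainable on any real library.
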