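# Methods

This note documents the models, conventions and numerical choices behind
`guideeff`, and what the synthetic-data validation does and does not show.

## Sequence representation

The unit of analysis is the 30-nt gRNA + context window: 4 nt upstream,
the 20-nt protospacer, the 3-nt PAM and 3 nt downstream.  Positions are
1-based on the 30mer (PAM at 25–27); protospacer positions run N1
(PAM-distal) to N20 (PAM-proximal), so N17 is the base 4 bp upstream of
the PAM that templates the dominant 1-bp insertion.  One-hot encoding
uses channel order (A, C, G, T) and position-major flattening — both are
conventions, fixed once and used consistently for distances and model
input, so two sequences differing at m positions are exactly 2·m apart in
one-hot Hamming distance (120-dim for 30mers, 80-dim for 20-nt spacers).
Ambiguity codes are rejected rather than imputed: silently mapping N to a
base would corrupt similarity distances.

The named feature vector contains position-specific single-nucleotide
(4×30) and dinucleotide (16×29, positions 1–29, non-wrapping) indicators,
16 NGGX indicators for the bases flanking the canonical GG (Y = 30mer
position 25 = N20, Z = position 28; all zero for non-canonical PAMs),
mono- and dinucleotide counts over the 30mer, the protospacer GC count,
three segment melting temperatures, the spacer folding energy and dGB —
626 features in total.

## Thermodynamics

**Binding energy.**  `dGB = −(dG_hyb + dG_open + dG_unfold)`, all terms
kcal/mol at 37 °C, assuming a perfect-match spacer:

* `dG_hyb` — nearest-neighbor free energy of the 20-bp RNA:DNA hybrid,
  Sugimoto et al. (1995) parameters;
* `dG_open` — minus the SantaLucia (1998, unified) DNA:DNA duplex free
  energy of the protospacer against its complement (≥ 0);
* `dG_unfold` — minus the spacer folding free energy (≥ 0).

The three terms enter with unit weights; no PAM-dependent or partial
R-loop weighting is modelled.  The sign convention makes larger dGB mean
more stable binding, so weak-binding spacers (e.g. TT-rich) score low.
Dimer ΔH/ΔS tables ship as plain-text data files under
`src/guideeff/data/` and are cross-checked in the test suite against the
same published sets shipped by Biopython.

**Melting temperatures.**  Nearest-neighbor Tm of protospacer segments
3–7, 8–15 and 16–20 (1-based, inclusive), computed with Biopython's
`Tm_NN` at fixed default conditions (50 mM Na+, 25 nM each strand),
recorded in `thermo.TM_CONDITIONS`.  Only relative differences matter
for the downstream models; the salt model is not a tunable of interest.

**Spacer folding.**  The default backend is a deliberately simple
built-in folder that enumerates Watson–Crick hairpins (stem of stacked
pairs around a loop ≥ 3 nt), scores them as stack-energy sums plus a loop
penalty, and returns the best energy capped at 0.  It does not model
multibranch structures, internal loops, wobble pairs or the partition
function — for a 20-nt spacer the dominant structure is a single hairpin,
and what the pipeline needs is a deterministic, monotone proxy for
structure stability.  Users who want full secondary-structure fidelity
can plug in an external program through `ExternalFolder` (an
RNAfold-style stdin/stdout contract); the test suite exercises the
adapter when such a program is installed.

## Surrogate library design

A library member couples a 20-nt spacer with a 37-bp surrogate copy of
its target (10 up + 20 protospacer + 3 PAM + 4 down) on a 170-bp oligo:
`acca · cgtctc · aCACC · g · spacer(20) · scaffold(82) · surrogate(37) ·
GTTTg · gagacg · acgg`.  The 82-nt scaffold is a configurable constant
(default: canonical SpCas9 scaffold + 6-T terminator); only its length is
contractual, and oligo parsing is the exact inverse of assembly.
Candidate surrogates containing a BsmBI site (CGTCTC or GAGACG) are
screened out because the pool is cloned by Golden-Gate assembly with
BsmBI.  Guide finding scans both strands for 20-mers followed by NGG,
requiring the full surrogate flanks (10/4 nt); coordinates are 0-based,
half-open on the input sequence with reverse-strand hits reported in
protospacer orientation.  Exon selection, off-target ranking and vendor
formatting are out of scope.

## Indel quantification

Merged reads are demultiplexed by exact containment of the library's
spacer + scaffold (a read matching several libraries is dropped and
counted — that indicates a design collision), retained only if the edited
downstream linker signature `GTTTGAAT` follows, and reduced to the window
between scaffold and linker (the *last* linker occurrence, since a window
can contain the 8-mer by chance).  Editing calls are length-based only:
substitution-only windows of length 37 count as unedited, because
background subtraction — removing any non-reference window sequence also
observed in the unedited control — is the guard against synthesis/PCR/
sequencing artifacts.  The 37-bp reference itself is never subtracted;
unedited reads legitimately dominate the control.  Efficiency is the
percentage of reads with window length ≠ 37 (out-of-window lengths are
included in the numerator; they are reads of non-reference length, but
fall outside the 1–30-bp deletion / 1–10-bp insertion classes).  The
pool-level average indel fraction divides in-window indel reads by the
total reads of the pool.  Libraries under 200 reads are flagged excluded.
1-bp insertions are localized by left-alignment at the canonical blunt
cut 3 bp upstream of the PAM, and stratified by (N17 identity, inserted
base); windows not alignable as a single insertion at the cut are counted
ambiguous.  Paired measurement days are intersected and averaged, with
the between-day Pearson correlation reported.

## Dataset preprocessing and fusion

Seven removal criteria are applied, each labelled in the removal report:
genome presence and gene-annotation match are lookups against
caller-provided tables (no genome download is ever required — the rule,
not the resource, is the method); between-setting variance above
Q3 + 1.5·IQR of the variance distribution (quartiles by linear
interpolation); genes with < 10 designed guides; non-NGG PAMs; tRNA-
expressed guides; and loss-of-function guides targeting the last 10% of
the coding sequence.  Gene-related criteria apply only to
loss-of-function records; criteria with missing inputs are skipped with a
logged notice, never guessed.  Efficiencies not reported as indel
frequencies are rank-normalized to rank/n in (0, 1] (average ranks for
ties, order-preserving); duplicate 30mers are averaged with the max–min
spread reported.  Two datasets on compatible scales are fused by OLS of
reference on source over their shared 30mers, the source rescaled by the
fitted line and clipped to [0, 100], overlaps averaged, and the union
returned.  Fusion requires ≥ 2 overlaps with non-constant source values.

## Partitioning and test independence

Cross-validation partitions are similarity-closed: the relation "≤ 4
mismatches on the 30mer" (one-hot Hamming ≤ 8) is closed transitively by
union–find and whole clusters placed together — first any reserved test
group (plus everything recursively similar to it) pinned to the
designated test partition, then remaining clusters uniformly at random
among partitions with sufficient remaining capacity, then singletons
dealt stratified by efficiency (≤ 25th percentile, 25–75th, > 75th,
computed on the singleton set being dealt, linear interpolation, ties to
the lower stratum) via capacity-proportional largest-remainder quotas.
Sizes are near-equal (±1) unless a cluster exceeds every remaining
capacity, in which case it goes to the partition with most room and a
warning is recorded.  Independent test sets are additionally cleaned by
removing every test guide within 3 mismatches (one-hot Hamming ≤ 6) of
any training spacer — on the 20-nt spacer, not the 30mer, because context
conventions differ between source studies.

## The efficiency regressor

Implemented natively in NumPy: im2col convolutions of widths 3, 5 and 7
acting directly on the one-hot 30mer, ReLU, flatten, a fully connected
"collect" layer, concatenation of z-scored dGB (training-fold statistics,
stored with the model — raw kcal/mol magnitudes are incommensurate with
unit-scale activations), two fully connected layers with dropout, and a
single linear output trained with MSE on the 0–100 percent scale.  An
alternative placement concatenates dGB directly with the flattened
convolutions; both variants are exposed, and the collect-layer placement
is the default.  Optimization is Adam with minibatches; training stops
when validation MSE has not improved for `patience` consecutive epochs
and the best-epoch weights are restored.  Each cross-validation fold is
trained `seed_repeats` times and the lowest-validation-MSE run kept; the
ensemble prediction is the arithmetic mean over per-fold best models, and
a designated holdout partition is never touched during training or model
selection.  Reference defaults are 100 filters per width, collect 80,
FC 80/60, dropout 0.3, learning rate 1e-4, batch 500, patience 100 — all
configuration, not contract; the validation runs below use a reduced
configuration (32 filters, collect 32, FC 48/32, learning rate 1e-3,
batch 128, patience 15, ≤ 200 epochs, 2 repeats), chosen as the smallest
setup that cleanly recovers the planted signal at n = 2000.

GBRT feature analysis uses scikit-learn gradient-boosted trees
constrained to the screened hyperparameter grids (learning rate
{0.08, 0.09, 0.1}, depth {3, 5, 7}, min-split/min-leaf {5, 10, 15, 20},
trees {400, 600, 800, 1000}; off-grid values require an explicit
override), best-of-5 seeds per fold, with impurity-based (Gini)
importances averaged over fold models and renormalized to sum to 1.
SHAP analysis is a library concern and is not reimplemented.

## Synthetic data: what it does and does not show

The generator plants a deliberately simple efficiency function — a
logistic-bounded linear combination of GC fraction, dGB and folding
energy plus a PAM-proximal base effect, penalized outside the 40–90%
protospacer GC window and below −7.5 kcal/mol folding energy — mapped to
[0, 100].  Covariates are centred with fixed reference moments of random
protospacers so the planted weights have comparable leverage.  Day
replicates add independent Gaussian noise calibrated in closed form to a
requested between-day Pearson correlation (default 0.91).  Dataset pairs
for fusion relate reference to source by a known linear transform
(default 0.8·x + 7) on an overlap sized at ≈ 49 pairs for a 10,592-guide
panel, with the reference panel ≈ 1.26× the source.  Read libraries plant
edit-class counts by deterministic largest-remainder rounding (1-bp
insertions dominant, deletion frequency decaying with size, insertions
1–10 / deletions 1–30 around the blunt cut), copy N17 into 1-bp
insertions with probability 0.8, and inject shared length-changing
synthesis artifacts into both sample and control at rate 0.05 — so exact
recovery of planted efficiencies through demultiplexing, subtraction and
length-based calling is a hard equality, not a statistical statement.  A
stochastic sampling mode exists behind a flag.

Passing tests therefore demonstrate that the implementation computes its
defined quantities correctly and that the training protocol recovers
planted signal without leakage.  They do not demonstrate predictive
accuracy on real screens: the planted sequence–activity function is far
simpler than biology, real reads carry quality artifacts the generator
omits (PCR bias, quality-score structure, large deletions and
rearrangements that a 37-bp surrogate cannot capture), and chromatin
context is absent entirely.

## Problem sizes and numerical choices

The validation suite runs the quantification at 12,000 libraries × 1,000
reads (exact recovery), fusion and day-merging at a 10,592-guide panel,
partitioning at n = 2,000 (k = 6), CNN recovery at n = 2,000 with noise
σ = 8 (5 folds + untouched holdout, 2 repeats), the dGB ablation at
n = 600 over 5 replicates, and GBRT importance at n = 500 — sizes chosen
so the full run completes in a few minutes on a single CPU while keeping
every check either exact or comfortably powered.  Ties, degenerate
inputs and conventions: quartiles and percentiles use linear
interpolation; rank ties get average ranks; empty window lists are an
error (efficiency undefined); fusion with constant source values is an
error; cluster-overflow partitioning emits a warning rather than failing;
all randomness flows from explicit integer seeds and identical seeds give
identical outputs end to end.

## Known limitations

* The built-in folder underestimates structure for spacers whose best
  fold is multibranched or wobble-stabilized; plug in an external folder
  where that matters.
* dGB uses perfect-match hybridization only — no mismatches, bulges or
  off-target energetics.
* Length-based editing calls cannot see substitution outcomes or
  rearrangements beyond the 37-bp window.
* The preprocessing criteria that need external annotations (genome
  presence, gene models) are lookups against caller-supplied tables;
  the package ships no genome resources.
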