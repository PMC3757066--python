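# Methods

## Ancestral reconstruction

The ancestor of the ingroup alleles is inferred by small parsimony on a
user-supplied rooted tree whose leaves name alignment rows. The alignment is
consumed as given (this package never aligns); `-` is the only gap character
and is treated as a fifth character state, so the state space per column is
`{A, C, G, T, -}` with uniform unit substitution costs. Indel *event*
semantics (collapsing gap runs) are applied afterwards by the mutation
caller; the reconstruction itself is strictly per column, which matches the
site-granularity bookkeeping of polymorphic and ambiguous positions.

Rather than the classic two-pass Fitch heuristic, the implementation runs
unit-cost Sankoff with an inside pass (minimal mutation count of each
subtree conditioned on its root's state) and an outside pass along the path
from the tree root to the ingroup MRCA (minimal count of everything outside
the MRCA's subtree). A state is reported at the MRCA iff the global minimum
is achievable with it, so the per-column state sets are exact — verified in
the test suite against exhaustive enumeration of all internal-node labelings
on trees of up to 8 leaves. Multifurcations are resolved arbitrarily to a
caterpillar first; with unit costs the resolution cannot change any minimum.

A column is *ambiguous* when more than one state is maximum-parsimony. One
consensus row is still resolved deterministically: at an ambiguous column
the state carried by the plurality of outgroup rows wins; if still tied, the
plurality of ingroup rows; if still tied, alphabetical order with `-` last.
The full state sets and the ambiguity flags are always retained, and
`enumerate_alternates` walks the Cartesian product of ambiguous-column state
sets (consensus first, deterministic order, truncation with the true total
reported) so the robustness of downstream conclusions to reconstruction
uncertainty can be assessed the same way one tests alternate ancestral
proteins.

Two related subtleties are worth knowing. Outgroups do not merely narrow
the ambiguity at the MRCA: adding an outgroup can also *admit* states (an
ingroup split {G, T} with one C outgroup has MP set {C, G, T} at the MRCA,
each at cost 2). What always holds — and what the property tests assert —
is that at least one ingroup-only optimal state remains optimal on the full
tree, and that adding leaves never lowers the minimal mutation count.
Second, `polymorphic_cols` counts columns, so a multi-column indel
polymorphism contributes several columns; event-level counts come from the
mutation catalogue. Both granularities are exposed rather than conflated.

## Mutation catalogue

Events between the reconstructed ancestor row and each allele row are called
in the alignment frame: a column with two different bases is a substitution;
a maximal run of columns gapped on exactly one side collapses to one
insertion or deletion event. Runs never merge across kinds — a gap run
flanked by substitutions yields three events — and homopolymer-tract length
changes are ordinary left-aligned indel events. `call_mutations` asserts its
own round trip (re-applying the events reproduces the allele exactly), so a
catalogue is a lossless edit script. Core-region events are lettered A, B,
C, … in column order and flank events numbered 1, 2, …; labels restart per
catalogue, so reproducing any particular published lettering requires the
same allele set, not just the rule.

## Binding-site analysis

Sites are consensus matches, not affinity-scored hits: a window matches a
motif iff every position satisfies the IUPAC class (`TTTAY` for ABD-B,
`RNNACWAWGTNNY` for DSX by default; both strands scanned because site
polarity differs between elements). Gain/loss between ancestor and allele
maps each ancestral site window through alignment columns to the allele and
re-tests the consensus: still matching → conserved, otherwise lost;
allele-only matches are gained. A reduced-affinity variant that still
satisfies the consensus is *conserved* here by design — that finer question
is answered by `evaluate_site_after_edit`, which applies a single mutation
event and re-tests a consensus-length window anchored at the site's shifted
*end* coordinate. End-anchoring is what makes the interesting case work: a
deletion that removes the first base of a site pulls upstream sequence into
the window, and whether the site survives depends on whether that new first
base satisfies the consensus.

## RFLP genotyping and segregation

A restriction enzyme is an IUPAC recognition pattern plus the 0-based top-
strand cut offset (BstXI: `CCANNNNN^NTGG`, offset 8); only gel-visible
fragment lengths are modelled. Patterns that are not their own reverse
complement are also matched in minus-strand orientation. Genotypes are
called by exact fragment-multiset match: either parental pattern →
homozygous, their union → heterozygous, anything else → no-call (no
tolerance windows; band sizes are exact in silico). Segregation of F2
classes is tested with the plain Pearson chi-square goodness-of-fit against
an integer ratio, upper-tail p on classes−1 degrees of freedom, no
continuity correction. For the classic 25:54:23 vs 1:2:1 case this gives
χ²=0.431, p=0.806. The p-value distribution under the null is discrete
(multinomial counts); at cohort size 102 its exact Kolmogorov distance from
uniform is 0.044, which the type-I-error test accounts for by using enough
simulated cohorts for the empirical distance to concentrate.

## Activity and titration statistics

Reporter activities are replicate intensities in arbitrary units.
Normalization fixes the reference mean at 100% and reports
`100·mean(test)/mean(ref)` with `sem = 100·sd(test, n−1)/√n/mean(ref)`;
reference uncertainty is deliberately not propagated, reproducing the
per-construct “± SEM” reporting convention. A consequence worth stating: a
nominal 2-SEM interval under-covers at small n (t₅'s 97.5% point is 2.57,
and the reference's variance is excluded), so the recovery guarantees in the
tests are about the *mean* estimate over many experiments (within 2
percentage points of truth at n=6 over 500 simulations), not about
per-experiment interval coverage. Additivity of combined mutations is
assessed on the percent scale as `expected = 100 + Σ(singleᵢ − 100)`.
Titrations are per-lane detection booleans over strictly increasing protein
amounts; detection must be monotone once seen (violations are data errors,
not noise). Relative affinity is the percent ratio of minimal detected
amounts, reported at the granularity of the titration steps (two-fold here)
without interpolation.

## Synthetic data generator

The generator produces the exact structures the analysis consumes, with
ground truth recorded, emulating the study conditions: a 700 bp ancestral
element with 14 ABD-B and 2 DSX instances planted without overlap
(instances sampled uniformly from consensus-compatible strings; background
i.i.d. at GC 0.40, typical of *Drosophila* non-coding sequence), 31 ingroup
alleles and 7 ladder outgroups, and per-branch evolution with substitutions
(probability = branch length, uniform over the three alternatives) and
geometric-length indels (mean 3 bp, initiation 10⁻⁴ per site per branch).

The ingroup is shaped as two caterpillar clades joined by longer stem
branches (stem 0.008, other ingroup branches 0.0008 expected substitutions
per site; outgroup branches 0.012). The stems make polymorphisms *shared*
between alleles, which is the only way to jointly satisfy the two
study-scale conditions the preset is calibrated to: mean ingroup pairwise
identity ≈ 98% and ≈ 50 polymorphic columns in total — on a star tree those
are mutually exclusive. Across seeds the preset yields 97.4–98.6% identity,
45–62 polymorphic columns, and parsimony recovers the true MRCA sequence at
≥ 99.8% of columns.

Alignment truth is maintained by construction: every residue carries a
persistent column identity, insertions mint fresh columns, deletions drop
residues, and no realignment step ever runs — the generator tests the
caller, not an aligner. Planted motif windows are kept intact on every
branch (no substitutions or indels), modelling binding sites under purifying
selection; this mirrors the study system, in which the ancestral element
retains all characterized sites and site turnover among alleles is
essentially absent. Binding-site gain/loss calling is therefore exercised
against explicitly constructed variants rather than generator output. All
randomness derives from one integer seed with deterministic per-branch and
per-stage substreams: identical configs give byte-identical datasets.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: recombination and gene conversion, selection outside
the protected windows, rate heterogeneity along the element, alignment
error (real pipelines must align first), sequencing error, and population
structure beyond the fixed two-clade shape. F2 crosses are multinomial at
(¼, ½, ¼) with full penetrance — a single semi-dominant locus with no
misclassification. Reporter replicates are truncated-Gaussian around the
true mean with a common sd — no day effects or batch structure.

## Numerical and interface choices

All coordinates are 0-based half-open (BED convention); 1-based values
appear only in rendered reports. Lowercase FASTA is uppercased with a
warning; `.` gaps and IUPAC codes in sequence input are rejected loudly
rather than coerced. Digest cuts at coordinate 0 or at sequence length are
ignored (no empty fragments); duplicate cut coordinates from overlapping
sites are applied once. Construct outputs carry their recipe (backbone,
donor, intervals, applied events) as key=value pairs in the FASTA
description. Cloning-adapter sequences are never part of designed
constructs; comparisons against vector-cloned sequences must strip adapters
first. The pipeline writes deterministic TSV/JSON (sorted keys, fixed
column orders) and tags every failure with its stage for scripting.

Known limitations: parsimony reconstruction is only trustworthy at high
sequence identity (here ~98%); for deeper divergence a likelihood method
with explicit alternate-reconstruction testing should replace it.
Consensus-match site calling has no notion of affinity below the all-or-
nothing threshold, and the titration statistic is bounded by its step size.
The segregation test is asymptotic; at very small cohort sizes an exact
multinomial test would be preferable.
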