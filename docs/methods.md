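# Methods

`evosig` detects three per-gene signatures of adaptive evolution in a focal
lineage across a panel of species, then intersects them into "multiple signs
of adaptive evolution" (MSA) calls. This note describes the models, the
choices behind every tunable number, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## The comparative setting

The unit of analysis is the orthogroup: genes across the species panel
descending from a single ancestral gene. From an OrthoFinder-style
membership table the pipeline keeps orthogroups represented in **every**
panel species, then selects the *fuzzy one-to-one* subset — at least 75% of
species exactly single-copy and no species with more than 3 copies. The 0.75
fraction and the copy cap of 3 mirror the defaults of the KinFin tool that
popularised the fuzzy one-to-one notion; both are exposed in configuration
because no canonical values exist. Where a species contributes several
genes, the representative is the longest protein, with ties broken by the
lexicographically smallest gene ID so reruns are reproducible.

For species-tree work the per-orthogroup alignments are trimmed of columns
that are gaps in every taxon and concatenated into a supermatrix with
recorded partition boundaries. The pipeline prefers a user-supplied species
tree; if none is given it falls back to neighbor joining on
Poisson-corrected protein distances, d = −ln(1 − p) with p the mismatch
fraction over mutually ungapped sites, rooted on the declared outgroup and
with negative NJ branch lengths clamped to zero. NJ is exact on additive
distances and entirely deterministic, which is what a desk-scale fallback
should be; it is not a substitute for a maximum-likelihood tree when one is
available.

## Signature 1 — branch-site positive selection

The core statistical object is branch-site Model A over GY94 codon dynamics
on the 61 sense codons. Sites fall into four classes with
nonsynonymous/synonymous ratios:

| class | background | foreground (focal terminal branch) |
|-------|-----------|------------------------------------|
| 0     | ω₀ ∈ (0,1] | ω₀ |
| 1     | 1          | 1  |
| 2a    | ω₀         | ω₂ |
| 2b    | 1          | ω₂ |

with weights p₀, p₁, p₂ₐ = (1−p₀−p₁)p₀/(p₀+p₁), p₂ᵦ = (1−p₀−p₁)p₁/(p₀+p₁).
The GY94 generator has off-diagonal rate π_j, times κ for transitions and ω
for nonsynonymous changes; multi-nucleotide changes are instantaneous-rate
zero. The alternative hypothesis estimates ω₂ ∈ [1, 50]; the null pins
ω₂ = 1. Twice the log-likelihood difference is referred to χ²(1) — a
deliberately conservative reference at the ω₂ = 1 boundary (the 50:50
χ²₀:χ²₁ mixture is available via `mixture_null=True`). Genes pass the
signature when the Benjamini–Hochberg-adjusted p-value is below 0.05 **and**
at least one site has posterior probability of the selected classes above
0.95.

**Rate-scaling convention.** Branch lengths are expected substitutions per
codon site *for a neutral (ω = 1) site*. Each ω class evolves under the
normalised GY94 matrix for time stretched by its relative total rate
r(ω)/r(1), where r(ω) = A(κ) + ωB(κ) is the unscaled GY94 mean rate (A the
synonymous, B the nonsynonymous flow). Equivalently: one common scale
factor — the neutral mean rate — is applied to every class generator, so
purifying classes accumulate proportionally fewer substitutions and
positively selected foreground sites proportionally more. This matches the
common-scaling behaviour of standard codeml-style implementations up to the
choice of unit. The alternative convention of normalising every class
matrix to mean rate 1 individually was rejected: it makes all classes
evolve at identical total rate, so ω affects only the synonymous/
nonsynonymous composition of events and the test loses most of its power.

**Likelihood engine.** Felsenstein pruning over 61 states with columns
compressed to unique site patterns; gaps are missing data (conditional
vectors of ones, so an all-gap column contributes likelihood 1). Transition
matrices come from one symmetric eigendecomposition per (κ, ω) — the GY94
chain is reversible — and per-pattern rescaling guards against underflow,
triggered only when a pattern's conditional likelihood drops below 1e-120.
Because the foreground is a terminal branch, the foreground variant of each
class recomputes only the focal leaf's ancestors, reusing the cached
background pruning. Quantities are cached on the parameter subset they
depend on (class 1 on κ alone, class 0 on (κ, ω₀), …), which makes
finite-difference derivatives with respect to the mixture weights free.

**Fitting.** Branch lengths are taken from the input tree and held fixed —
re-estimating 2n−2 lengths per orthogroup is neither identifiable nor
affordable on few-hundred-codon alignments. Free parameters (κ, ω₀, and the
simplex coordinates a = p₀+p₁, r = p₀/(p₀+p₁), plus ω₂ in the alternative)
are maximised by box-constrained L-BFGS-B with numeric gradients,
three seeded starts per model (the alternative is additionally started at
the null optimum, which guarantees the nesting inequality in practice),
relative function tolerance 1e-9 (≈1e-6..1e-5 in lnL units at typical
alignment sizes). A derivative-free simplex was tried and rejected: it
needs several-fold more likelihood evaluations for the same optimum.
Equilibrium codon frequencies default to F3x4 estimated from the alignment
(uniform available for controlled experiments).

**Site identification.** Naive empirical Bayes at the MLE: posterior
(class | site) ∝ p_class · L_site(class); the reported value is P(2a) +
P(2b). Full Bayes Empirical Bayes (integrating parameter uncertainty over a
prior grid) is not implemented; outputs are labelled `neb_posterior` and
NEB is slightly anticonservative relative to BEB on short alignments —
site-level calls should be read accordingly.

## Signature 2 — unique substitutions with functional impact

A column carries a focal-unique substitution when every background species
has the same residue and the focal species differs. Columns are first
masked if any taxon has a gap there — or an 'X', which cannot certify
background identity — or lies within 10 columns of such a column. The
10-column flank is the study convention this pipeline implements; the
per-column (any-taxon) reading of "around any gap" was chosen as the
stricter of the two possible readings. Coordinates are 0-based half-open
internally and 1-based in every report.

Impact is scored with an alignment-derived, SIFT-style normalised
probability: with c(a) the count of residue a among the N background rows,
p(a) = (c(a) + λ/20)/(N + λ) with pseudocount λ = 1, and
score = p(focal)/max_a p(a). The score is 1 when the focal residue is among
the most common background residues and small when an unseen residue
appears at a conserved column; a substitution is impactful below 0.05,
SIFT's canonical deleterious cutoff. This is a self-contained
position-specific conservation score in the SIFT family, computed from the
orthogroup alignment itself rather than from an external homolog database
search; output rows are labelled `sift_like`, and externally computed SIFT
calls can be supplied to override it (`external`). With only ~16 background
sequences the score is coarser than a database-backed profile — it cannot
see conservation in homologs outside the panel.

## Signature 3 — root-to-tip divergence

Per orthogroup, a rooted gene tree (supplied, else the NJ fallback) gives
each species a root-to-tip distance — the summed branch lengths from root
to leaf. "Comparatively higher" divergence of the focal gene is undefined
in prose, so two rules are implemented and reported: the default,
parameter-free strict-maximum rule (flag iff focal > ratio × max of
non-focal, ratio 1.0) and a z-score rule (flag iff (focal − mean)/sd > 2).
The strict maximum is the most conservative parameter-free reading; with
zero spread among non-focal species the z-score statistic is reported as an
infinity sentinel and the flag falls back to focal > mean. Both statistics
scale-cancel, so the flags are invariant to global rescaling of the tree.

## The MSA intersection

A gene is an MSA gene when at least two of the three signatures hold.
Genes absent from a signature table count as negative for it; duplicate
(orthogroup, gene) rows are an error rather than silently merged. The
summary reports per-signature totals plus all seven exclusive Venn cells,
checked in tests against explicit set algebra.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular genome. Species trees are coalescent-style ultrametric
topologies rescaled to a root-to-tip depth of 0.5 neutral substitutions per
codon site, with lognormal (σ = 0.15) per-branch rate jitter so depths vary
as real species trees do; the focal lineage joins only among the last few
coalescences, emulating a focal species without close relatives in the
panel, and the outgroup attaches at the root. Defaults are a 17-species
panel, 300-codon genes, κ = 2, ω₀ = 0.2, p₀ = 0.75, p₁ = 0.15 (so 10% of
sites sit in the selected classes), uniform codon frequencies; F3x4
frequencies, when requested, are drawn once per fixture set from Dirichlet
nucleotide frequencies per codon position and recorded in the truth.

Codon evolution is simulated by Gillespie event sampling along every
branch — never by drawing from matrix exponentials — so exact per-branch,
per-site substitution counts exist; tests use them as an event-count oracle
(e.g. a neutral site on a branch of length 0.5 must average 0.5 recorded
events). Planted focal-unique substitutions replace the focal codon in
background-invariant, gap-free columns with a sense codon translating to a
different residue, keeping the codon and protein views consistent. Gaps are
injected per (taxon, column) cell independently at the configured rate;
planted columns and a configurable clearance around them (default 10) are
protected so planted truth stays recoverable. Truth files record site-class
labels, planted columns, the rate-acceleration flag, the true parameters
and the per-branch event counts.

What the generator does **not** emulate: indel evolution (gaps are
missing-data noise, not an evolutionary process), sequencing or assembly
error, alignment error, paralogy mixed into orthogroups, and rate variation
beyond the branch-site class structure. Passing the planted-signal tests
therefore demonstrates that the detectors recover the signals they define,
under the model they assume — not that those signals are unconfounded in
real genomes.

## Calibration and problem sizes

The validation suite measures, amongst others: the pruning likelihood
against exhaustive enumeration over internal-state assignments (50 small
alignments, relative error ≤ 1e-8); the LRT's type-I error on 100 null
simulations (8 taxa, 300 codons, focal branch 0.3 — rejection at α = 0.05
must stay within two binomial standard errors of 0.05, and is in practice
well below, χ²(1) being conservative at the boundary); power ≥ 0.6 on 100
simulations at ω₂ = 8 (measured ≈ 0.9); perfect recovery of planted unique
substitutions on gap-free fixtures; divergence-flag recall ≥ 0.9 at a 3×
focal rate multiplier; and byte-identical reruns of the full pipeline on 20
orthogroups. These sizes keep the full suite comfortably inside a desk-scale
run while leaving the conclusions unchanged at larger n.

## Known limitations

- NEB, not BEB, for site posteriors; site lists on short alignments are
  anticonservative.
- Branch lengths fixed at input values; a misspecified input tree biases
  both the LRT and the divergence flags.
- The sift_like impact score sees only the panel's alignment, not external
  homology.
- The divergence "max" rule is sensitive to the jitter of a single longest
  non-focal lineage; the z-score alternative trades that for a
  distributional assumption.
- One gene per species per orthogroup is tested (the longest); additional
  focal paralogs in fuzzy orthogroups are not separately tested.
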