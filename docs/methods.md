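# Methods

## Model

A regulatory triplet (RF1, RF2, T) is modelled as a two-input one-output
Boolean gate: the binarized activities of the regulators are the inputs,
the target's binary state the output. There are 2⁴ = 16 such gates; each is
identified by its truth-table output vector over the input combinations
v₁=(0,0), v₂=(0,1), v₃=(1,0), v₄=(1,1) and carries a canonical algebraic
expression (`T=RF1*RF2`, `T=~RF1+RF2`, …) used verbatim in all output
tables, with the electronics names (AND, OR, XOR, NAND, NOR, XNOR) as
aliases. Gate ids order the 16 gates as the 4-bit integer of the output
vector read MSB-first; this fixed ordering makes all outputs reproducible.
Note the truth table (1,0,0,0), `T=~RF1*~RF2`, is NOR (not NAND) by
De Morgan; the package uses the standard names.

The model assumes (i) binary regulator activity is a usable proxy for
regulatory input — appropriate when expression is strongly bimodal across
samples; (ii) the two regulators jointly determine the target up to
sample-independent noise; and (iii) samples are exchangeable (no
time-series structure is used). Triplets violating these assumptions —
more than two effective regulators, dose-dependent response — tend to come
out gate-inconsistent, which is the intended negative result.

## Scoring

For binary vectors x, y, z over m samples, mᵢ counts samples with inputs
vᵢ and nᵢᵍ those among them whose target equals gate g's output fᵍ(vᵢ).
Laplace's rule of succession gives sᵢᵍ = (1+nᵢᵍ)/(2+mᵢ) and the
consistency score Cᵍ = Πᵢ sᵢᵍ ∈ (0,1]. The smoothing penalizes gates
distinguished on few observations; with mᵢ = 0 everywhere every gate
scores (1/2)⁴ = 1/16, the chance level for 16 gates. The unique maximizer
of Cᵍ is the matched gate; any tie at the maximum (equivalently, a
per-combination majority tie 2nᵢ = mᵢ, since the product factorizes over
combinations) yields "inconsistent".

Numerical choice: all 16 scores share the denominator Π(2+mᵢ), so the
implementation compares the integer numerators Π(1+nᵢᵍ) and reports exact
`fractions.Fraction` scores. Tie detection is therefore exact; file output
rounds to a configurable precision (default 6 decimals). An optional
minimum-score cutoff (default off) additionally marks low-scoring unique
maxima as inconsistent; no cutoff is imposed by default because none is
canonically defined.

Samples with a missing value in any of a triplet's three genes are dropped
for that triplet only, keeping per-triplet m maximal without imputation.

## Binarization

Per gene, the exact 1-D 2-means partition is found by scanning all n−1
sorted-order split points with prefix sums (O(n log n)); the higher-mean
cluster codes 1. This is deterministic and affine-invariant, unlike seeded
k-means. Degenerate inputs: constant genes are coded all-0 (0 = low
expression) and flagged "uninformative"; triplets touching them are
skipped with a logged count. Ties among split costs take the first minimal
split in sorted order. Already-binary input is accepted verbatim after
validation. Two preprocessing modes are provided for continuous data:
per-sample z-scoring of log(x+1) (abundance data) and per-sample mean
centering (log-scale time courses).

## Permutation filter

For a matched triplet, the target is replaced M = 1000 times (configurable)
by a gene drawn with replacement from all genes in the binarized matrix
except RF1, RF2 and the target; the permutation score is the fraction of
replacements whose own match is gate-consistent *and* equal to the original
gate. Calls with score ≥ 0.1 (configurable) fail the filter. A replacement
counts only if it passes the tie check itself — consistency and gate
identity are both required. The pool definition ("any other gene, with
replacement") is the package's choice; the procedure is deterministic
given a seed.

## Enrichment

Gate enrichment of a triplet subset uses the hypergeometric strict tail
Σ_{i=k_g+1}^{k} C(K_g,i)C(N−K_g,k−i)/C(N,k) — the probability of strictly
exceeding the observed count. The strict form is the package default for
fidelity to the method's original definition even though the conventional
one-sided test is inclusive (P(X ≥ k_g)); `tail="inclusive"` switches.
Note the strict tail is exactly 0 when the subset saturates (k_g = k).
Raw p-values are reported (no multiple-testing correction by default).
The background N should be the scored triplets of the same regulator-class
combination as the subset.

## Feed-forward loops

A triplet is an FFL when the edge RF1→RF2 exists, evaluated on the
assigned role order only (the definition is directional); the reverse edge
is reported separately. Role assignment is deterministic lexicographic by
default (rf1 < rf2), with an opt-in seeded random assignment for analyses
of symmetric gate pairs; when the two regulators' classes differ, the
non-TF (miRNA or distTF) always takes the RF1 slot. A static annotation
table maps gates to coherent FFL types (1, 2, 4) as interpretation, not
computation.

## Motif scanning

Promoters are fixed windows upstream of the TSS (0-based half-open;
plus strand [TSS−w, TSS), minus strand the reverse complement of
[TSS, TSS+w)), clipped at chromosome bounds. A length-L PWM window scores
the sum of per-position weights of observed bases; a hit requires the
min-max-normalized score (score − S_min)/(S_max − S_min) ≥ 0.8 by default.
The min-max convention is well defined for any weight sign (raw counts or
log-odds); the alternative reading 0.8·S_max is available as
`threshold_mode="absolute"` but breaks for negative weights. Both strands
are scanned by default (promoter motifs are orientation-ambiguous);
windows containing N never hit. A gate-consistent triplet with zero hits
for exactly one regulator is classified `rf1_indirect`/`rf2_indirect` — a
candidate for protein-protein-interaction-mediated regulation; PWM
construction (counts vs log-odds) is left to the user, as weights are used
as given.

## Synthetic data

The generator plants a known gate per target: regulator states are i.i.d.
Bernoulli(input_p), the target is the gate function of its two regulators
with each bit flipped independently with probability ε (symmetric bit-flip
noise — the simplest corruption model that exercises the score's
robustness). Defaults are 60 samples, input_p = 0.5, ε = 0.05, matching
the regime the method is characterized under; continuous mode emits
Normal(μ_b, σ) per bit with μ₁−μ₀ = 4σ. Ground truth is always written
alongside the fixtures. What the generator does *not* emulate: correlated
regulators, unbalanced on/off marginals, asymmetric noise, batch effects,
dropout, and >2 effective regulators per target — so passing recovery
tests demonstrates correctness of the matcher under the model's own
assumptions, not performance on real expression data.

Under these defaults, planted input-sensitive gates are recovered in well
over 90% of replicates and the permutation filter retains essentially all
correct calls while fewer than 10% of random target replacements reproduce
a call. At ε = 0.5 the target is independent noise and recovered gates are
near-uniform over the 16 — the calibration check. Note that an independent
noise target is still gate-consistent with *some* gate in roughly
two-thirds of draws at m = 60 (a per-combination majority tie has
probability ≈ 0.1 per combination); consistency alone is therefore not
evidence of regulation, which is why the permutation filter and the score
magnitude matter.

One statistical subtlety in testing the binarizer: for a two-Gaussian
mixture the per-sample Bayes error at 4σ mean separation is Φ(−2) ≈ 2.3%,
so ≥99% label recovery needs ≈5σ; the recovery test uses 5σ while the
continuous generator keeps 4σ (where the round-trip criterion is relative,
not absolute).

## Problem sizes

Test and acceptance runs use desk-scale problems chosen to make the
statistical assertions sharp: 1000 replicates per gate for recovery, a
60-triplet planted dataset with a 300-gene noise pool and M = 200 for the
permutation study, exhaustive enumeration up to N = 10 for the
hypergeometric oracle, and networks of ≤ 10 regulators elsewhere. Genome-
scale datasets (tens of thousands of triplets) run through the same code
path; runtime is dominated by the permutation filter, which is linear in
M × triplets.

## Known limitations

- Two-input gates only; triplets sharing a target are scored independently.
- The score compares gates relatively; absolute calibration (what score is
  "high") depends on m and is left to the permutation filter.
- Binarization assumes bimodality; graded responses lose information.
- FFL coherent-type annotation is a static lookup, not computed from edge
  signs.
- The motif module does not look up protein-protein interactions; it only
  flags candidates.
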