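# Methods

## The recombination model

A pool is a multiset of sequences over a declared alphabet (default ACGU).
One recombination round consists of a hydrolysis pass followed by a ligation
pass.

**Hydrolysis.** Each molecule of length *L* is cleaved independently with
probability `hydrolysis_rate`. The breakpoint is a bond index drawn from
𝒩(*L*/2, σ), rounded to the nearest integer and clipped to [1, *L*−1];
clipping (rather than resampling) is used because its effect is negligible
for σ ≤ *L*/4 and it keeps the draw count fixed. σ defaults to *L*/6, which
places ≈99.7% of draws inside the strand; it is an exposed parameter because
no canonical value exists for the breadth of near-midpoint cleavage. Each
molecule is cleaved at most once per round.

**Ligation.** Fragments shorter than `min_ligatable_length` (default 3 nt,
i.e. only molecules longer than two nucleotides react) are inert. Each
eligible fragment, visited in random order, initiates a ligation with
probability `ligation_rate`; its partner is drawn from the union of the
remaining eligible fragments and the uncleaved survivors, choosing the class
with probability proportional to its current size and uniformly within the
class. Partners are consumed — sampling is without replacement and ligation
is single-pass, so a molecule participates in at most one joining event per
round. The partner is concatenated 3′ of the initiator; orientation
randomization is off by default. A fragment cannot ligate to itself (the
physical molecule), but it can ligate to another copy of the same sequence.

These choices (single-pass, without replacement, class-proportional partner
choice) are the simplest consistent reading of a population-weighted random
ligation step; alternatives such as iterative ligation rounds can be emulated
with the explicit `rounds` argument of `simulate_recombination`.

**Conservation.** Cleavage and ligation move residues between molecules and
never create or destroy them, so Σ length×copies is exactly invariant across
a round. This is asserted as an integer identity in the tests.

**Diversity.** The Shannon index D = −Σ nᵢ log₂ nᵢ over unique-sequence
proportions is computed before and after the round; ΔD is the reported
outcome. D is 0 for a monomorphic pool and log₂ N for a uniform pool of N
unique sequences. `delta_D_grid` averages ΔD over replicates with a fresh
random pool per (cell, replicate), seeded from a single master
`SeedSequence`, so grids are reproducible bit-for-bit.

Default grid conditions follow the redundant-pool scenario: N20 4-letter
cores, 1000 unique sequences at 100 copies each (10⁵ molecules), a 5×5 rate
grid over {0.2, …, 1.0}² and 10 replicates per cell. Simulating the full
4²⁰ sequence space is impossible, so redundancy is emulated by a sampled
subset of uniques at the stated copy number, with `n_unique` exposed.
At these sizes one grid takes on the order of two minutes on a single core.

## Synthetic pools and products

`PoolSpec` describes the pool designs used throughout: fully random cores
(N20), semi-random bait (5′ constant flank, e.g. C1₂₀-N₂₀) and prey
(N₂₀-C2₂₀), homopolymer tails (A₁₀), and a `blocked5` flag modelling a 5′
label that prevents a molecule from acting as a ligation acceptor.

`make_products` forms concatenation products: a donor ("bait" role) truncated
at its 3′ end joined to a full-length acceptor ("prey" role) — acceptor
length is always preserved, reproducing the truncation-ladder asymmetry of
sequenced products. The truncation prior is geometric over cut offsets with
p = 0.8 by default, so ~80% of products are direct full-length × full-length
ligations, matching the dominance of direct 20+20 joins in sequenced product
bands; the family and parameter are configurable.

The junction-dinucleotide bias is applied by rejection sampling on the joint
(donor, truncation, acceptor) proposal: a proposal with junction context
(N₋₁, N₊₁) is accepted with probability weight/max-weight. The accepted joint
law is therefore exactly the truncation prior tilted by the bias, which gives
a closed-form marginal: with uniform cores, a weight w on CpN yields
P(N₋₁=C) = (w/4)/(w/4 + 3/4), i.e. an odds ratio of exactly w against the
input-pool background. Parameter-recovery tests exploit this identity, always
measuring enrichment against the *empirical* input-pool composition (finite
pools deviate from 0.25 per base, and the fingerprint analysis compares
against the unligated input for the same reason). Absolute per-dinucleotide
rate constants are not modelled.

`attach_quality` injects uniform substitutions (errors get low Phred scores)
and optional low-quality 3′ tails, returning reads plus a truth table; the
quality-filter tests check survivor sets against these labels exactly.

What the generator does **not** emulate: hybridization-driven proximity (the
mechanism that creates the junction bias in real pools), sequencing indels,
position-dependent error rates, PCR amplification bias, and chimeric
artefacts. Passing tests therefore demonstrate that the analyses recover
known statistical structure from reads with that structure — not that real
libraries are free of confounders.

## Read preprocessing

Quality filtering keeps a read iff (#bases with Q ≥ `min_q`) / length ≥
`min_fraction`, with the boundary inclusive (9/10 at Q ≥ 20 passes a 90%
filter) — fastx-toolkit semantics for the standard "90%, Q20" setting.
Quality encoding is fixed to Phred+33. Collapsing returns counted records
sorted by descending count then lexicographically. Flank trimming is
terminus-anchored with Hamming mismatches only (constant regions are
fixed-length, so indel-aware alignment is unnecessary); untrimmable reads
pass through flagged. T and U are both accepted and not converted unless
asked.

## Nucleotide signatures and fingerprints

Frequency profiles require equal-length record sets (split by length first;
the length histogram doubles as the product-size distribution). The RGB
signature per position is R = 255(1−f_C−f_A), G = 255(1−f_C−f_U),
B = 255(1−f_A−f_G−f_U), kept real-valued and clipped to [0, 255]; rounding
(half-up) happens only at image export, since e.g. a uniform composition maps
to (127.5, 127.5, 63.75). Pure compositions render C-blue, U-red, A-green,
G-yellow.

The junction fingerprint tabulates (N₋₁, N₊₁) frequencies at a stated 1-based
bond index. Enrichment is log₂(observed/expected) with the expectation taken
as the outer product of the background profile at the two junction-adjacent
positions (independence assumption); the background should be the unligated
input pool when available, else uniform. Because it is unsettled whether a
difference or a ratio panel is the better visualization, both are emitted.
Contexts observed on a zero background are flagged separately rather than
folded into the log ratio.

## Folding and structure profiles

The internal folder maximizes base-pair count (Watson–Crick + G·U wobble,
min hairpin loop 3) over nested structures by dynamic programming. The
traceback is deterministic: within each interval the 5′ base is paired with
the smallest admissible partner achieving the optimum, else left unpaired.
Pair-count maximization is *not* an energy model; it serves as a
self-contained, deterministic structure source for profiles and as a test
oracle (verified against exhaustive enumeration for short sequences). True
MFE structures and energies come from an external backend (command template,
e.g. `RNAfold --noPS`) whose absence raises a clear capability error; all
profile operations equally accept precomputed dot-bracket files.

Structure profiles report per-position frequencies of opening pairs (paired
downstream), closing pairs (paired upstream) and unpaired bases; comparisons
report experimental − mean(synthetic) with the replicate standard deviation.
Energy distributions are summarized (mean, sd, histogram) with the negated
pair count as a stability proxy when no energies are present; cross-pool
stability claims are reported, not asserted.

## Motif scanning

Submotifs are local element patterns over `( ) . p N` (`p` = either paired
state). The published 25-motif/408-submotif catalogue is not reproducible
from text, so a parametric generator spans the described space — one strand
of an a-base internal loop flanked by h-nt helices (`p^h .^a p^h`, a ∈ 1..6,
h ∈ 1..4) plus hairpin loops — with the J (four unpaired bases flanked by
3-nt helices) and H patterns predefined. Matching requires the junction bond
strictly inside the motif span and the span within a window (default 10 nt)
of the junction; matches record which intra-motif bond carries the junction.

Ligation profiles are normalized *within* each motif (Σ bond frequencies = 1),
with cross-motif abundance reported separately, since cross-motif
normalization conventions vary; bonds exceeding a configurable fold (default
2×) of the motif's unpaired-region mean frequency are flagged as enriched.
Consensus extraction uses a pseudocounted PWM with per-column information
content IC = 2 − H bits, replacing an external discriminative motif finder
with a deterministic, self-contained equivalent adequate for anchored
windows.

## Kinetics

Ligation time courses are fit by least squares to the pseudo-first-order form
y(t) = plateau·(1 − e^(−k·t)), with k ≥ 0 and plateau ∈ [0, 1] enforced as
bounds (estimates at a bound are flagged). The single-exponential form is a
design choice — reversible or biphasic schemes are out of scope. A flat
all-zero series returns plateau 0 with the rate flagged indeterminate.
Under the simulation study conditions (8 timepoints over 50 time units,
additive Gaussian noise with sd = 5% of the plateau), the median relative
error of k across 100 replicates is well under 20%.

## Pipeline and seeding

`run_pipeline` executes all stages on a self-generated synthetic dataset.
One master seed is split into per-stage seeds via `numpy.random.SeedSequence`
spawning in a fixed stage order; all tabular outputs are TSV with a units
comment, and the manifest lists every output with its SHA-256, so identical
configs produce byte-identical outputs. Stage failures abort with the stage
name. Default pipeline sizes are deliberately small (hundreds to thousands
of reads) so an end-to-end run finishes in seconds; analysis-scale runs set
the sizes in the config.

## Known limitations

- The simulator is sequence-agnostic: cleavage and ligation probabilities do
  not depend on sequence or structure, so the CpN junction preference is an
  analysis-side observation only, never a simulator rule.
- Circular, lariat and branched products are not modelled.
- The internal folder's pair-count objective differs from free-energy
  minimization; profiles built with it are internally consistent but not
  comparable to MFE-derived profiles.
- Experimental effect magnitudes (band yields, exact CpN enrichment levels)
  depend on the original sequencing reads and are emulated only qualitatively
  by the synthetic generator.
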