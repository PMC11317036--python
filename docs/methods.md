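# Methods

## The measurement system

The package models a controlled primer–template interaction assay. Ten
synthetic templates share one backbone and differ only at three positions
inside the 20-base forward priming site — at offsets −14 ("5′"), −8 ("M")
and −2 ("3′") from the primer's 3′ end — and inside a 12-base recognition
window placed at 1-based offset 99 from the start of the priming site.
Sixty-four primers cover all 4³ base combinations at the same three
positions. Because each priming-site variant is linked bijectively to a
unique recognition sequence, a sequencing read carries two independent
pieces of information: which template was copied (recognition window) and
which primer sequence it bears (first 20 bases). Comparing the two yields
the read's mismatch profile (0–3 mismatches, each with a position label and
an annealing pairing written primer-base–antisense-template-base).

The reference template's priming site is `GGACTACCAGGGTATCTAAT` (variant
triple C/T/A). Primers V1–V9 are the nine single mismatches to it, in the
fixed order 5′: G, T, A; M: A, C, G (pairings A-A, C-A, G-A); 3′: C, G, T —
the 3′ base order is alphabetical because no published order exists for it.
V10–V36 are the 27 double mismatches and V37–V63 the triple mismatches,
each group in row-major A<C<G<T enumeration order; this makes the bundled
"pool 27" exactly V10–V36. Template STi carries Vi's triple, so the
ten-primer pool contains exactly one perfect match per template.

Recognition sequences are drawn by seeded rejection sampling until all
pairwise Hamming distances are ≥ 4 (budget 10,000 attempts per slot, then a
hard error naming the constraint). The backbone interior is seeded-random
and shared by all templates; its content is irrelevant to every computation
here, only its constancy matters. The amplicon is 250 nt so a 2×153 read
pair merges with ample overlap. All window coordinates are 1-based
inclusive and counted from the first base of the forward priming site; the
recognition window length defaults to 12 (offset 99, occupying 99–110) and
both values are overridable where the 11-base reading (99–109 inclusive) is
preferred.

## Annealing-efficiency model

A primer–template pair anneals with efficiency
`e = Π penalty(position, T, pairing)` over its mismatches; a perfect match
has e = 1. Penalties live in (0, 1] and are keyed by position label,
temperature and pairing, with a positional fallback when a pairing has no
specific entry. The default calibration comes from equimolar head-to-head
competition, where a single mismatch with penalty p produces an expected
mismatch-to-match ratio of exactly p. Defaults (position @temperature):

| position | 45 °C | 55 °C |
|---|---|---|
| 5′ (−14) | 0.65 | 0.21 |
| M (−8)   | 0.54 (C-A pairing: 0.36) | 0.155 (C-A pairing: 0.10) |
| 3′ (−2)  | 0.13 | 0.01 |

These are midpoints of measured per-position ranges, with the
middle-position C-A pairing pinned to the low end of its range (the clear
outlier among M pairings). Multiplicative composition across multiple
mismatches is a model assumption — no composition rule has been measured —
and a user-supplied penalty table can override any entry. Temperatures
other than 45/55 °C raise an explicit model error rather than
interpolating.

## Amplification dynamics

**DePCR.** Copy events pair one template molecule with one primer with
probability ∝ template proportion × primer proportion × efficiency. The
recorded (primer, template) identity is fixed at the copy event; the
subsequent barcode-attachment cycles and linker-driven exponential
amplification only propagate it, so reads are multinomial draws from the
event distribution (only error injection can corrupt them afterwards).
Reverse priming uses a constant site shared by all templates and is modeled
as efficiency 1.

**Standard PCR.** Molecule classes are (origin template, priming-site
state); a copy's site state is the variant triple of the primer that
founded its lineage's most recent forward strand. Cycles 1–2 copy original
templates with the DePCR rule; from cycle 3 every copy is re-copied once
per cycle by a pool primer — chosen ∝ primer proportion in `neutral`
scrambling mode, or ∝ proportion × efficiency against the copy's site state
in `penalized` mode, where poorly primed states also replicate more slowly.
Originals keep contributing one linear copy generation per cycle.
Dynamics are propagated as expected values (a 640-class linear recursion),
which keeps 28 cycles exact and cheap; replicate-to-replicate variation
enters through independent multinomial read sampling, one numpy Generator
stream per (seed, replicate, purpose). Primer concentrations are treated as
non-limiting and no saturation ceiling is applied; neither is needed for
any quantity computed here. PCR drift beyond multinomial sampling,
melting-temperature thermodynamics, chimeras and elongation kinetics are
out of scope.

In neutral mode the total-variation distance between copy-site-state usage
and the input primer proportions halves every cycle once exponential growth
starts, reaching < 0.02 well before 28 cycles — this is the quantitative
form of "scrambling".

## Reads and errors

Merged-mode reads span the amplicon and begin at the forward priming site
(linkers are trimmed; a literal CS1-prefix trim is applied to external
reads). Substitution errors are independent per base, uniform over the
three alternative bases. In DePCR the primer region is itself a polymerase
copy, so errors may hit it; in standard PCR the first 20 bases are the
synthetic oligonucleotide and are emitted error-free while downstream bases
receive errors. Error presets: `MT-like` 0.010/base (non-proofreading
polymerase, unmodified primers) and `DT-like`/`QB-like` 0.004/base
(phosphorothioate-protected primers), loosely anchored to measured
cumulative error ranges of roughly 0.74–1.4% and 0.27–0.66% over the first
100 bases. Qualities use a two-tier synthetic model (Q38 head, Q28 tail);
they carry no error information and exist to exercise the quality filter.
Paired emission splits the amplicon into overlapping 2×153 reads; the
merger scores every gap-free overlap (matches − mismatches, mismatch
fraction ≤ 0.25, minimum overlap 12) and resolves overlap disagreements
toward the higher-quality base.

## Classification and matrices

Matching is exact by design: bases 1–20 must equal a known primer core
(`full_primer` mode) or match at the three variant positions
(`variant_positions` mode), and the recognition window must equal a known
recognition sequence. No error tolerance is applied; the ≥ 4 Hamming
separation makes matches unambiguous. Reads are checked primer first, then
recognition; pairs whose primer or template is outside the experiment's
declared pools are excluded (`excluded_not_in_design`), and every input
read is accounted for in a per-status sidecar. The quality filter keeps
reads with mean Phred ≥ 20, inclusive (a per-read mean, the conventional
reading of a "minimum quality 20" filter).

Counts form a replicates × (primer, template) matrix, serialized as TSV and
as minimal BIOM v1.0 JSON. Rarefaction subsamples each row without
replacement (multivariate hypergeometric) to depth 7,000 by default;
replicates below depth are dropped and recorded, never resampled. Exclusion
of out-of-design pairs happens before rarefaction. Default reads per
replicate (20,000) keeps rarefaction always feasible. Template and primer
margins are sums over the other id.

## Metrics

`IS = Σ |100·oᵢ − 100·eᵢ|` on proportion vectors, range 0–200, equal to
200 × Bray–Curtis; percent units reproduce the published 0–200 scale. The
expected vector is the *input pool's* proportions (so an uneven 1:2:4:8
staircase reproduced exactly scores 0); a uniform-expectation variant is
available via `expected="uniform"`. ITS uses template margins (higher =
more distortion of the input template ratios), IPS primer margins (higher =
more selective primer use). The mismatch ratio divides reads on mismatched
pairs by reads on perfect-match pairs; a row with mismatches but no perfect
matches yields a typed infinity sentinel serialized as `"Inf"`, never a
float overflow. Error profiling aligns reads gap-free against their known
truth reference (indels are outside the error model) and averages
per-position mismatch rates over the 1-based inclusive windows 1–20
(primer), 21–40 and 41–100. Ordination is classical principal-coordinates
(Gower double-centering + eigendecomposition, axes ordered by eigenvalue,
each axis signed so its first nonzero loading is positive). Alpha diversity
is Shannon (natural log) and richness.

## Statistics and reporting

Group comparisons use Welch's unequal-variance t-test (two-sided,
Welch–Satterthwaite df, no multiple-comparison correction) and, for ≥ 3
groups, one-way ANOVA followed by Tukey's HSD. Stars follow the five-level
convention: ns (p ≥ 0.05), * (< 0.05), ** (< 0.01), *** (< 0.001),
**** (< 0.0001). Report bundles are pure functions of the manifest and
metric tables (sorted keys, no timestamps), so regeneration is
byte-identical and the manifest hash is a complete provenance record.

## What the generator does and does not emulate

The synthetic system reproduces the combinatorial design, pool
compositions (A–E × 1/9/10/27/64, eight technical replicates, 28 standard
cycles vs 2 linear DePCR cycles, 45/55 °C), exact-match classification and
all downstream metrics. It does not contain real sequencing artifacts
(quality-dependent miscalls, indels, chimeras), polymerase kinetics, or
primer depletion. Passing tests therefore validate the *pipeline and the
model's internal consistency* — closed-form event probabilities, round-trip
identity between simulator and classifier at zero error, penalty recovery
from head-to-head counts — not the biochemical accuracy of any particular
penalty value on real reactions.

## Numerical and design choices

- Problem sizes: simulation-based tests use 10³–10⁵ reads per condition,
  chosen so binomial/total-variation bounds (3–4σ) are tight enough to
  detect real defects while the whole suite stays fast.
- Stochastic assertions use explicit standard-error bounds (binomial,
  delta-method for ratios, hypergeometric for rarefaction) rather than
  loose ad-hoc tolerances.
- Under the multiplicative penalty model the DePCR-vs-standard ITS ordering
  holds design-by-design for B10 (both temperatures) and for B27/B64 at
  45 °C; it is an exact tie for B1 (one primer leaves no copy competition)
  and inverts for B27 at 55 °C, where the extreme 3′ penalty (0.01) makes
  the two-cycle DePCR margin more distorted than the growth-flattened
  standard-PCR margin. Aggregated over the B series the ordering holds at
  both temperatures, which is the form the acceptance suite asserts. This
  is a known limitation of composing extreme penalties multiplicatively;
  measured complex-pool behavior is flatter than the model predicts there.
- Rarefaction, recognition-set generation and all simulators are
  deterministic per seed; per-replicate streams derive from
  (seed, replicate index, purpose) so replicates are independent yet
  reproducible.
- Degenerate inputs fail loudly with typed errors (all-zero abundance
  vectors, empty matrix rows, zero-variance t-tests, infeasible Hamming
  constraints, unknown temperatures).
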