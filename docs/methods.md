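# Methods

This note records the model behind `entromatch`, the conventions the
implementation commits to where the underlying methodology leaves room,
and what the synthetic test conditions do and do not demonstrate.

## The selection model

The premise is that the cost of exact string matching depends not only
on the algorithm but on the *searched pattern's* statistical structure.
`entromatch` quantifies that structure with the Shannon entropy of the
pattern's character frequencies, H = −Σ p_c log₂ p_c (bits, all
characters significant including case, spaces and punctuation), and
quantifies cost with the character-comparison count (CC): the number of
pattern-character vs text-character equality tests an algorithm executes
while scanning.  CC is independent of hardware, language and compiler,
yet tracks running time for comparison-based matchers.

Model building runs a campaign — every pattern searched with every
selected algorithm on the domain text — then:

1. rounds each pattern's entropy to 2 decimals (half away from zero) and
   discretizes the distinct rounded values into C equal-width classes,
   C = round(2·n^(1/3)) with n the number of distinct values, width
   h = (max − min)/C;
2. per pattern, places each algorithm in a quartile of the pattern's CC
   spread across algorithms;
3. per (class, algorithm), computes the share of the class's patterns
   falling in each quartile (shares sum to 1 per algorithm within a
   nonempty class);
4. ranks a class's algorithms by descending first-quartile share, with
   q2, q3, ascending q4 and finally the algorithm identifier as
   tie-breaks.

Prediction for an unseen pattern is entropy → rounded entropy → class →
that class's ranking; values outside the model's entropy range take the
nearest (first or last) class so prediction always resolves.

## Matcher implementations and the CC convention

The seven matchers follow their textbook formulations: BF scans each
window left to right; MP and KMP use the weak and strong failure
functions; BM combines the bad-character and good-suffix rules with a
right-to-left window scan; Horspool keeps only the bad-character rule
keyed on the window's last text character; Quick Search scans left to
right and shifts on the character just after the window.  No sentinel or
guard tricks are used, so counts reflect the published control flow.

Counting scope: **only scan-phase pattern-vs-text equality tests count**,
each success or failure as 1.  Preprocessing (failure functions, shift
tables, suffix tables) compares pattern characters with pattern
characters and is excluded — CC measures text-touching work.  Offsets
are 0-based and all occurrences, including overlapping ones, are
reported; a pattern longer than the text yields no occurrences and zero
comparisons.

The Apostolico–Crochemore matcher is implemented from its defining
factorization: write the pattern as a^ℓ·b·u (a the first character, ℓ
its initial run length, b ≠ a), compare within an attempt in the order
ℓ…m−1 and then 0…ℓ−1, and remember across shifts how many of the
leading a's are already verified so they are never re-compared.  Because
published sources disagree on minor dialect details, the shift logic
here is derived and proved from the scan invariants: after forward
progress to position i, the only window starts below i−ℓ that can
survive are re-occurrences of the head a^ℓ·b inside the pattern
(precomputed); the immediate-mismatch case shifts by one and decrements
the prefix memory; the forward-knowledge pointer resets conservatively
after interior shifts (costing only re-comparisons, never correctness).
Unary patterns a^m use the prefix-memory slide directly.  Occurrence
equivalence with a naive oracle is enforced by property tests across
thousands of random cases; CC counts are deterministic by construction.

## Quartile convention

With seven CC values there is no canonical quartile map, so the package
declares one: Q1/Q2/Q3 are the medians of the lower half, the full set
and the upper half of the pattern's CC values, halves *excluding* the
overall median when the count is odd (for values 10…70 by tens:
Q1 = 20, Q2 = 40, Q3 = 60).  An algorithm falls in the first quartile
whose threshold its CC does not exceed; ties share the lower quartile.
Consequences worth knowing: several algorithms can occupy quartile 1 for
the same pattern (with 7 values the two cheapest always do), and a
strictly CC-minimal algorithm always accrues a first-quartile share of
1.0.  It is ranked first outright whenever no competitor also lands in
quartile 1 for *every* pattern — true for any campaign in which the
runner-up varies across patterns, which is what real and synthetic
campaigns produce.

## Parameters and defaults

| parameter | default | meaning |
| --- | --- | --- |
| z_score | 1.96 | survey z-score in the finite-population sample size n′ = n₀/(1+n₀/N), n₀ = z²p(1−p)/ε² |
| margin ε | 0.01 | half-width of the confidence interval on observed proportions |
| proportion p | 0.5 | conservative variance maximizer |
| pattern lengths | {2, 4, 8, 16, 32} | campaign pattern lengths, cycled during sampling |
| rounding | 2 decimals, half away from zero | entropy rounding before classing |
| md_i | 1.0 | maximum squared discrepancy per share variable (shares are bounded by 0 and 1) |

On z: the conventional z for 95% confidence is 1.96, and that value also
reproduces the reference campaign sizes (4,269 from N = 7,682; 1,685
from N = 2,043); some survey texts quote 1.65, which belongs to 90%
two-sided confidence.  The parameter is configurable.

Sample sizes round up (a fractional pattern is a whole pattern);
class counts round half away from zero with a floor of 1.  A degenerate
observation set (all rounded entropies identical) produces a single
class of width 0 rather than an error.

## Validation statistics

Model and held-out campaigns are compared per entropy class on the
(algorithm × quartile) share cells that are nonzero in at least one of
the two campaigns, in fixed alphabetical-algorithm order.  The
double-scaled Euclidean distance d₂ = √(Σᵢ(p1ᵢ−p2ᵢ)²/mdᵢ)/√v lies in
[0, 1] whenever each squared difference is bounded by its mdᵢ; with
mdᵢ = 1 it is the root-mean-square share difference.  The square root is
taken of the scaled sum *before* dividing by √v — the only placement
that keeps the distance in [0, 1] and makes 1 the maximum discrepancy.
Similarity is 1 − d₂.  Pearson's r over the paired share vectors is
computed with scipy; it is reported as missing when either vector is
constant.  A class empty in both campaigns is reported as perfectly
similar (d₂ = 0) with no correlation.  Distribution summaries (sample
mean, n−1 standard deviation, histogram counts) support checking that a
validation pattern set resembles the model-building set.

## Synthetic corpora: what they emulate and what they do not

`synthetic_dna_corpus` draws i.i.d. characters from {A, C, G, T}
(uniform by default, configurable); `synthetic_english_corpus` draws
i.i.d. letters and spaces from a skewed English letter-frequency table.
These reproduce the *alphabet sizes and symbol skews* of the two target
domains so that every pipeline stage — sampling, searching, classing,
ranking, validation — runs offline and deterministically under a seed.

They do not reproduce the long-range structure of real data: genomes
carry repeats, GC skew and low-complexity runs; English has word and
n-gram structure, capitalization and punctuation patterns.  Entropy
classes of sampled patterns are correspondingly narrower on i.i.d. text
(low-entropy patterns are rare), and on uniform DNA the skip-loop family
(BM, QS, HOR) dominates every populated class.  Green tests therefore
demonstrate that the machinery is correct and reproducible, not that a
ranking learned on i.i.d. text transfers to a real corpus — building
the model on the actual domain text is the point of the method.

Pattern sampling cycles through the requested lengths so each is equally
represented, de-duplicates, and skips a length once its distinct
substrings are exhausted (a 4-letter alphabet has only 16 distinct
2-mers); the remaining lengths absorb the slots.

## Numerical choices

- Entropy uses `math.log2` on exact character counts; the
  single-character case returns +0.0.
- Rounding goes through `decimal` with half-away-from-zero to avoid
  binary-float surprises on exact halves.
- Class assignment uses bisection on the precomputed boundaries; a value
  exactly on a boundary joins the upper class.  Rounded (2-decimal)
  entropies never coincide with the 5-decimal boundary grid in practice.
- Campaign CSV tables store exact float reprs and are read back with
  pandas' round-trip float parser, so records survive a write/read cycle
  bit-exactly.

## Test problem sizes

The default suite builds its shared campaign on a 20 kb synthetic DNA
corpus with 120 patterns, and the end-to-end reproducibility check runs
the full study configuration — a 10⁵-character DNA corpus, 500 sampled
patterns, all seven algorithms, model build plus rebuild and
self-validation — chosen so the entire suite completes in about a
minute on one CPU while exercising every stage at realistic scale.

## Known limitations

- Scope is single-pattern, online, comparison-based exact matching;
  bit-parallel, hashing and multi-pattern families fall outside the CC
  metric's comparability assumptions.
- The ranking depends on the declared quartile convention; other
  reasonable conventions reorder near-tied algorithms.
- CC ignores memory traffic and branch behaviour; two algorithms with
  equal CC can differ in wall-clock time.
- The natural-language discretization is structurally faithful (9
  classes from 105 distinct observations) but an equal-width scheme's
  bounds depend on the observed maximum, so published class bounds from
  other campaigns are not expected to match to all decimals.
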