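# Methods

`promdissect` re-implements, as a tested pipeline, the computational side of a
promoter-dissection workflow for bacterial promoters that are active
specifically in the tumor microenvironment.  The working model of such a
promoter is a two-element architecture: a strong binding site for the
anaerobiosis regulator FNR (a palindromic TTGAT-N4-ATCAA site bound by the FNR
dimer under low oxygen) combined with a deliberately *weak* sigma70 basal
promoter (-35 and -10 hexamers) in a locally AT-rich context.  The weak basal
promoter prevents transcription without the FNR boost; the FNR site provides
the tumor-specific (hypoxia-linked) activation.

## Discriminative element analysis

Input are four labeled sets of promoter-length DNA fragments:

* **TSP** — the positive set (tumor-specific promoters), default size 13;
* **NP** — the negative set (fragments that initiate no transcription), 115;
* **lowTSP** — an independent holdout of weaker tumor promoters, 12;
* **RP** — random genome fragments cut to the TSP length distribution,
  7682 at full size (1000 in the desk-scale default).

For a feature *E* and set *S*, `E^S` is the fraction of sequences in *S* with
at least one detected occurrence.  Each detector exposes a per-sequence score
(maximal window log-odds, best bipartite placement score, maximal window A+T
fraction, maximal window adenine fraction), and the threshold sweep is run on
the **exact grid** of observed per-sequence scores — frequencies can only
change at observed values, so no step-size parameter exists.

The optimal threshold maximizes the discrimination ratio `E^TSP / E^NP`
subject to the boundary conditions `E^TSP >= 0.75` and `E^NP <= 0.50` (both
inclusive).  When `E^NP = 0` the ratio is reported as
`E^TSP / (1/(2 n_NP))` — a half-count pseudofrequency — so that features
entirely absent from the negative set rank finitely and comparably instead of
dividing by zero.  Ratio ties are broken by higher `E^TSP`, then higher
threshold; the pipeline-level feature *ranking* breaks remaining ties by the
lower background frequency `E^RP` (the feature rarer in random genomic
sequence is the more promoter-specific one).

Enrichment against the background is the exact binomial upper tail
`P(X >= k)`, `X ~ Binomial(n_TSP, E^RP)`, with `E^RP` measured at the same
selected threshold; the tail is computed by direct term summation, not by a
normal approximation.  No multiple-testing correction is applied to the
selection; a Bonferroni column is emitted in reports for transparency only.
The holdout frequency `E^lowTSP` is evaluated at the frozen threshold and
reported next to `E^TSP` as an overfitting estimate.

## Feature detectors

* **PWM scan** — log2-odds against a background composition (uniform by
  default, overridable); both strands for transcription-factor motifs,
  reverse-strand hits reported in forward coordinates.  `N` scores zero
  (background).  Probability columns get a 0.01 pseudocount when built from
  counts, so no score is −∞.  Consensus-derived matrices place probability
  0.91 on the matched base (rest spread uniformly), which makes a single
  mismatch cost log2(0.91/0.03) ≈ 4.9 bits.
* **Bipartite basal promoter** — two hexamer matrices (-35 default `TTGTCA`,
  -10 default `TATAAT`) joined by a 15–21 nt spacer with a linear penalty of
  0.5 bits per nt of deviation from the canonical 17 nt optimum; the reported
  transcription start sits 7 nt downstream of the -10 end.  Forward strand
  only (trap-library fragments are fused to the reporter in one orientation).
  This scorer is a transparent stand-in for external basal-promoter
  recognizers; it is not a re-implementation of any of them.  The -35 default
  is deliberately kept as printed in the source material (`TTGTCA`); the
  canonical `TTGACA` variant is available via `basal_model(canonical_minus35=True)`.
* **AT-rich region** — every 100 nt window with A+T fraction strictly greater
  than 0.6; overlapping qualifying windows are merged into maximal regions.
* **A8 repeat** — every 8 nt window with at most one non-A base, merged into
  maximal runs; forward strand only (an A-run on the reverse strand is a
  T-run on the forward strand and is deliberately not the same feature).

## Module search

Combinations of 2–5 heterogeneous features that co-localize on positive
sequences are sought with a genetic algorithm.  A sequence supports a module
iff one hit of every member fits inside a window of `max_span` nt, order-free.
Genotype: a membership bitmask over the feature catalogue plus an integer
span gene in [50, 500] nt.  Defaults: population 200, 100 generations,
tournament size 3, mutation 0.2 per genome (member add/drop/swap and span
perturbation), single-point crossover at rate 0.7, elitism 2, early stop
after 20 stagnant generations.  Fitness is
`support_TSP / (support_NP + 1/(2 n_NP))` plus a compactness bonus
`0.1 (1 − mean_span/max_span)`.  Duplicate member sets are deduplicated
keeping the best span, and returned modules carry exact binomial p-values
against the RP background.

Member hits for the module stage are generated at the **sensitivity-first**
threshold: the lowest-score grid point that maximizes `E^TSP` subject to
`E^NP <= 0.50`.  The ratio-optimal threshold is the right operating point for
reporting a single element, but it deliberately sacrifices recall (for the
weak basal element it drops placements with off-optimum spacers), which
starves co-occurrence detection; in the combinatorial stage the module, not
the individual member, carries the specificity.  Discrimination reporting is
unaffected.

## Promoter engineering

All edits are recorded as ordered, non-overlapping `DesignEdit`s; applying a
plan's edits to its template must reproduce its product exactly (checked on
construction), and every operation re-verifies its product by re-scanning:

* **split** — partition into 50–100 nt fragments whose boundaries avoid
  bisecting hits where possible (ids: parent + `_` + consecutive number);
* **knockout** — substitute a hit's critical positions with seeded random
  other bases ({G,C} only for TATA-box knockouts); the built-in critical
  catalogue marks the two 5 nt FNR half-sites and all six -10 positions and
  is user-overridable data, not code;
* **randomize** — seeded substitutions at listed positions with re-scan
  confirmation that preserved features survive (bounded retry, 20 attempts);
* **symmetrize** — replace the second FNR half-site by the reverse complement
  of the first, producing a perfect palindrome (never decreases the score of
  a palindromic-consensus matrix);
* **compose** — implant element strings into a neutral template, then
  optionally convert G/C positions outside the implants to A (p = 0.75) or T
  until a window around the prospective start reaches a target A+T fraction
  (a DNA-melting proxy; the verification report also prints the A+T fraction
  of ±10 nt around the start).

## Synthetic studies and what they do (not) show

The generator emulates the study conditions with full ground truth: 13
positives each carrying a perfect-consensus FNR site 5–60 nt upstream of a
weak basal pair (2 mismatches in -35, 1 in -10; spacer uniform 15–21 nt),
implanted adenine runs and locally AT-enriched 100 nt windows each with
probability 0.77, over an i.i.d. background of GC 0.488; 115 negatives of
plain GC-0.55 background; 12 holdouts with one extra mismatch per basal
element; and a background set cut from a synthetic GC-0.52 genome following
the positive length distribution.  The AT-context enrichment converts G/C to
A or T with equal probability — a natural AT-rich context is strand-balanced;
the A-biased conversion is reserved for the engineering melting rule, keeping
the AT-region and A-run signals independent in the truth.

The weak-basal default (2+1 mismatches) is gentler than the most extreme
published weak pairs so that detection remains feasible at n = 13; the
holdout attenuation (+1 mismatch per element) makes `E^lowTSP < E^TSP` the
expected direction.  Everything is reproducible from `(config, seed)`.

What passing recovery tests shows: the pipeline finds a strong planted motif,
selects sensible thresholds, and the GA recovers a planted co-localized pair
against decoy features.  What it does not show: performance on real genomic
sequence, where background composition is non-i.i.d. (repeats, skews, operon
structure), motif instances are degenerate rather than consensus-perfect, and
negative sets are biologically, not statistically, defined.  The bipartite
stand-in also cannot reproduce scores of external basal-promoter programs.

## Numerical choices and degenerate inputs

Log base 2 throughout; pseudocount 0.01 on matrices built from counts;
consensus match probability capped below 1 so log-odds stay finite.
Bipartite ties break to the smaller -35 start; multi-placement bipartite
scanning picks placements greedily best-score-first without extent overlap.
Sequences shorter than a detector's window yield no hits (score −∞ in
sweeps), not errors.  A matrix wider than the sequence scans to an empty hit
list.  `k = 0` gives a binomial tail of exactly 1.  Empty promoter sets,
unsorted threshold grids, overlapping design edits and out-of-range
parameters raise errors rather than degrade silently.

## Scale defaults

The CLI and `RunConfig` default to 1000 background fragments (the full-size
7682 is one flag away) and the module search stops early on convergence; a
full pipeline run on the default study takes about one second on one CPU, and
the repeated-seed recovery analyses in the test suite and acceptance script
(20 studies) run in well under a minute.
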