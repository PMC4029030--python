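# Methods

## The problem

Discordant-pair SV callers (HYDRA, GASV, VariationHunter and kin) report a
candidate rearrangement whenever read-pairs map with unexpected distance or
orientation. The dominant failure mode is homology: when two loci share a
diverged duplicated segment, reads from one copy multi-map to the other and
the caller emits a junction that joins the two copies. `svrescore` rescores
each candidate by asking the generative question directly: are the
supporting reads more probable under a reference that contains the
rearranged junction, or under the contiguous reference around either
breakpoint?

## Model

For each candidate with breakpoint loci (side5, side3), three references
are built from the genome:

* **sv** — `W5 ⊕ W3`, the `flank` bases adjacent to each breakpoint,
  oriented by the strand signature and concatenated at the junction;
* **c5**, **c3** — `2·flank` bases of unmodified reference centred on each
  breakpoint.

Every supporting read (pairs with one mate mapping within `pad` of each
breakpoint) is realigned to all three references by affine-gap local
alignment, in both orientations, keeping the better. Alignments are
reduced to per-*cycle* tallies: at read position `p`, `l_p` reads cover the
cycle, `m_p` of them disagree with the reference and `i_p` open an indel.
The probability that the sequencer produced those disagreements is a
product of independent binomials with position-specific rates
`err_mm(p)`, `err_ind(p)`:

    log p(config) = Σ_p [ log B(m_p; l_p, err_mm(p)) + log B(i_p; l_p, err_ind(p)) ]

and the candidate's score is the log likelihood ratio

    L = log p_sv − max(log p_c5, log p_c3)

Only the better-fitting contiguous fragment is compared, since it is the
more plausible contiguous origin of the reads. `L > 0` favours the SV. A
real junction yields split-reads and properly placed mates that fit the sv
reference with nothing but sequencing error, while fitting each contiguous
reference forces half of each spanning pair to be clipped or mismatched —
driving `L` strongly positive. A repeat artifact is the mirror image:
reads truly drawn from one duplication copy fit that copy's contiguous
reference perfectly, while the joined reference forces ~(1 − identity)
mismatch rates on half the reads, driving `L` negative.

Assumptions inherited by the model: mismatches and indels are independent
of one another, within and across reads, and independent of genomic
context; error rates depend only on cycle number; each supporting pair
either belongs at both junction sides or at exactly one (reads belonging
to a *different* overlapping SV are not modelled); SNPs are not separated
from sequencing errors — a heterozygous or private SNP simply contributes
to the mismatch tally in all three configurations, where it largely
cancels.

## Error profile estimation

Per-cycle rates are estimated per experiment: concordant pairs (proper-pair
flag, both mates on one contig, insert within mean ± 3 SD) are
reservoir-sampled (default 100 000 pairs, seeded), each read is realigned
to the reference window at its recorded mapping position, and
`err_mm(p)` / `err_ind(p)` are the observed per-cycle frequencies. Two
deliberate choices:

* **Fit (read-global) alignment for estimation.** The candidate-scoring
  path uses local alignment and counts clipped bases as mismatches (see
  below). Local alignment, however, clips any trailing run whose summed
  score is negative, so a single substitution two or three cycles from the
  read end drags its error-free neighbours into the clip and would be
  multiply counted — inflating terminal-cycle rates several-fold. For
  estimation the read's origin is *known*, so the read is aligned
  end-to-end against a locally free reference window (no clips) and every
  cycle is counted exactly once. Simulations with known rates confirm the
  estimator is unbiased under this scheme (see the recovery tests).
* **Rate floor.** Observed rates can be exactly zero at a cycle, which
  would give any later observed mismatch probability zero and an infinite
  score. Rates are floored at `1/(2·n_reads)` (half an expected count) and
  capped just below 0.5.

The statistical recovery tests use a *family-wise* 99% exact binomial band
(Bonferroni-corrected per cycle) rather than independent per-cycle 99%
intervals: with 100 cycles, per-cycle intervals would flag a correct
estimator roughly half the time.

## Alignment engine

A Gotoh affine-gap dynamic program (numba-compiled) with deterministic
traceback: diagonal is preferred over an up-gap over a left-gap, and among
equal-scoring end cells the smallest `(ref_end, read_end)` wins. Scores are
log2-odds of the mean error rates against the 0.25 background, rescaled so
a match is exactly +1 (`mismatch = log2((ē_mm/3)/0.25)/log2((1−ē_mm)/0.25)`,
`gap_open = log2(ē_ind)` scaled likewise, `gap_extend = gap_open/4`). With
the default 1%/0.1% rates this gives mismatch ≈ −3.14 and gap open ≈ −5.0
per match point. The parameters are exposed as configuration
(`SWParams`). `N` bases never match anything.

Tally rules that matter:

* **Clips count as mismatches in the score.** A local aligner clips away
  exactly the disagreement that distinguishes the three references; if
  clipped bases were free, the configurations would be indistinguishable.
  In the *picture*, clips follow the drawing convention instead (shortened
  bars, not red) — the score/plot divergence is intentional.
* **A multi-base gap counts once**, at its opening read position, keeping
  `i_p ≤ l_p` plausible; `i_p` is clamped at `l_p` before the binomial.
* **Cycle coordinates.** Tallies are indexed by sequencing cycle: when a
  read aligns reverse-complemented, alignment position `p` maps to cycle
  `L−1−p`.
* **The junction is a reference feature.** Reads cross `junction_offset`
  freely; the crossing is never an indel. A read whose aligned span covers
  the junction is flagged a split-read.

### Fast mode

A read can reach the perfect score bound `read_length × match_score` only
via an all-match alignment, whose tally contribution is provably zero.
Fast mode therefore runs a score-only pass first and performs a traceback
only for imperfect reads; scores, tallies and `ScoreResult` are bit-identical
to full mode, but per-base op lists (plot data) are not guaranteed for the
elided reads.

## Coordinate and orientation conventions

BEDPE is 0-based half-open; internal breakpoints are 0-based. The
breakpoint of each BEDPE interval is its inner edge selected by strand
(`+` → interval end, `−` → interval start), matching discordant-pair
geometry. Junction assembly treats each side independently so the
junction-adjacent base always sits at the join: side5 `+` takes the left
flank as-is and side5 `−` the right flank reverse-complemented; side3 `−`
takes the right flank as-is and side3 `+` the left flank
reverse-complemented. The deletion signature `(+,−)` therefore joins
as-is; inversion signatures reverse-complement one window; the `(−,−)` and
`(−,+)` cases produce the reverse-complement of the equivalent
opposite-signature junction, which is alignment-equivalent because both
read orientations are tried.

## Defaults and units

| parameter | default | why |
|---|---|---|
| `pair_support` | 5 pairs | standard support filter for high-confidence candidates |
| `max_mean_edit_distance` | 2.6 (strict `<`), mean NM per supporting read | removes candidates supported only by poorly matching reads |
| `pad` (pair extraction) | insert mean + 3 SD, estimated from the BAM | any mate of a junction-spanning fragment falls inside the window |
| `flank` (reference windows) | read length + pad | every supporting read fits entirely on one side of the junction |
| concordant sample | 100 000 pairs | ample counts per cycle for rate estimation |
| score cutoff | 100 (natural-log units); 170 for target-capture libraries | recommended operating points for prioritization |
| rate floor | `1/(2·n_reads)` | half an expected count; avoids zero-probability cycles |

The log base is not dictated by the model; this implementation uses
natural logarithms throughout and calibrates the cutoffs in those units
(exposed as `--cutoff`).

## Synthetic benchmark

The `simulate` module generates the study conditions end-to-end from one
seed: a uniform-random 200 kb genome; a 2 kb segmental duplication at 95%
identity (iid substitutions), source at 20 kb and copy at 120 kb; three
deletions (3 kb, 3.5 kb, 3 kb) implanted into a donor haplotype; 30×
coverage of 100 bp pairs with insert ~ N(300, 30²) truncated at the read
length; per-cycle mismatch rates ramping 0.001 → 0.01 (an Illumina-like
phasing ramp) and a constant 10⁻⁴ indel rate. Reads are placed in the BAM
at their true source coordinates with flat `100M` CIGARs (the rescorer
distrusts CIGARs by design) and honest NM tags (Hamming distance at the
recorded position). Decoy candidates join homologous positions of the two
duplication copies with deletion-signature strands; fragments spanning the
decoy point inside the source copy have their reverse mate relocated to
the homologous copy coordinate, reproducing the cross-copy mismapping that
generates such calls in real data.

What the simulation does *not* emulate — and hence what passing tests do
not establish about real data: non-uniform base composition and true
repeat families beyond a single duplication, GC- and context-dependent
error, quality-string variation (qualities are constant and unused, as in
the model), PCR duplicates, heterozygosity/SNPs, micro-homology or
untemplated bases at breakpoints, and real aligner behaviour (mapping is
by construction, not inference). The benchmark demonstrates that the
likelihood machinery separates junction-supported events from
homology-induced artifacts under the model's own assumptions, at desk
scale; it is not a re-estimate of any sensitivity/specificity figure from
capture or whole-genome experiments.

Problem sizes used by the shipped checks: the benchmark above (~30 000
pairs, 6 candidates), error-profile estimation from 2 500 sampled pairs
(5 000 reads), 500 random kernel-vs-oracle instances with sequences up to
12 bp, and exhaustive binomial enumeration up to l = 6.

## Numerical choices, degenerate inputs, limitations

* `binomial_log_pmf` uses the log-gamma closed form; pmfs sum to 1 to
  ~1e-15 at the sizes checked.
* Zero-coverage cycles contribute log 1 = 0; an empty tally has
  probability 1.
* Windows are clamped at contig ends with clamp amounts recorded; a
  zero-length breakpoint window is an error. A degenerate "deletion" whose
  breakpoints coincide reproduces the contiguous reference exactly and
  scores 0.
* Orientation ties go to the forward read; equal-scoring contiguous sides
  are interchangeable (`max` is symmetric).
* Alignment is O(read × reference) per read; the default flank keeps the
  reference ~1 kb, and fast mode skips tracebacks for perfect reads.
  Candidates with very high support simply take proportionally longer.
* Known limitations: no joint assignment of reads shared between
  overlapping candidates; no breakpoint refinement or micro-homology
  search (breakpoints are taken as the caller reports them); no
  quality-aware scoring; insertions (novel sequence) are not a supported
  event class — deletion, inversion, translocation and generic junctions
  are.
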