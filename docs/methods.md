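# Methods

## Problem setting and model

A sequencing library from ancient dental calculus is modelled as a
mixture of reads of ancient-oral origin and contaminant reads from
environmental sources, chiefly skin and sediment/soil. No read-level
label is observable, and neither the oral nor the contaminant side has a
usable reference database, so classification is done purely by k-mer
consensus across previously sequenced, environment-labelled metagenomes:
a k-mer seen in oral samples and never in contaminant samples is
evidence of oral origin for any read that carries it.

All k-mers are canonical (a word is identified with its reverse
complement and spelled as the lexicographic minimum of the two). The
source matrices this package consumes are built by canonical k-mer
counters, and reads arrive from either strand, so matching must be
strand-symmetric; canonicalizing everywhere is the only consistent
choice and is asserted by a strand-invariance test. Windows containing
any non-ACGT character are skipped during k-merization while their
positions are kept, so adjacency between surviving windows is still
judged on the original coordinates — an N gap therefore breaks
"consecutive" matches, the conservative reading.

## Trusted-set construction

Input is a k-mer × sample presence matrix with per-column environment
labels from the closed vocabulary {aOral, mOral, Skin, SedimentSoil}
(optionally with per-cell counts). The pipeline is:

1. **Row subsampling** (default fraction 0.10, seeded): applied first,
   since its purpose is to bound the memory of everything downstream.
   The processing order relative to the other filters is a design
   choice; selection quality is insensitive to it because each step is
   row-local.
2. **Within-sample singleton removal** (default on): entries with count
   exactly 1 are set absent — one observation of a 31-mer in one sample
   is most plausibly a sequencing error. Requires counts; requesting it
   without counts is an explicit error, not a silent skip.
3. **Prevalence filter** (default ≥3 samples): a k-mer must remain
   present in at least 3 samples. All samples count toward prevalence,
   oral and contaminant alike — the filter's job is error removal, and
   an error-like k-mer is one with little support anywhere.
4. **Boolean selection**: keep a k-mer iff present in ≥1 oral column
   (aOral or mOral) and absent from every Skin and every SedimentSoil
   column. A matrix without oral columns is rejected as degenerate.

Steps 2–3 are exposed as explicit, optional operations even though
published source matrices often arrive with them already applied, so
users starting from raw matrices reproduce the same semantics.

## Bloom filter

Sizing follows the textbook formulas `m = ceil(-n ln p / (ln 2)^2)`,
`h = max(1, round((m/n) ln 2))` for capacity `n` and error rate `p`
(defaults 2×10⁹ and 0.001; the capacity default is sized for a
full-scale trusted set of ~1.5×10⁹ k-mers and should be lowered to the
actual set size for small inputs). Hashing is double hashing over a
single 128-bit blake2b digest of the k-mer string: the two 64-bit halves
give `g1` and `g2`, probe `j` touches bit `(g1 + j*g2) mod m`, and `g2`
is forced odd so the probe sequence cannot collapse. blake2b is in the
standard library, fast at these sizes, and has far better avalanche
behaviour than ad-hoc polynomial hashes, which matters for meeting the
error-rate contract empirically.

Inserting beyond capacity logs a warning rather than raising: the
contract degrades gracefully and the bound simply stops applying.
`inserted_count` counts insert *calls* (re-inserting an element changes
no bits but increments the counter); this is documented behaviour. The
on-disk format is magic + version + (k, capacity, p, m, h, inserted) +
raw bit payload, with byte-exact round-trip and validation of magic,
version, payload length and (optionally) k on load. No compatibility
with any other tool's filter files is attempted.

## Two-pass classification

**Pass 1 (anchors).** A read is an anchor iff it has trusted-set matches
at two adjacent window starts (start positions differing by exactly 1,
i.e. k−1 overlap). Adjacency is the strictest natural reading of
"consecutive" and gives the false-positive robustness argument its
teeth: a single Bloom false positive cannot anchor a read, and two
false positives at adjacent positions occur with probability ~p² per
position. Reads with fewer than two valid windows can never anchor.

**Pass 2 (retention).** All anchor reads are k-merized into an exact
anchor k-mer set — deliberately *not* restricted to the trusted set, so
that novel putative ancient k-mers carried by anchor reads (e.g. from
taxa underrepresented in the reference collection, or divergent strains)
propagate to the retention decision. Each read's anchor proportion is
(# read k-mers in the anchor set) / (# valid windows), defined as 0 for
reads with no valid windows; the read is retained iff the proportion is
≥ τ, inclusive, with τ = 0.5 by default. Non-anchor reads are routinely
retained this way; that rescue is the method's point. The exact set (not
a second Bloom filter) is used for pass 2, trading memory proportional
to the anchor k-mer count for simplicity and exactness.

The one-pass baseline retains exactly the pass-1 anchors and reports
anchor proportion 0 as a sentinel; it exists to quantify what the second
pass buys and is dominated by the two-pass variant on the ROC.

Input files are scanned twice by re-opening the stream, so read storage
is constant-memory; only the anchor k-mer set is held in RAM. Paired
ends are treated as independent reads. τ is tuned, when desired, by
re-thresholding a single pass-1 computation across a grid (0.1–0.9 by
default) — exact, because pass 1 is τ-independent.

## Synthetic data generator

The generator emulates the balanced three-source evaluation design:
one oral and two contaminant toy genomes (default 20 kb, i.i.d. uniform
bases), a read mixture of equal thirds (default 3 × 2,000 reads of
100 bp), uniform start positions, random strand, and substitution-only
errors at 0.5% per base (Illumina-like; the data the method targets is
short-read Illumina). A `shared_fraction` dial plants a contiguous block
of the oral genome inside contaminant genomes sized so the pairwise
k-mer Jaccard approximates the requested value (`c = 2nJ/(1+J)` shared
k-mers); the default is 0 (disjoint sources). Truth labels live in a
sidecar TSV keyed by read id, never in the ids, so header-annotation
tests stay independent of truth bookkeeping.

Matrix samples are random subsets (default 90%) of their genome's k-mer
set, optionally plus noise k-mers from the other genomes; counts, when
generated, are 1 + Poisson(3) so a realistic ~5% of entries are
within-sample singletons. Scenarios: *seen* draws reads from the same
genomes behind the trusted set; *unseen* draws oral reads from a variant
of the trusted oral genome diverged by 3% substitutions (strain-level
distance at which only ~0.97³¹ ≈ 39% of 31-mers survive intact, enough
to visibly stress pass 1 while the anchor harvest recovers most reads)
and contaminant reads from entirely fresh genomes; *partially_seen*
diverges only the oral source. These scales keep a full two-scenario
evaluation in the tens of seconds on one core.

What the generator does **not** model: indels, quality-score structure,
aDNA damage (C→T deamination gradients, fragment-length decay),
coverage bias, and real inter-environment k-mer sharing. Passing the
synthetic recovery tests therefore demonstrates the algorithm's
correctness and its seen-vs-unseen ordering, not field performance on
real calculus libraries.

## Evaluation

Truth is binarized: aOral is positive, Skin and SedimentSoil collapse to
negative. Sensitivity = fraction of aOral reads retained = TPR;
specificity = fraction of non-aOral reads removed = 1 − FPR; retainment
= fraction of all input reads kept (the only metric available on real
data, where per-read truth does not exist). Files store fractions; the
console renders percentages.

## Numerical and edge-case choices

- τ boundary inclusive (≥), matching the "proportion ≥ 50%" rule.
- Reads with zero valid windows get proportion 0 and are dropped for any
  τ > 0; with τ = 0 everything is retained by construction.
- Palindromic k-mers (possible for even k) canonicalize to themselves;
  the default k = 31 is odd, so the case cannot arise there.
- Lowercase input is uppercased on ingestion; CRLF input is tolerated,
  LF emitted.
- Subsampling uses `numpy.random.default_rng` with a recorded seed;
  selected rows keep their original order, so output is deterministic.
- Bloom filters above 2⁴³ bits are refused with the required size named,
  rather than attempting the allocation.

## Known limitations

- The anchor k-mer set is exact and grows with the anchored fraction of
  the input; a Bloom-backed second stage would bound this but is out of
  scope.
- No aDNA damage-aware authentication: retention says "oral-like k-mer
  content", not "ancient".
- The trusted set is only as good as the labelling of the source
  collection; mislabelled samples leak k-mers across the boolean fence
  in either direction.
- Higher per-base error rates than short-read Illumina (e.g. long-read
  data) will depress anchor formation and are untested territory.
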