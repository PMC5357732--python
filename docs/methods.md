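# Methods

## Coordinate model

The germline genome is a gap-free tiling of labeled intervals — MDS,
type-A IES, type-B IES — per chromosome, in 0-based half-open (BED)
coordinates. Only IES records are required in an annotation BED; MDS
segments are reconstructed as the complement. Overlapping IESs and IESs
running past a chromosome end are hard errors; abutting IESs are legal
and no zero-width MDS is inserted between them. IES identifiers are
taken from the BED name field (`IES_A:<id>`) or assigned
deterministically in coordinate order.

## Boundary windows

Each IES contributes two boundary windows (left and right edge). A
window pairs the `W` bases inside the IES abutting the edge with the `W`
bases outside it; `W` = 500 bp by default. Right edges are mirrored so
that in every boundary-relative frame positive offsets point into the
IES: a position `x` maps to offset `x − start` at a left edge and
`end − 1 − x` at a right edge, which makes the mapping an exact
reflection (double mirroring is the identity, and reflecting a whole
chromosome end-for-end leaves every meta-profile unchanged — both are
tested).

Eligibility: a window is eligible only when **both** intervals reach the
full width `W` — IESs shorter than `W` and IESs within `W` of a
chromosome end are excluded from meta-profiles and the BBI by flag, not
by truncation, so the compiled axis always aggregates windows of
identical geometry. Windows whose outside interval overlaps a
neighboring IES are kept but flagged (`overlaps_foreign_ies`), and the
two sides of an IES shorter than `2W` are flagged `sides_overlap`;
both policies are switchable because reasonable analyses differ here.

## Read layer

Reads are consumed as BED6 alignment records; alignment, deduplication
and multi-mapper resolution are out of scope and each record counts
once. The scnRNA filter keeps lengths in the inclusive 26–32-nt band.
Anchors: `five_prime` (start on +, end−1 on −) for 100-bp locus
profiles; `nt13` (start+12 on +, end−13 on −) for 10-bp meta-profiles
and 50-bp heatmaps — the 13th nucleotide marks the center of the
scnRNA–target duplex and sits inside the read for every filtered
length; `midpoint` for ChIP fragments, which have no meaningful strand
polarity at enrichment level. RPM normalization divides by the number
of reads passing the filter and mapped to the analysis genome (for
ChIP/input, all mapped records); the denominator is recorded in every
library's metadata so results remain interpretable under a different
normalization convention.

## Profiles

Locus profiles bin anchors per strand at 100 bp. Meta-profiles place
anchors from the outside∪inside window pair of every eligible boundary
of one IES type onto the common −W..+W axis (10-bp bins), flipping the
strand of mirrored (right-edge) boundaries so sense/antisense stay
boundary-relative; counts are **summed** across boundaries and then
normalized — summing weights boundaries by coverage, which matches how
a pooled library is actually sequenced; the per-boundary count sum is
conserved and tested against a naive per-read membership oracle.
ChIP/input profiles are the per-bin ratio of RPM-normalized profiles;
bins with zero input reads are masked (NaN), never 0 or ∞, and the
masked count is reported in run manifests.

## Broken boundary index

For a boundary, with `m`/`i` the outside/inside window counts (both
strands pooled, `nt13` anchors):

```
BBI = ((m_s + p) / (i_s + p)) / ((m_c + p) / (i_c + p))
```

with pseudocount `p` = 1 on all four counts. `p` stabilizes the ratio of
ratios at zero counts at the cost of a bias that vanishes as counts grow
(checked at counts ≥ 10³: relative error < 1%). Boundaries with a
control inside-count below 10 raw reads are flagged ineligible for
distribution summaries — the ratio of ratios is dominated by noise
there. Ranks (1 = highest BBI) are assigned among eligible boundaries
with ties broken by (chrom, boundary position, side), making rankings
deterministic. BBI is computed per **boundary**, the unit the statistic
is defined on; `per_ies_table` collapses to one row per IES (max-BBI
side) for locus-level reporting. Top-N heatmaps fix their row set once
from a designated reference strain's ranking and profile the same rows
in every strain's library (50-bp bins, RPM), so strains are comparable
row by row.

## Synthetic data

The generator emulates the developmental scnRNA program at coordinate
level; no nucleotide sequence is simulated. Defaults are the study
conditions of the tests and examples:

- genome: alternating MDS/IES, IES types shuffled over positions, IES
  lengths uniform 1–4 kb and MDS lengths 2–6 kb (the kb-scale regime of
  eliminated elements); the final MDS stretches to the declared
  chromosome length, and infeasible packings are hard errors;
- read lengths: unimodal over 26–32 nt peaking at 28–29, plus a 5%
  contaminant fraction drawn uniformly from {20–25, 33–40} nt, which
  exercises both edges of the length filter;
- `early_3h`: anchors from type-A IES bodies (length-weighted) or, with
  probability 0.5, from a flank, at an exponentially distributed
  distance (mean 300 bp) outside a type-A edge — a compact stand-in for
  bidirectional transcription of the element and its surroundings;
- `post_selection_6h`: the early model followed by removal of
  MDS-anchored reads with probability `selection_efficiency` (default
  0.9) — "scnRNA selection" against the parental somatic genome;
- `late`: anchors uniform over type-A and type-B IES bodies (type-B
  share 0.4, matching the type-B fraction of elements), with optional
  per-boundary spreading: a fraction `f` of reads anchored within 500 bp
  inside a designated edge is displaced outside to an exponentially
  distributed distance (decay `λ`). The one-sided exponential is the
  minimal one-parameter displacement kernel — the real mutant profiles
  are only known graphically, so the kernel is a modeling choice,
  isolated behind the `spread` mapping so alternatives can be added.
  The closed-form outside/inside ratio `f·(1−e^(−W/λ))/(1−f)` is used
  as the recovery oracle in tests;
- ChIP: fragment midpoints drawn directly from a piecewise-constant
  density (`chip_enrichment`-fold over IES bodies, 1 elsewhere) with an
  independent uniform input. Drawing midpoints from the density (rather
  than convolving fragments) gives sharp edges by construction; real
  ChIP transitions are blurred by fragment size, so edge sharpness in
  simulations should not be over-interpreted;
- `global_scale` multiplies the library size, emulating mutants with
  globally elevated scnRNA output.

All randomness derives from one integer seed (independent substreams
per operation), so genomes and libraries are bit-reproducible; every
artifact records its seed. What the simulations do **not** contain —
sequence composition, mappability structure, repeat families shared
between IES types, PCR duplication, ligation bias — means passing
recovery tests demonstrates correctness of the computation, not
robustness to real-library artifacts.

Two consequences of the minimal kernels are worth knowing. The
exponential flank of an early-stage type-A IES has unbounded support,
so a vanishing fraction of flank reads (≈0.03% at default geometry) can
cross a short MDS into a neighboring type-B boundary's window; type-B
signal is therefore asserted as < 0.1% of type-A flank signal rather
than literally zero. And displaced late-stage reads can likewise
overshoot a narrow MDS — a feature mirrored in real spreading, which
does not respect the next element's edge either.

## Numerical and policy choices

- Bin assignment is floor division on half-open bins; an anchor on a
  bin edge belongs to the upper bin.
- TSV floats are written with `%.10g`, making reruns byte-identical.
- Ratio profiles average per-bin ratios only where defined; consumers
  should note that the mean of per-bin ratios is upward-biased at low
  input counts (≈1/count), so plateau estimates in tests use ≥10⁶
  fragments.
- Library emptiness, inverted filter bounds, ineligible windows passed
  to counting, unknown spread targets, and top-N beyond the eligible
  count are hard errors; degenerate IES geometry is never an error,
  only an ineligibility flag.
- The BBI null (two independent same-model libraries) is summarized by
  the median across boundaries; with ≥400 eligible boundaries and
  ≥5×10⁵ filtered reads the median sits within 0.05 of 1, the
  "no disturbance" baseline, and the acceptance script recomputes this
  from scratch at exactly that scale (problem sizes: 420 IESs, two
  560k-read libraries — chosen as the smallest scale at which the
  per-boundary counting regime matches the statistic's intended use).

## Known limitations

- One annotation convention (label in the BED name field); no GFF
  input.
- ChIP anchoring is fragment midpoint; single-end 5′-shift models are
  not implemented (the anchor mode is configurable for scnRNA only).
- Element eligibility is one uniform rule (full-width windows plus the
  control-coverage floor); published meta-analyses sometimes tally
  slightly different element sets for different assays, and no attempt
  is made to reproduce any particular tally.
- No statistical test is attached to BBI shifts between strains; the
  package reports distributions, rankings and heatmaps only.
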