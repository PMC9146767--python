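# Methods

## Problem

A metallic sheet microneedle array senses through its tips, but only through
the tips that actually pierced the stratum corneum (SC).  The *transdermal
rate* — the fraction of tips past the SC — therefore scales the usable
sensing area, and a tip count cannot be read off optically once the array is
on skin.  The quantity that *is* measurable in situ is the DC current
between two metal sheets under a small constant voltage: an unpenetrated tip
faces the highly resistive SC instead of conductive dermis, so each
unpenetrated tip removes a low-impedance path and lowers the inter-sheet
test current.  This package implements the full inference chain:

1. a forward electrical model of the array in skin (``penrate.solver``),
2. exhaustive penetration-state sweeps and the statistics that turn them
   into current→state calibration tables (``penrate.stats``), plus the
   reference device's printed tables packaged verbatim (``penrate.tables``),
3. exact and fuzzy decoders that recover per-sheet unpenetrated-tip counts
   from measured pairwise currents (``penrate.decoder``).

## Forward model

**Geometry.**  The array is a row of parallel sheets (default 100 μm thick,
800 μm pitch), each carrying needle tips 200 μm wide at 800 μm pitch,
inserted 600 μm into the skin.  The skin is a two-layer block: 100 μm of SC
at 0.0005 S/m over 1800 μm of pooled viable epidermis + dermis at 0.2 S/m.
The block's lateral area is 9× the array footprint (3× the extent per axis,
array centered), so the insulating outer boundary is far from the current
paths; the ratio is configurable.

**Contact impedance.**  The needle/skin interface is a thin contact layer of
effective thickness 20 μm whose conductivity switches with the tip's
penetration flag XY (1 = unpenetrated):

    σ_contact = (1 − XY)·σ_dermis + XY·σ_SC

This is the key modelling device: penetration state becomes a boundary
parameter, and one discretization serves all 2^(2n) combinations of a sheet
pair.

**Discretization.**  Uniform voxel finite volumes (7-point stencil,
harmonic-mean face conductances).  Needle columns are carved out of the
grid; every exposed face couples the adjacent skin voxel to its sheet
through g = σ_contact·A_face/t_contact.  The metal sheets
(10⁷ S/m, 5·10⁷× dermis) are not meshed: each sheet is one equipotential
node, which is numerically equivalent at this contrast and keeps the system
well conditioned.  The tested pair is driven at 1 V / grounded; non-tested
sheets are floating equipotential nodes with zero net current (they can also
be suppressed entirely; floating is the default since the physical sheets
are present during a measurement).  Outer skin faces are insulating.  The
200 μm of needle protruding above the skin carries no current and is not
modelled; the tip taper is ignored by default (needles are rectangular
prisms), with an optional stepped half-width taper over the final tip
section for sensitivity checks.

**Linear solve.**  The system is symmetric positive definite and is solved
by Jacobi-preconditioned conjugate gradients to a 1e-10 relative residual
(1e-2 × the configured 1e-8 tolerance), with zero initial guess — fully
deterministic.  Every solve verifies source/ground current balance to 1e-6
relative and fails loudly otherwise.  On a homogeneous slab with plate
electrodes the scheme reproduces G = σA/L to machine precision (the exact
solution is linear in depth), which the validation helper checks.

**Resolution.**  Default voxel size is 50 μm; exhaustive sweeps use the
100 μm coarse option (the 3×3 pair grid is then ≈52k unknowns, ≈0.25 s per
solve, ≈17 s per 64-combination sweep).  Absolute currents depend on the
discretization and are *not* expected to match the packaged tables'
boundaries; all assertions about the solver concern orderings and
contrasts: currents decrease monotonically in each flipped tip, per-state
means decrease strictly along the state ranking, distant pairs respond more
weakly, and the nonconductive class sits far below every conductive state
(measured contrast ≈40× at coarse resolution, bounded above by
σ_dermis/σ_SC = 400; the packaged tables imply a similar ~25–40×).

## State algebra and calibration

A pairwise test observes only the unordered pair of per-sheet unpenetrated
counts — the *transdermal state* "low-high" (e.g. 1-2).  When one sheet is
fully unpenetrated the pair is effectively an open circuit and all such
states pool into the nonconductive class "n+".  States rank by (high, low)
lexicographically: the dominant factor in the current is the maximum count
on a single sheet.  The number of position-specific assignments (*events*)
realizing a state over an ordered pair is 2·C(n,low)·C(n,high) for
low ≠ high and C(n,low)² otherwise; the counts partition all 4ⁿ
combinations.

Calibration divides the current axis at midpoints of adjacent ranked state
means; the top interval is half-open above and the nonconductive interval
closes at 0.  Computed tables map one state per interval; the packaged 6×6
table maps printed *groups* of states per interval (single states are no
longer separable by current there) and is used as-is rather than re-derived,
since the grouping reflects the reference study's own forward-model
clustering.  The packaged tables preserve their printed values verbatim,
including an overlapping interval pair in the 3×3 adjacent-pair block and a
handful of interval-length entries that disagree with the printed bounds by
1–2 μA (boundaries are rounded midpoints of unrounded means).  Interval
lookup treats intervals as [low, high); a current inside a printed overlap
resolves to the higher-current interval and flags the pair as ambiguous.

Counting heat maps come in two modes: *combinatorial* (exact event counts
from the state→interval mapping; solver-independent, used for the headline
numbers) and *by_current* (actual sweep records binned by computed current;
reproduces the bleed-over between neighbouring intervals that appears as
arrays grow).  Per-interval summaries report the probability distribution,
mean and population standard deviation of the axis quantity (total count
N_total or single-sheet maximum N_max-s).

## Decoders

**Exact method** (3×3, 4×4 — tables with one state per interval).  With
three sheets A, B, C and the three pair states, the branch logic is: if the
two A-C numbers agree, A = C = that number and B is the A-B element not
matched by it; otherwise the value common to the A-B and B-C states is B
(test the smaller B-C element against the A-B pair, fall back to the
larger), and A, C follow as the unmatched elements.  Element matching uses
multiset semantics — a matched element is used up — which resolves the
duplicated-value cases.  Further sheets chain on one adjacent-pair state
each: the element complementary to the previous sheet's count is the next
count.  Exhaustive enumeration over all conductive truth vectors (n = 3, 4;
3- and 4-sheet chains) confirms the logic recovers every truth exactly.
Nonconductive pairs and inconsistent inputs raise named errors rather than
guessing; invoking the exact method with a grouped (6×6) table is a usage
error.

**Fuzzy method** (6×6 — grouped tables expose only each pair's maximum
count).  Two published estimators: for disjoint adjacent pairs,
N = 1.5 × Σ(pair maxima), i.e. half a maximum as the guess for each unknown
minimum (uncertainty rate 1/2); for a sheet triple, three pairwise
comparisons extract the largest and median per-sheet counts
(verified equal to the sort oracle on all {0..6}³ triples) and
N = N_MAX + 1.5·N_MED (uncertainty rate 1/3).  Physically impossible
pairwise-maxima triples (top two unequal) emit a warning but still return
the flow result.  The transdermal rate is 1 − N/(n_sheets·tips_per_sheet),
clamped to [0, 1] with a warning if an estimate overshoots.

## Synthetic fixtures

The fixture generator stands in for bench measurements: each tip is
unpenetrated with probability p (Bernoulli, seeded generator), and each
sheet pair's current is either the forward solver's output or a
representative current of the packaged table — the interval midpoint, or
for the half-open top interval the boundary plus half the neighbouring
interval's width — plus optional Gaussian noise, clipped at 0.  A fixed
spec reproduces its output bit-exactly.  What the generator does *not*
emulate: position-dependent within-state current scatter (the table source
collapses each state to one current), electrode drift, AC/capacitive skin
behaviour, and any correlation between neighbouring tips' penetration.
Zero-noise round trips therefore demonstrate decoder correctness, not
measurement robustness; the noise-sweep property test (decode failure rate
grows with noise s.d.) probes the latter qualitatively.

## Defaults and parameters that matter

| parameter | default | why |
|---|---|---|
| drive voltage | 1 V | reference study's test condition |
| σ_SC / σ_dermis | 0.0005 / 0.2 S/m | two-layer skin simplification |
| contact thickness | 20 μm | contact-impedance surface thickness |
| footprint ratio | 9 | weakens fringe effects at the insulating boundary |
| voxel size | 50 μm (coarse 100 μm) | 100 μm resolves tip width (2 voxels) and is the sweep workhorse |
| CG tolerance | 1e-8 (config) × 1e-2 | keeps current balance ≪ the 1e-6 check |
| fixture p | 0.2 | a mostly-successful insertion, the regime the decoders target |

## Known limitations

- DC conduction only; capacitive skin behaviour is out of scope by design.
- Absolute currents shift with voxel size and taper treatment; only the
  packaged tables are suitable for decoding real measurements of the
  reference device.
- The exact decoder's one-to-one premise fails beyond ~4 tips per sheet;
  that failure is the motivation for the fuzzy method, not a defect of the
  implementation.
- Fuzzy decoding is defined only for the published pair/triple layouts
  (even sheet counts, or exactly three sheets).
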