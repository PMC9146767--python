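# penrate

Impedance-based estimation of the transdermal (penetration) rate of metallic
sheet microneedle arrays.

## The problem

A sheet microneedle biosensor only senses through the tips that actually
pierced the stratum corneum — the outermost, highly resistive skin layer
(~0.0005 S/m, vs ~0.2 S/m for the dermis).  Once the array is applied you
cannot count the penetrated tips optically, but you *can* measure the DC
current between two metal sheets under a 1 V drive: every unpenetrated tip
faces stratum corneum instead of dermis and removes a low-impedance path,
so the inter-sheet test current falls monotonically with the number of
unpenetrated tips.  `penrate` turns that observation into a measurement
pipeline for device engineers and biosensor researchers:

- a **forward model**: voxel finite-volume electrostatics of the array in a
  two-layer skin block, with the needle/skin interface as a contact-impedance
  boundary whose conductivity follows the per-tip penetration flag XY,
  σ_contact = (1 − XY)·σ_de + XY·σ_sc;
- **exhaustive sweeps** over all 2^(2n) penetration combinations of a sheet
  pair, and the statistics that divide the current axis into calibration
  intervals (boundaries at midpoints of adjacent state means);
- packaged **reference calibration tables** for 3×3, 4×4 and 6×6 arrays;
- two **decoders** that map measured pairwise currents back to per-sheet
  unpenetrated counts N and the transdermal rate 1 − N/(total tips):
  an *exact* branch-logic method (small arrays, one state per interval) and
  a *fuzzy* method using pairwise maxima, N = 1.5 × Σ(pair maxima) or
  N = N_MAX + 1.5·N_MED for a sheet triple.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Forward-solve one penetration state (tips A1 and B2 unpenetrated) on the
3×3 array at coarse resolution:

```bash
$ penrate simulate --array 3x3 --pair A-B --unpenetrated A1,B2 --voxel-size 100
I_AB = 382.66 uA (state 1-1)
```

One unpenetrated tip on each sheet (the 1-1 state) drops the A–B current
from ~549 μA (fully penetrated) to ~383 μA.

Generate a synthetic 6×6 measurement (each tip unpenetrated with
probability 0.2, seed 9) and decode it with the fuzzy method:

```bash
$ penrate fixtures --array 6x6 -p 0.2 --seed 9 -o fix/
$ penrate decode -i fix/currents.csv --array 6x6 --method fuzzy -o result.json
N = 7.5, transdermal rate = 0.7917
```

The drawn truth has per-sheet unpenetrated counts (0, 2, 1, 0, 1, 2) —
6 of 36 tips, true rate 0.833.  The disjoint pairs A–B, C–D, E–F classify
into calibration intervals with maxima (2, 1, 2), giving the estimate
N = 1.5 × (2 + 1 + 2) = 7.5 and rate 1 − 7.5/36 ≈ 0.792: the fuzzy method
trades a known 1/2 uncertainty rate (each pair's minimum is guessed as half
its maximum) for robustness on arrays too large for exact decoding.

The same pipeline is available as library calls
(`penrate.discretize` / `solve_pair_current` / `sweep_pair` /
`interval_boundaries` / `decode_currents`), and `penrate sweep` /
`penrate calibrate` rebuild a calibration table from scratch.

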