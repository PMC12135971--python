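# disksq

Structure factors of randomly packed hard disks in two dimensions —
equivalently, of parallel rigid cylinders viewed down the fiber axis — as a
function of the packing area fraction φ.

Dense fibrillar biological materials (cellulose microfibrils in wood cell
walls, collagen fibrils in cornea and tendon, sterically stabilized
colloidal rods) scatter X-rays and neutrons with the form factor of one
fibril multiplied by an interference function S(Q) of the packing.  At the
30–50% volume fractions typical of such tissues the two factors overlap on
the same length scale and are easily confused.  `disksq` produces the
liquid-like S(Q) of hard-disk packings by explicit simulation, so that
scattering models can separate particle shape from packing:

1. **Monte Carlo packing** — unit-radius hard disks in a periodic square
   box, hexagonal start, single-disk normal displacement moves with an
   auto-tuned step size, and a tile grid (cell list, one disk per tile)
   that makes each collision check O(1).
2. **Pair distribution function** — pair distances are histogrammed inside
   the circle inscribed in the box and normalized by the exact density of
   the distance between two uniform random points in a disk,
   ρ(x) = (16x/π)(arccos x − x√(1−x²)), x = r/l, which removes the finite
   geometry without edge corrections.
3. **Structure factor** — the zero-order Hankel transform
   S(Q) = 1 + 2πν ∫ h(r) J₀(Qr) r dr, with h = g − 1 tapered linearly to
   zero between l/4 and l/2, evaluated as one reusable matrix product;
   the noisy region below Q = 0.6 is replaced by a Q²-weighted parabola
   and the curve is Savitzky–Golay smoothed (window 29, order 3).
4. **Tabulation** — smoothed curves over an area-fraction grid are fitted
   with a bivariate degree-2 smoothing B-spline in (φ, Q) and serialized
   to a documented binary format plus a TSV mirror.
5. **Analytic references** — the scaled-particle (Rosenfeld-type) closed
   form, with Z = 1/(1−φ) and Ĵ(Q) = 2J₁(Q)/Q:

       1/S(Q) = 1 + 4φZ·J₁(2Q)/Q + 4φ²Z²·J₀(Q)Ĵ(Q) + φ²Z²(1+2φZ)·Ĵ(Q)²

   (exact in the dilute limit and at Q = 0, where S(0) = (1−φ)³/(1+φ));
   the infinite-cylinder form factor P(QR) = (2J₁(QR)/QR)²; and the
   intensity model I(q) = scale·S(qR)·P(qR) + background for comparing
   with fiber scattering data.

Lengths are in units of the disk radius; Q is the dimensionless QR, so a
physical scattering vector is Q/R for fibrils of radius R.

## Worked example

```python
import numpy as np
from disksq import pipeline, analytic, table

# simulate phi = 0.4 in a 100-radius box, average 50 pair distributions
pdf, info = pipeline.simulate_pdf(phi0=0.4, l=100.0, seed=42, n_samples=50)
curve = pipeline.pdf_to_curve(pdf)

print(f"realized area fraction: {info['phi_actual']:.4f}")
print(f"disks: {info['n_disks']}, acceptance rate: {info['acceptance_rate']:.2f}")
q_peak, s_peak = max(table.locate_peaks(curve, q_window=(1.5, 4.5)),
                     key=lambda p: p[1])
print(f"S(Q) main peak: Q = {q_peak:.2f}, S = {s_peak:.2f}")
ref = analytic.rosenfeld_sq(curve.phi, curve.q_grid[curve.q_grid >= 0.6])
dev = np.max(np.abs(curve.s[curve.q_grid >= 0.6] / ref - 1))
print(f"max deviation from the analytic form (q >= 0.6): {100*dev:.1f}%")
print(f"peak in physical units at R = 13 A: {q_peak/13.0:.3f} A^-1")
```

prints

```
realized area fraction: 0.3940
disks: 1254, acceptance rate: 0.52
S(Q) main peak: Q = 2.81, S = 1.51
max deviation from the analytic form (q >= 0.6): 5.6%
peak in physical units at R = 13 A: 0.216 A^-1
```

The lattice initialization floors the disk counts, so the realized φ sits
slightly below the 0.4 target.  The interference peak at QR ≈ 2.8 is what
appears at ≈ 0.21 Å⁻¹ for 13 Å fibrils; the few-percent deviation from the
closed form at this φ (a short scaled-down run) shrinks below 2% at lower
densities and longer averaging, while at φ ≳ 0.65 the analytic form fails
and only the simulated table is reliable.

## Command line

Each stage is also a subcommand of `disksq` (flags or a `key = value`
config file; every run writes a `run.log`):

```
disksq simulate --phi 0.6 --box 500 --sweeps 5000 --seed 1 --out runs/phi060/
disksq pdf      --in runs/phi060/ --out g060.tsv
disksq sq       --pdf g060.tsv --rmax 250 --out s060.tsv
disksq tabulate --phis 0.05:0.65:0.05 --box 200 --samples 100 --out table.bin
disksq compare  --table table.bin --out deviation.tsv
disksq saxs     --radius 13 --phi 0.4 --table table.bin --out intensity.tsv
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the headline numbers from scratch (about 3 minutes on one
core): the three diffraction-like peak positions of a fresh simulation at
target φ = 0.71 (hexagonal-ratio peaks 1 : √3 : 2), and the maximum
relative deviation of simulated structure factors from the analytic closed
form over Q ∈ [0.6, 10] for the low-density runs (φ₀ = 0.10–0.25).  The
`--seed` argument drives every random number; the JSON maps each quantity
to its value and the number of disks simulated.

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
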