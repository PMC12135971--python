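# Methods

## Model and scope

`disksq` computes the static structure factor S(Q) of an equilibrium (or,
at high packing, history-dependent) fluid of hard disks of unit radius in
two dimensions.  The system is equivalent to an array of parallel rigid
cylinders with uncorrelated axial positions, so S(Q) multiplies the
cross-section form factor of one cylinder in fiber-diffraction geometry.
The hard-core interaction is purely geometric: configurations are legal
iff every pairwise center distance (minimum image in the periodic box) is
at least 2.  Temperature plays no role; the only thermodynamic variable is
the area fraction φ = Nπ/l².

## Monte Carlo packing

* **Initialization.** Disks start on a hexagonal lattice with spacing
  a = √(2π/(√3 φ₀)), n_x = ⌊l/a⌋ columns and n_y = ⌊l/(a√3/2)⌋ rows
  (alternate rows offset a/2).  The realized φ = n_x n_y π/l² is therefore
  slightly below the target — all analyses use the realized value.  When
  n_y is odd and the wrap-around row gap falls below contact the last row
  is dropped; an O(N) cell-list scan certifies the start overlap-free.
* **Moves.** One uniformly chosen disk per attempt is displaced by
  independent N(0, σ²) steps per axis; any other center strictly closer
  than 2 rejects the move (touching at exactly 2 is allowed).  One sweep
  is N attempts.
* **Cell list.** The box is divided into n = ⌈l/√2⌉ tiles per side so that
  tile_side ≤ √2 and a tile can host at most one center.  Collision
  candidates are looked up in the 5×5 tile block around the proposed
  position.  The corner tiles of that block are *included*: excluding them
  (the idealized 20-tile rule) is exact only when tile_side = √2, while
  for tile_side < √2 a corner tile can hold a center just under distance
  2.  The superset guarantees bit-identical agreement with a brute-force
  check at every box size, at the cost of four usually-empty lookups.
* **Step-size tuning.** σ starts at a/2 − 1 and is multiplied by 0.8
  whenever a 10N-attempt window rejects more than half the moves, until a
  window passes.  Tuning runs once, at the start, and its sweeps count
  toward burn-in.  From an ordered (hexagonal) start the very first window
  often passes even at φ ≈ 0.71, so σ retains its initial value there;
  the shrink loop engages whenever σ is genuinely oversized for the state.
* **Burn-in.** Defaults: 100 sweeps for φ ≤ 0.5, 1000 above.  The local
  structure (contact peak of g) equilibrates within tens of sweeps, but
  the long-wavelength part of S is measurably suppressed if sampling
  starts too early: at φ = 0.6 the low-Q valley sits ~10% below the
  Percus–Yevick reference after 100 sweeps and recovers with 1000+.  Runs
  that compare low-Q behavior (the analytic-form band, the integration-
  limit study) use 1000–6000 sweeps explicitly.  Above φ ≈ 0.69 the
  system never decorrelates from its history on reachable time scales;
  there the sampled state is a near-hexagonal liquid and peak *positions*,
  not heights, are the reproducible observables.
* **Randomness.** A single numpy Generator seeded from the run seed
  produces move selections and displacements in a fixed order; identical
  seed and parameters give identical trajectories.  The hot loops (move
  kernel, pair histogram) are numba-compiled but consume pre-drawn
  random batches, so they are deterministic and stateless.

## Pair distribution function

Pairs are counted among disks strictly inside the circle of radius l/2
inscribed in the box, with *direct* (non-periodic) distances, in bins of
width w_b = 0.1 radii over [0, l] (N_b = l/w_b bins).  The histogram is
normalized by the expected counts of an ideal gas in the same geometry:
n_i = ρ(x_i)/N_b with the exact density of the normalized distance
x = r/l between two uniform points in a disk,

    ρ(x) = (16x/π)(arccos x − x√(1−x²)),  0 ≤ x ≤ 1,

and by the theoretical pair number N̄(N̄−1)/2, N̄ = ν π (l/2)², instead of
the per-sample count, which fluctuates.  The closed form is validated in
the test suite against a 10⁷-pair Monte Carlo oracle and exact
normalization.  Because the theoretical-count normalization is only
unbiased *on average*, finite ensembles inherit a g-scale fluctuation of
order 2·σ(N₀)/N₀/√k for k samples — the uniform-points oracle tolerances
budget for exactly this.  g is averaged over samples taken every 50
sweeps.

## Structure factor

    S(Q_i) = 1 + 2πν Δr Σ_j h(r_j) r_j J₀(Q_i r_j),   ν = φ/π,

a midpoint rule on the histogram bin centers up to r_max (default l/2),
evaluated with the reusable matrix A[i,j] = r_j J₀(Q_i r_j) so that a
family of samples costs one matrix–vector product each.  The correlation
function h = g − 1 (not g itself — tapering g would destroy the S → 1
limit) is multiplied by a window equal to 1 up to l/4 and falling
linearly to 0 at l/2, which suppresses truncation ringing from the weakly
sampled tail.  The Q grid is 0 to 10 in steps of 0.01.  Below Q = 0.6 the
transform oscillates spuriously; those values are replaced by a parabola
fitted on (0, 0.6] with weights ∝ Q² (the weight vanishes at Q = 0, so
the worst points do not steer the fit).  Finally the curve is smoothed
with a Savitzky–Golay filter, window 29 grid points (0.29 in Q),
polynomial order 3 (order unstated in the underlying procedure; 3 is the
package default and configurable) — degree-≤3 signals pass through
unchanged.

Truncation behavior: at φ = 0.6 curves with r_max = 25 and 200 differ by
less than 0.02 for Q > 1; at φ ≈ 0.71 an r_max below ~100 visibly smears
the sharp second peak near Q = 5.6.  Sharp peaks carry windowed-sinc
sidelobes at spacing ~π/r_max; the `principal_peaks` helper therefore
ranks local maxima by height with a minimum separation of 0.5 in Q
(hexagonal-order peaks are ≥ 0.85 apart), which rejects sidelobes without
touching the physical peaks.

## Tabulation

Smoothed curves on the φ grid (0.05 to 0.65 in steps of 0.05, optionally
0.70 — that row is lower-confidence because of history dependence) are
fitted with scipy's bivariate B-spline (`bisplrep`), degree 2 in both
variables, unit weights, smoothing factor 0.1.  The table serializes to a
little-endian binary layout (magic `DISKSQTB`, version, grid sizes,
length-prefixed float64 arrays for grids, values and spline knots, plus a
JSON provenance blob) with a TSV mirror; round trips are bit-exact.
Evaluation outside the tabulated (φ, Q) rectangle raises instead of
extrapolating.

## Analytic references

The scaled-particle closed form implemented here,

    1/S(Q) = 1 + 4φZ·J₁(2Q)/Q + 4φ²Z²·J₀(Q)Ĵ(Q) + φ²Z²(1+2φZ)·Ĵ(Q)²,
    Z = 1/(1−φ),  Ĵ = 2J₁(Q)/Q,

was reconstructed from fundamental-measure/scaled-particle theory (the
three terms are the transforms of the excluded-area core, the disk–shell
cross convolution, and the disk–disk overlap area; note
φ²Z²(1+2φZ) = φ²·(1+φ)/(1−φ)³, the SPT inverse compressibility).  It is
exact in two independent limits — the second-virial form
S = 1/(1 + 4φ J₁(2Q)/Q) as φ → 0, and S(0) = (1−φ)³/(1+φ) — and was
screened against a numerical Percus–Yevick Ornstein–Zernike solution
(development-time oracle only): maximum relative deviation ≈ 0.3%, 1.1%,
2.5% at φ = 0.1, 0.2, 0.3, growing to ~9% at φ = 0.6 and unbounded
beyond — the expected failure of compressibility-route closed forms as
hexagonal-like order develops.  Against package simulations the
deviation over Q ∈ [0.6, 10] is ≲1% for φ < 0.2 and ≲2% for φ < 0.3;
at φ ≈ 0.6 the main peak matches within ~2% in position but the shallow
valley near Q ≈ 1 (S ≈ 0.05) differs by up to ~13% relative.  The form
loses positivity above φ ≈ 0.77, so the implementation restricts its
domain to φ ≤ 0.75.  Because the published coefficients could not be
consulted directly, residual transcription uncertainty of order 1% at
moderate φ cannot be excluded; all package claims about the analytic
form are stated at the levels actually validated above.

The cylinder form factor is P(x) = (2J₁(x)/x)², x = QR, with zeros at the
roots of J₁ (first at 3.8317).  The intensity model is
I(q) = scale·S(qR; φ)·P(qR) + background, with an optional q·I(q) output
for comparison with azimuthally averaged fiber data (a perfectly aligned
line trace vs. a powder-like average differs by one factor of q).  The
product peak always sits below the bare S peak in q because P decays —
the reason interfibrillar spacings read off raw intensity maxima are
systematically overestimated.

## Scaled-down protocols and what a green test establishes

The acceptance checks run minutes, not the hours of a full production
tabulation, using the presets in `disksq.pipeline`:

| protocol | φ₀ | box l | burn-in | PDFs | purpose |
|---|---|---|---|---|---|
| PEAK_RUN | 0.71 | 190 | 1000 | 40 | peak positions (l = 190 maximizes realized φ = 0.7091 against lattice flooring) |
| ROSENFELD_RUN | 0.10–0.25 | 200 | 1000 | 1800 | deviation from the analytic form |
| DILUTE_RUN | 0.05 | 200 | 100 | 1600 | first-virial closed-form check |
| TRUNCATION_RUN | 0.60 | 400 | 6000 | 60 | r_max sensitivity (r_max up to 200) |
| BAND_RUN | 0.30–0.50 | 150 | 1000 | 100 | wood-band table and peak location |

Sample counts come from the transform noise budget
Var[S(q)] ≈ 16·r_max/(π q n l²) (empirically verified): maximum-deviation
statistics over ~10³ grid points demand point noise well below the band
being tested.  The dilute check needs 1600 PDFs because the first-virial
form itself is wrong by a genuine second-virial excess of up to ~0.008
at low Q for φ ≈ 0.05 — the 0.01 band leaves only ~0.002 for noise.
Burn-in for the truncation study was set by measurement: residual lattice
memory in the large-r tail inflates the r_max = 25 vs 200 difference at
Q ≈ 1, halving between 1000 and 4000 sweeps.

A green suite establishes that the pipeline reproduces the documented
observables *at these scales*: peak positions at φ ≈ 0.71 to ±0.1,
analytic-form agreement to the 1%/2% bands, truncation insensitivity at
0.02, and the wood-band peak near QR = 2.75.  It does not certify
production-scale (l = 500, thousands of PDFs) noise levels, the 0.70
table row (history-dependent), or any soft-interaction extension.

## Known limitations

* Above φ ≈ 0.69 results depend on initialization and run length; only
  peak positions are stable observables.  Alternative packing generators
  (disk swelling/expansion) are out of scope.
* The analytic reference is a validated reconstruction (see above), not a
  verbatim transcription; its documented envelope is the authority.
* The fixed-N canonical box suppresses number fluctuations at wavelengths
  comparable to the box; quantified here as < 10⁻⁴ in S for l ≥ 200 after
  tapering (negligible at the tested tolerances).
* Monodisperse disks only; no polydispersity, soft tails, or oriented
  (non-azimuthally-symmetric) form factors.
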