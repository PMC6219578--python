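# Methods

`cardiomaze` simulates how an infarct region — ischemic myocytes interleaved
with non-conducting fibrosis — can turn into an ectopic pacemaker through
micro-reentry, and estimates the probability of that outcome as a function
of the fibrosis fraction φ and the hypoxia level [ATP]i.

## Cell model

The membrane model is the ten Tusscher–Panfilov 2006 epicardial human
ventricular formulation with reduced concentration dynamics: intracellular
Na⁺ and K⁺ are held at their 1 Hz paced steady-state values (8.604 and
136.89 mM), while the calcium subsystem (cytosolic, subspace and SR calcium
with RyR release gating) is retained in full.  Units are mV, ms and
per-capacitance currents (pA/pF), so the membrane capacitance cancels in
the cell ODE.

Ischemia enters through three mechanisms:

* **Hypoxia.**  An ATP-sensitive K⁺ current
  `I_KATP = g_KATP (V − E_K)` with
  `g_KATP = G_max · P_ATP · ([K]o/5.4)^0.24` and
  `P_ATP = 1/(1 + ([ATP]i/0.25 mM)^2)`, plus an ATP gate on the L-type
  Ca²⁺ permeability, `P_CaL,ATP = 1/(1 + (1.4 mM/[ATP]i)^2.6)`.
* **Hyperkalemia.**  Elevated [K]o enters every potassium reversal
  potential and the √([K]o/5.4) scalings of I_K1 and I_Kr.
* **Acidosis.**  Multiplicative scales f_gCaL, f_gNa ∈ (0, 1] on the
  L-type Ca²⁺ and fast Na⁺ conductances.

**Calibration of G_max.**  The source formulation expresses the K_ATP
conductance on a channel-density scale (`195×10⁻⁶/Nichols_area nS/cm²`,
`Nichols_area = 5×10³`) that has no unique conversion into per-capacitance
units.  The package fixes the effective maximal conductance once, by
bisection, so that a single hypoxic cell ([ATP]i = 3 mM, everything else
healthy) paced at 1 Hz has APD90 = 50 ms — the documented hypoxic behaviour
of the modified model.  The result, `g_katp_max = 7.223 nS/pF`, is frozen
in `KatpConstants` and reproducible with `scripts/calibrate.py`.

**Known limitation.**  With the Hill exponent H = 2 the K_ATP conductance
contrast between healthy (6.8 mM) and hypoxic (3 mM) ATP is capped at
(6.8/3)² ≈ 5.1×, and the APD-vs-conductance response of this baseline is
close to linear (≈ −10 ms per 0.00135 nS/pF) before saturating.  No single
conductance therefore satisfies both the healthy (≈300 ms) and the hypoxic
(≈50 ms) APD anchors: anchoring the hypoxic value — which governs the short
wavelengths that drive every reentry experiment in this package — leaves
the healthy APD90 at ≈228 ms and the combined-ischemia APD90
([ATP]i = 4 mM, [K]o = 7 mmol/l, 50% g_CaL/g_Na) at ≈56 ms rather than
≈100 ms.  A related definition effect: with [K]o = 7 the diastolic
potential rises to ≈ −79 mV and the AP tail flattens, so APD90 measured
toward the hyperkalemic diastolic potential reads much shorter than one
measured toward −85 mV.  The APD definition used everywhere is: upstroke
crossing of −20 mV (rising) to 90% repolarization toward the pre-stimulus
diastolic potential.

**Numerics.**  Gates use the Rush–Larsen exponential update (exact for
frozen rates); concentrations use forward Euler; dt = 0.02 ms.  The
production path is a numba kernel with all voltage-dependent factors
tabulated on a 0.01 mV grid (nearest-neighbour lookup) built from the same
rate functions as the plain-NumPy reference implementation; the two paths
are compared in the test suite.  Calcium concentrations are floored at
10⁻⁹ mM; single-cell pacing uses −52 μA/μF for 1 ms at 1000 ms intervals,
five beats, measuring the last.

## Tissue model

Monodomain reaction–diffusion on a regular hexahedral grid,
cell-centred finite volumes with a 6-face stencil, harmonic-mean face
conductivities, and no-flux boundaries; non-conducting cells carry no state
and exchange no flux.  Operator splitting advances the reaction at
dt = 0.02 ms and the diffusion term explicitly; when the explicit stability
bound `dt ≤ h²βC_m/(2dσ)` is tighter than 0.02 ms (it is at h = 100 μm in
3D), the diffusion update is sub-stepped automatically, with a hard error
past 64 sub-steps.

σ, β and C_m are not fixed by the physiology alone; the defaults
(σ = 1.85 mS/cm, β = 1400 cm⁻¹, C_m = 1 μF/cm²) were calibrated once so a
healthy planar wave at h = 200 μm travels at ≈67 cm/s, a typical human
ventricular conduction velocity.  Stimulus amplitudes are per-capacitance
(μA/μF, negative depolarizing) for consistency with the cell model.

Event definitions: activation = upward crossing of −20 mV with a 10 ms
refractory guard; repolarization = downward crossing of the per-cell 90%
level toward its running diastolic reference.  Runs terminate early once
every cell has been below −75 mV for 20 ms after the stimulus (no further
activity is possible); the record notes the truncation time.

## Synthetic geometry and fibrosis

The synthetic wedge is a regular slab with a cylindrical (transmural) or
spherical scar core, a peri-infarct shell and a healthy rim.  Inside the
PZ, [ATP]i and φ ramp linearly with radial distance from their scar values
to (6.8 mM, 0) at the outer PZ edge.  Diffuse fibrosis removes lesion
cells independently (Bernoulli per cell with the local φ) at (100 μm)³
resolution — each removed block stands for a pack of ≈25 myocytes — and
coarser grids refuse fibrosis generation rather than rescaling, because
percolation behaviour is lattice-resolution dependent.

What the generator does **not** emulate: patient-specific lesion shapes,
anisotropic fiber architecture, patchy/interstitial/compact fibrosis
patterns, and myocyte–fibroblast coupling.  Passing tests therefore show
that the mechanism operates on idealized lesions, not that any particular
patient geometry is pro-arrhythmic.

## Percolation

Connectivity is 6-neighbour face adjacency, matching the flux stencil, so
"same cluster" is exactly "electrically connected".  Spanning means one
conducting cluster touches two opposite domain faces (by default along any
axis; thin slabs should restrict to in-plane axes).  The threshold
estimator scans a φ grid, enforces monotonicity with a decreasing isotonic
fit and interpolates the 0.5 crossing; on a 32³ lattice with 200 trials
per φ it reproduces the cubic-lattice removed-fraction threshold
(measured 0.688; literature 1 − 0.3116 ≈ 0.688, commonly quoted as 0.68).
Useful measured slab values (60×60×n, in-plane spanning): n = 1 → 0.41,
n = 2 → 0.53, n = 4 → 0.61, n = 6 → 0.63, n = 8 → 0.65.

## Monte-Carlo sweep

`SweepDesign` mirrors the study protocol: φ = 0.64…0.69 in steps of 0.01,
scar [ATP]i ∈ {2, 3} mM, 20 maze realizations per pair (240 runs), one
point-like stimulus in the healthy rim, classification of sustained
reentry 1 s after the stimulus (an activation event within ±50 ms of the
1 s mark, or any cell above −70 mV there).  Per-run seeds derive from
`SeedSequence([base_seed, i_phi, i_atp, i_realization])`, so any single
run is reproducible in isolation; failed runs are recorded and excluded
from denominators; aggregation reports Wilson 95% intervals.

**Desk-scale limitation (important).**  The default wedge is a 6×6 mm,
one-cell-thick slab with a 2 mm scar — sized for tens of seconds per run.
Systematic experiments with this solver show that sustained micro-reentry
does not occur at that scale, for two reasons measured directly:

1. *Dimensionality of the source–sink mismatch.*  In a one-cell-thick
   lattice a wave exiting a one-cell strand into an open sheet blocks
   robustly (the unidirectional-block test), but inside a near-threshold
   maze the exits open into small pockets whose sink is too small to
   block; no wavebreaks form at any φ, so every realization activates once
   and dies (re-excited cells: 0 across all probes).
2. *Circuit length vs wavelength.*  In thin-3D slabs (8 layers), where
   blocks and re-excitations do occur, the fractionated wave traverses an
   8 mm lesion in ≈50–100 ms while the hypoxic wavelength is ≈2–4 mm;
   transient reentrant loops complete one to a few cycles (up to ≈16
   re-excited cells per realization near φ_c) but find no circuit long
   enough to outlast refractoriness.  Extrapolating the measured traversal
   times, self-sustained circulation requires lesions of roughly
   centimetre scale — the size of the study's patient wedges — which is
   ~10⁶ cells × 75 000 steps per realization, far beyond a desk-scale
   Monte-Carlo budget.

Consequently the scaled-down sweep reports reentry fractions of ≈0
everywhere, the band property ("> 0 somewhere in φ ∈ [0.60, 0.72]") fails
at desk scale, and the comparative properties (2 mM ≥ 3 mM; larger scar ≥
smaller) hold degenerately at 0 = 0.  The mechanism itself is verified at
desk scale by two deterministic experiments: unidirectional block at a
strand exit, and transient micro-reentry loops in a thin-3D maze just
below its percolation threshold.

## Tunable parameters (defaults)

| parameter | default | units | why |
|---|---|---|---|
| dt | 0.02 | ms | fixed time discretization of both solvers |
| h (lesion) | 100 | μm | fibrosis block size; percolation scale |
| σ | 1.85 | mS/cm | healthy CV ≈ 67 cm/s at h = 200 μm |
| β | 1400 | 1/cm | typical ventricular surface-to-volume ratio |
| C_m | 1.0 | μF/cm² | standard monodomain value |
| g_katp_max | 7.223 | nS/pF | hypoxic anchor APD90(3 mM) = 50 ms |
| [K]o,normal | 5.4 | mmol/l | baseline of the cell model |
| stimulus | −52, 1–3 | μA/μF, ms | ≈2× threshold, standard practice |
| sweep slab | 60×60×1, 2 mm scar | — | desk-scale default (see limitation) |

## Degenerate inputs and tie-breaks

Zero-radius scars give all-healthy grids; φ = 0 gives no removals; grids
whose lesion touches a non-transmural boundary are rejected; a cell fully
surrounded by fibrosis has an all-zero operator row and evolves as an
isolated cell; multiple activations within 10 ms count once; percolation
threshold interpolation averages the bracketing grid points when the
isotonic fit is flat at 0.5.
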