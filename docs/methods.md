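# Methods

This note documents the models, statistics and numerical choices behind the
package: what each component computes, which parameters matter, what the
synthetic data emulate (and what they do not), and where the design was
genuinely open.

## The fractional-distance statistic

The dispersion of a fluorescently labeled organelle population inside one
cell is summarized by a radial statistic. With the nucleus center as origin,
every in-mask pixel contributes its full intensity to a 1-px-wide annulus at
its center-to-center distance; distances are normalized so that the farthest
mask pixel (the cell border) maps to 1. The fractional distance

> d_f = min { r : cumulative intensity inside radius r ≥ f · total }

is the smallest normalized radius whose annuli contain a fraction *f* of
the cell's total fluorescence. Peripheral clustering pushes d_f → 1;
perinuclear clustering pulls it toward nucleus-radius / r_max. d_f is
nondecreasing in *f*, invariant under global intensity scaling, and
invariant under rotation about the center up to one bin.

Numerical conventions (fixed because no standard exists):

- annuli store **integrated** (summed) intensity, not the per-annulus mean a
  radial-profile plugin typically reports — d_f is defined through fractions
  of total intensity, so bins must add up to the cell total;
- bins exactly partition [0, r_max] with n = ⌈r_max⌉ equal bins (physical
  width ≤ 1 px); d_f is reported at the **upper edge** of the first bin
  reaching f·total, so the stated fraction is fully contained;
- quartiles in box summaries use linear interpolation between order
  statistics (inclusive convention);
- cells with zero in-mask intensity in any frame are rejected, not imputed;
- `select_f` scans a grid of fractions for the one maximizing the absolute
  mean d_f difference between an initial and a final condition, breaking
  ties toward larger f (keeping more of the signal).

### Accuracy of time constants fitted to d_f(t)

A movie whose *distribution* relaxes exponentially between two states with
time constant τ does not, in general, give a d_f(t) curve that is a clean
exponential with the same τ: the quantile of a mixture responds
nonlinearly to the mixture weight. Where the start distribution is strongly
clustered at the far periphery and f is high, the response is very
sublinear and a single-exponential fit overestimates τ severalfold (the
bias is analytic — it can be reproduced by root-solving the mixture CDF,
with no sampling noise at all). The response is near-linear, and τ is
recovered within a few percent, for the perinuclear-release direction at
f ≈ 0.7–0.75, which is the configuration the recovery analyses here use.
When comparing fitted time constants across conditions, keep f and the
release direction fixed; absolute τ values from the peripheral-release
direction should be treated as upper bounds.

## Synthetic data

The generator produces every input the analysis needs with known ground
truth. It emulates:

- **cell geometry**: circular, elliptical or smoothly lobed ("blob") masks
  with the nucleus center annotated; r_max is computed from the mask;
- **organelle fields**: point organelles whose normalized radii follow a
  mixture of three families — perinuclear Beta(1, c), peripheral Beta(c, 1)
  and area-uniform (CDF r²) — with uniform angles, rejection-sampled into
  the mask. The concentration c sharpens clustering. Defaults: peripheral
  c = 8 (tight accumulation at the membrane, as in motor-driven peripheral
  clustering); perinuclear c = 2, broader because a perinuclear cluster
  rings the nucleus at ~0.2–0.3 normalized radius rather than collapsing to
  the geometric center. The steady state is modeled as 60% perinuclear
  (c = 2) + 40% uniform — a modeling choice, since no quantitative
  description of the steady-state distribution exists, only "higher
  concentration in the perinuclear area". One consequence worth knowing:
  with this synthetic steady state the peripheral-vs-steady contrast
  |Δ mean d_f| peaks at low f, not in the 0.70–0.95 band reported for real
  cells — the f-selection sweep is condition-dependent by design;
- **images**: each point deposits a Gaussian spot (exact per-pixel
  integrals via the normal CDF, so total intensity is conserved to < 1% for
  σ ≥ 1 px and spots ≥ 4σ from the border); optional Poisson shot noise and
  Gaussian read noise, both off by default so oracle tests are exact;
- **recovery movies**: at time t the field is a mixture with weight
  exp(−t/τ) on the start spec and 1 − exp(−t/τ) on the end spec, sampled
  fresh per frame (the downstream statistic is distributional; no
  per-organelle tracking is implied). Default cadence mirrors live-cell
  acquisition: 1 frame/min for 45 min;
- **motion movies**: spots translating at constant signed speed along a
  straight horizontal path (0.6–1.1 μm/s covers the measured neuronal
  range); spots leaving the field are flagged truncated;
- **shape populations**: non-overlapping disks (round) or capsules with
  aspect ratio in [2, 5] (elongated), with analytic per-object area, axes
  and perimeter.

Not emulated: realistic optics (Airy PSF, z-blur), photobleaching, camera
gain, neuron-shaped geometries, organelle motion within a frame. Passing
tests on these data demonstrate the correctness of the *analysis*, not
robustness to every imaging artifact.

All generators are pure functions of (parameters, seed).

## Tug-of-war transport model

A cargo carries fixed numbers of plus-end kinesins and minus-end dynein on
a 1-D radial track, x ∈ [r_nuc, R_cell] (defaults 5 and 20 μm, a typical
adherent cell), plus ends at the periphery. The kinetics follow the
classical stochastic tug-of-war framework:

- binding of species i: (N_i − n_i)·π0_i;
- unbinding: n_i·ε0_i·exp(F_c / (n_team·F_d_i)) — exponential in the load
  per bound team member;
- linear force–velocity per motor (forward speed v_F to stall F_s,
  back-slip at v_B beyond), equal load sharing within a team, team stall
  forces additive, team speeds force-weighted harmonic means (this reduces
  exactly to the two-team single-species reference formulas).

With both teams bound, the common load F_c solves force balance between the
winning team's forward branch and the losing team's back-slip branch:

> F_c = (v̄_F^win + v̄_B^lose) / (v̄_F^win/F_win + v̄_B^lose/F_lose),

which lies between the two team stall forces and equals both at a draw; the
cargo velocity is v = (F_win − F_lose)/(F_win/v̄_F^win + F_lose/v̄_B^lose),
signed toward the winner. With one team bound the cargo runs unloaded. The
load-assignment convention is stated explicitly because the reference
family leaves it implicit and it must be pinned to be testable.

The bound-count state space is tiny, so all rates, velocities and
transitions are precomputed per state and the simulation is an exact
event-driven (Gillespie) process: exponential waiting times from the total
rate, linear motion between events, position clamped at both boundaries
with kinetics continuing (so boundary accumulation is representable — this
is how the pre-release clustered initial condition persists). A
first-order fixed-step integrator of the same kinetics (dt = 1 ms) is kept
as an independent cross-check; the two agree in ensemble mean position
within sampling error.

**Parameters.** Single-motor kinetics are literature values of this model
family: kinesin π0 = 5 s⁻¹, ε0 = 1 s⁻¹, F_s = 6 pN, F_d = 3 pN, v_F =
1.0 μm/s (0.8 for the kinesin-3-like species), v_B = 6 nm/s; dynein π0 =
1.75 s⁻¹ (within the 1–2 s⁻¹ range), ε0 = 0.27 s⁻¹, F_s = 7 pN
(optical-trap stall of mammalian dynein), F_d = 2 pN, v_F = 0.65 μm/s,
v_B = 72 nm/s. Copy numbers (1 + 1 kinesins vs 3 dynein) were chosen, as
part of model setup, to put the two teams near force balance: this is the
regime in which the steady-state radial distribution is an interior spread
(not pinned at either boundary) and release from either boundary relaxes
exponentially toward it — the wild-type phenotype the model exists to
reproduce. The balance is genuinely delicate (the tug-of-war is bistable
in copy number), so changing any motor parameter generally requires
re-balancing the stoichiometry.

**Ensembles.** Releases start with all motors detached (the cargo was held
by the exogenous construct, which is represented only through the initial
condition): periphery → x0 = R_cell, center → x0 = r_nuc, steady → x0 from
a long-run pre-simulation (uniform start + 900 s burn-in). Per-cargo RNG
streams are spawned from one master seed. The point-based d_f at each
sample time is the minimal normalized radius (x/R_cell) containing a
fraction f of cargos; its uncertainty is a bootstrap SD over cargos (200
resamples) — whether the reference uncertainty was per-cargo or
per-replicate is unstated, so bootstrap-over-cargos is used and documented.
With the default parameters the model's intrinsic relaxation time is
~1 min, faster than measured recoveries (~20–30 min); the gap is expected,
since cellular reversal kinetics include the reagent uptake and
dissociation steps the transport model deliberately omits. Ensemble
analyses therefore sample at 10 s over an 8-min window — sized to resolve
the model's own decay plus a plateau — rather than the 1/min × 45 min
cadence of the microscopy protocol.

## Mitochondrial morphometry

The preprocessing chain is applied in the stated order with the stated
parameters: rolling-ball background subtraction (radius 50 px), despeckle
(3×3 median), CLAHE (kernel 9; the max-slope parameter s maps to the
clip limit as s/256 of the local histogram), bandpass with limits (0,
256 px) — retained for chain fidelity but a no-op whenever the limits do
not cut the image's spectrum — then Li auto-thresholding and 8-connected
labeling. Border-touching objects are retained by default (flag available)
since the original macro's behavior is unstated.

Descriptors per object: area, Crofton (weighted boundary-step) perimeter —
a pixel-edge count would bias the form factor upward — moment-fitted
ellipse axes, aspect ratio AR = major/minor, form factor
FF = perimeter²/(4π·area) (the standard formula with minimum 1 for a
circle). "Length" is the ellipse major axis, consistent with the AR
definition. Per-image aggregates: object count, mean length, area² =
Σa²/Σa (self-weighted mean size), mean AR, mean FF and area-weighted FF =
Σ(a·FF)/Σa. Objects too small to fit an ellipse are excluded and counted.
Two conditions are declared *changed* when ≥ 3 of the six aggregates
differ at α = 0.05 under a two-tailed two-sample t test (pluggable;
a rank-based alternative is provided).

## Kymographs

Frames are resampled along a traced soma→tip polyline at unit arc-length
steps with bilinear interpolation; widths > 1 average perpendicular
offsets (the interpretation adopted for the "reslice then Z-project"
toolchain step, which collapses the width dimension). Row k of the
kymograph is frame k's straightened line, so per-frame path-integrated
intensity is conserved. Segment endpoints are *inputs* (ground truth or a
user annotation file), mirroring manual measurement — automatic line
detection is intentionally out of scope. Speed = |Δd|·pixel_size /
(Δframes·frame_interval); direction follows the slope sign (toward the
tip = anterograde), with |speed| < 0.05 μm/s (config-exposed) labeled
stationary, since "vertical" lines need a numeric cutoff.

## Problem sizes and reproducibility

Test and summary runs use 500-cargo ensembles (the study-scale condition),
200-cargo integrator cross-checks, 20-seed movie fits, 30-image morphology
groups and 10⁴-point sampling checks. `scripts/acceptance.py --seed S
--out results/acceptance.json` recomputes every reported quantity from
scratch; all randomness derives from the one seed. Known limitations are
stated above inline: 1-D transport geometry, no optics realism, the
quantile-response bias of fitted time constants, and the delicacy of team
balance in copy number.
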