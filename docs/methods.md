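# Methods

This note records the models, numerical choices and known limitations
behind each module, in the order the pipeline runs them.

## Coil field model

The wand is modelled as a single circular filament with lumped
ampere-turns (default radius 0.075 m, 11 AT RMS).  The winding
cross-section, self-inductance, tuning and any tissue eddy-current
perturbation are ignored: at low-MHz operation the quasistatic
approximation holds over head-scale distances, and the filament field
has an exact closed form in the complete elliptic integrals K and E.
Because the drive is specified RMS, the returned field is the RMS
amplitude; no waveform is modelled.  Points within 1 µm of the filament
raise an error rather than returning a near-singular value.  The
implementation is validated against an adaptive Biot–Savart line
integral (independent quadrature, agreement < 1e-9 T over the head
volume), a mirror-symmetry property, exact linearity in ampere-turns, a
divergence stencil, and the 1/r³ dipole asymptote beyond ten radii.

## Head geometry and voxelization

Head surfaces are watertight icosphere-based ellipsoids (default
semi-axes 70 × 90 × 80 mm — a realistic adult half-breadth/length/height
— subdivided until the edge length reaches the requested resolution).
These stand in for anatomical surface meshes; the coverage machinery
accepts any watertight STL/PLY/OBJ mesh in mm.

The interior is discretised on a rectilinear grid (default 1 mm;
centre-of-voxel convention, 0-based indices, one-voxel margin).  A voxel
centre is *strictly inside* or not: containment is decided by vertical
column ray parity — every triangle is rasterised over the column lattice
with a half-open edge rule so a crossing on a shared projected edge is
counted exactly once, and any column whose total crossing count comes
out odd (an exact-tie pathology) is re-resolved on a nudged column.  A
second, independent containment algorithm (generalized winding number,
van Oosterom–Strackee solid angles) cross-checks the mask in the tests.
On a 50 mm sphere at 1 mm spacing the strict-interior count agrees with
the analytic volume to 0.06%.

Closest-point/distance queries used by pose placement run a vectorised
exact point–triangle search over KD-tree-preselected candidate faces,
falling back to the exhaustive search whenever the candidate ring cannot
be proven to contain the nearest face; signs are positive outside.

## Wand pose placement

Pose seeds are quasi-uniform directions (golden-angle spiral; the seed
only rotates the spiral phase).  Each seed is optimized by nonlinear
least squares over a free 3-D point that is *projected* onto a
scalp-contact pose: the contact point is the nearest surface point, the
coil axis is the barycentrically interpolated outward vertex normal
there, and the coil plane sits one housing thickness (standoff, default
5 mm) above the contact point along the axis.  The residuals are the 16
rim-point distances to the surface minus the standoff, so the search
slides the contact point to whichever placement lets the whole coil hug
the head most closely.  Rim penetration beyond 0.25 mm invalidates a
pose; failed seeds are dropped and logged, never substituted.  On a
sphere of radius R this construction has a closed form — every rim point
sits at √((R+s)² + r²) from the centre — which the tests verify to
better than 1 mm.

## Orientation minimax

The available field at a point with implant orientation **a** is
max over poses of |**B**_p·**a**|; the worst case W minimises this over
the unit sphere.  Properties used by the solver:

* With fewer than three linearly independent field vectors an exactly
  orthogonal orientation exists (SVD null space) and W = 0.
* f(**a**) = max_p |**B**_p·**a**| is piecewise linear in the angle with
  Lipschitz constant max|**B**_p|, so a direction sample with covering
  radius θ overestimates the minimum by at most θ·max|**B**_p|.
* Local minima occur where up to three constraints are active; the
  equal-|dot| solutions of pose triples (all sign patterns) and the
  pairwise cross products enumerate every candidate basin for small pose
  counts.

The single-point solver samples 2562 icosphere directions, restarts a
shrinking-ring pattern search from every sampled local minimum (by
icosphere adjacency), from the smallest singular vector and from the
enumerated active-set candidates, and returns the best.  Against an
exhaustive 100,000-direction search it is never higher, and doubling the
sampling density changes the result by far less than 0.5% — to machine
precision on the tested instances, because the candidate enumeration
pins the global basin.

The map-scale solver (hundreds of thousands of voxels × ~10² poses)
cannot afford that per voxel.  It evaluates a coarse 162-direction pass
with a running maximum over poses, takes the three best local minima of
the coarse field per voxel, re-evaluates them on their fine-icosphere
(2562) neighbourhoods, and finishes with a vectorised pattern-search
polish of every voxel simultaneously.  Spot checks against the
single-point solver show agreement within a few percent, and the map
invariants (W ≤ M, classification thresholds, exact amp-turns scaling)
hold at every voxel by construction.  The classification threshold is
the bench-measured 28 µT RMS powering minimum at ideal orientation.

Reduced problem sizes are used where full resolution adds nothing to
the property under test: the end-to-end demonstration runs the default
ellipsoid at 2 mm spacing with 120 poses (and the packaged demo config
at 4 mm with 48), while the operation defaults remain 1 mm and 720
poses.

## SAR duty-cycle arithmetic

All SAR field values are *inputs* (a quasistatic solver's printed
outputs); the module implements only the IEEE C95.1 time-averaging on
top: psSAR averaged over 360 s (limit 2 W/kg), whole-body absorbed power
averaged over 1800 s (limit 0.08 W/kg), a single measurement of at most
120 s per window.  Minimum safe mass and maximum measurement time are
exact algebraic inverses.  Rounding (2 decimals for W/kg, nearest
0.05 kg for mass) happens only at the reporting layer.  Repeated
measurements within one averaging window are out of scope: the device
permits one 120 s exposure and typical use is far shorter.

## Drift and aging qualification

Zero-point error: implant absolute pressure − (barometer + head_cm ×
0.73559 mmHg/cm).  The fluid-head constant is used verbatim, never
re-derived.  A missing barometer reading is an error — the reference is
never silently assumed.  Series are re-zeroed at the first reading, so
the statistic is pure change over time; it is invariant to any
common-mode offset of implant and barometer.  Qualification is
per-implant maximum |excursion| against the limit (the conservative
reading; the cohort mean ± SD envelope is also reported).  Drift rates
are estimated by OLS of the zero-point series on elapsed years; on
synthetic logs the fitted slope recovers the injected rate within
3 standard errors in ≥ 95% of seeded replicates across rates 0–5
mmHg/yr.

Accelerated aging uses the Q10 shortcut AF = Q10^((T_el−T_w)/10) × duty
rather than a fitted activation energy.  Defaults: 39 °C working, 85 °C
elevated, Q10 = 2, duty 162/168 (the weekly hours actually spent hot),
giving AF = 2^4.6 × 162/168 = 23.385, reported as 23.4 at one decimal
(a truncated 23.3 is sometimes quoted for the same protocol).  Weeks
convert to years with a 365.25-day year, so 22 elevated weeks ≈ 9.86
years.

Accuracy grids must *span* 475–950 mmHg × 35–45 °C before they are
judged; a non-spanning grid is a coverage failure, deliberately distinct
from a tolerance failure.  Pass requires every cell within ±2 mmHg and
±2 °C (temperature mirrors pressure: reading − set point).  The default
synthetic grid is 22 pressures × 21 temperatures = 462 measurements.

## ICP analytics

Per reading (≥ 5 s at 50 Hz): mean ICP is the arithmetic mean; the
cardiac component is isolated by a zero-phase (forward–backward)
4th-order Butterworth band-pass, default 0.67–3.0 Hz (40–180 bpm).
Beats are segmented by peak detection with a minimum spacing of 70% of
the shortest in-band period and a prominence floor of a quarter of the
filtered signal's 5–95% spread; peak times are refined by parabolic
interpolation so the heart-rate estimate is not sample-quantised
(noiseless recovery is exact to < 0.01 bpm across 50–110 bpm).  The
amplitude is the *median* over beats of peak-to-trough on the filtered
signal; a single-bin spectral amplitude is available as a cross-check
mode.  Fewer than five beats flags `low_beats`; a dominant frequency
within 5% of a band edge flags `aliased`.  The amplitude is invariant
to constant offsets and exactly linear in signal scale.

Diary analytics group per-reading rows by posture (ICP is strongly
posture dependent and legitimately negative upright).  Rolling medians
and IQRs over a configurable window summarise stability; the stability
statistic is the largest deviation of any window median from the
posture's whole-diary median.  Excursion flagging compares each reading
with the *trailing* per-posture median (reading excluded) and flags
deviations beyond k × IQR (default k = 3, an arbitrary descriptive
choice, not a clinical threshold); readings with fewer than five
baseline points are `not_evaluable`.

## Synthetic generators: what they emulate, and what not

Every generator is a pure function of its spec including an explicit
seed; there is no global random state.  The drift rig is barometer (a
Gaussian random walk clipped to 730–790 mmHg — ambient statistics are
otherwise unconstrained) + fixed fluid head + linear drift + white
noise; real drift need not be linear, and the rig's true noise floor is
a free parameter, so passing recovery tests demonstrates estimator
correctness, not sensor physics.  The ICP generator is mean + single
cardiac sinusoid (optional harmonics off by default) + respiratory
sinusoid + white noise + additive posture steps with no transient;
morphology (percussion/tidal/dicrotic waves, B-waves, plateau waves) is
deliberately absent, so the analytics are validated for amplitude and
rate recovery, not for waveform-shape features.  The generator refuses
heart rates at or beyond Nyquist for the configured sampling rate.
Head meshes are smooth ellipsoids: coverage numbers on them demonstrate
the machinery, not anatomy — anatomical meshes can be supplied as
STL/PLY/OBJ.

## Degenerate inputs and tie-breaks

Zero-variance ICP recordings return amplitude 0 with `low_beats`.
Empty SAR tables produce empty reports; malformed rows are reported by
index and excluded.  Direction-sample ties in the minimax resolve to the
first index.  Voxel centres exactly on a surface crossing count as
outside (strict interior).  Pose optimization failures drop the pose
and log it.

## Output formats

Meshes are written as ASCII PLY/STL (binary available).  Coverage
volumes are NIfTI (float32 tesla for W and M, uint8 classes) with a JSON
sidecar carrying grid origin/spacing/dims, threshold and pose counts;
slices export as PNG + CSV of class labels.  Tables are CSV with header
rows, ISO-8601 timestamps, mmHg and °C.  Pipeline runs write a resolved
config and a manifest (seed, library versions, SHA-256 of every output)
sufficient to re-run bit-identically; config files are TOML with units
encoded in key names.
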