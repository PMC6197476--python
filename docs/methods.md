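# Methods

This note documents the models and numerical choices behind `absaxs`: what
is computed, under which assumptions, which knobs matter, and what a passing
test does and does not establish.

## 1. Scattering model

**Debye sum.** The reference evaluator is the exact orientational average
for point scatterers,

    I(Q) = Σᵢ Σⱼ fᵢ(Q) fⱼ(Q) · sin(Q rᵢⱼ)/(Q rᵢⱼ),   sinc(0) = 1,

so I(0) = (Σ fᵢ(0))². Pair distances are computed once (`scipy` `pdist`,
chunked at 2·10⁶ pairs to bound memory) and reused across the Q grid; cost
is O(N²) in atoms, fine up to a few 10⁴ pseudo-atoms.

**Golden-vector quadrature.** The fast evaluator averages |Σⱼ fⱼ e^{i q·rⱼ}|²
over M quasi-uniform directions on a spherical Fibonacci (golden-angle)
lattice. At M = 299 it agrees with the Debye sum to better than 1% on the
working range Q ≤ 0.2 Å⁻¹ for toy-scale structures, and the average
deviation falls as M grows (verified 35 → 280).

**Form factors.** Pseudo-atoms scatter with constant f (default 1, "point"
mode) — the natural contrast model for the toy world. An "atomic" mode
provides Cromer–Mann f(Q) for H/C/N/O/P/S (f(0) = Z; other elements fall
back to constant Z).

**In vacuo.** There is no excluded-volume or hydration-layer term. This is
the main fidelity gap against real solution data: absolute intensities and
high-Q features of real profiles are not reproduced. It is deliberate — the
synthetic experiments are generated by the same physics, so closed-form
oracles (sphere form factor, two-point Debye sum) check the implementation
exactly rather than a solvent parameterisation.

## 2. One-dimensional analyses

**Guinier.** Weighted least squares of ln I on Q² (weights (I/σ)² when σ is
present, i.e. error propagation into log space; unweighted otherwise), on
the largest low-Q window satisfying Q_max·R_g ≤ 1.3 *self-consistently*:
fit, shrink the window for the fitted R_g, repeat to a fixed point (2-cycles
on noisy data settle on the smaller window). Reports R_g = √(−3·slope),
I(0) = e^intercept, the window, Q_min·R_g, Q_max·R_g and r².

**P(r).** The coordinate-space pair-distance histogram (weights fᵢ(0)fⱼ(0)),
normalised to unit area, with d_max the largest pairwise distance. The
second-moment identity R_g² = ∫r²p dr / 2 holds up to an O(1/N) bias because
self-pairs are excluded from the histogram; tests allow 1%. This is *not*
an indirect Fourier transform of a measured profile — regularised IFT of
experimental data is out of scope.

**Reduced χ².** Model and experiment are linearly interpolated (I and σ)
onto n equally spaced grid points with spacing q_max/n, default 19 points
at 0.01…0.19 Å⁻¹; the grid starts one spacing above zero because Q = 0 is
unmeasurable. With the scale fitted, c = Σ(I_m I_e/σ²)/Σ(I_m²/σ²) minimises
the weighted residual and one parameter is charged: χ²_red = Σr²/(N−1);
with the scale fixed the divisor is N. The dof convention is stated in the
CLI output. Experiments without σ require an explicit constant-σ policy.

## 3. The toy world

Generators are pure functions of (config, seed); every stochastic stream is
a `numpy` `default_rng` seeded from the config seed plus a stable CRC32
stream tag, so results are process-independent.

**Domains** are carbon-like point scatterers on a jittered cubic lattice
inside a sphere (spacing scales with the radius so site counts stay
feasible). This keeps Debye sums cheap while giving realistic R_g and P(r)
shapes. The canonical Fab cloud is *identical in every copy* (standalone,
both antibody arms, docked poses), which makes heavy-chain-style
superpositions between copies exact (RMSD 0) and lets alignment selections
pair by atom order.

**Antibody.** Y-shaped: an Fc ball at the origin and two Fab balls on arms
at 71°, each arm joined by a 3-residue polypeptide hinge with ideal backbone
geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, ω = 180°), built by
internal-coordinate (NeRF) placement, so hinge φ/ψ are genuine torsions.
Labels mark Fc/Fab1/Fab2/hinges, the paratope face (outer 20% of each Fab by
outward coordinate), the non-interface alignment region, and the
hinge-proximal anchor atom pinned at the −x pole of the Fab sphere — the
analogue of the heavy chain's last Fab residue Cα.

The proportions (domain radius 15 Å, short hinge, 71° arms; R_g ≈ 28 Å) are
*derived from consistency with the assembly filters*, not fitted to any
measurement: (i) the antigen's D2 symmetry subtends
2·arccos(1/√3) = 109.47° between paired binding sites, and a planar 2:2 ring
closes when 2·(arm angle) + 2·109.47° ≈ 360°, i.e. arms near 71°; (ii) the
two hinge anchors of one antibody sit ~34 Å apart, inside the 40 Å
ring-closure threshold, exactly as the real molecule's short upper hinge
keeps its residue-211 Cα pair within reach. A toy with long hinges or wide
arms makes the 40 Å rule unsatisfiable by construction — the filter, not
the R_g, is the structure-determining constraint this package exists to
exercise.

**Antigen.** Four identical subunit balls with *exact* D2 symmetry: subunit
1 at a generic centre, subunits 2–4 its images under 180° rotations about
z, x, y. The centre of mass is exactly zero (the four rotation matrices sum
to zero) and two generating 2-fold axes are recorded in metadata. Default
R_g ≈ 27 Å, the real antigen's scale.

**Docked poses.** Stand-ins for docking output: the Fab's paratope normal is
aimed at a chosen subunit, spun by a seeded random angle about the approach
axis, and translated until the minimum Fab–antigen distance equals the
requested gap (bisection to 0.02 Å; default gap 4 Å, a typical interface
contact distance). No binding energetics — pose diversity comes entirely
from subunit choice and spin.

**Noise.** σ(Q) = a·I(Q)·(1 + b·Q) with a = 0.02, b = 5 Å: a 2% relative
floor with Q-proportional growth, emulating the monotone loss of
signal-to-noise of column-coupled SAXS. Gaussian, seeded, with the true σ
reported in the profile. Not emulated: incident-flux calibration, buffer
subtraction residuals, inter-particle structure factors, radiation damage.
A green synthetic test therefore establishes correctness of the chain from
coordinates to verdict under stated statistics — not robustness to real
instrument systematics.

## 4. Torsion-angle Monte Carlo

One pivot (chain, residue, φ|ψ) is chosen uniformly per move, rotated by
δ ~ U(−max_step, +max_step) (default 30°), and accepted iff no moving atom
comes within `overlap_cutoff` (default 1.8 Å, heavy-atom contact) of the
static set — a pure hard-sphere criterion, no Metropolis energy. Pairs in
the same chain with residue separation ≤ 1 are exempt; otherwise the
covalent bond across the pivot (1.33 Å) would reject every move. Accepted
states become the current state; 1000 consecutive rejections trigger a
restart from the input (chain-growth restart); an exhausted attempt budget
raises with the acceptance rate. Because each accepted move re-checks the
moved set against everything else, every emitted member satisfies the full
per-pivot overlap criterion — the test suite re-verifies this exhaustively.

Bond lengths and angles are preserved exactly (rigid rotation about the
bond axis, IUPAC sign convention). Production scale in the original study
was ~47,000 accepted members; tests run ≤ 1,000.

## 5. Assembly

All assembly is rigid-body: superposition (Kabsch, own SVD implementation,
cross-checked in tests against an independent implementation) of a unit's
Fab onto a target Fab, using alignment atoms that exclude the paratope.
Nothing is energy-minimised — the geometric filters are the
structure-determining steps, and they are applied exactly:

* **Clash:** any inter-unit atom pair < 8.0 Å rejects (strict inequality;
  8.0 Å exactly passes). Maintained docked Fab–antigen contacts are the
  binding interface and are exempt; everything newly apposed is checked.
* **Symmetric replication:** the second Fab of a block is the first rotated
  180° about a recorded antigen 2-fold (an involution, tested as such).
* **Monodentate build:** block + two full antibodies + one extra antigen on
  a free Fab → path topology, uniform seeded draws until n_target.
* **Bidentate build:** antibodies pre-filtered to Fab–Fc–Fab ∈ [70°, 90°]
  (angle between domain centroids, the natural reading when no atom-level
  definition is given); a block on each arm; ring closure iff the dangling
  Fabs' anchor atoms are < 40 Å apart, evaluated *before* the second Fc is
  placed; the Fc then completes the second antibody on the outward ray at
  the built antibody's Fab–Fc separation. Ring-compatible combinations are
  a < 0.1% fraction of blind draws at desk scale, so the builder enumerates
  dangling-anchor positions first (one rigid superposition per combination)
  and assembles a seeded random order of the compatible list — the
  desk-scale equivalent of the production-scale exhaustive ensembles. The
  assembled second antibody consists of two Fabs + Fc without rebuilt hinge
  linkers (rigid-body scope); label bookkeeping still counts it as one
  antibody.

Open points resolved as documented defaults: the 8 Å monitor uses all atoms
of both units (configurable nowhere — the toy has only heavy pseudo-atoms);
one pivot is perturbed per TAMC move; the χ² grid is linear in Q.

## 6. Kinetics and stoichiometry

The 1:1 interaction model is fitted globally over all injections with a
shared R_max, in log-parameter space for positivity, by Levenberg–Marquardt;
dissociation curves are tied to their association end point through the
model (not the noisy data). Standard errors are asymptotic ((JᵀJ)⁻¹ scaled
by residual variance) with K_D by the delta method. Mass transport and
drift are omitted. Unweighted least squares is assumed.

The stoichiometry search enumerates (i, j) ∈ [0, n_max]², i + j ≥ 1, with
predicted mass i·m_ag + j·m_ab and uncertainty √(i²σ_ag² + j²σ_ab²),
accepting |predicted − measured| ≤ z·√(σ_pred² + σ_meas²), z = 1 by default
(match within one combined standard deviation). With the measured component
masses (63.3 ± 0.8, 160 ± 3, complex 447 ± 12 kDa) the unique combination
is 2 + 2 at 446.6 kDa.

## 7. The verdict

For each candidate class the ensemble is ranked by χ²_red (ties broken by
lower R_g, documented because ranking must be deterministic); a class passes
iff its best member has χ²_red ≤ 2 (a toy-data default — against real data
the rejected classes in the motivating study sat at χ² > 150, quoted as
context only, not reproduced) *and* its (n_antigen, n_antibody) passes the
mass window. This joint rule is what excludes the 2-antibody/1-antigen
class, whose profiles alone can fit the data. The report is a pure function
of (config, seeds); reruns are byte-identical.

## 8. Known limitations

* In-vacuo scattering; no solvent contrast, smearing, or calibration.
* Pseudo-atom domains: no sequence, side chains, or physical energetics;
  clash thresholds act on point clouds, not van der Waals surfaces.
* The assembled second antibody in rings lacks hinge linkers.
* The bidentate candidate space is quantized by pose spins and TAMC members;
  at very small ensemble sizes the builder can legitimately return an empty
  ensemble (reported with diagnostics, never silently).
* PDB round-trips preserve coordinates to the format's 10⁻³ Å precision;
  labels and metadata are in-memory only.
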