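# Methods

This note records the models, conventions, numerical choices, and
limitations behind `chiralfil`.  Everything quantitative stated here is
computed by the test suite, the analysis drivers, or
`scripts/acceptance.py`.

## Filament model and synthetic ensembles

A six-helix DNA origami bundle is represented at nucleotide resolution:
six duplexes on a hexagon (axis distance 2.6 nm from the centerline,
strand offset 1.0 nm from each duplex axis), rise 0.34 nm/bp, relaxed
winding 10.5 bp/turn (`Tw₀ = 1/(10.5 × 0.34 nm) = 280.1 turns/μm`),
nominal diameter σ = 6 nm, contour length 420 nm (1235 bp planes) at
full scale.  The hexagon circumscribes σ slightly (strand orbit 7.2 nm
across); the validity check therefore bounds the duplex-axis circle by
σ within 10% and the strand orbit by 1.3 σ.

Centerlines are discrete wormlike chains: per step of length Δs the
polar kink angle is drawn from `p(θ) ∝ exp[(l_p/Δs) cos θ] sin θ`
(exact inverse-CDF sampling), the azimuth uniformly; the material frame
is transported by the minimal rotation carrying t to t′ (no spurious
twist) plus optional intrinsic curvature/torsion applied as a single
Rodrigues rotation per step.  Intrinsic (κ₀, τ₀) produce a helical
ground state; `solenoid_curvature_torsion` converts (turns, radius,
l_c) into them, positive turns meaning right-handed.

Decoration re-samples the centerline at bp planes via an arc-length
spline, builds a twist-free (double-reflection rotation-minimizing)
frame, rotates the hexagon at the designed axial twist rate ω₀, and
winds each duplex's two strands in the duplex axis's own
rotation-minimizing frame.  Because winding happens in a twist-free
frame, the built winding rate *is* the twist measured by the
stacking-angle integral — the generator's twist bookkeeping is exact by
construction.

**Linking bookkeeping.**  A design overtwist ΔTw_design (turns/μm; the
duplex overtwist if the filament were straight and untwisted) is
partitioned under the default `thermal` rule: the chain receives a
solenoidal bias of the same handedness as the overtwist
(`writhe_coupling` = 0.25 solenoid turns per turn/μm, amplitude 5 nm by
default), and the built duplex winding is reduced by the conformation's
actual centerline polar writhe, so over the ensemble
`⟨ΔTw⟩ + ⟨Wr⟩·(turns/μm) = ΔTw_design` exactly up to trimming effects.
With the defaults and l_c = 420 nm, a 7 turns/μm design produces
⟨Wr⟩ of a few tens per mm — the order observed for real origami
ensembles.  The coupling constant and amplitude are *choices*: the
microscopic twist–writhe coupling of real origamis lives in the
nucleotide-level force field and has no closed form; only the sign
(writhe co-signed with overtwist) and the linking balance are modeled.
The amplitude distribution of the bias is a further unknown; it is
exposed (`amplitude_sd`, default 0 = fixed amplitude).

What the generator does *not* emulate: the large elastic relaxation of
duplex twist between the straight-untwisted reference and the true
ground state (a finite-element/molecular-mechanics result), sequence
effects, staple-level design detail, and any interaction between
filaments during sampling (ensembles are i.i.d. by construction — the
end-to-end autocorrelation diagnostic is provided for imported
trajectories, where frames may be time-correlated).

## Backbone spectra and the helicity order parameter

The backbone is the per-bp-plane mean of the six duplex midpoints,
trimmed by `trim_bp` (default 10) planes per end, re-parameterized to
uniform Δs by arc length, and centered.  The molecular frame is the
principal frame of the gyration tensor: u = maximum dispersion,
v = minimum, w = u × v; signs are fixed by u·(r_last − r_first) > 0 and
v·(first non-negligible transverse displacement) > 0, so that H and Wr
signs are reproducible (only relative handedness is physical; the
convention is calibrated once against the right-handed helix fixture).

Transforms use the exact sum `r̂(k) = Σ_j Δs r_⊥(s_j) e^{−2πiks_j}`
with N samples at s_j = jΔs and the convention l_c ≡ NΔs, evaluated by
FFT (identical on this grid).  Under this convention the aliasing sums
cancel exactly on the ideal-helix fixture and |H| = 1 to machine
precision in the fixture's own frame.  Via the gyration frame the
principal axis tilts by O(a/l_c) (a finite-size cross moment of the
helix), limiting |H| to ≈ 0.998 at a = 4 nm — tested at its own
tolerance.  H is set to 0 where the power denominator underflows; the
ensemble mean is formed per-conformation-H first (the alternative —
averaging the cross-spectra first — is inequivalent and not used).
Savitzky–Golay smoothing (order 9, default window 15) is applied to
the mean helicity curve for presentation only.

**Semiflexible reference.**  In the weak-bending regime the discrete
chain is Gaussian: per transverse component the tangent performs a
random walk with step variance Δs/l_p.  `wlc_reference_spectrum`
builds the resulting displacement covariance exactly, applies the same
observation operators as the pipeline (mean removal and least-squares
linear detrend, the linear-response equivalent of the gyration frame),
and returns the expected transform power; it matches generated
ensembles within ~10% at l_p/l_c = 8 (residual: bending
nonlinearity).  Note that the transform power of an open filament is
boundary-leakage dominated at high k (asymptotically k⁻²); the
familiar 1/(l_p k⁴) equipartition law holds in cosine-mode space,
measured by `bending_mode_spectrum` (observed slope −4.0 over modes
2–10).

## Twist and writhe

Duplex twist integrates `t·(n × dn/ds)/(2πl)` on cubic splines of the
two strand curves versus centerline arc length, with dn/ds evaluated
analytically from the splined strand difference (projection formula),
composite Simpson on a 4× oversampled grid (8× halves nothing beyond
0.1%).  End planes are trimmed (default 10/end) before integration.
Worked example: the relaxed straight bundle gives ΔTw = 0 within
2 × 10⁻⁴ turns/μm; winding at 10.0 bp/turn gives
(1/10 − 1/10.5)/0.34 = +14.006 turns/μm, reproduced to 10⁻³.

The local polar writhe `(1/2πl_c)∫ u·(t×t′)/(1+u·t) ds` is evaluated
the same way after Savitzky–Golay pre-smoothing of the backbone
(order 9, default window 21 — an independent knob from the
presentation smoothing).  It requires dr_u/ds > 0 throughout; a
turning point raises an error naming the abscissa (the nonlocal part
of the polar writhe is out of scope).  Conformations failing the
precondition are excluded from ensemble statistics and counted;
above a 5% failure fraction the ensemble statistic errors out instead
of silently biasing.  The closed-form oracle — an ideal solenoid of m
turns at pitch angle α has local polar writhe m(1 − cos α)/l_c — is
reproduced to 7 digits; reported units are turns/μm for ΔTw and mm⁻¹
for Wr.

## Interactions and coarse-graining

The intermolecular potential is hard cores plus Debye–Hückel tails per
site pair: `u(r) = q_i q_j ℓ_B e^{−r/λ_D}/r` in kT with
ℓ_B(293 K, ε_r = 80.1) = 0.70 nm, truncated at max(3λ_D, 1.5d).
λ_D(0.26 M, 293 K) = 0.597 nm.  The per-nucleotide effective charge
(default 0.5 e) is the main fidelity knob of the electrostatic stage;
no counterion-release or hydration physics is modeled.  Site-site
energies run through a direct double loop for small bodies and a
cell-list (cell edge = cutoff) above ~2.5 × 10⁵ site pairs.

For the virial stage, filaments are coarse-grained in their molecular
frame: `duplex` mode places beads along the six duplex axes (retaining
the chiral bundle surface; default spacing 2.0–2.4 nm, bead diameter
2.2–2.4 nm), `centerline` mode places σ-sized beads on the backbone
(shape chirality only).  Bead charges aggregate the nucleotides they
replace.  Capsule bounds per body give O(1) rejection in the Monte
Carlo loops.

## Onsager stage: conventions and numerics

Orientations carry the normalized Haar measure (E_R[·]); the
orientation distribution ψ(cos θ) of long axes u about the director
n = e_x satisfies ψ = 1 in the isotropic state
((1/2)∫ψ d cos θ = 1).  The free energy density (kT, per volume) is

    βf₀ = ρ(ln ρ − 1) + ρ⟨ln ψ⟩ + (ρ²/8)∬ ψψ(−κ) dx dx′,

with the kernel κ(θ,θ′) the Mayer integral averaged over conformations
and azimuth/spin angles (for hard particles, minus an excluded
volume).  Functional minimization gives the standard self-consistency
equation, solved by damped Picard iteration (mixing 0.4, residual
10⁻¹⁰, the fixed-point image returned on convergence).  These
conventions are validated end to end against classical hard-rod theory:
with the pure `sin γ` kernel the coexistence comes out at
bρ = 3.290/4.191 with S = 0.792 (the classical Onsager values), and at
L/D = 5 the Picard + coexistence route agrees with an independent
L-BFGS grid minimization + common-tangent construction within 1%.

**Kernel estimation.**  κ is estimated by stratified MC over
θ-uniform bin pairs (conformation pairs, Haar rotations via
x-convention Euler angles, separations uniform in a box spanning twice
the capsule reach plus the cutoff — the full Mayer support; a smaller
box truncates near-collinear pairs and biases the poles).  Bins are
uniform in θ, not cos θ: the |sin γ| cusp at parallel alignment is
otherwise rounded enough to visibly weaken the first-order character
of the transition (L/D = 5 oracle: density gap 7.9% exact, 7.1% with
16 θ-bins, 3.6% with 16 cos-bins).  Batch means (16 batches) give
per-bin standard errors; a bicubic spline maps bins to the
Gauss–Legendre grid (48 nodes by default).

**Elastic constants.**  K₂ and k_t are the standard second-virial
perturbations of a weakly twisted director field (helical axis e_z):

    βK₂ = (ρ²/2) ∫dr ∬dR f̄ ψ̇(x₁)ψ̇(x₂) r_z² u_{1y} u_{2y},
    βk_t = (ρ²/2) ∫dr ∬dR f̄ ψ(x₁)ψ̇(x₂) r_z u_{2y},

with ψ̇ the analytic derivative of the converged distribution (spline
of the fixed-point map; finite differences agree).  cos θ is
importance-sampled from a proposal ∝ ψ + |ψ̇| (floored), tabulated with
an inverse CDF; weights are bounded by construction.  Errors are batch
means.  P = 2πK₂/k_t (positive = right-handed); when |k_t| ≤ SE the
state is flagged achiral-within-error instead of reporting a pitch.

**Binodals.**  μ and Π follow from βf₀ by the envelope theorem;
coexistence equates them between the isotropic branch and the aligned
branch, which is tracked *downward* in density with ψ-continuation
(a fixed aligned seed can fall into an oblate Picard artifact near the
transition and mask the weakly ordered branch), then bisected on the
equal-μ pressure mismatch.  Mass concentrations use 650 Da/bp.  The
chiral term's effect on coexistence (k_t·2π/P) is orders of magnitude
below f₀ at the pitches of interest and is neglected.

**Chiral pair potential of mean force.**  W(γ) = −ln⟨e^{−βU}⟩ at fixed
interaxial angle γ (rotation about the crossing normal e_z), averaged
over conformations, spins, lateral offsets around the filament
midpoints, and *one-sided* normal offsets r_z ∈ [0, box]: symmetric
r_z sampling maps (γ, r_z) → (−γ, −r_z) by a proper rotation and
cancels the chiral asymmetry identically.  W is referenced to γ = 0;
the antisymmetric part W_odd isolates the chiral component (zero for
achiral particles), and the minimizing γ* gives the preferred pair
handedness — right-handed solenoids prefer left-handed crossings
(γ* < 0).  This operational definition (box choice, one-sidedness) is
an interpretation; only signs and orders of magnitude should be read
from it.

**Bootstrap convergence.**  `bootstrap_pitch` repeats
kernel → ψ → (K₂, k_t) → P on bootstrap resamples of the conformational
ensemble and reports the relative pitch dispersion against a
configurable threshold (default 10%).

## Desk-scale study conditions

The production-scale computation (10³ nucleotide-level conformations,
~10¹⁴ MC steps) is cluster work.  All shipped tests and drivers run at
desk scale: geometric stages at full size (420 nm, l_p/l_c = 8), the
virial stages on stand-in filaments of l_c = 105 nm stiffened to
l_p = 25 l_c (so that the 4×-shorter bundles, aspect ≈ 14, still order
nematically — at l_p/l_c = 8 and this length thermal bending destroys
the aspect ratio), with 10⁶–10⁷ MC samples.  Consequences:

- the thermalized chiral strength resolves at 3–4σ
  (k_t ≈ −1.0 × 10⁻³ kT/nm², pitch ≈ −0.6 μm for the overwound
  design), and parity (mirror) symmetry is verified at the same
  budgets;
- the *ground-state* (surface-twist-only) chiral strength is
  intrinsically ~10⁻³ of the excluded-volume scale and stays below MC
  resolution at desk budgets (measured 1.6 ± 1.5 × 10⁻⁴ kT/nm² at
  4.8 × 10⁷ samples); its antichiral handedness is instead established
  through the chiral PMF odd part, which resolves cleanly, with k_t
  bounded away from the thermalized sign.  Sign-level conclusions are
  unaffected; absolute ground-state pitches are not claimed at desk
  scale;
- desk-scale coexistence concentrations (~120–135 g/L) sit well above
  the tens of g/L of real 420 nm origami suspensions: at fixed
  diameter, second-virial transition densities scale inversely with
  filament length.  The machinery accepts full-scale imported
  trajectories unchanged.

## Known limitations

- No attractions, hydration, or counterion release; electrostatics is
  an effective-charge Debye–Hückel tail.
- Biaxial order corrections are neglected (uniaxial ψ(cos θ) only).
- The polar writhe implements the local term only (valid for
  turning-point-free, stiff filaments).
- The generator's twist–writhe coupling constant is phenomenological
  (sign and balance are modeled; the magnitude is a documented knob).
- oxDNA import handles the classic text dialect with simple
  consecutive-strand duplex pairing; real origami topologies (staples)
  require an explicit duplex map file.
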