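# Methods

## Scope and model

The package analyzes bilayer trajectories of LNP lipid mixtures for
structural descriptors of the ionizable lipid and of the membrane, and
correlates those descriptors with experimental delivery readouts. It
deliberately does not run molecular dynamics: trajectories, lateral
pressure profiles, and area series are *inputs*, and a synthetic-data
module supplies inputs with analytic ground truth for validation.

## Critical packing parameter

**Volume route (CPP_V).** Each ionizable lipid in each analysis frame
is reduced to three truncated-cone descriptors: the head radius r_head
(half the maximum pairwise xy distance among head atoms), the tail
radius r_tail (same over terminal tail atoms), and the effective length
l_c (mean distance from the head-group centroid to each terminal tail
atom — the averaging set for "head-to-tail-end distance" is a
documented choice; any consistent choice cancels, see below). Then
a₀ = π r_head², V = (π l_c/3)(r_head² + r_head r_tail + r_tail²), and
CPP_V = V/(a₀ l_c). Algebraically l_c cancels:
CPP_V = (r_head² + r_head r_tail + r_tail²)/(3 r_head²), which the test
suite uses as an independent oracle (agreement to 1e-12 over random
geometries). CPP_V is strictly increasing in r_tail/r_head and equals
1 exactly for a cylinder and 1/3 for a point tail.

Aggregation is per-lipid mean over frames first, then mean over lipids;
the reported dispersion for CPP_V is the SEM across lipid means (CPP_V
is noisy per frame, so the uncertainty of the central tendency is the
meaningful error bar), and the across-lipid and pooled lipid-frame
variances are both exported since CPP variance is itself a candidate
delivery predictor. Lipids with r_head = 0 or l_c = 0 are excluded and
counted, never silently dropped.

**Gyration route (CPP_Rg).** Per lipid-frame, head and tail
mass-weighted centers of mass define the orientation vector
v = R_head − R_tail; coordinates are translated to the midpoint and
rotated (Rodrigues) so v ∥ ẑ; the mass-weighted planar radius of
gyration R_g = sqrt(Σ mᵢ(xᵢ²+yᵢ²)/M) is computed for the head and tail
subsets. Per lipid, the frame-averaged R_g values are ratioed
(CPP_Rg = ⟨R_g^tail⟩/⟨R_g^head⟩), and the dispersion reported is the SD
of the per-lipid-frame ratio distribution (single-block averaging).
Lipids with |v| below 1e-8 Å (no defined axis) are excluded with a
warning. CPP_Rg is invariant under rigid motion of the lipid and under
uniform mass rescaling; both are enforced by tests at 1e-9.

**Shape classes.** CPP < 1 cone, > 1 inverted cone; "close to 1" is
operationalized as |CPP − 1| ≤ 0.05 (the cylinder band is a package
choice, configurable).

## Membrane estimators

**Leaflets and recentering.** The midplane is the mass-weighted z
center of all membrane atoms, recentered to z = 0 per frame before
density/thickness analysis. A lipid is in the upper leaflet iff its
reference atom (fallback: lipid center of mass) sits above the
midplane. Cholesterol-like components without phosphates use their
flagged representative atom (hydroxyl O) or COM fallback.

**Thickness.** d_B(t) = ⟨z_ref,upper⟩ − ⟨z_ref,lower⟩ over per-lipid
reference atoms, averaged over the analysis window. Translation
invariance is exact by construction.

**Density profiles.** One representative atom per lipid (hydroxyl O
for cholesterol, P for helper lipids, head N for ionizable lipids) is
histogrammed along z after recentering, averaged over frames and
divided by bin width, so each profile integrates back to the component
count.

**Torque density.** From a lateral pressure profile table
(z, p_xx, p_yy, p_zz on uniform bins; 0.2 Å default width),
p_T = (p_xx + p_yy)/2 and p_N = p_zz, p = p_T − p_N, and leaflet
torques τ = ∫ z p(z) dz over [0, L_z/2] and [−L_z/2, 0]. Taking the
normal component as p_zz is deliberate: identifying p_N with p_xx
would make p ≡ (p_yy − p_xx)/2, which vanishes for isotropic lateral
stress; that alternative convention remains available behind
`normal_component="p_xx"` for cross-checks. Two averages are reported:
the literal (τ_up + τ_low)/2, which is identically 0 for any symmetric
profile, and the leaflet-oriented (τ_up − τ_low)/2, which equals τ_up
on symmetric profiles — nonzero reported torques in practice imply the
sign-corrected convention, so both are always exported. Quadrature is
the per-bin midpoint sum Σ z_c p(z_c) Δz, exact for bin-aligned
piecewise-constant profiles and second-order otherwise; tests require
< 0.5% error at 0.2 Å bins against closed forms.

**Area compressibility.** K_A = k_B T ⟨A⟩ / var(A) with the sample
(n−1) variance, converted from Å units to mN/m (the Å²/Å⁴ ratio
carries a factor 1e20 to SI). Constant series are a degeneracy error.
At 5000 samples the estimator's relative sampling error is ~2%
(var(Â) ≈ 2/n), comfortably inside the 5% test band.

**Stability screen.** An ionizable lipid has escaped when its COM
satisfies |z − midplane| > d_B/2 + margin for a persistence run of
consecutive analysis frames; defaults margin 10 Å, persistence 5
frames. Any single escaped ionizable lipid marks the bilayer unstable
(the any-escape policy). The exact numeric criterion is not uniquely
fixed by practice; these defaults are documented package choices, and
one-frame excursions never trigger the flag. Note that an escaped
lipid's reference atom still contributes to d_B, slightly inflating
thickness in unstable systems; the screen is robust to this because
the escape offset (tens of Å) dominates.

## Protonation-site decision tree

Nitrogens are classified on the RDKit molecular graph: aliphatic
amines by heavy-atom substitution (tertiary/secondary/primary, all
single bonds required), aromatic ring nitrogens as imidazole
(pyridine-type N in a 5-membered aromatic ring with ≥ 2 N) or pyridine
(other pyridine-type ring N), exocyclic amines bonded to an aromatic
atom as aromatic amines by substitution level. Amide and sulfonamide
nitrogens (SMARTS `[#7][CX3]=[OX1]`, `[#7][#16]=[OX1]`), quaternary or
charged nitrogens, pyrrole-type [nH] ring nitrogens, and any nitrogen
with multiple bonds (imine, nitrile, nitro) are excluded — the
hierarchy does not cover them. A single nitrogen is always protonated;
otherwise the priority order is tertiary > secondary > primary amine >
imidazole > pyridine > tertiary > secondary > primary aromatic amine.
Ties within a class go to the greatest heavy-atom graph eccentricity
(peripheral head-group nitrogens); the opt-in `tail_amine_central`
rule instead minimizes the mean squared graph distance to all other
atoms (graph rather than Euclidean distance, for determinism).
Remaining ties break by lowest canonical atom rank, so the selection
is invariant to SMILES atom ordering (property-tested under random
renumbering). Protonation adds +1 formal charge and one hydrogen at
the site; net molecular charge rises by exactly 1.

The protonated fraction at a given pH follows Henderson–Hasselbalch,
f = 1/(1 + 10^(pH − pKa)) — one half at pH = pKa = 6.5, the early
endosome condition motivating half-protonated bilayer systems.

## Delivery standardization

Readouts are comparable only within one publication and one delivery
context, so z-scoring (sample SD, n−1) is applied per
(publication_id, delivery_context) group with no cross-group pooling.
When the max/min ratio of positive raw values reaches the trigger
(default 100, i.e. two decades — the numeric threshold for "orders of
magnitude" and the base-10 log are package choices), readouts are
log10-transformed first; a triggering group containing nonpositive
values is a transform error, as is any constant group. Standardization
is idempotent and invariant to positive affine rescaling of non-log
groups (property-tested). Optional composition fields are tri-state:
present, reported-absent (empty string), or unreported (missing),
since "no PEG lipid" and "PEG lipid not recorded" are different facts.

## Correlation stage

Pearson r with a least-squares line and two-sided p is the primary
statistic, reported overall, per amine stratum, and on rule-defined
subsets (the built-in `cpp>1` rule filters on per-formulation *mean*
CPP, the theoretical negative-curvature transition). Strata with fewer
than 3 finite pairs are skipped; zero variance is an explicit error. A
Spearman option exists for robustness checks but is not the default.
Group comparisons default to the two-sample Wilcoxon–Mann–Whitney
rank-sum test — the natural choice for independent stable vs unstable
formulation groups — with the paired signed-rank test also exposed;
the report names the test used. Ties are midranked; p-values are
uncorrected for multiple testing by default (a correction flag exists).
Monte-Carlo calibration tests require the empirical type-I error at
α = 0.05 to lie in [0.03, 0.07] over 2000 replicates at n = 34 for
both tests, and mean sample r within 0.05 of ρ = 0.7 over 500
replicates.

## Synthetic-data generator

Each synthetic lipid is a rigid pseudo-atom scaffold: `atoms_per_head`
equal-mass atoms on a circle of radius r_h at the head plane and
`atoms_per_tail` atoms (all flagged terminal) on a circle of radius
r_t at depth l below it; leaflets are mirrored about z = 0 with a 1 Å
tail-plane offset; lipids sit on an xy grid sized to the box. Per-atom
per-frame Gaussian noise emulates thermal disorder; escape events add
a persistent signed z offset from a start frame; protonated lipids
differ only by a topology label. Defaults (25 lipids per leaflet ×
2 leaflets, r_h = 4 Å, r_t = 6 Å, l = 15 Å, 0.1 Å noise, 100 frames
at 1 ns) give a 50-lipid inverted-cone system of roughly phospholipid
dimensions — small enough to analyze in seconds, large enough for
sub-percent estimator bias.

Ground truth is exact by construction: CPP_V = (r_h² + r_h r_t +
r_t²)/(3 r_h²) (the length cancels), CPP_Rg = r_t/r_h (equal-mass
circle points have planar R_g equal to the circle radius), thickness
= 2(l + 1 Å). The generators are pure functions of their spec
including the seed.

What the generator does **not** emulate: conformational flexibility,
atom-level chemistry, inter-lipid packing correlations, periodic-image
wrapping, undulations, or protonation-dependent electrostatics.
Passing recovery tests therefore demonstrates estimator correctness on
known geometry — not force-field realism; on real trajectories the
estimators face additional variance that these fixtures do not probe.
The estimator-side noise bias is small but real: with max-pairwise
radius estimation, positional noise biases r_head and r_tail upward by
order σ; at σ = 0.1 Å the net CPP_V bias is ≲ 1%, inside the 2%
recovery band.

## Numerical choices

* Trajectory formats: multi-model PDB (MODEL/ENDMDL + CRYST1, via
  MDAnalysis; coordinates round-trip to 1e-3 Å, the format's
  precision) and a plain-text frame format with full float precision.
  A single header CRYST1 record (constant-volume runs) is applied to
  all frames.
* Analysis window: frames with t > t_end − window, strided backward
  from the last frame so it is always included (e.g. 1500 frames at
  1 ns, window 500 ns, stride 1 ns → exactly the final 500 frames).
* Terminal tail atoms default to explicit topology flags; a lipid with
  tail atoms but no flags gets its last tail atom auto-flagged with a
  warning (chain-end convention).
* Rotation to ẑ uses Rodrigues' formula with a 1e-12 parallelism
  guard; the antiparallel case maps to a 180° rotation about x.
* All tie-breaks (protonation site, frame selection) are deterministic
  and documented; no estimator consumes global RNG state.

## Problem sizes

Tests and the acceptance script run on deliberately small systems:
50-lipid bilayers with 60–100 frames, 5000-sample area series, and
2000-replicate Monte-Carlo calibrations — sizes at which every check
completes in seconds while sampling error stays well inside the stated
tolerance bands.

## Known limitations

* The analysis pipeline validates against synthetic geometry only; no
  claim is made about agreement with experimental CPP measurements.
* Headline field results (e.g. CPP–delivery Pearson r on real LNP
  libraries) require microsecond all-atom trajectories of dozens of
  bilayers and are out of desk-scale reach; the package reproduces the
  *method*, with its statistical behavior verified by calibration.
* The protonation tree assigns a single representative site; real
  ionizable lipids populate multiple protonation states dynamically.
* Pressure profiles are inputs; computing them from forces/virials is
  out of scope, as is estimating bending modulus or spontaneous
  curvature from the torque.
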