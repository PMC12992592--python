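# lnpstruct

Structure–function analysis of lipid nanoparticle (LNP) bilayers.

LNPs — four-component particles of an ionizable lipid, a helper lipid,
cholesterol, and a PEG lipid — are the leading non-viral carriers for
nucleic acid delivery, but transfection screens report delivery on
incompatible scales, and the molecular features that make one ionizable
lipid outperform another are poorly understood. This package implements
the trajectory-analysis and statistics layer that links simulated
bilayer structure to delivery performance:

* **Critical packing parameter (CPP)** of ionizable lipids, by two
  estimators. The volume route models each lipid as a truncated cone,

  CPP_V = V / (a₀ · l_c),  a₀ = π r_head²,
  V = (π l_c / 3)(r_head² + r_head·r_tail + r_tail²),

  with r_head (r_tail) half the maximum pairwise in-plane distance among
  head (terminal tail) atoms and l_c the mean head-centroid-to-tail-end
  distance. The gyration route aligns each lipid's head→tail axis with
  the membrane normal and takes CPP_Rg = R_g^tail / R_g^head of the
  mass-weighted planar radii of gyration. CPP < 1 is a cone (positive
  curvature), ≈ 1 a cylinder, > 1 an inverted cone (negative curvature,
  fusion-prone).
* **Bilayer mechanics**: thickness d_B(t) = ⟨z_ref,upper⟩ − ⟨z_ref,lower⟩,
  monolayer torque density τ = ∫ z·p(z) dz per leaflet from the lateral
  pressure profile p(z) = p_T(z) − p_N(z), and the area compressibility
  modulus K_A = k_B T ⟨A⟩ / var(A) from projected-area fluctuations.
* **Stability screening**: ionizable lipids escaping the membrane slab
  mark a bilayer unstable.
* **Protonation-site assignment**: a rule-based decision tree picks one
  representative +1e protonation site per ionizable lipid from its
  molecular graph (amine-class hierarchy, amide/sulfonamide/quaternary
  exclusions, graph-eccentricity tie-break).
* **Delivery standardization and correlation**: per-publication,
  per-context z-scoring of delivery readouts (log10 first when they
  span orders of magnitude), then Pearson correlation of simulated
  features against delivery — overall, per amine stratum, and on the
  CPP > 1 subset — plus rank-based stable-vs-unstable comparisons.

Because microsecond all-atom MD trajectories are not desk-computable,
the package ships a first-class synthetic-data module that generates
bilayer trajectories with *analytically known* cone geometry, pressure
profiles with closed-form torques, area series with known K_A, and
delivery datasets with prescribed correlation — so every estimator is
validated against ground truth.

## Worked example

```python
from lnpstruct.synthetic_data import SyntheticBilayerSpec, make_bilayer_trajectory
from lnpstruct.membrane_features import compute_lipid_geometry, compute_cpp_v, classify_shape

spec = SyntheticBilayerSpec(n_lipids_per_leaflet=25, head_radius=4.0,
                            tail_radius=6.0, positional_noise_sd=0.1,
                            n_frames=100, seed=0)
traj, topo, truth = make_bilayer_trajectory(spec)
res = compute_cpp_v(compute_lipid_geometry(traj, topo))
print(f"CPP_V = {res.pooled_mean:.4f} ± {res.dispersion:.4f} (SEM), "
      f"truth {truth.expected_cpp_v:.4f}, shape {classify_shape(res.pooled_mean).value}")
```

prints

```
CPP_V = 1.5740 ± 0.0005 (SEM), truth 1.5833, shape inverted_cone
```

i.e. the estimator recovers the generator's analytic CPP of
76/48 ≈ 1.583 to well under 2% from a noisy 50-lipid, 100-frame
trajectory, and classifies the lipid as an inverted cone.

The `analysis/` directory holds the numbered end-to-end drivers
(standardize a formulation screen → assign protonation sites →
simulate bilayers and extract features → membrane mechanics →
structure–function correlations); each writes its tables under
`results/`. A `lnpstruct` CLI exposes the same steps
(`validate`, `standardize`, `protonate`, `synth`, `features`,
`correlate`).

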