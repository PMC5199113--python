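# hnmargin

Internal-margin (CTV→ITV) generation and evaluation for daily pose
variation in head-and-neck image-guided radiotherapy (IGRT).

Head-and-neck patients are immobilized and couch-corrected daily, but
the anatomy still deforms between planning and treatment — little near
the skull, up to ~9 mm at the shoulders. The clinical target volume
(CTV) must be expanded by an internal margin so the dose still covers it,
and every millimetre of margin irradiates healthy tissue. `hnmargin`
implements and compares three ways of building that margin:

1. **Constant** — isotropic 3 mm morphological dilation (clinical
   practice under daily IGRT).
2. **Distance-weighted variable** — per-landmark residual-error
   statistics from the rest of the cohort, interpolated over the CTV
   surface as `r(x) = Σᵢ wᵢ mᵢ` with inverse-distance weights and
   per-axis margins `mᵢ = 1.96 σᵢ` (95 % CI) or `mᵢ = 2.5 Σᵢ + 0.7 σᵢ`,
   applied as a spatially varying ellipsoidal dilation.
3. **Biomechanical** — a cohort statistical pose model (probabilistic
   PCA over couch-corrected landmark poses, 5 modes) is sampled for
   N pose scenarios; each scenario drives a patient-specific
   co-rotational tetrahedral finite-element model through landmark
   springs (`fᵢ = k·dᵢ`, E = 10 MPa, k = 1000 N/mm); the CTV is
   propagated through every scenario's displacement field and voxels
   hit in more than 5 % of scenarios form the ITV.

The supporting stages — NCC landmark tracking, Mahalanobis outlier
gating against a rigid-body geometric model, rigid Procrustes
couch-correction simulation, spring-stiffness calibration against a
0.5 mm mean-residual criterion, and four evaluation metrics
(V_ITV\CTV, V_ITV\fCTV, V_fCTV\ITV, slice-wise distance to the spinal
cord d_SC(z)) with a leave-one-out cohort protocol — are all included,
along with a synthetic head-and-neck phantom cohort with known ground
truth so the whole chain runs without any patient data.

## Worked example

Run the full pipeline on the tiny synthetic cohort (6 patients,
10 fractions, 100 pose scenarios per patient):

```bash
hnmargin run --preset tiny --patients 6 --fractions 10 \
    --set n_scenarios=100 --seed 1 --report-dir reports/
```

or from Python:

```python
from hnmargin import evaluate, phantom as ph
from hnmargin.config import PipelineConfig

body = ph.generate_phantom(ph.PhantomSpec.tiny(), seed=1)
cohort, truth = ph.simulate_fraction_poses(
    body, ph.PoseSimSpec(n_patients=6, n_fractions=10), seed=1)
report = evaluate.run_loocv_comparison(
    cohort, approaches=(1, 2, 3),
    config=PipelineConfig(n_scenarios=100), seed=1)
print(report.margin_volume.loc[["mean", "pct_vs_approach_1"]].round(2))
```

which prints the cohort-mean internal-margin volumes in ml (approach 1
= constant 3 mm, approach 2 = distance-weighted, approach 3 =
biomechanical); with seed 1 this run prints:

```
                   approach_1  approach_2  approach_3
mean                    18.78       16.51       11.21
pct_vs_approach_1        0.00      -12.08      -40.30
```

Both variable approaches produce a smaller total margin than the
constant 3 mm expansion: the margin shrinks where the cohort shows
little motion (cranial CTV) and widens where it shows much (caudal,
toward the shoulders). `report.missed`, `report.healthy_tissue` and
`report.oar_distance` carry the per-fraction coverage, healthy-tissue
and spinal-cord-distance metrics; exact values vary with the seed, and
whether the biomechanical margin also misses less CTV than the constant
one depends on the cohort draw (see the model-error discussion in
`docs/methods.md`).

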