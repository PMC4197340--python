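# tarsokin

Talocrural and subtalar joint kinematics of forefoot landing from
single-plane fluoroscopy — a tested, end-to-end pipeline with a synthetic
phantom ground truth.

## The problem

The ankle is two joints: the **talocrural** joint (talus relative to the
tibia, the dorsi/plantarflexion hinge) and the **subtalar** joint
(calcaneus relative to the talus, the main site of eversion/inversion).
Skin-marker motion capture cannot see the talus, and shoes hide the
markers anyway, so barefoot-vs-shod comparisons of these joints need
radiographic **3D–2D model–image registration**: a CT-derived bone surface
model is posed in six degrees of freedom until its projected silhouette
matches the bone's outline in a fluoroscopic frame.

This package implements that measurement chain for a forefoot landing
(lateral fluoroscopy at 60 Hz, vertical ground reaction force at 1000 Hz):

1. **anatomy** — anatomical coordinate frames for the distal tibia (plafond
   centroid, shaft axis), talus (circle circumscribing the trochlea tali),
   and calcaneus (articular landmarks, inferior/lateral surfaces);
2. **registration** — cone-beam silhouette projection, one-way chamfer cost
   against an edge distance field, derivative-free multi-start pose search,
   and frame-to-frame tracking;
3. **kinematics** — Grood–Suntay joint-coordinate-system angles
   (dorsiflexion +, eversion +, external rotation +, right foot), zeroed to
   a static standing reference;
4. **events** — toe contact from a vertical-GRF threshold, heel contact
   from the calcaneal inferior-vertex height, and the −33…+250 ms analysis
   window around toe contact;
5. **stats** — paired two-tailed t-tests, condition summary tables,
   ICC(3,1) reliability, and noncentral-t sample-size calculation;
6. **synthetic** — parametric phantom bones with analytic landmarks,
   scripted study-shaped landing motions, rendered fluoroscopic sequences
   and impact-peaked GRF traces, all with exact ground truth.

No human data ship with the package: the phantom generator stands in for
the study subjects, so every stage can be validated against a known truth.

## Worked example

```python
import numpy as np
from tarsokin.synthetic import make_phantom, condition_script, make_trial
from tarsokin.registration import RegistrationOptions, track_sequence
from tarsokin.kinematics import series_from_poses

phantom = make_phantom()
trial = make_trial(phantom, condition_script("barefoot"), seed=1,
                   image_noise=0.02, n_before=0, n_after=14)
rng = np.random.default_rng(5)
init = {b: trial.truth_poses[b][0].perturbed(rng, 3.0, 3.0)
        for b in phantom.meshes}
result = track_sequence(trial.camera, phantom.meshes, trial.sequence, init,
                        RegistrationOptions(n_starts=3, max_evals=300))
series = series_from_poses(result.masked_poses(), phantom.frames,
                           trial.frame_times_ms)
err = np.abs(series["talocrural"].dorsiflexion
             - trial.truth_angles["talocrural"].dorsiflexion)
print(err.mean())
```

Running the numbered analysis drivers prints, for the default seeds:

```
$ python analysis/01_simulate_trials.py
condition  frames  toe_contact_ms  heel_contact_ms  peak_vgrf_bw  tc_dorsiflexion_deg
 barefoot      18             0.0             77.3          1.59                -20.5
     shod      18             0.0             85.3          1.40                -17.9
```

— the barefoot script lands ~2.6° more plantarflexed with a higher impact
peak, and heel contact follows toe contact by ~80 ms;

```
$ python analysis/02_registration_repeatability.py
            in_plane_translation_mad    mm 0.114
        out_of_plane_translation_mad    mm 0.383
                       rotations_mad   deg 0.407
           icc31_dorsiflexion_series       0.99985
dorsiflexion_mean_abs_error_vs_truth   deg 0.182
```

— repeated registrations from independent ±3 mm/±3° initializations agree
to ~0.1 mm in-plane and ~0.4° in rotation, the depth direction is an order
of magnitude worse (the single-plane ambiguity), and the tracked
dorsi/plantarflexion series is highly repeatable (ICC(3,1) > 0.99).

`analysis/03_joint_kinematics.py` tracks a full rendered landing and
recovers the scripted talocrural dorsiflexion curve to 0.25° mean absolute
error; `analysis/04_group_statistics.py` generates a 7-subject paired
cohort and emits the two condition summary tables (toe-contact angles;
per-period angular changes plus peak vGRF per body weight).

There is also a thin CLI: `tarsokin simulate|register|kinematics|analyze|report`.

## Layout

```
src/tarsokin/    library (anatomy, registration, kinematics, events,
                 stats, synthetic, experiments, io, pipeline, cli)
analysis/        numbered narrative drivers writing results/
tests/           pytest suite (unit, property, study-level checks)
scripts/         acceptance.py
docs/methods.md  models, conventions, parameters, limitations
```
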