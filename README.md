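# vnsim

A headless simulator of **Veress-needle (VN) insertion** through the layered
abdominal wall, together with the skill metrics and paired-study statistics
used to evaluate insertion training.

The Veress needle is inserted blindly at the umbilicus to insufflate the
peritoneal cavity before laparoscopy. The operator steers almost entirely by
feel: the needle must enter at roughly 45° to the body, and the crucial cue is
the sensation of **two distinct "pops"** as the tip ruptures the linea alba
and then the peritoneum, after which the advance must stop before the bowel
and great vessels. `vnsim` reproduces the computational core of a VR/haptics
trainer for this task — the tissue force model, the mistake detection and the
performance analytics — without any graphics or haptic hardware, so the
physics and the statistics can be tested, calibrated and reused headlessly.

## What it computes

**Force model.** The needle pose is a stream of (t, tip position p,
orientation quaternion Q). Once the tip pierces the skin at insertion point
*r*, lateral motion is resisted by the *fulcrum* spring

    F = k (p′ − p),   p′ = projection of p onto the line through r along the needle axis,

so the tool can run back and forth along its axis but not sideways. Axially,
every wall layer (skin, subcutaneous fat, linea alba, peritoneum) carries
dimensionless 0–1 haptic parameters — stiffness, damping, static/dynamic
friction and *pop-through*, the fraction of the device force scale `f_max` at
which its entry membrane yields. A membrane loads a spring
`stiffness_scale · stiffness · penetration` until the threshold
`pop_through · f_max`, then releases (the pop); layer bulk adds damping
proportional to axial velocity and constant friction opposing motion. The
expert-tuned default parameter table is built in
(`vnsim.default_tissue_table()`), e.g. linea alba = (0.5, 0.1, 0.1, 0.02).
Contact primitives (proxy/god-object stepping, an AABB bounding-volume tree,
sphere-filled deformable volumes) detect collisions with forbidden organs.

**Skill metrics.** Per attempt: insertion angle at the freeze event and its
absolute error from the 45° reference (±5° tolerated), task duration between
the timer events, and number of mistakes = debounced forbidden-organ contacts
(vessels, bowel/colon, pancreas, lateral peritoneum) + 1 if the orientation
was wrong.

**Study statistics.** Per-subject attempt-A/attempt-B pairs are compared with
a two-tailed Wilcoxon signed-rank test (exact by full 2ⁿ enumeration up to 12
effective pairs, tie-corrected normal approximation above; p < 0.1
significant), descriptives as median (Q1–Q3), and usability questionnaires
scored with the standard 10-item System Usability Scale.

**Synthetic data.** Because no patient meshes or participant recordings ship
with the package, a deterministic generator stands in for both: a layered
synthetic anatomy with forbidden organs placed below/lateral to the insertion
corridor, and synthetic trainees whose angle bias/variability, speed, tremor
and overshoot probability are drawn per subject, with a multiplicative
`learning_gain` improving attempt B.

## Worked example

```python
import vnsim

anatomy = vnsim.generate_anatomy(seed=1)          # 26 mm wall + organs
profile = vnsim.TraineeProfile(angle_bias=8.0, angle_sd=0.0, overshoot_prob=0.0,
                               speed_jitter_sd=0.0, lateral_tremor_sd=0.2)
traj = vnsim.generate_attempt(profile, anatomy, attempt="A", seed=1)
sim = vnsim.simulate_trajectory(anatomy, traj)
for e in sim.pops:
    print(f"t={e.t:6.2f}s  {'pop' if e.distinct else 'puncture':8s} "
          f"{e.layer:12s} threshold={e.threshold_force:.3f} N")
m = vnsim.score_attempt(traj, sim, skin_frame=anatomy.skin_frame)
print(f"angle={m.insertion_angle:.1f} deg  error={m.relative_error:.1f} deg  "
      f"duration={m.duration:.1f} s  mistakes={m.n_total_errors}")
```

prints

```
t= 15.25s  puncture skin         threshold=0.165 N
t= 50.71s  pop      linea_alba   threshold=0.066 N
t= 55.05s  pop      peritoneum   threshold=0.165 N
angle=53.0 deg  error=8.0 deg  duration=60.4 s  mistakes=1
```

The skin puncture is logged but only the linea alba and peritoneum ruptures
count as the two clinical pops; the 8° bias puts this attempt outside the ±5°
band, hence one mistake. A full cohort runs through
`generate_cohort → simulate_trajectory → score_attempt → cohort_report`,
whose `summary()` prints the median (Q1–Q3) per group/platform/attempt with
the paired p-value per performance index. The same pipeline is scriptable
from the shell:

```sh
vnsim run-all --seed 1 --out results/
```

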