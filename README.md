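# gaitstab

Gait-stability analysis for perturbed treadmill walking: margins of
stability from marker kinematics, peri-perturbation step analysis with
the 6S deviation statistic, local dynamic stability of trunk velocity,
and a synthetic dual-belt treadmill walking generator that makes the
whole pipeline runnable — and testable against exact ground truth —
without any motion-capture data.

It is written for movement scientists who study how people recover
from mechanical (platform sway, belt speed change) and sensory (visual,
auditory) perturbations during treadmill walking, and who need a
tested, scriptable implementation of the standard outcome measures.

## The measures

**Margins of stability (MoS).** Walking is modelled as an inverted
pendulum of length *l* (mean greater-trochanter marker height × 1.34).
The extrapolated centre of mass is

    XCoM = CoM + v_CoM / ω₀,      ω₀ = √(g / l)

with CoM velocity taken in the belt frame (stance-side belt speed added
to the anterior-posterior component) so that treadmill walking looks
like overground progression.  At each heel strike, with the striking
foot leading:

* ML MoS = ±(malleolus_ML − XCoM_ML), signed so positive means the
  lateral malleolus lies lateral to the XCoM;
* AP MoS = XCoM_AP − heel_AP, positive when the heel lands behind the
  XCoM.

Negative margins mean instability laterally / backward.

**Spatio-temporal parameters.** Step time, step length (AP) and step
width (ML) between the two heel markers at consecutive heel strikes,
detected as local maxima of the anterior heel-minus-pelvis excursion
after 6 Hz zero-phase Butterworth filtering.

**6S.** Perturbations are triggered at a non-dominant heel strike; the
six post-perturbation steps are labelled 1D, 2ND, …, 6ND.  For a gait
parameter with baseline means B(1) (dominant) and B(2) (non-dominant),

    6S = Σᵢ₌₁² Σⱼ₌₁³ | B(i) − P(i + (j−1)·2) |

— the L1 norm of the side-matched deviations of the six
post-perturbation steps, averaged over the last three of four
repetitions per trial.

**Local dynamic stability.** The divergence exponent of trunk velocity
over 100 strides (time-normalized to 10,000 samples, 5-D delay
embedding, Rosenstein-style nearest-neighbour divergence, slope over
0–0.5 stride).  Lower values mean gait that is more resistant to small
internal perturbations.

## Worked example

Run the analysis scripts in order from the repository root:

```bash
python analysis/01_simulate_session.py      # synthetic session -> results/session/
python analysis/02_baseline_gait.py         # heel strikes, step table, 100-step baseline
python analysis/03_perturbation_response.py # peri-step labels and 6S per perturbation type
python analysis/04_local_dynamic_stability.py
python analysis/05_figures.py
```

Step 02 prints the baseline summary of the synthetic walker (100 steps
per side, noiseless template, hence zero SD):

```
             mean_D  sd_D  mean_ND  sd_ND
step_time    0.5500   0.0   0.5500    0.0
step_length  0.6796   0.0   0.6796    0.0
step_width   0.1200   0.0   0.1200    0.0
mos_ml       0.0178   0.0   0.0178    0.0
mos_ap       0.1835   0.0   0.1835    0.0
```

Step 03 ranks the perturbation types by their 6S response.  The
scripted recovery templates reproduce the experimental ordering: the
contralateral sway disturbs the ML margin the most and the belt
deceleration the AP margin, while sensory perturbations leave the gait
pattern unchanged:

```
ML margin: largest 6S from sway_contra (0.222 m)
AP margin: largest 6S from belt_dec   (0.521 m)
visual / auditory: 6S = 0.000 m
```

Step 04 shows the divergence exponent rising with trunk variability
(per stride; lower = more stable):

```
baseline_periodic      ML=-0.000  AP= 0.002  VT= 0.002
trunk_noise_2mm        ML= 2.735  AP= 2.956  VT= 2.732
trunk_noise_10mm       ML= 3.067  AP= 3.329  VT= 3.175
```

The same functionality is available as a library (`import gaitstab`)
and the simulator as a CLI (`gaitstab simulate --out dir --seed 1`).

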