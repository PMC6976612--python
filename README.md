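# vchinrest

Remote psychophysics without a chinrest: estimate a participant's
viewing distance from their blind-spot geometry, convert between
pixels, millimetres and degrees of visual angle, drive a 1-up 3-down
visual-crowding staircase, and reproduce cohort-level reliability and
group-difference statistics on fully synthetic participants.

The package is for vision scientists and methods developers who want to
study — or extend — browser-style distance calibration and adaptive
crowding measurement without collecting human data: every component of
the deployed procedure is available as a simulable, testable Python
object.

## The method

**Display calibration.** A participant scales an on-screen card image
until it matches a physical credit card (85.60 mm wide), giving the
display's logical pixel density

```
LPD (px/mm) = cardImageWidth / 85.60
```

**Viewing distance.** With the right eye closed, a dot sweeping from
right to left vanishes when it enters the blind spot, whose entry point
sits at a stable angle α ≈ 13.5° temporal to fixation. From the mean
on-screen offset *s* (mm) between fixation and the vanishing point,

```
d = s / tan(α)
```

**Crowding measurement.** Four flanker circles (1° diameter) surround a
gap target at 4° or 6° eccentricity. Target–flanker spacing is adapted
by a 1-up 3-down staircase (start 1.3 × eccentricity/2, multiplicative
steps ×1.2, bounds [1°, eccentricity]), which converges where
p(correct)³ = ½, i.e. at 0.5^(1/3) ≈ 79.4 % correct. The crowding
effect (critical spacing) is the geometric mean of the last six
reversal spacings, averaged over two independent 25-trial blocks.

**Synthetic observers** respond through a 2AFC Weibull psychometric
function of log spacing (guess rate 0.5, lapse ~0.01) anchored so that
p = 0.794 exactly at the observer's critical spacing, which follows
Bouma's law (critical spacing ∝ eccentricity) with additive dyslexia
and quadratic age effects. Blind-spot angles, ages, seating distances
and between-session drift are drawn from truncated normals matching the
reference cohort.

## Worked example

```python
from vchinrest import BlindspotTrial, compute_lpd, estimate_distance

cal = compute_lpd(card_image_width_px=342.4)      # LPD = 4.000 px/mm
offsets_px = [509.3, 512.1, 505.8, 514.6, 508.2]  # five sweep keypresses
trials = [BlindspotTrial(disappear_offset_px=o) for o in offsets_px]
result = estimate_distance(trials, cal, alpha_deg=13.5)
```

prints, via `python examples/01_calibrate_and_estimate_distance.py`:

```
logical pixel density: 4.000 px/mm (card image 342.4 px over 85.60 mm)
mean on-screen offset s = 127.5 mm over 5 sweeps
estimated viewing distance d = s / tan(13.5 deg) = 53.1 cm
```

— the five keypress offsets average to s = 127.5 mm on screen, and the
trigonometric inversion puts the eye 53.1 cm from the display.

At cohort scale, `python examples/03_cohort_simulation.py` simulates
300 participants end-to-end (calibration, three blind-spot tests, two
staircase blocks) and prints:

```
eccentricity 4 deg: mean crowding 1.73 deg (ratio to eccentricity 0.43)
eccentricity 6 deg: mean crowding 2.52 deg (ratio to eccentricity 0.42)
within-subject sd across the three blind-spot tests: 3.8 cm; ICC(1) = 0.83
4 vs 6 deg: Mann-Whitney U = 1476, p = 3e-35
```

Crowding grows with eccentricity at roughly 0.4× (Bouma's constant),
participants barely move between the three distance checks (3.8 cm
within-subject SD, ICC 0.83), and the eccentricity effect is decisive.

A thin CLI wraps the same functions:

```
vchinrest simulate --n 100 --seed 7 --out sessions/
vchinrest estimate --trials trials.csv --card-width-px 342.4
vchinrest analyze --sessions sessions/
```

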