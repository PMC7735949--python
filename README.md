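# vbikit

Quantifying a child's exposure to the environmental risk factors of
myopia from wearable-sensor streams.

Spectacle-mounted wearables can record, all day long, the two behaviours
most strongly implicated in school-age myopia: **working distance** (WD,
the eye-to-target distance during near work, sampled every 5 s over a
15–60 cm infrared sensor range) and **eye-level light intensity** (LI,
sampled every 120 s over 1–65,536 lux). `vbikit` turns a week of such
recordings, together with each child's cycloplegic refraction, into a
per-pixel map of how time spent in each (distance, illuminance)
circumstance relates to refractive error — and collapses each child's
whole behavioural week into a single exposure score, the **Visual
Behaviour Index (VBI)**. It is written for researchers in myopia
epidemiology and visual-behaviour analytics.

## Method

1. **Denoising.** LI is moved to a log10 scale, then both channels are
   low-pass filtered per contiguous wear segment with an ideal
   (brick-wall) filter: FFT, zero every coefficient above the cutoff,
   inverse FFT.
2. **Behaviour space.** Filtered WD and log10 LI samples are paired
   (most recent LI carried forward onto WD timestamps) and binned on a
   40 × 40 grid spanning 0–70 cm × 0–5 log10-lux. Each subject's pixel
   value is the percentage of time (PoT) spent in that circumstance;
   every grid sums to 1.
3. **Kernel-smoothed per-pixel regression.** Individual occupancy is
   sparse, so each pixel (i, j) borrows strength from its neighbours
   inside a circle of radius 2σ using Gaussian weights
   w = exp(−d²/2σ²). For each pixel, the smoothed occupancy
   x_m = Σ w·PoT_m over the neighbourhood is the predictor in an
   ordinary least-squares fit SER_m = β·x_m + b across subjects, with a
   two-sided t test on β.
4. **Effect map and VBI.** The effect map keeps B_ij = β_ij where
   p_ij < 0.05 and sets B_ij = 0 elsewhere. Each subject's score is

   VBI_m = Σ_ij PoT_m[i,j] · B[i,j]

   a convex combination of significant pixel effects: negative when time
   concentrates in myopiagenic circumstances, positive in protective
   ones. SER is finally regressed on VBI across the cohort.

Because no device cohort of this kind is publicly deposited, the package
ships a first-class synthetic cohort generator
(`vbikit.synthetic_data`): subjects alternate between activity states
(reading, desk work, screens, dim-light near work, outdoor, other
indoor) in a seeded renewal process with per-subject Dirichlet
preferences; sensor clipping, quantisation, wear windows and non-wear
gaps are applied at generation; and refraction is produced from a known
ground-truth effect map, so the whole analysis can be validated by
parameter recovery.

## Worked example

```python
import numpy as np
from vbikit import (SimConfig, simulate_cohort, fit_effect_maps, KernelSpec,
                    compute_vbi, regress_ser_on_vbi)

cohort = simulate_cohort(60, SimConfig(days=2, seed=7))
maps = fit_effect_maps(cohort.pot_grids, cohort.sers, KernelSpec(sigma=1.0), alpha=0.05)
vbis = np.array([compute_vbi(g, maps).vbi for g in cohort.pot_grids])
reg = regress_ser_on_vbi(vbis, cohort.sers)

print(f"SER: mean {cohort.sers.mean():+.2f} D, SD {cohort.sers.std(ddof=1):.2f} D")
print(f"significant pixels: {int(np.count_nonzero(maps.b_map))} of {int(maps.defined_map.sum())} defined")
print(f"VBI: mean {vbis.mean():+.2f}, SD {vbis.std(ddof=1):.2f}")
print(f"SER ~ VBI: slope {reg.slope:+.4f} D/unit, R^2 {reg.r_squared:.3f}, p {reg.p_value:.2e}")
```

prints

```
SER: mean -0.18 D, SD 1.31 D
significant pixels: 230 of 503 defined
VBI: mean -4.90, SD 6.02
SER ~ VBI: slope +0.1703 D/unit, R^2 0.609, p 1.91e-13
```

The 60 simulated children average slightly myopic refraction with a
realistic spread; about half of the pixels that any subject occupies
carry a significant effect; and the in-sample VBI predicts SER with a
positive slope — children whose week concentrates in significant
protective circumstances sit toward hyperopia, those in myopiagenic
circumstances toward myopia. (In-sample scoring is optimistic; see
`docs/methods.md`.)

The same pipeline runs from the shell:

```sh
vbikit simulate --n 60 --days 2 --seed 7 --out cohort/
vbikit run --input-dir cohort/ --out results/
```

which writes per-subject PoT grids, the β/p/B maps, the VBI table and
regression summary, heatmap and scatter figures, and a reproducibility
manifest.

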