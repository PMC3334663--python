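# osteoct

Micro-CT subchondral bone morphometry and longitudinal paired-limb
statistics for small-animal osteoarthritis models.

## The problem

In rodent models of osteoarthritis — e.g. a low-dose monosodium iodoacetate
(MIA) injection in one knee with saline in the contralateral control — the
tibial subchondral bone remodels over the course of the disease: early
trabecular bone loss, later sclerosis, and a thickened, increasingly porous
subchondral plate. In vivo micro-CT tracks these changes in the same animal
at successive timepoints. Quantifying them requires a fixed protocol:

1. **Segmentation** — binarize every 8-bit stack of the study with one
   uniform grey-level threshold (bone iff intensity ≥ t).
2. **Volume of interest** — stack manually drawn medial/lateral polygon
   ROIs over consecutive slices (e.g. 52 slices × 8.7 μm ≈ 0.45 mm).
3. **Trabecular morphometry** — BV (mm³), BV/TV (%), and direct-3D
   Tb.Th/Tb.Sp (μm): the local thickness at a voxel is the diameter of the
   largest sphere fully inscribed in the phase (bone or marrow) that covers
   it; Tb.N (1/mm) is derived as `Tb.N = (BV/TV)/Tb.Th`.
4. **Subchondral plate** — separate the cortical plate from the
   trabeculae (column scan with marrow-gap bridging), then plate thickness
   Pl.Th (mean direct-3D thickness) and porosity Pl.Por (pore volume over
   plate-envelope volume); the total compartment is the mean of medial and
   lateral.
5. **Inference** — per parameter and compartment: Shapiro–Wilk normality
   screen, two-way repeated-measures ANOVA (time × limb, both
   within-subject), ANOVA-gated paired t-tests per timepoint, Holm
   stepdown adjustment, α = 0.05.

No scan data ships with the package; every stage is validated on synthetic
phantoms (slabs, rod lattices, thresholded Gaussian random fields, drilled
cortical plates) whose ground truth is known by construction, and on a
cohort simulator that reproduces the published group summary structure.

## Worked example

```bash
python examples/01_phantom_morphometry.py
```

```
slab phantom (truth: Tb.Th 104.4 μm, Tb.Sp 261 μm, BV/TV 28.57 %):
  BV/TV   28.57 %
  Tb.Th   104.4 μm
  Tb.Sp   261.0 μm
  Tb.N     2.74 /mm   (= (BV/TV)/Tb.Th)
rod phantom (truth: Tb.Th 87 μm, BV/TV 8.73 %):
  BV/TV    9.00 %
  Tb.Th    87.4 μm
```

The slab phantom (104.4 μm plates, 261 μm gaps) is recovered exactly;
the rod phantom's thickness lands within one voxel of the analytic 87 μm
and its BV/TV within 0.3 points of π·r²/pitch². The other examples cover
plate separation and porosity (`02`), the full statistical recipe on a
simulated 12-animal cohort (`03`), and the worked-number checks against
the published summary tables (`04`).

A thin CLI wraps the same library for batch work:

```bash
osteoct phantom --kind subchondral --out plate.tif
osteoct segment --volume scan.tif --spacing-um 8.7 --out mask.tif
osteoct study --seed 1 --out results/
```

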