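# tauscape

Quantitative analysis of whole-brain tau pathology from cleared-tissue
light-sheet microscopy, plus PET-based tau quantification.

In tauopathy mouse models, hyperphosphorylated-tau (AT8-positive) deposits
can be imaged across the entire cleared brain at micrometre resolution.
`tauscape` implements the computational side of that experiment as a tested,
reusable library:

- **Tau deposit extraction** — resample to an isotropic 8.3 µm grid, apply a
  Gaussian-minus-mean band-pass (σ = 0.83 voxels, FWHM ≈ 16 µm, against an
  83 µm mean filter), build a brain mask at 1.5× the global mean intensity
  refined by ten binary erosions, threshold at 2× the out-of-brain
  intensity, and label connected components as spots (centroid, integrated
  band-pass intensity, volume).
- **Regional aggregation** — assign spots to a pre-aligned atlas by centroid
  voxel, drop excluded structures (ventricular systems, fibre tracts),
  compute regional tau density (summed intensity per region volume, /mm³),
  pool into medium-sized anatomical groups and select subregions of
  above-mean groups.
- **Tau gradient consensus** — find the longest region sequence whose
  descending order of log₁₀ tau density is identical in every sample.  This
  is the longest common subsequence of the k per-sample rankings, computed
  as the longest path in the precedence DAG with edge *u → v* iff *u*
  precedes *v* in every sample (O(k·n²)).  Significance comes from an
  empirical permutation null: with n = 47 regions and k = 3 samples,
  P(length ≥ 8) ≈ 0.0269 over 10,000 random permutations, making 8 the
  α = 0.05 threshold length.  Retained sequences form a directed network
  whose edge weights are adjacency counts + 1, normalized to a total of 250.
- **Evaluation and PET** — voxel-level precision/recall/F against expert
  annotation masks in 423 µm cubic ROIs, and SUV/SUVR quantification of
  dynamic PET time–activity curves (SUV = activity/(dose/body weight);
  SUVR = target SUV / cerebellar SUV averaged over 45–60 min).
- **Synthetic ground truth** — generators for toy atlases, planted Gaussian
  tau deposits, rankings with a planted order-conserved chain, and
  two-region time–activity curves on the 20-frame schedule
  (4 × 1, 8 × 2, 8 × 5 min), so every stage is testable without any data
  download.

## Worked example

```python
import tauscape as ts

# a 64^3 synthetic brain with 20 planted tau deposits
atlas = ts.make_toy_atlas(shape=(64, 64, 64), n_regions=8)
specs = ts.random_spot_specs(atlas, n_spots=20, amplitude=200.0, seed=7)
volume, truth = ts.make_tau_volume(atlas, specs, seed=7)

table = ts.extract_from_volume(volume)
print(len(table))                       # 20

densities = ts.regional_density(ts.assign_spots(table, atlas), atlas)
print(round(max(d.density_per_mm3 for d in densities)))   # 2357087

null = ts.permutation_null(n_regions=47, k_samples=3, n_perm=10_000, seed=1)
print(null.p_at[8], null.threshold_length)   # 0.029 8
```

The extraction finds every planted deposit (on other seeds a deposit rim
occasionally splits into a small extra face-connected component); the
densest region's tau density is its summed band-pass intensity per mm³
(arbitrary intensity units); and the permutation
null reproduces the ≈ 0.027 tail probability at sequence length 8, so
consensus sequences of 8 or more regions are unlikely to arise by chance
(threshold length 8 at α = 0.05).

A CLI mirrors the library (`tauscape simulate | extract | aggregate | rank |
consensus | null | graph | fscore | suvr | pipeline`); `tauscape pipeline
--config config.json --out-dir out/` runs every stage and writes a manifest
recording all thresholds and seeds.

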