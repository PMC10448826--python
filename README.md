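# boldmod

Analysis stack for a two-session resting-state fMRI study design: quality
fingerprints, task-response parameterization, seed-based connectivity
graphs, permutation inference over those graphs, and detection of
post-task resting-state connectivity modulation ("offline replay"
correlates). The package ships a synthetic-study generator with known
ground truth, so every stage — and the pipeline end to end — is testable
without any data download.

## Who this is for

Researchers analysing block-design + resting-state fMRI sessions
(rs1 → task/rest → rs2) who want a transparent, fully scripted version of
the following analysis chain, and methodologists who want its calibration
properties measurable on synthetic data.

## The analysis chain

1. **Preprocessing** (`boldmod.preprocess`): discard the first 2 volumes,
   zero-phase band-pass 0.009–0.08 Hz, 3D Gaussian smoothing (FWHM 4 mm),
   regression of white-matter and ventricle mean time courses. Task runs
   use a GLM-Fourier high-pass (2 cycles) instead of the band-pass.
2. **Quality metrics** (`boldmod.quality`): SNR, CNR, FBER, EFC on the
   temporal mean image; tSNR, zDVARS, MDI, Gcorr over time; an automatic
   background mask (largest dark component outside the brain); ratio
   fingerprints and a PCA reporting utility.
3. **Task response** (`boldmod.task`): GLM with one HRF-convolved boxcar
   predictor, BY-FDR voxel selection, activation probability (AP) and
   activated volume per region, trial-averaged ΔR/R% profiles with
   PH/PT/PW/PS shape parameters, and tCNR = ΔS_CNR/σ_t-noise with a
   Savitzky–Golay (order 2, window 5) noise estimate.
4. **MSRA connectivity** (`boldmod.msra`): a ~7.5 mm spherical seed at each
   region's centre of mass; seed-correlation maps (SCM) thresholded by
   BY-FDR (q = 0.05); connectivity(i→j) = Fisher z of the mean r over j's
   significant target voxels — an asymmetric region × region matrix.
5. **Graph inference** (`boldmod.graphs`): homotopic-rank QC with a
   distance fit, DMN specificity ratios, 7%-density thresholding, Louvain
   communities, the network-based statistic (NBS) and its paired-control
   variant (pNBS), and matrix similarity / reproducibility measures.
6. **Modulation pipeline** (`boldmod.modulation`): NBS on rs2 (ft vs rest
   group) → dominant (highest-degree) component regions become seeds →
   voxelwise paired t of rs2−rs1 SCM z maps per group and correlation sign
   → TFCE (H = 2, E = 0.05) with a sign-flip permutation null (99.9th
   voxel percentile summary, rejection at its 95% quantile) → OR-combined
   group masks → per-subject region mean Δz → homoscedastic ft-vs-rest
   t-test with BH-FDR (q = 0.05).

The synthetic generator (`boldmod.simulate`) draws region time courses
from a multivariate normal with a community + homotopic correlation
structure, broadcasts them to voxels with thermal noise, drift, and tissue
baselines, and plants a Δr = 0.3 connectivity modulation on five
within-community edges in the ft-group's second resting session only.

## Worked example

```python
from boldmod.simulate import SimConfig, default_planted_edges, dataclasses_replace, simulate_study
from boldmod.modulation import ModulationConfig, run_modulation_pipeline

cfg = SimConfig(seed=1)
cfg = dataclasses_replace(cfg, planted_edges=default_planted_edges(cfg))
study = simulate_study(cfg)          # 9 ft + 9 rest subjects, 300 volumes/session
result = run_modulation_pipeline(
    study, ModulationConfig(seed=1, nbs_n_perm=500, tfce_n_perm=200)
)
print("dominant seeds:", result.seeds)
print("planted edges: ", study.ground_truth["planted_edges"])
print(result.region_tests[result.region_tests.significant][["seed", "sign", "region", "t", "p"]])
```

Output from this exact script:

```
dominant seeds: [9]
planted edges:  [(9, 2, 0.3), (9, 3, 0.3), (9, 4, 0.3), (9, 10, 0.3), (9, 11, 0.3)]
   seed      sign  region         t         p
0     9  positive       2  2.763816  0.013835
1     9  positive       3  5.666375  0.000035
2     9  positive       4  6.288273  0.000011
3     9  positive      10  2.580823  0.020108
4     9  positive      11  3.901536  0.001270
```

Region 9 (the right member of the first bilateral pair, the planted hub)
is recovered as the dominant seed, and all five planted target regions are
flagged with ft > rest Δz — the pipeline detects exactly the modulation
that was planted, in the positive-correlation lobe.

A thin CLI mirrors the library: `boldmod simulate|preproc|qc|msra|modulate`
(see `boldmod --help`).

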