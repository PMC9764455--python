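# phenoquant

Quantification pipeline for multi-level *Drosophila* developmental
phenotyping ("phenomics"): the same animals, or the same genotypes, are
measured at the chromatin, imaging, metabolic, behavioral and
morphological levels, and the group statistics that tie those levels
together are computed in one place.

The package is aimed at researchers analyzing studies of chromatin-mark
perturbations — e.g. catalytic mutants of the H3K4 monomethyltransferase
Trr that deplete H3K4me1 — where the phenotype surfaces simultaneously
in nuclear organization, lipid metabolism, locomotion and cuticle
morphology. Every analysis stage consumes standard formats (TIFF,
bedGraph, imzML or TIFF+TSV, CSV trajectories) and every stage has a
seeded synthetic-data generator with machine-readable ground truth, so
the full pipeline is testable end to end without any deposited data.

## What it computes

- **`microenv`** — transcription sites detected as 3D local maxima in
  RNA-FISH confocal stacks (threshold µ + k·σ, non-maximum suppression
  at a physical radius), and the nuclear microenvironment around them:
  the average radial intensity profile of a second channel
  *I*(r)/*I*(r_outer) in physical µm distance, per-site peak/integrated
  intensities, site density per region mask (sites/pixel and sites/µm²),
  and per-cell mean intensities over label masks.
- **`chiptracks`** — ChIP coverage normalization on uniformly binned
  tracks: per-bin control subtraction (signal − control), centered
  moving-average smoothing (500 bp default), replicate averaging with
  pairwise Pearson correlations.
- **`maldi`** — MALDI-MSI population sections deconvolved to a
  larva × metabolite abundance matrix: total-ion-current segmentation,
  per-larva aggregation, a location/scale batch alignment
  ("combat_lite"), column-standardized PCA, and lipid-class contrasts
  ("class_ranksum": per-channel log2 fold changes summarized per class
  by median + rank-sum test).
- **`behavior`** — per-larva crawling speed (path length / time),
  moving/still classification, and head-cast events (pause with a ≥45°
  reorientation within 1 s), with rates in events/min.
- **`morpho`** — trichome counts via prominence-based maxima inside
  ROIs; body area/length from thresholded silhouettes.
- **`stats`** — pooled-variance Student's t tests (two- or right-tailed,
  "second group greater"), mean/SD/±2 SD summaries, and a cross-modality
  comparison report.
- **`synthetic`** — seeded generators for all of the above with ground
  truth; `pipeline` wires a complete two-group synthetic study.

## Worked example

```python
from phenoquant import microenv, synthetic

cfg = synthetic.ConfocalPhantomConfig(
    shape_voxels=(40, 256, 256), n_sites=30, site_peak_snr=6,
    enrichment_amplitude=2.0, enrichment_sigma_um=0.5,
    min_separation_um=2.5, seed=42)
stack, truth = synthetic.gen_confocal_phantom(cfg)
sites = microenv.detect_sites(stack, "rna")
profile = microenv.radial_profile(stack, "mark", sites)
print(len(sites), profile.mean[:3])
```

prints (from `examples/01_transcription_site_microenvironment.py`):

```
detected 33 sites (ground truth: 30)
  r = 0.05 um   normalized mark intensity = 1.775
  r = 0.15 um   normalized mark intensity = 1.745
  r = 0.25 um   normalized mark intensity = 1.688
```

The innermost bins read as fold enrichment of the mark over its
far-field baseline: the injected 2-fold Gaussian enrichment is recovered
(attenuated slightly by the PSF), and the profile decays monotonically —
the transcription sites sit on a local maximum of the mark. The
`examples/` directory holds one such narrative script per capability,
including the full two-group study (`06_full_study_report.py`) whose
report flags exactly the four generator-perturbed metrics (speed,
head-cast rate, site intensity, triglyceride abundance) and none of the
negative controls.

A thin CLI mirrors the library: `phenoquant simulate|sites|chip|maldi|
behavior|morpho|report|study --help`.

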