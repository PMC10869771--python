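# spatialniche

Spatial statistics for segmented imaging-based spatial transcriptomics
(in situ sequencing, Xenium, MERFISH and kin), built for tissue-scale
questions in organs with a strong radial architecture such as the kidney.

The package consumes the output of a transcript-to-cell segmenter (a
per-molecule table with positions, gene identities, cell assignments and
optional molecule-cluster labels, plus per-cell segmentation statistics in
the style of Baysor) and provides:

- **QC and labeling** — cell filtering on segmentation statistics (transcript
  count with a strict lower bound, area, elongation, confidence), cell-type
  labeling by the majority molecule-cluster label among a cell's transcripts,
  gene-by-cell count-matrix construction, and FOV selection via a grid system.
- **Organ coordinates** — an alpha-shape tissue boundary and a polar organ
  frame: each cell gets a *depth* (0 at the capsule, 1 at a user-chosen
  origin, e.g. the papilla centre) and an *angle*, computed along the
  origin→cell ray so that depth = |p−b| / |o−b| for the ray's boundary
  intersection b. Depth-binned composition profiles trace how cell types and
  transcripts shift from cortex to papilla.
- **Proximity statistics** — nearest-neighbour distance distributions and
  multi-scale density profiles between cell types; neighborhood
  pair-enrichment within a search radius (default 50 μm) against a
  random-pairing permutation null, with enrichment ratio, z-score and
  permutation p-value per unordered type pair; a Mann–Whitney U test (exact
  by enumeration for small samples, tie- and continuity-corrected normal
  approximation otherwise) for comparing distance distributions.
- **Spot-grid integration** — landmark-based least-squares similarity
  registration (Procrustes/Umeyama, reflections rejected) of the single-cell
  data onto a Visium-style spot grid, nearest-spot binning of cells, directly
  *measured* per-spot cell-type composition, and Pearson-correlation
  benchmarking of external deconvolution predictions against that measured
  ground truth (pooled, per-type or per-spot).
- **Synthetic tissue** — a seeded generator of kidney-like datasets (zoned
  cell types on a disk, Poisson expression programs, noise molecules, planted
  proximity niches, an overlaid spot grid with recorded truth) that emits
  every file format the other modules read; all tests run on it, no downloads.

The enrichment statistic for a type pair (A, B) at radius r is

    E(A,B) = P_obs(A,B) / mean_perm P_perm(A,B)

where P(A,B) is the fraction of all unordered cell pairs within r that are an
A–B pair, and the null redistributes the observed labels over the fixed cell
positions (1000 permutations by default; p = (1 + #{null ≥ obs}) / (1 + N)).
Because the null shares the geometry, boundary effects cancel in the ratio.

## Worked example

Simulate a tissue, run QC and pair enrichment from the shell:

```bash
spatialniche simulate --seed 7 --out demo
spatialniche qc --cells demo/cells.csv --transcripts demo/transcripts.csv \
    --min-transcripts 5 --out demo_qc
spatialniche enrich --cells demo/cells.csv --radius 50 --perms 1000 \
    --seed 7 --out demo_enrich
```

which prints

```
wrote synthetic dataset (1210 cells) to demo
retained 1210/1210 cells
tested 91 type pairs at radius 50.0 um
```

`demo_enrich/enrichment.csv` then contains one row per type pair. For the
planted glomerular niche (podocyte + glomerular endothelium doublets) the
demo run reports

```
type_a type_b  observed_pairs  enrichment        z        p
  Podo    gEC             108    1.954857 6.896996 0.000999
```

i.e. podocyte–gEC pairs co-occur within 50 μm almost twice as often as
random label pairing predicts, at the smallest p the 1000-permutation null
can resolve (1/1001). Same-zone pairs (e.g. DCT–TAL) also show enrichment
above 1: the statistic picks up zonal colocalization as well as cell-to-cell
niches, which is exactly how it behaves on real organ sections. Every output
directory contains a `manifest.json` recording the command, parameters,
input digests and seed that regenerate it.

The same pipeline in Python:

```python
import spatialniche as sn

tissue = sn.simulate_tissue(sn.default_config(7), seed=7)
results = sn.neighborhood_enrichment(tissue.dataset.cells,
                                     radius=50.0, n_permutations=1000, seed=7)
table = sn.enrichment_to_frame(results)
```

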