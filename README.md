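# spectracell

Multispectral tissue cytometry for chromogenic multiplex
immunohistochemistry: quantify marker expression per cell and per tissue
region from multispectral image cubes.

Brightfield multiplex IHC of lymphoid tissue typically combines a
nuclear counterstain (Nuclear Red) with a lineage marker (CD3 or CD20,
Warp Red) and a marker of interest such as a tetraspanin (CD37 or CD53,
True Blue). Two of these chromogens are nearly collinear in spectrum, so
per-pixel spectral unmixing against a measured library is required
before any per-cell measurement is meaningful. `spectracell` implements
the complete analysis chain:

- **Spectral libraries** from single-stain images (mean foreground
  spectrum, peak-normalized), with autofluorescence estimation and
  subtraction for fluorescence cubes.
- **Beer–Lambert conversion**: `OD(x,b) = −log10(I(x,b)/I0)`, clamped to
  `[0, od_max]`, so chromogen contributions add linearly.
- **Per-pixel unmixing** by non-negative least squares,
  `a(x) = argmin_{a≥0} ‖Sᵀa − y(x)‖₂`, where the rows of `S` are the
  peak-normalized endmembers; a coefficient is the chromogen's OD at its
  peak band. Cubes are solved with an exact vectorized active-set
  enumeration (equivalent to Lawson–Hanson, orders of magnitude faster).
- **Cell segmentation** from the nuclear channel (Gaussian smoothing →
  Otsu → distance transform → watershed → area filter).
- **Tissue-region classification** (B-cell follicle / T zone / stroma /
  other) from per-tile composition features with a Gaussian
  class-conditional model trained on a handful of labeled images.
- **Four-class phenotyping**: positivity and dim/bright OD thresholds
  derived as nearest-rank percentiles of negative-control cells
  (non-immune cells in marker-negative regions), scoring each cell
  lin−/dim, lin+/dim, lin+/bright or lin−/bright.
- **Image QC** (images with less than 10% tissue are discarded) and
  **region statistics**: OD histograms binned per 0.05 OD and normalized
  to % of max, per-region OD_mean and % bright, and two-group
  comparisons (Student's t when both groups pass a Shapiro–Wilk
  normality gate, Mann–Whitney otherwise; significance at P ≤ 0.05,
  one image = one statistical unit).
- A **synthetic scene generator** that renders lymphoid-tissue cubes
  through the same forward optical model with complete ground truth
  (region masks, per-cell classes and ODs), so every stage is testable
  without slide data.

## Worked example

```python
import numpy as np
import spectracell as sc

# three-chromogen library: Nuclear-Red-, Warp-Red- and True-Blue-like
# spectra, the two reds deliberately 8 degrees apart
endmembers = sc.default_endmembers()
print(np.round(endmembers.pairwise_angles_deg(), 1))

# one synthetic 20x field with ground truth
truth, cube = sc.generate_scene(sc.SceneConfig(seed=7), endmembers)

# Beer-Lambert OD conversion + per-pixel NNLS unmixing
amap = sc.unmix_cube(sc.to_optical_density(cube), endmembers)

# nucleus segmentation, per-cell quantification, scoring
cells = sc.segment_nuclei(amap.channel("nuclear_red"))
records = sc.quantify_cells(cells, amap, truth.region_mask, image_id="demo")
scorer = sc.PhenotypeScorer().fit(records)   # thresholds from control cells
scored = scorer.transform(records)

for region in ("follicle", "t_zone", "stroma"):
    s = sc.summarize_region(scored, region)
    print(f"{region:>8}: n={s.n_cells:4d}  OD_mean={s.od_mean:.3f}  "
          f"bright={s.pct_bright:5.1f}%  lin+={s.pct_lineage_pos:5.1f}%")
```

Output:

```
[[ 0.   8.  89.9]
 [ 8.   0.  89.8]
 [89.9 89.8  0. ]]
follicle: n= 337  OD_mean=0.274  bright= 85.8%  lin+= 88.4%
  t_zone: n= 744  OD_mean=0.191  bright= 57.1%  lin+=  8.9%
  stroma: n= 415  OD_mean=0.173  bright= 48.7%  lin+= 44.8%
```

The scene contained 1584 true nuclei, of which 1578 were segmented. The
follicle shows high lineage positivity and bright tetraspanin
expression; the T zone is lineage-poor (the lineage marker here is the
B-cell surrogate); the stroma is mixed — each number is recoverable from
the generator's ground truth for validation.

The same stages are available from the shell:

```sh
spectracell simulate --seed 7 --out scene/
spectracell run-all --seed 7 --out results/
```

`run-all` writes `cells.csv` (scored records), `summaries.csv`,
`stats.csv`, `qc.csv`, `thresholds.json` and a manifest; reruns with the
same seed are byte-identical.

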