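# lobequant

Segmentation-free quantification of cell counts and reporter positivity in
two-channel confocal stacks of *Drosophila* lymph-gland primary lobes — the
larval haematopoietic organ — with a synthetic-image test-bed that validates
every stage against known ground truth.

## The problem

Haematopoietic phenotypes in the lymph gland are scored per primary lobe:
how many cells does a lobe contain (*N* cells), and what fraction of them
express a cytoplasmic reporter (e.g. *pxn>*mRFP marking the cortical zone)?
Nuclei in these tissues are densely packed and poorly separable by
segmentation, so the pipeline counts cells without segmenting them:

1. **Detection** — each 2-3-plane nuclear-stain ("DAPI") channel is filtered
   with a Laplacian of Gaussian at the nuclear scale (σ = diameter/4, sign
   flipped so nuclei are positive peaks). Cells are the strict local maxima of
   the response, thresholded relative to the per-plane maximum, kept at least
   one nuclear diameter apart, and merged across planes so a nucleus visible
   on several planes is counted once. *N* cells = number of accepted peaks.
2. **Shell quantification** — the cytoplasmic reporter ("RFP") is sampled on
   its maximum-intensity projection in an annular shell centred on each
   nuclear peak, offset by an empty gap of one nuclear diameter so the shell
   reads cytoplasm, never nucleus.
3. **Classification** — a cell is reporter-positive when its
   (background-corrected) shell statistic reaches 75% of the lobe's maximal
   shell statistic; the rule is relative, so calls are invariant to overall
   intensity rescaling. Per lobe: `% positive = 100 · n⁺ / N`.
4. **Statistics** — per-lobe percentages are compared between genotype groups
   with the two-sided two-sample Kolmogorov–Smirnov test
   (D = sup |F̂ₐ − F̂ᵦ|; exact p for small samples), summarised by mean, SEM
   and 5%/95% percentiles. qPCR Ct tables reduce to fold changes by
   2^(−ΔΔCt) with the control group normalised to 1.

Because no deposited image data exist for this assay, the package ships a
generator of confocal-like lobes (Gaussian-profile nuclei, annular reporter
rings for the positive cells only, additive background and clipped Gaussian
noise) with exact per-cell answer keys.

## Worked example

```python
from lobequant import (SynthesisParams, generate_lobe_image,
                       DetectionParams, ShellParams, quantify_lobe)

params = SynthesisParams(positive_fraction=0.6, seed=1)   # 100 nuclei, SNR ~ 5
stack, truth = generate_lobe_image(params)
q = quantify_lobe(stack, DetectionParams(), ShellParams())
print(q.n_cells, q.n_positive, q.percent_positive)
```

prints `100 60 60.0`: all 100 nuclei found and exactly the 60 truly
reporter-positive cells called positive at these conditions. The same flow
from the shell, on a two-group cohort (15 control lobes at 20% positive vs
15 JAK-activation-like lobes at 60%):

```bash
lobequant run --config examples/cohort.yaml
```

writes per-cell, per-lobe and comparison tables; the comparison row reports
`D=1.000, p=1.29e-08` with group means 20.0 and 60.0 — the JAK-like expansion
of the reporter-positive population is unambiguous at these cohort sizes.
The numbered scripts under `analysis/` run this cohort study end to end
(simulate, validate detection, quantify, compare, fold changes) and leave
their tables under `results/`.

CLI subcommands: `simulate`, `detect`, `quantify`, `compare`, `foldchange`,
`run` (see `lobequant --help`).

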