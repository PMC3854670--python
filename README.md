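# mfishsparse

Pixel classification for multicolour fluorescence in-situ hybridization
(M-FISH) chromosome images by sparse representation over a dictionary of
labelled training pixels — pixel by pixel via orthogonal matching pursuit
(OMP), or jointly with each pixel's neighborhood via simultaneous OMP (SOMP)
under a shared row support.

M-FISH labels each of the 24 human chromosome classes with a distinct
combination of five fluorochromes, so every chromosomal pixel carries a
5-channel intensity vector whose expected pattern is its class's binary code.
Given a dictionary `A = [A_1 … A_m]` of training pixels grouped by class, a
test pixel `y` is coded sparsely,

```
x̂ = argmin ‖Ax − y‖₂   s.t.  ‖x‖₀ ≤ K₀,
Class(y) = argmin_i ‖y − A_i x̂_i‖₂,
```

and the joint model codes the `n×s` matrix `Y` of a pixel and its square
window together under a row-sparsity constraint (`‖X‖₀,₂ ≤ K₀`, all columns
share one support), deciding the central pixel by
`argmin_i ‖Y − A_i X̂_i‖_F`.  Neighboring chromosome pixels share a class, so
the joint decision suppresses the isolated single-pixel errors a pixelwise
classifier leaves behind.

The package is aimed at cytogenetic image-analysis work: it includes the
greedy solvers, dictionary construction with seeded train/test splitting and
optional SCI screening, neighborhood extraction with mask-aware boundary
handling, RCC evaluation with paired model comparison, a synthetic M-FISH
cell generator with ground truth (so everything is testable without a
proprietary database), readers/writers for cell directories, and a small CLI.

## Worked example

`examples/02_joint_vs_pixelwise.py` simulates five noisy cells, classifies
each with the pixelwise (s=1) and joint (s=9) models from the same
dictionary, and compares them:

```
cell 0: pixelwise 67.5%  joint 84.8%  isolated spots 127 -> 51
cell 1: pixelwise 66.3%  joint 86.4%  isolated spots 111 -> 50
cell 2: pixelwise 66.8%  joint 84.7%  isolated spots 113 -> 47
cell 3: pixelwise 67.3%  joint 84.5%  isolated spots 118 -> 48
cell 4: pixelwise 65.3%  joint 85.4%  isolated spots 113 -> 49

joint:     85.16 +/- 0.76 %
pixelwise: 66.66 +/- 0.87 %
paired t = 28.73, two-sided p = 8.7e-06
```

Each line is one simulated cell: the per-cell RCC (ratio of correctly
classified held-out pixels) of both models, and the number of isolated
(single-pixel, 8-connected) misclassification components inside the
chromosome mask before and after joint coding.  The summary is a two-sided
paired t-test over the per-cell RCC values, in percent.  The other examples
cover the basic pipeline on a noiseless cell (`01_simulate_and_classify.py`,
held-out RCC 100%) and the parameter effects (`03_parameter_effects.py`:
accuracy rises with training fraction, and s=9 beats both s=1 and an
oversized window).

The same pipeline runs from the shell:

```
mfish simulate --seed 7 --out cell/
mfish train --cell cell/ --fraction 0.1 --seed 1 --out dict
mfish classify --cell cell/ --dict dict --k0 3 --s 9 --out pred.png
mfish evaluate --pred pred.png --truth cell/truth.png \
      --test-pixels dict_test_pixels.csv --out report.csv
```

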