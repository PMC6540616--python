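# synscreen

Quantification pipeline for split-DHFR protein-complementation interaction
screens and synaptogenesis imaging assays, with synthetic-data generators
that provide exact ground truth for both stages.

## The problem

Presynaptic-organizer receptors such as PTPσ trigger presynaptic
differentiation where they engage a postsynaptic partner, and dissecting
which of their intracellular interactions (liprin-α, caskin, trio,
homodimerization) carry that signal requires two bespoke quantification
pipelines:

1. **Interaction scoring from yeast growth curves.** In the split-DHFR
   protein-complementation assay, two candidate binding partners are fused
   to complementary fragments of a methotrexate (MTX)-insensitive DHFR.
   Yeast grow in MTX only if the fusions interact and reconstitute the
   enzyme, so the MTX-vs-control growth-rate ratio reads out binding.
   For each well, the slope of the blanked log2(OD600) curve is fitted in
   the linear range between log2 values of −3 and −2; each MTX well's slope
   is divided by the mean slope of the same strain's MTX-free wells on the
   same plate (ratio_x), and the interaction score is normalized against
   on-plate controls:

   score = (ratio_x − ratio_NC) / (ratio_PC − ratio_NC)

   so 1 means wild-type-like growth (intact interaction) and 0 growth
   equivalent to the negative control. Scores are clipped to [0, 1] and
   binned into five color classes only for heatmap display; mutants with
   scores < 0.3 for at least three ligands are flagged as nonspecific
   (likely folding/expression defects).

2. **Fluorescence recruitment measures.** Three imaging assays are
   quantified by boolean ROI algebra on thresholded channels:
   a HEK-cell co-clustering ratio (mean reporter intensity inside
   scaffold puncta ÷ the remaining cell area, after rolling-ball
   background subtraction with radius 14 px); coculture contact measures
   (punctate synapsin per unit axon–COS contact area, with the MAP2
   dendrite mask dilated by 5 px and removed to exclude native synapses);
   and per-field Tau/MAP2 areas per nucleus. Per-cell measures are
   normalized per culture to a control condition and compared with
   Mann-Whitney or Kruskal-Wallis + Dunn's tests.

Real plates and micrographs are not required anywhere: `synscreen.growth`
and `synscreen.scenes` generate plates and multi-channel scenes with known
rate ratios, recruitment ratios, puncta densities, masks and counts, so
every measure can be checked against an analytic expectation.

## Worked example

`examples/score_dhfr_plate.py` simulates two replicate plates carrying
the controls and three mutants with MTX/DMSO rate ratios between the
control anchors, and scores them end to end:

```
strain        score   SEM     n   heatmap bin
PC            +1.000  0.006   6   >0.8
NC1           -0.000  0.001   6   <0.2
mut_strong    +0.906  0.008   6   >0.8
mut_partial   +0.508  0.006   6   0.4–0.6
mut_dead      +0.043  0.002   6   <0.2
```

The controls sit on the score anchors (1 and 0), and each mutant's score
matches its configured growth-rate ratio position between them; n = 6 is
two experiments × three replicate MTX wells. Likewise
`examples/hek_recruitment.py` recovers known recruitment ratios from noisy
scenes:

```
true ratio   recovered (median over 5 seeds)
    0.5       0.505
    1.0       1.001
    2.0       1.986
    4.0       3.922
```

`examples/coculture_recruitment.py` and `examples/field_morphology.py`
demonstrate the coculture contact measures (with per-culture
normalization and rank tests) and the per-field morphology measures.

## Layout

- `src/synscreen/growth.py` — plate simulator (logistic growth, artifacts, I/O)
- `src/synscreen/scoring.py` — QC, slope fitting, ratios, interaction scores
- `src/synscreen/scenes.py` — synthetic microscopy scenes with ground truth
- `src/synscreen/quant.py` — masks, rolling ball, recruitment/contact/morphology measures
- `src/synscreen/stats.py` — group summaries, Mann-Whitney, Kruskal-Wallis + Dunn's
- `src/synscreen/report.py` — score heatmap and bar-with-points figures
- `docs/methods.md` — models, parameters, numerical choices, limitations
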