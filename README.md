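# gravitome

Analysis pipeline for altered-gravity transcriptome experiments on human
immune cells.  Parabolic flights expose cell cultures to ~20 s of 1.8 g
hypergravity and then ~20 s of microgravity; suborbital ballistic rockets
extend this to ~75 s of up to 13.5 g followed by ~300 s of microgravity.
Given RMA-normalized expression matrices from such campaigns (or synthetic
ones the package generates), `gravitome` answers: which transcripts respond
to hypergravity, which respond to microgravity once delayed hypergravity
effects are controlled away, how the response evolves between seconds and
minutes of exposure, and which genes respond consistently across cell lines
and array platforms.  Its intended users are researchers analyzing
gravitational cell biology screens and anyone who needs the exact published
conventions (signed fold change, direction-controlled set logic, four-way
temporal classification) as tested, reusable code.

## The statistics at the core

For each probe set and ordered group pair with linear-scale group means
x̄₁, x̄₂ and ratio r = x̄₁/x̄₂:

* **Signed fold change**  FC = r if r > 1, FC = −1/r if r < 1, FC = +1 at
  equality — so FC ∈ (−∞,−1] ∪ [+1,∞) and a halving reads −2.0.
* **Significance**: equal-variance two-sample t-test (or the algebraically
  identical two-group one-way ANOVA, F(1,ν) = t²) on log2 intensities;
  a probe set is differentially expressed when p < 0.05 (raw).
* **Controlled microgravity sensitivity**: probe sets significant in
  µg vs baseline-hypergravity, *excluding* those also significant in the
  preceding hypergravity control comparison (baseline vs ground control)
  **in the same direction** — the excluded intersection is the
  "double-sensitive, same direction" pool.
* **Temporal categories** across a short and a long exposure of the same
  contrast: `no_response` (never significant), `continuous` (significant at
  both, same direction), `adaptation` (initial response disappears or
  reverses), `late_response` (appears only at the longer exposure); shares
  are half-up one-decimal percentages.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate the Jurkat campaign pair (parabolic flight, 6 replicates per group;
rocket flight, 7–9 per group) with 184 panel probe sets and planted response
classes, fit each campaign, and classify the hypergravity time course:

```python
from gravitome import (CampaignModel, NoiseModel, classify_timecourse,
                       get_design, generate_campaign, plant_timecourse_truth)

short, long = get_design("23rd_DLR_PFC"), get_design("TEXUS-51")
truth = plant_timecourse_truth(n_probe_sets=184, short_design=short,
                               long_design=long, effect_log2=1.0, seed=7)
noise = NoiseModel(sigma_log2=0.1, seed=8)
fitted = {d.campaign_id:
          CampaignModel(generate_campaign(d, truth, noise), d).fit(method="anova")
          for d in (short, long)}
print(fitted["23rd_DLR_PFC"].summary())
tc = classify_timecourse(fitted["23rd_DLR_PFC"], fitted["TEXUS-51"],
                         condition="hypergravity")
print(tc.summary())
```

prints

```
Campaign 23rd_DLR_PFC (Jurkat, platform hta_2_0)
method=anova, alpha=0.05, 184 probe sets

Differentially expressed probe sets per comparison:
                      up  down  total
IF_1g_vs_HW_1g_GC      4     5      9
BL_hyp_g_vs_IF_1g     45    52     97
MU_G_vs_BL_hyp_g       4     3      7
BL_hyp_g_vs_HW_1g_GC  44    51     95

Gravisensitivity sets:
  hypergravity-sensitive            95
  microgravity-responsive           7
  microgravity-sensitive (controlled) 4
  double-sensitive same direction   3
  double-sensitive opposite         3

Temporal classification (hypergravity): 23rd_DLR_PFC (short) vs TEXUS-51 (long), 184 units
  no_response       40  (21.7%)
  continuous        42  (22.8%)
  adaptation        53  (28.8%)
  late_response     49  (26.6%)
```

Reading it: 95 of 184 probe sets responded to the planted hypergravity
shifts in the short campaign (the in-flight control comparison is near-null,
as designed); of the 7 probe sets nominally responsive to microgravity, 3
moved in the same direction as in the preceding hypergravity phase and are
excluded, leaving 4 controlled microgravity-sensitive probe sets.  The
temporal shares recover the planted class mix (≈25% per class) up to the
~5% per-contrast false-positive rate.

The same chain runs from the shell:

```bash
gravitome simulate --seed 1 --out bundle/
gravitome report --bundle bundle/ --out results/
gravitome validate
```

## Validation script

`scripts/acceptance.py` recomputes the worked-example validation targets
from their published inputs: the per-category probe-set counts of the Jurkat
(n = 184) and U937 (n = 375) time courses are fed through the
category-share computation, and the temporal classifier is applied to the
packaged continuous-response fold-change table.  Run it from the repository
root:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`gravitome validate` runs the same targets plus structural checks
(set-logic identity on 1000 randomized fixtures, classifier decision table)
and exits non-zero on any failure.
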