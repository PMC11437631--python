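# retmorph

Automated morphometry of the retinal vasculature from segmented fundus
images, plus the statistical layer used to compare vascular geometry
across refractive groups (normal, low, moderate and high myopia).

Myopia progressively deforms the posterior eye, and the retinal vessel
tree remodels with it. `retmorph` quantifies that remodeling from a
pair of binary vessel masks (artery and vein, produced by any upstream
segmenter) and an optic-disc annotation, without any manual tracing:

1. each mask is thinned to a one-pixel skeleton and converted to a
   rooted centerline graph (endpoints, junctions, crossings, per-segment
   caliber from sub-pixel cross-section chords);
2. vessel segments receive **Strahler orders** (leaf segments are order
   1; a parent's order increments only where two daughters tie at the
   maximal order), crossings of two vessels (degree-4 skeleton nodes)
   are dissolved by tangent-continuity pairing, and each junction is
   classified as a **branching point** (daughter orders differ) or a
   **bifurcation point** (daughter orders equal);
3. five metrics are measured per image and vessel class:

   | metric | definition |
   |---|---|
   | MA | main angle: angle at the optic-disc center between the rays to the distal anchors of the superior and inferior highest-order arcades |
   | BA | branching angle: angle between the two daughter vessels at a branching junction |
   | BEA | bifurcation edge angle: the same angle at a bifurcation junction |
   | BC | branching coefficient: (d₁² + d₂²)/d₀² at branching junctions |
   | BEC | bifurcation edge coefficient: (d₁² + d₂²)/d₀² at bifurcation junctions |

   Branch metrics are restricted to an annulus 0.5–2.0 disc diameters
   outward from the disc edge; MA is not annulus-restricted.
4. cohort tables of per-image values are summarized per group (mean,
   SD, 95% CI), compared by one-way ANOVA, and broken down into
   pairwise mean differences with 95% CIs and p-values (Fisher LSD by
   default; Bonferroni and Welch available).

Because clinical fundus images cannot ship with the code, the package
includes a first-class synthetic vasculature generator: parametric
arcade trees with exactly known branch angles, diameter ratios and
Strahler structure, rasterized into masks, and cohort simulators
parameterized by published group summaries from a pediatric myopia
cohort (2 366 images: 279 normal, 1 193 low, 510 moderate, 384 high
myopia). Every stage of the pipeline is validated against this
analytic ground truth.

## Worked example

```python
import retmorph as rm

# a synthetic image with exactly known geometry
disc = rm.DiscGeometry(center=(350, 350), diameter=110)
sup, inf = rm.generate_arcade_pair(disc, "artery", seed=7)
mask = rm.render_trees([sup, inf], 700, 700)

graph = rm.extract_graph(mask, disc)           # skeleton -> ordered graph
record, _ = rm.measure_image(graph, graph, disc, image_id="demo")
print(record.MA, record.BA_mean, record.BC_mean)
```

prints (alongside the generator's analytic main angle of 116.88°):

```
MA  = 116.99 deg   (ground truth 116.88)
BA  = 65.23 deg over 4 branching junctions
BEA = 81.30 deg over 2 bifurcation junctions
BC  = 1.122   BEC = 1.403
```

The measured main angle agrees with the planned tree to 0.11°; the
branching/bifurcation means aggregate the junctions inside the
measurement annulus.

The same pipeline is scriptable from the shell:

```bash
retmorph simulate --trees 2 --seed 1 -o sim/          # masks + ground truth
retmorph measure sim/img000_artery.png sim/img000_vein.png \
    sim/img000_disc.json -o out/                      # per-image metrics CSV
retmorph simulate --cohort vein --seed 1 -o sim/      # simulated cohort
retmorph stats sim/cohort_vein.csv -o report/         # descriptives/ANOVA/pairwise
```

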