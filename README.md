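# myoquant

Quantification pipeline for imaging, ChIP-seq and qPCR readouts of
C2C12 myoblast (MB) → myotube (MT) differentiation experiments, centred on
the distribution of nuclear-basket proteins such as the nucleoporin TPR
between the nuclear periphery (NP) and the nucleoplasm.

It is written for experimentalists and analysts who need reproducible,
tested implementations of five common quantification steps:

1. **Nuclear-periphery shell profiling** ("nuclear circle analysis").
   Nuclei are segmented on the DNA stain; a protein channel is profiled in
   one-pixel shells parallel to the nuclear boundary (iso-distance layers
   of the Euclidean distance transform). Shells within 1.5 µm of the
   boundary form the NP band, the rest the nucleoplasm; after background
   subtraction the nucleoplasm : NP mean-intensity ratio is reported per
   nucleus. Within-nucleus compartments are compared with a paired
   *t*-test, groups with Welch's *t*-test.
2. **NPC density**: punctate nuclear-pore spots in a peripheral section are
   thresholded, labeled (8-connectivity), size-filtered and reported as
   spots/µm².
3. **Gene-level ChIP binding**: reads/gene (fragment-midpoint assignment),
   reads/kbp = reads/gene ÷ (length/1000), and the dual-threshold binding
   call *bound ⇔ reads/kbp ≥ 17 AND reads/gene ≥ 100*. Differential
   binding between conditions uses median-of-ratios size factors, per-gene
   method-of-moments NB dispersions, a negative-binomial two-group maximum
   likelihood fit with a Wald test on the log2 fold change, and
   Benjamini–Hochberg adjustment. Sample similarity is summarized by
   complete-linkage clustering of Euclidean distances between
   variance-stabilized (log2(normalized + 1)) profiles.
4. **qPCR**: Livak 2^−ΔΔCT relative expression with a reference gene and a
   calibrator group, a CT ≤ 30 replicate filter, and ChIP-qPCR fold change
   over the histone-H3 immunoprecipitate (fold > 1 = binding).
5. **Morphometry**: myotube fusion index, width at the widest point, and
   the shared square-root / log transform *t*-test conventions.

Because studies of this kind rarely deposit raw images, every stage ships
with a synthetic-data generator (`myoquant.synthetic`) that produces inputs
with known ground truth — nuclei with a bright rim and a dimmer interior at
a configurable intensity ratio, spot fields of known density,
negative-binomial count tables with known bound/differential genes, and Ct
tables with known fold changes — so the whole pipeline is testable end to
end.

## Worked example

Recover the two intensity regimes seen in myogenesis imaging — a
nucleoplasm at ~40 % of NP intensity in myoblasts and ~15 % in myotubes —
from simulated fields, through the full segment → background → shells →
compartments → statistics path:

```python
import pandas as pd
from myoquant import synthetic, segmentation, shells

summaries = []
for regime, ratio in [("MB", 0.4), ("MT", 0.15)]:
    for seed in range(3):
        spec = synthetic.ImageSimSpec(field_shape_px=(800, 800), n_nuclei=10,
                                      interior_to_rim_ratio=ratio, seed=seed)
        sim = synthetic.simulate_image_field(spec)
        labels = segmentation.segment_nuclei(sim.field)
        bg = segmentation.estimate_background(sim.field.channels["target"],
                                              labels, spec.pixel_size_um)
        prof = shells.shell_means(sim.field.channels["target"], labels,
                                  spec.pixel_size_um)
        s = shells.compartment_summary(prof, band_um=1.5, background_fi=bg)
        s["group"] = regime
        summaries.append(s)

report = shells.aggregate_and_test(pd.concat(summaries, ignore_index=True))
print(report.group_stats[["group", "n_nuclei", "ratio_mean", "ratio_sem",
                          "paired_p"]].to_string(index=False))
```

Output:

```
group  n_nuclei  ratio_mean  ratio_sem     paired_p
   MB        30    0.399561   0.000161 2.976777e-81
   MT        30    0.149473   0.000154 1.225756e-85
```

The recovered per-nucleus ratios match the simulated truth (0.4 and 0.15)
to three decimals, and the paired NP-vs-nucleoplasm test is decisive in
both groups; the accompanying Welch comparison of the two regimes
(`report.between_groups`) separates MB from MT at p ≈ 10⁻¹²⁷.

A command-line interface mirrors the library
(`myoquant simulate|segment|shells|npc-density|chip|qpcr|morph`), e.g.:

```bash
myoquant simulate counts --seed 3 --out sim/
myoquant chip diff --counts sim/counts.tsv --samples sim/samples.tsv --out diff.tsv
```

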