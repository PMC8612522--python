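# tempcode

Toolkit for quantifying the **temporal transcription-factor (TF) code** of
the developing central nervous system — the observation that neurons are
stratified by *when* they are born: early-born neurons express Onecut-family
TFs, intermediate-born neurons express Pou2f2 and Zfhx3, and late-born
neurons express Nfia/Nfib and Neurod2, while progenitors themselves switch on
late genes (Sox9, Nfia/b) as the gliogenic transition approaches.

The package is aimed at developmental neurobiologists and image/scRNA-seq
analysts who want a tested, reusable implementation of the quantification
steps behind this kind of study, together with synthetic-data generators that
carry exact ground truth, so every stage can be validated end to end without
any external data download.

## What it computes

* **EdU birthdating quantification** (`tempcode.imagequant`).  A thymidine
  analog injected at embryonic day *t* labels cells in S-phase; neurons born
  near the pulse retain the label.  Sections are quantified as: watershed
  segmentation of DAPI nuclei (adaptive local-mean threshold, distance-
  transform seeds), area filtering, per-nucleus mean intensities, per-section
  min–max normalization to [0, 1], trimming of the 0.3% brightest and dimmest
  objects per channel, neuron/progenitor classification (HuC presence or Sox2
  absence), positivity calls at normalized intensity > 0.25, and finally

  percent = 100 · #(EdU⁺ ∧ TF⁺ neurons) / #(EdU⁺ neurons).

* **Flow-cytometry gating** (`tempcode.flowgate`).  Live gate, Sox2/Tubb3
  progenitor–neuron split, and a per-sample *dynamic* positivity threshold:
  the (1 − f) quantile of the Sox2⁺ progenitor marker intensities with
  f = 1.5% (so 1–2% of progenitors score positive), or a global threshold for
  markers expressed in both compartments.  Group comparisons use unpaired
  t tests (pooled and Welch), with the usual star coding.

* **Temporal marker discovery** (`tempcode.tempmarkers`).  Counts are
  normalized to 10,000 per cell (then log1p).  Within each progenitor domain,
  one-vs-rest stage comparisons use a Wilcoxon rank-sum test (exact
  enumeration for groups ≤ 8, tie-corrected normal approximation otherwise)
  behind min.pct ≥ 0.25 and |ln fold change| ≥ 0.25 pre-filters with
  Bonferroni adjustment; genes recurring in **more than 7** of the 10 eligible
  domains (dp6 excluded) form the temporal gene set, intersected with a TF
  symbol list.

* **Correlation dynamics** (`tempcode.corrdyn`).  Spearman TF–TF matrices,
  genome-wide correlation-rank tables against a reference gene (Nfib/Zfhx3
  style), and the in-vivo vs in-vitro Pearson partition over paired stages
  (e9.5–e13.5 ↔ differentiation days D5–D9): correlated if r > 0.5,
  anticorrelated if r < −0.5, uncorrelated otherwise.

* **Pseudotime waves** (`tempcode.pseudotime`).  Minimal lineage ordering on
  a provided 2D embedding (unique path between start and end cluster in the
  MST of cluster centroids, cells projected onto the centroid polyline),
  LOESS smoothing into 30 pseudotime bins per stage, per-gene normalization
  to a global maximum of 1, and a wave-order statistic asking whether the
  early → intermediate → late TF groups peak in strictly increasing bins.

* **Synthetic ground truth** (`tempcode.synthdata`).  Multi-channel section
  images whose TF staining is a deterministic function of sampled birthdates,
  negative-binomial count matrices with planted stage-monotone genes, flow
  event clouds, paired stage profiles, and planted trajectories.

## Worked example

```python
from tempcode import synthdata, imagequant

program = synthdata.TemporalProgram()          # Onecut2 [e9,e10.5), Zfhx3 [e9,e11.5), ...
spec = synthdata.SectionSpec(edu_pulse_day=12.5, tf_channel="Nfib")
image, truth = synthdata.generate_section(spec, program, seed=1)
records, result = imagequant.quantify_section(image, edu_day=12.5)
print(result)
```

```
ColocResult(tf='Nfib', edu_day=12.5, n_edu_pos_neurons=14, n_double_pos=14,
            percent=100.0, undefined=False)
```

All 14 neurons born within ±0.25 day of the e12.5 pulse carry Nfib — exactly
what the temporal program plants, recovered by the full image pipeline.

The end-to-end study runs from the shell:

```bash
tempcode demo --out demo_run --seed 3
```

which writes `birthdating.csv` (pipeline vs ground-truth percentages per TF
and pulse day):

```
tf,edu_day,n_sections,pipeline_pct,truth_pct
Zfhx3,9.5,2,100,100
Zfhx3,12.5,2,0,0
Nfib,9.5,2,0,0
Nfib,12.5,2,100,100
Neurod2,11.5,2,70.6349,70.6349
...
```

plus marker-discovery outputs (8/8 planted temporal genes recovered, 0 false
discoveries), flow group statistics (ventral vs dorsal Welch t = 55.3,
p = 7.7e-07, ***), the correlation partition (180/74/46 split, 99.7% class
accuracy against planted truth), and the pseudotime wave verdict (`true`,
early < intermediate < late peak bins at every stage).

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions, and the limits of what the synthetic benchmarks demonstrate.
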