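# wavegrn

Tools for studying how insect segmentation-gene expression waves arise from
enhancer switching, and how enhancer activity relates to chromatin
accessibility. The package bundles four things that normally live in
separate scripts around such a study:

1. **`wavegrn.grn_model`** — the Enhancer Switching ODE model: three genes,
   each driven by a *dynamic* enhancer (wired as a repressilator-like clock,
   activated by a speed-regulator gradient *R*) and a *static* enhancer
   (wired as a multi-stable network, repressed by *R*), with in-silico
   reporter genes and enhancer-deletion experiments.
2. **`wavegrn.wave_analysis`** — kymographs, wave-peak tracking, wave
   direction/speed, and classification of enhancer activity as
   *static-like* (wave gains amplitude toward the anterior) or
   *dynamic-like* (wave fades toward the anterior).
3. **`wavegrn.ms2_imaging`** — the MS2/MCP live-movie chain: maximum
   z-projection, CLAHE, half-max-seeded watershed nucleus segmentation, 3D
   difference-of-Gaussians spot detection with an ImageJ-style tolerance,
   spot-to-nucleus assignment, nearest-centroid nucleus tracking, and
   10-frame moving-average mRNA estimation.
4. **`wavegrn.accessibility`** — ATAC-seq-style post-processing rules:
   consensus-peak merging (≥1 bp overlap, ≥2-sample support), blacklist
   flagging of 50 bp bins with cross-library mean signal ≥ 100, selection of
   the most variable accessible sites (mean > median AND SD > Q3), k-means
   clustering of z-scored scores, the 90%-of-site construct-overlap rule,
   and the construct-activity × differential-accessibility association
   table.

`wavegrn.synthetic` generates every input with known ground truth (embryo-
like MS2 movies, accessibility matrices with a 3 regions × 2 time points ×
3 replicates design, peak sets, coverage tracks), and `wavegrn.benchmark`
scores the pipeline against that truth.

## The model

Each cell along the anterior-posterior (AP) axis carries, for genes
*i* = 1..3 (indices cyclic, anterior = index 0, *R* ∈ [0, 1] rising toward
the posterior):

```
D_i = R · 1/(1 + G_{i+1}^n)                                (dynamic enhancer)
S_i = (1−R) · G_i^n/(1+G_i^n) · Π_{j≠i} 1/(1+G_j^n)        (static enhancer)
dG_i/dt = α_i·D_i + β_i·S_i − λ·G_i
dRD/dt = D_2 − λ·RD          dRS/dt = S_2 − λ·RS           (reporters)
```

High *R* (posterior) runs the clock fast; low *R* (anterior) hands control
to the multi-stable network, which freezes each cell in the state the clock
left it in. The phase gradient appears as expression waves that sweep from
posterior to anterior and resolve into stripes — and the two enhancers of
the same gene leave opposite spatial signatures, which is what
`wave_analysis` quantifies.

## Worked example

```python
import wavegrn.grn_model as gm
import wavegrn.wave_analysis as wa

profile = gm.make_speed_profile(100, "linear")      # R: 0 (anterior) -> 1
result = gm.simulate(gm.DEFAULT_PARAMS, profile, record_every=10)

for species in ("RS", "RD"):
    kymo = wa.extract_kymograph(result, species)
    tracks = wa.detect_wave_peaks(kymo, 0.1 * kymo.values.max(), 5.0)
    tr = max(tracks, key=len)
    s = wa.classify_enhancer_dynamics(tr, axis_length=kymo.n_positions)
    print(species, s.direction, s.classification, round(s.amplitude_slope, 3))
```

prints

```
RS posterior_to_anterior static_like -0.02
RD posterior_to_anterior dynamic_like 0.014
```

Both reporter waves travel posterior → anterior; the static-enhancer
reporter (RS) gains amplitude toward the anterior (negative slope under the
anterior = 0 convention), the dynamic-enhancer reporter (RD) fades — the
opposite spatial signatures the model predicts for the two enhancer types.

The same checks run from the shell:

```bash
wavegrn simulate --config cfg.yaml --out run.h5
wavegrn analyze-waves --in run.h5 --species RS --report waves.json
wavegrn reproduce --target deletions --out deletions.json
wavegrn synth movie --snr 5 --out movie_dir/
wavegrn atac consensus --peaks a.bed --peaks b.bed --out consensus.bed
```

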