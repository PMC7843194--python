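# sdaeconn

Adaptive EEG feature extraction with stacked denoising autoencoders and
directed brain-area connectivity by conditional Granger causality.

EEG has a poor signal-to-noise ratio: rhythms of interest (delta, theta,
alpha, beta) sit on broadband background, slow drift and sensor noise, and
that noise produces false connections when one asks which brain areas drive
which. `sdaeconn` is for researchers who want to go from multichannel
recordings (or fully synthetic, ground-truthed stand-ins) to a directed
connectivity graph between areas, with every stage testable:

1. **Preprocess** — zero-phase band-pass/notch filtering, the 4-neighbor
   surface Laplacian `V_C = V_CO − (V1+V2+V3+V4)/4`, optional decimation.
2. **Compress** — a two-stage stacked denoising autoencoder (SDAE) per
   area: masking corruption (p = 0.5), sigmoid encoder/decoder
   `Y = s(WX+b)`, `Z = s(W′Y+b′)`, squared-error SGD, greedy stacking
   c → n → m units; the m deep series averaged form the area feature.
   Hidden widths can be chosen by the spectral score
   `c_f = λ·e^{−(e₁+e₂)/2c} + (1−λ)·Σ c̄³` over admissible pairs
   (m·n ≤ 30, m ≤ n < 15, m < 5).
3. **Score** — RPFA, the ratio of the power at the dominant in-band
   frequency to the mean in-band power (alpha+beta when awake, delta+theta
   for fatigue / sleep deprivation), against raw-average and PCA baselines.
4. **Connect** — conditional Granger causality
   `F_{2→1|3..m} = ln(var(ξ₁ᵣ)/Σ₁₁)` from per-equation least-squares VAR
   fits (order by BIC), circular-shift permutation significance at
   α = 0.01, with AR pre-whitening and a time-reversal contrast for
   robustness against noise-induced spurious edges.

A synthetic-EEG generator with known directed couplings makes the whole
chain verifiable without any recordings.

## Worked example

```python
import sdaeconn as sc

# 4 areas x 25 channels, 60 s at 120 Hz, planted causal chain 1->2->3->4
rec, truth = sc.generate(sc.chain_spec(gain=0.6, lag=2, seed=7))
rec = sc.surface_laplacian(rec)

features = []
for area in (1, 2, 3, 4):
    x = rec.area_data(area)
    model = sc.stack_train(x, n=8, m=3, cfg=sc.TrainConfig(seed=area, epochs=80))
    features.append(model.extract_feature(x))

gc = sc.ConditionalGC(features, labels=["frontal", "motor", "parietal", "visual"])
result = gc.fit(n_perm=199, alpha=0.01, seed=7)
print(result.summary())
```

Output (abridged):

```
Conditional Granger causality (order p=2, alpha=0.01)
F[target, source]:
[[    nan -0.2563 -0.0013 -0.0006]
 [ 0.2562     nan -0.1865  0.0001]
 [ 0.0004  0.1866     nan -0.1171]
 [ 0.0008 -0.0001  0.118      nan]]
significant edges:
  frontal -> motor: F=0.2562, p=0.0050
  motor -> parietal: F=0.1866, p=0.0050
  parietal -> visual: F=0.1180, p=0.0050
```

Exactly the three planted edges are significant and no reverse edge
appears: the F shown is the net time-reversed statistic (forward minus
time-reversed GC), positive for genuine directed flow, near zero for
noise-induced artifacts, and each p = 0.005 means the observed statistic
beat all 199 circular-shift permutations.

The same flow runs from a YAML config:

```sh
sdaeconn run --config examples/demo.yaml --seed 7 --out results/
sdaeconn simulate --seed 7 --out data/           # synthetic recording
sdaeconn select --input data/synthetic.npz --out grid.csv   # c_f width search
```

Each run writes the RPFA table, the selection grid, the edge list and a
`connectivity.json` stamped with the config hash and seed; reruns with the
same config and seed are bit-identical.

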