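# glomnet

A spiking-network model of the **glomerular layer of the olfactory bulb**,
built to study how the first synaptic stage of olfaction can split one
input stream into two output codes: **odor identity** on the mitral cells
(MC) and **odor concentration** on the external tufted cells (ET).

The package is for computational neuroscientists who want a compact,
fully reproducible microcircuit model of glomerular-layer processing —
contrast enhancement and input normalization by lateral inhibition — with
the stimulus generators and analysis metrics needed to quantify both
codes.

## The model

Each of 16 glomeruli contains four Izhikevich point neurons — mitral
(MC), external tufted (ET), periglomerular (PG) and short-axon (SA) —
governed by

```
C dv/dt = k (v − v_r)(v − v_t) − u + I(t)
  du/dt = a [ b (v − v_r) − u ]        with reset  v ≥ v_peak → v ← c, u ← u + d
```

integrated by classical RK4 at dt = 0.1 ms. MC and ET share identical
membrane parameters, so any difference between their output codes is a
*network* effect. Wiring per glomerulus: receptor input → {MC, ET, PG};
MC⇄PG negative feedback (PG→MC is the only inhibitory synapse); ET→PG;
ET→SA. Every SA cell projects excitatory synapses to the PG and ET cells
of all *other* glomeruli with a single lateral weight `sa_weight` — the
model's key parameter. The ET/SA subnetwork receives nothing from MC or
PG. Synapses are current-based single-exponential (tau = 10 ms).

Odors are combinatorial codes: a sensitivity row S ~ U(0, 40) pA per
glomerulus; the stimulus at concentration c is `min(S·c, 40)` pA injected
as constant current for 0.5 s. The standard experiments are 6 odors ×
6 concentrations {0.4 … 1.4} (36 exposures) and a 21-step binary morph
between two odors.

Identity coding is scored with Fisher's discriminant ratio
`FDR = tr(S_B)/tr(S_W)` of the population-mean firing rate with odor
labels as classes; concentration coding with the per-odor Pearson
correlation between responses and concentration (mean ± sd across
odors); structure with mean-centred PCA and divisive bisecting-k-means
dendrograms.

## Worked example

```bash
$ glomnet exp1 --seed 1 --out-dir results
   MC: FDR=0.566  PCC=0.103+/-0.033  PC1=30.6%
   ET: FDR=0.035  PCC=0.927+/-0.013  PC1=95.7%
input: FDR=0.108  PCC=0.534+/-0.051  PC1=38.6%
```

Reading this output: at the calibrated lateral weight (19), the mitral
rates separate the six odors about five times better than the raw input
does (FDR 0.57 vs 0.11) while carrying almost no concentration signal
(PCC 0.12); the tufted rates do the opposite — nearly perfectly
concentration-ordered (PCC 0.93, with 96 % of their variance on a single
principal axis) and nearly odor-blind (FDR 0.04). The input mixes both
codes. Values vary with the random odor panel (`--seed`).

Other entry points:

```bash
glomnet sweep --out-dir results            # objectives vs lateral weight, 10 panels
glomnet morph --seed 1 --out-dir results   # C->E mixture series + dendrograms
glomnet config-dump > my.yaml              # full default configuration
glomnet fig --out-dir results              # PCA / sweep figures from saved runs
```

All outputs are plain text (TSV rate matrices, JSON metrics and
manifests, Newick dendrograms), and every run is bit-reproducible from
its saved manifest.

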