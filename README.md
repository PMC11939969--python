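# speechnet

Regularized partial-correlation network analysis of voice acoustics and
state anxiety.

Transient (state) anxiety changes how people speak, but single acoustic
measures correlate with it inconsistently. `speechnet` implements the
network view of the problem for researchers in voice biomarkers and
psychological assessment: instead of testing five acoustic parameters one
at a time, it estimates the *conditional* dependence structure linking
local jitter, mean fundamental frequency (F0), the F1/F2 formant ratio,
RMS intensity, speech rate, and a 4-point (0–3) anxiety self-rating, and
asks how that structure differs between low-anxiety (ratings 0–1) and
high-anxiety (ratings 2–3) speakers.

## The model

Node variables are assumed monotonically related to a latent Gaussian
vector. Edges are partial correlations obtained from a sparse inverse of
the Spearman correlation matrix **S**, estimated by the graphical lasso

&nbsp;&nbsp;&nbsp;&nbsp;max<sub>K≻0</sub> log det **K** − tr(**S K**) − λ Σ<sub>i≠j</sub>|K<sub>ij</sub>|

with the penalty λ selected by the Extended Bayesian Information Criterion
EBIC<sub>γ</sub> = −2ℓ(**K**) + E·log n + 4γE·log p at γ = 0.5 (sparse,
replication-oriented selection). Edge weights are
w<sub>ij</sub> = −K<sub>ij</sub>/√(K<sub>ii</sub>K<sub>jj</sub>); node
centrality is expected influence EI<sub>i</sub> = Σ<sub>j</sub>w<sub>ij</sub>.
Edge accuracy and EI stability come from nonparametric and case-dropping
bootstraps (95% CIs, difference tests, the CS coefficient), and group
networks are compared with a label-permutation test on global expected
influence, individual edges, and node EI.

The package also contains the two ends of the pipeline: a feature
extractor (Praat-convention local jitter from epoch-refined periods,
autocorrelation F0, 12th-order LPC formants with harmonic-envelope
refinement, frame-RMS intensity, annotation-based speech rate) and a
synthetic-data module that generates source–filter vowels and two-group
feature tables from planted sparse Gaussian graphical models, so the whole
chain is testable without any recordings.

## Worked example

```python
import speechnet as sn

table = sn.generate_study_table(seed=0)      # 119 low / 197 high speakers
low, high = sn.split_groups(table)

fit = sn.SpeechNetwork(high, columns=["jitter", "f0", "f1f2",
                                      "intensity", "speech_rate"]).fit()
print(fit.summary())
```

```
Partial-correlation network (graphical lasso + EBIC)
========================================================
nodes: 5   n = 197   edges: 4
gamma = 0.5   selected lambda = 0.1086

Edges (partial correlation):
        jitter -- f0           -0.350
          f1f2 -- intensity    +0.237
     intensity -- speech_rate  +0.098
            f0 -- f1f2         +0.044

Expected influence:
        jitter -0.350
            f0 -0.306
          f1f2 +0.281
     intensity +0.335
   speech_rate +0.098
```

This high-anxiety fit recovers the planted structure: a strong negative
jitter–F0 edge, the intensity–F1/F2 coupling that characterizes anxious
speech, and positive intensity–speech-rate coupling, with shrinkage
pulling the weights toward zero as expected from a lasso at n = 197.
Comparing the groups:

```python
result = sn.NetworkComparisonTest(low, high).fit(n_permutations=1000, seed=1)
print(result.summary())        # global S, max edge difference, per-edge p
```

The same analysis runs from the shell:

```bash
speechnet synth --seed 0 --out features.csv
speechnet table1 features.csv
speechnet network features.csv --group high
speechnet run --seed 0 --out run1        # full pipeline, all artifacts
```

`speechnet extract recording.wav --transcript recording.txt` extracts the
five features from a WAV file (16/24/32-bit PCM; speech rate needs a
transcript or syllable annotation).

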