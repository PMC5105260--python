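# cdplib — Consensus Diversity Plots for compound libraries

`cdplib` quantifies the structural diversity of compound collections —
screening decks, natural-product sets, drug libraries — under three
independent molecular representations and condenses the result into a
single two-dimensional *Consensus Diversity Plot* (CDP):

* **Scaffold diversity.** Each molecule is reduced to its *chemotype*: the
  core cyclic system (all rings plus inter-ring linkers, substituents
  pruned), with every ring-free molecule collapsing into one shared
  `ACYCLIC` chemotype. From the chemotype population counts `c_i` the
  package computes count ratios (N/M, N_sing/N, N_sing/M), the
  cyclic-system recovery (CSR) curve with its area under the curve
  (AUC ∈ [0.5, 1]; 0.5 = every molecule its own chemotype, the diagonal),
  the fraction of chemotypes covering half the library (F50), and the
  Shannon entropy of the distribution,

      SE = −Σᵢ pᵢ log₂ pᵢ,   pᵢ = cᵢ / P,   SSE = SE / log₂ n ∈ [0, 1],

  where SSE is evaluated over the n most populated chemotypes.
* **Fingerprint diversity.** The full distribution of pairwise Tanimoto
  similarities over all M(M−1)/2 compound pairs, on MACCS keys (166 bits)
  or ECFP4 (Morgan radius 2, 2048 bits); the median similarity is the CDP
  x-axis (lower = more diverse).
* **Property diversity.** Six descriptors of pharmaceutical relevance
  (HBD, HBA, logP, MW, TPSA, rotatable bonds) and the mean pairwise
  Euclidean distance between property vectors,

      I_uv = (1 / UV) Σᵢ Σⱼ ‖xᵢ − yⱼ‖,

  within one set (u = v, the intra-set distance, shown as point color) or
  between two sets (a full inter-set distance matrix).

The CDP places each library at (median fingerprint similarity, scaffold
metric), sizes the point by library size, colors it by property diversity,
and splits the plane into four quadrants by thresholds (conventionally
AUC = 0.75 and the median of the similarity distribution): red = diverse by
both fingerprints and scaffolds, white = diverse by neither, blue =
fingerprint-only, yellow = scaffold-only.

A synthetic-library generator ships with the package: it decorates a pool
of 124 curated ring systems with acyclic side chains, so every generated
molecule's chemotype is known exactly and every metric can be verified
against ground truth without any external data.

## Worked example

Generate two 200-molecule libraries — one spread over 40 scaffolds, one
concentrated on 5 scaffolds plus 30% acyclic molecules — then compute every
metric and render the CDP:

```sh
cdplib simulate --n-scaffolds 40 --n-molecules 200 --distribution zipf:0.3 \
    --seed 42 --out diverse.smi
cdplib simulate --n-scaffolds 5 --n-molecules 200 --distribution zipf:2.0 \
    --acyclic-fraction 0.3 --seed 42 --out concentrated.smi
cdplib compute --input diverse.smi --input concentrated.smi --out-dir results
cdplib plot --in results --y-metric auc --y-threshold 0.75 \
    --x-threshold median --out cdp.svg
```

`results/scaffold_summary.tsv` (first columns):

```
set_name      N    M    N_sing  N_over_M  Nsing_over_N  Nsing_over_M  AUC    F50
diverse       40   200  0       0.200     0.000         0.000         0.560  0.425
concentrated  6    200  0       0.030     0.000         0.000         0.755  0.333
```

The diverse library keeps a CSR curve near the diagonal (AUC 0.560, F50
0.425: 42.5% of chemotypes are needed to cover half the compounds), while
the concentrated one — 6 chemotypes, including the shared acyclic class —
bulges away from it (AUC 0.755). `cdp_records.tsv` shows the consensus
classification with the resolved thresholds (x = 0.2643, the median of the
two libraries' median MACCS/Tanimoto similarities):

```
set_name      x_fp    y_metric  y_value  quadrant
diverse       0.2453  auc       0.560    both_high
concentrated  0.2833  auc       0.755    both_low
```

`diverse` lands in the red quadrant (high fingerprint *and* scaffold
diversity), `concentrated` in the white one. The intra-set property
distances (3.02 vs 3.17 z-score units) color the points on the
green-to-red ramp of `cdp.svg`.

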