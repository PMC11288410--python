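# lithnet

Similarity-network analysis of artefact assemblages through time.

`lithnet` is for archaeologists and cultural-evolution researchers who
want to trace how cultural connectivity between communities changed
across a sequence of calendar time slices, using nothing more than
presence/absence of artefact types in dated contexts.  It was built
around the geometric-microlith record of Mediterranean Iberia across
the Mesolithic–Neolithic transition (c. 8600–6800 cal BP), but every
stage is generic: any table of artefacts with categorical traits plus a
table of radiocarbon dates will do.

## What it computes

1. **Paradigmatic typology.** Each artefact is classified by the
   unordered cross-product of five trait dimensions — shape (Tra/Tri/
   Seg), symmetry (S/As), edge form (R/Cc/Cv/RCc/RCv/CcCv), retouch
   mode (A/S/AS) and retouch direction (D/Al/B/Db/I) — a paradigm of
   3·2·6·3·5 = 540 possible types.  Types observed only once carry no
   information about contact and are filtered out.
2. **Calibrated time bins.** Radiocarbon dates (σ ≤ 100 yr, no
   aggregate samples) are calibrated on a 1-year grid,
   p(t) ∝ N(y | μ(t), σ² + σ_curve(t)²), and a context joins every
   200-year bin that captures ≥ 35% of the two-sigma (95.4% HPD)
   posterior mass of any of its dates.
3. **Normalised Jaccard networks.** Per bin, contexts × types counts are
   binarised and pairwise similarity is J(a,b) = |T_a ∩ T_b| / |T_a ∪ T_b|;
   matrices are rescaled by n_types(bin)/max_b n_types(b) so bins with
   few types in circulation do not look spuriously similar.  Every
   positive similarity becomes a weighted edge of an undirected graph.
4. **Structure and turnover.** Density, global clustering (triangle
   method), average path length, betweenness and eigenvector
   centrality; Leiden community detection under the Constant Potts
   Model (resolution 0.02, 1000 iterations, 100 restarts); and the node
   turnover ratio between consecutive bins,
   NTR_t = (|N_t \ N_{t−1}| − |N_{t−1} \ N_t|) / |N_t|.
5. **Small-world test.** Each network is compared against 1000 matched
   G(n, m) Erdős–Rényi graphs (same nodes, exactly the same density);
   the Watts–Strogatz coefficient σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩) > 1
   flags candidate small-world structure.
6. **Bootstrap stability.** Per-context type counts are redrawn from
   multinomials with observed proportions and sample sizes, and the
   networks rebuilt, to quantify how fragile degree ranks and structural
   metrics are to sampling error.
7. **Synthetic data.** A generator plants regional communities with
   known type profiles, occupation dates and ground truth, so the whole
   pipeline can be exercised and validated with no download.

## Worked example

Generate a synthetic study (14 sites in 3 planted regions, moderately
distinct repertoires) and run the full pipeline:

```python
from lithnet.synthetic import SynthConfig, generate
from lithnet.pipeline import RunConfig, run_pipeline

bundle = generate(SynthConfig(n_sites=14, n_regions=3, concentration=0.85,
                              levels_per_site=(1, 3), count_range=(40, 150), seed=5))
paths = bundle.write("demo_inputs")
res = run_pipeline(RunConfig(assemblages=str(paths["assemblages"]),
                             dates=str(paths["dates"]),
                             curve=str(paths["curve"]),
                             outdir="demo_out", seed=1))
print(res.metrics.to_string())
print(res.ntr.round(3).to_string(index=False))
```

prints (abridged):

```
                       8600-8401 8200-8001 8000-7801 7800-7601 7600-7401 7400-7201 7200-7001 7000-6801
n_nodes                        2         2         5         6         6         2         2         2
n_edges                        1         1        10        15        15         1         1         1
density                      1.0       1.0       1.0       1.0       1.0       1.0       1.0       1.0
clustering_coefficient       0.0       0.0       1.0       1.0       1.0       0.0       0.0       0.0
leiden_n_clusters              1         1         1         1         1         1         1         1

 from_bin       bin  created  destroyed    ntr
8600-8401 8200-8001        2          2  0.000
8200-8001 8000-7801        4          1  0.600
8000-7801 7800-7601        5          4  0.167
7600-7401 7400-7201        2          6 -2.000
```

Reading it: every bin network is complete (density 1) because even
across regions the 15% shared background repertoire produces some type
overlap — presence/absence similarity networks are dense by nature, and
the interesting signal is in the edge *weights*, communities and
turnover.  NTR = 0.600 into bin 8000–7801 says the network grew (4 new
contexts against 1 lost, relative to 5 present); −2.000 into 7400–7201
records a collapse to 2 contexts.  With fully disjoint regional
repertoires the planted structure is recovered perfectly:

```python
from lithnet.synthetic import SynthConfig, recovery_experiment
rep = recovery_experiment(SynthConfig(n_sites=9, n_regions=3, concentration=1.0,
                                      count_range=(80, 200), seed=2))
# ari_by_bin: {'7800-7601': 1.0, '7000-6801': 1.0}
# mean_ari: 1.0
```

(adjusted Rand index 1.0 between Leiden communities and planted regions
in every bin that mixes regions).

The same stages are available from the shell:

```bash
lithnet simulate --outdir syn --seed 4
lithnet run-all --assemblages syn/assemblages.csv --dates syn/dates.csv \
        --curve syn/curve.14c --outdir out --seed 4
lithnet bin syn/dates.csv syn/curve.14c --threshold 0.5   # stricter binning
```

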