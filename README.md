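# replitime

Replication-timing analysis of BrdU-IP-seq time courses in synchronised
yeast populations, with a forward simulator of replicating cells so the whole
pipeline is testable without sequencing data.

## The problem

In a population of cells released synchronously into S phase and labelled
with BrdU, immunoprecipitation of BrdU-containing DNA followed by sequencing
(BrdU-IP-seq) measures, for every genomic locus, the fraction of cells in
which that locus has replicated.  Comparing how this *local replication
extent* advances against the *global* replication extent of the genome
reveals where replication initiates (origins), how fast forks move, and —
when two strains are compared — which regions fall behind in a mutant.  A
companion S1-nuclease gel assay quantifies single-stranded gaps in nascent
DNA from the size distribution of the fragments they produce.

`replitime` implements the full computational chain for both assays, aimed at
genomicists analysing Repli-seq/BrdU-IP-seq time courses at fixed-bin
resolution and at anyone who wants a tested, reproducible reference
implementation with simulated ground truth.

## The model

Read centers are counted in 300-bp bins.  For a BrdU-IP sample at time *t*
and the pre-release input sample, counts are depth-normalised and combined
into an A/T-corrected enrichment:

    N_B(t,x) = C_B(t,x) / Σ C_B(t,x)        N_I(x) = C_I(x) / Σ C_I(x)
    E(t,x)   = N_B(t,x) / N_I(x)
    E'(t,x)  = E(t,x) / AT(x)               (BrdU capture is A/T-biased)

smoothed with a uniform ±8-bin moving average.  A dot-blot of total BrdU
gives the global replication extent G(t) = s(t)/s(t_ref), with t_ref the
time point at which replication is complete.  Local extents are standardised
to the final time point,

    L(t,x) = E'(t,x)·G(t)        L'(t,x) = L(t,x) / L(t_last, x)

and, per bin, the mid-S time points are fitted with a cumulative normal in
the global extent:

    F(G,x) = Φ((G − μ_x) / σ_x)

so μ_x is the global extent at which locus x is half-replicated (small μ =
early locus) and σ_x the spread of its replication across the population.
Origins are detected as peaks in hydroxyurea-arrested profiles; origins with
≥15 kb of enrichment shoulder on both sides become "replication tracks" for
peak-normalised ensemble overlays.  The S1-gel module calibrates gel pixels
to fragment size (log-linear against a marker ladder) and converts lane
intensity to a *number* fraction of fragments per pixel (intensity divided by
fragment length, since label deposits per unit length).

The simulator inverts the logic: origins fire at Normal(τ_i, s_i) times per
cell, forks move at constant speed v, a locus replicates at the earliest
fork arrival, giving the closed form

    R(t,x) = 1 − Π_i [ 1 − e_i · Φ((t − d_i/v − τ_i) / s_i) ]

from which Poisson read counts, dot-blot signals, HU samples and gel lanes
are emitted with ground truth retained.

## Worked example

```python
import numpy as np
from replitime import simulate as sim
from replitime.binning import compute_at_ratio
from replitime.enrichment import enrichment_chain
from replitime.timing import (ReplicationTimingModel, local_extent,
                              global_curve_from_dotblot)

# study conditions: 5-Mb three-chromosome genome, ~75 origins, BrdU pulse
# sampled at 60-160 min after G2 release
cfg = sim.demo_config(seed=1)
genome = cfg.genome()
at = compute_at_ratio(sim.synthetic_genome_sequences(cfg), genome)
truth = sim.compute_truth(cfg)
ip_tracks, input_track = sim.emit_count_tracks(cfg, truth, at)
_, dotblot = sim.emit_global_curve(truth, cfg)

curve = global_curve_from_dotblot(dotblot)
eprime = {t: enrichment_chain(tr, input_track, at) for t, tr in ip_tracks.items()}
series = local_extent(eprime, curve, t_last=160.0)
results = ReplicationTimingModel(series, curve,
                                 fit_timepoints=[70, 75, 80, 85, 90]).fit()
print(results.summary())

rho = np.corrcoef(results.mu[results.status == 0],
                  truth.half_rep_g[results.status == 0])[0, 1]
print(f"\ncorrelation of fitted mu with true half-replication G: {rho:.3f}")
```

prints

```
Replication timing model (per-bin cumulative normal in G)
============================================================
bins: 16666   converged: 14387   fallback: 2279   masked: 0
fit timepoints (min): [70.0, 75.0, 80.0, 85.0, 90.0]
G at fit timepoints:  [0.12, 0.2099, 0.3242, 0.4535, 0.5857]
mu  (half-replication G): median 0.4531  IQR [0.2872, 0.6199]
sigma (spread on G axis): median 0.1730  IQR [0.1592, 0.1894]
median per-bin SSE: 0.00107

correlation of fitted mu with true half-replication G: 0.987
```

Every bin's fitted μ (the global extent at which it is half-replicated)
tracks the simulator's ground truth almost perfectly at a sequencing depth
of ~100 reads per replicated bin; `evaluate_extent([0.25, 0.5, 0.75])` then
gives the local extents F(0.25,x), F(0.5,x), F(0.75,x) used for early/late
meta-analysis, and `results.compare(other, classes)` contrasts two
conditions with a rank test per region class.

## Command line

The same stages are exposed as a CLI:

```sh
replitime run --seed 1 --out runs/demo          # full two-condition demo
replitime count reads.bam --chrom-sizes sizes.txt --out counts.tsv
replitime enrich --brdu counts.tsv --input input.tsv --at at.tsv --out ep.tsv
replitime fit --eprime ep70.tsv --eprime ep75.tsv ... --dotblot blot.csv --out model.tsv
replitime origins / tracks / overlay / compare / deviants / gaps / dotblot
```

`replitime run` executes simulate → count → enrich → fit → origins →
compare → gaps from one YAML config and writes a manifest of SHA-256 hashes;
reruns with the same config and seed are byte-identical.

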