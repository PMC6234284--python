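# saltscan

Detecting recent marine–freshwater habitat transitions from 16S rRNA
V4 amplicon-like data.

Crossing the salinity divide is one of the hardest moves a microbial lineage
can make, and surveys often conclude it happens rarely. `saltscan`
implements, as a tested and reusable pipeline, the sequence-level analyses
that probe that conclusion: if a lineage crossed recently, a marine and a
freshwater sample should still share near-identical 16S sequences; if the
split is ancient, sharing should only appear at coarse identity cutoffs.
The package bundles:

- **Multi-threshold clustering** — mothur-style one-gap pairwise distances
  and farthest-neighbor (complete-linkage) clustering at every distance
  cutoff on a 0.001 grid, from unique sequences down to a single cluster.
- **The shared-identity scan** — for each phylum (or proteobacterial class)
  and each marine–freshwater sample pair, the maximum identity threshold
  `1 − t` at which the pair still shares a cluster (equivalently the finest
  clustering with Jaccard distance < 1). High values flag recent
  transitions; a proxy for time since the most recent crossing.
- **UniFrac machinery** — unweighted and normalized weighted UniFrac over a
  rooted tree, rarefaction to even depth, pooled-habitat per-group
  distances, independent-swap null ensembles (margin-preserving
  checkerboard randomizations) with one-sample z-tests and Bonferroni
  correction, and label-permutation PerMANOVA
  (pseudo-F = (SS_B/(k−1))/(SS_W/(N−k))).
- **Sharing statistics** — shared-taxon identification (count > 0 in ≥ 1
  sample of each habitat, unrarefied), group-inclusion filters, shared-taxon
  accumulation curves versus sites sampled, and log10 median
  relative-abundance fold enrichment.
- **A detection-limit model** — binomial read-count probabilities
  P(k reads) = C(N,k) p^k (1−p)^(N−k) with p = population density /
  community density, census-size arithmetic, and the branching-process
  drift barrier (establishment probability ≈ 2s, hence 1/(2s) expected
  appearances).
- **A synthetic community generator** — pure-birth trees, habitat
  assignments with clade-level transitions at controlled sequence
  divergences, Jukes-Cantor-like sequence evolution, and log-normal count
  tables with near-detection-limit taxa — so every stage is testable
  without external data.

## Worked example

```python
from saltscan import (SyntheticSpec, simulate_community, pairwise_distance,
                      farthest_neighbor_cluster, group_scan)
from saltscan.unifrac import lineage_groups

spec = SyntheticSpec(n_taxa=40, n_transitions=1, transition_divergences=(0.04,),
                     immigrant_weight=0.0, rare_fraction=0.0, seed=0)
com = simulate_community(spec)
event = com.truth.events[0]
phylum = com.lineage[event["focal_flipped"]].split(";")[0]
sub = com.seqs.subset(lineage_groups(com.lineage, 1)[phylum])
clustering = farthest_neighbor_cluster(pairwise_distance(sub), grid_step=0.001)
(result,) = group_scan({phylum: clustering}, com.counts, com.metadata)
print(result.summary["median"], event["realized_divergence"])
```

prints

```
0.958 0.041379310344827586
```

One transition was planted at 4% divergence; the generator realized the
nearest cross-habitat pair at 12/290 = 4.14% mismatches, and the scan's
median maximum shared identity over all 64 marine–freshwater sample pairs
is 95.8% — the planted divergence read back from the count table, one grid
step below 1 − 0.0414.

The numbered scripts under `analysis/` run the full set of analyses and
write their tables to `results/`:

```bash
python analysis/01_simulate_community.py   # reference community + truth
python analysis/02_threshold_scan.py       # divergence recovery, d = 1%..23%
python analysis/03_habitat_unifrac.py      # PerMANOVA + swap-null z-tests
python analysis/04_shared_taxa.py          # sharing, accumulation, enrichment
python analysis/05_detection_limits.py     # rare-population arithmetic
```

A config-driven CLI wraps the same stages:

```bash
stscan all --config analysis/config_smoke.json
stscan detect --pop-density 1 --community-density 500000 --library 150000 --k 0
```

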