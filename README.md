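# cyclenet

Circadian transcriptome time courses pose two linked questions: *which
genes cycle*, and *is their timing organized by the gene-interaction
network*?  `cyclenet` is a tested Python implementation of a complete
answer pipeline for two-experiment, two-condition bulk RNA-seq designs
(e.g. two independently sequenced experiments V1/V2 at 18°C and 25°C,
sampled every 2 h over two days), together with a synthetic-data generator
with known ground truth so every stage can be validated without external
data.

## The model and statistics

**Cycling detection.**  Each gene's TPM series is fit by harmonic
regression at a fixed 24 h period,

    y(t) = m + a·cos(2π (t − φ) / 24),

estimated by OLS on `[1, cos(2πt/24), sin(2πt/24)]`; rhythmicity is the
F-test of the two harmonic coefficients (df 2, n−3), the amplitude is
`a = √(β_cos² + β_sin²)` and the peak phase `φ = (24/2π)·atan2(β_sin,
β_cos) mod 24` in ZT hours.  A gene is **cycling** when the evidence
replicates: p < 0.1 in *both* experiments and the circular distance
between the two phase estimates Δφ = min(|φ₁−φ₂| mod 24, 24−|φ₁−φ₂| mod
24) is below 3 h.  Under a flat null this criterion admits
`N · 0.1² · (3/12)` chance calls — for N = 6774 filtered genes,
16.935 ≈ 17.

**Phase statistics.**  Consensus phases (circular means), two-sample KS
comparisons of phase distributions, von Mises kernel-density peaks,
per-gene signed phase shifts between conditions, the Jammalamadaka–
SenGupta circular correlation, and paired Wilcoxon signed-rank tests of
variance and amplitude.

**Network phase organization.**  On the largest connected component of an
interaction network, the median Δφ of cycling-gene pairs is profiled
against their geodesic (BFS hop) distance, a linear trend is fit across
distance classes, and significance per class comes from a permutation
null that re-places the cycling genes uniformly on the network (keeping
the observed phase multiset) with the add-one empirical p-value
`(1 + #{null ≤ observed}) / (1 + n_perm)`.

## Worked example

Plant phase organization on a random network, simulate a noisy
two-experiment study, detect cyclers, and test for organization:

```python
import cyclenet as cn
from cyclenet import network

net = cn.generate_network(200, 8.0, "erdos_renyi", seed=21)
truth = cn.plant_phases(net, frac_cycling=0.25, coupling=0.9, n_smooth=20, seed=22)
design = cn.SimDesign(noise_cv=0.05, inter_experiment_phase_jitter_sd=0.2, seed=23)
fits = {e: cn.fit_harmonic_table(cn.simulate_experiment(truth, design, e))
        for e in ("V1", "V2")}
calls = cn.call_cycling(fits["V1"], fits["V2"])
print(f"called cycling: {int(calls['is_cycling'].sum())} of {len(calls)}")
print(f"expected by chance: {cn.expected_chance_cyclers(len(calls)):.2f}")

lcc = network.largest_connected_component(net)
cyc = [g for g in calls.index[calls["is_cycling"]] if g in lcc]
res = cn.permutation_null(lcc, cyc, calls.loc[cyc, "consensus_phase"],
                          n_perm=1000, seed=24, min_pairs=10)
print(res.profile.to_string(index=False))
print("empirical p:", res.empirical_p)
```

prints

```
called cycling: 50 of 200
expected by chance: 0.50
 distance  n_pairs  median_dphi
        1       39     2.461961
        2      309     5.024163
        3      747     6.281918
        4      130     6.634467
empirical p: {1: 0.000999000999000999, 2: 0.005994005994005994, 3: 0.996003996003996, 4: 0.926073926073926}
```

All 50 planted cyclers are recovered (0.5 expected by chance), and
immediate network neighbours peak ~2.5 h apart versus ~6 h for distant
pairs — uniform-phase pairs sit at a median of 6 h — so the neighbour
class is far below its permutation null (p ≈ 0.001, the add-one floor at
1000 permutations is 1/1001).

The same pipeline runs from the shell over TSV inputs:

```bash
cyclenet simulate --outdir study/ --coupling 0.9 --frac-cycling 0.25 --seed 1
cyclenet run --config config.yaml          # filter → fit → call → phases → network
```

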