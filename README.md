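# tdabreak

Dynamic topological data analysis for multivariate time series: track the
*shape* of a signal through time and test whether that shape changes.

Non-stationary multichannel recordings — EEG during an epileptic seizure is
the motivating case — can change in ways that amplitude or spectral summaries
miss: channels may start tracing loops or shells in state space rather than
merely getting louder. `tdabreak` detects such changes by combining
persistent homology with a fractal-dimension-based structural-break test.

## Method

Given a P-dimensional series X(t) observed at T samples, the pipeline is:

1. **Windowed point clouds.** Slice the series into non-overlapping windows
   of width w; the w samples of a window form a point cloud in R^P.
2. **Time-varying total persistence.** For each cloud, compute the
   Vietoris-Rips filtration and its persistence barcode B_k for homology
   dimensions k = 0, 1, 2, and summarize it by the total persistence

       TP_k(t) = Σ_{[ε_b, ε_d] ∈ B_k} (ε_d − ε_b),

   time-stamped at the window end. TP_0 measures connectivity scale (it
   equals the total length of the cloud's minimum spanning tree), TP_1 the
   prominence of loops, TP_2 of cavities.
3. **CUSUM break test with a fractal statistic.** Under the null of no
   structural break, the deviations D_k(t) = TP_k(t) − mean(TP_k) are
   exchangeable, so their CUSUM S_k(0) = 0, S_k(t) = S_k(t−1) + D_k(t)
   behaves like a random walk, whose Higuchi fractal dimension (HFD) is
   ≈ 1.5. A sustained mean shift makes the CUSUM drift smoothly and pulls
   its HFD toward 1. The test permutes the deviations B times, re-computes
   the CUSUM HFD each time, and reports the add-one lower-tail p-value
   p = (1 + #{HFD*_b ≤ HFD_obs}) / (B + 1).

The Higuchi estimator itself fits the scaling law L(k) ∝ k^(−HFD) of the
normalized curve length L(k) over lags k = 1..kmax; it is anchored by
HFD = 1 for smooth curves, 1.5 for Brownian motion, 2 for white noise, and
HFD = 2 − H for fractional Brownian motion with Hurst index H.

The Rips persistence engine is implemented in-package (numba-accelerated
persistent cohomology with clearing, H0 by union-find) and is validated
against a textbook boundary-matrix reduction in the test suite.

## Worked example

Five 30-second epochs at 100 Hz: Gaussian noise, a circle of radius 4,
noise again, a sphere of radius 2.5, then noise (the bundled `example1`
scenario, 15,000 × 3 samples, window width 50):

```python
import numpy as np
from tdabreak import build_scenario, run_full_test

signal, preset = build_scenario("example1", rng=np.random.default_rng(0))
results, curves = run_full_test(signal, preset.window_config,
                                n_permutations=999,
                                rng=np.random.default_rng(0))
for k, r in results.items():
    print(k, round(r.observed_hfd, 3), round(r.p_value, 3))
```

prints

```
0 1.067 0.001
1 1.027 0.001
2 1.028 0.001
```

Mean TP_1 rises from ≈ 1.8 in the Gaussian epochs to ≈ 4.6 in the circle
epoch and TP_2 from ≈ 0.07 to ≈ 1.08 in the sphere epoch; all three
observed CUSUM fractal dimensions fall near 1, far below the permutation
reference around 1.5, so every p-value sits at the permutation floor
1/(B+1): the epochs change the clouds' connectivity scale as well as their
loop and cavity content. The `examples/` scripts walk through each stage
and print these numbers.

The same pipeline runs from the shell on delimited-text signals:

```sh
tdabreak simulate --scenario example1 --seed 0 --out sig.csv
tdabreak tp   --input sig.csv --window 50 --out tp.csv
tdabreak test --input sig.csv --window 50 --permutations 999 \
              --seed 0 --report report.json
```

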