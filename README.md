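# brackish

Community-assembly and co-occurrence network-stability analysis for
microbial (especially microeukaryotic plankton) OTU time series sampled
along a salinity gradient.

Freshwater salinization is a growing disturbance in urban reservoirs and
other inland waters. Even small shifts in salinity (0–6 ‰) can tip the
balance of community assembly from stochastic dispersal toward
deterministic environmental filtering, and can restructure the
co-occurrence networks of the core (high-occupancy) and satellite
(low-occupancy) fractions of the community. `brackish` packages the
quantitative toolkit used to ask those questions of a rarefied OTU count
table with per-sample salinity metadata:

- **OTU-table handling** — TSV readers/writers (QIIME-classic wide format),
  rare-OTU filtering, seeded rarefaction without replacement, core /
  intermediate / satellite occupancy classes (≥75 % / <50 % occupancy), and
  salinity-level binning ([0, 0.2], (0.2, 2], (2, ∞) ‰).
- **Diversity & permutation statistics** — richness, ACE, Chao1, Shannon
  (nats), Gini–Simpson, Pielou; Bray–Curtis distances; ANOSIM, Mantel and
  partial Mantel tests with seeded permutations; time-lag regression with
  absolute and annual-cycle lags; a multi-nutrient cycling index.
- **Assembly diagnostics** — Sloan's neutral community model fitted by
  non-linear least squares (occurrence frequency vs mean relative
  abundance, `1 − I_d(Nm·p, Nm·(1−p))`, d = 1/N, R² by Östman's method,
  95 % Wilson envelope); Levins' niche breadth `B_j = 1/Σ_i P_ij²` and the
  community mean `Bcom`; the checkerboard C-score with a sequential-swap
  fixed-marginal null and its standardised effect size (SES).
- **Networks** — a from-scratch SparCC implementation (basis correlations
  from log-ratio variances with Dirichlet resampling and iterative
  exclusion), permutation p-values, thresholded networks (|r| > 0.6,
  p < 0.01), topology vs Erdős–Rényi G(n, M) nulls, greedy/Louvain module
  detection, Zi–Pi node roles and keystone candidates (thresholds
  2.5 / 0.62), βw edge-set dissimilarity, and robustness as natural
  connectivity under random node removal.
- **Synthetic data with known truth** — a first-class generator producing
  neutral assemblages with tunable migration `m`, salinity-driven Gaussian
  selection, implanted pairwise basis correlations, and seasonal
  salinity/precipitation metadata, so every estimator above can be tested
  against ground truth.

## Worked example

Simulate a neutral community and a salinity-selected one from the same
source pool, then ask each assembly diagnostic which is which:

```python
import numpy as np
import brackish as bk
from brackish import assembly as asm

pool = bk.make_source_pool(300, seed=1)
cfg = bk.NeutralSimConfig(S=300, N=5000, m=0.1, n_samples=120, seed=2)
neutral = bk.simulate_neutral_series(pool, cfg)

rng = np.random.default_rng(3)
sel = bk.SelectionConfig(optima=rng.uniform(0, 6.1, 300), sigma=1.0, strength=6.0)
salinity = np.r_[np.full(60, 0.1), np.full(60, 4.0)]
selected = bk.simulate_selection_series(pool, cfg, sel, salinity)

for name, t in (("neutral", neutral), ("selection", selected)):
    fit = asm.fit_ncm(t)
    nb = asm.levins_niche_breadth(t)
    ses = asm.ses_c_score(t, n_sim=3000, thin=5, seed=4)
    print(f"{name:9s}  m_hat={fit.m:.3f}  R2={fit.r_squared:6.3f}  "
          f"mean Bcom={nb.bcom.mean():5.1f}  C-score SES={ses.ses:7.2f}")
```

prints

```
neutral    m_hat=0.117  R2= 0.964  mean Bcom= 64.5  C-score SES=  -0.73
selection  m_hat=0.008  R2=-0.271  mean Bcom= 40.3  C-score SES= 199.40
```

The neutral series recovers the generating migration rate (m = 0.1) with a
strong fit (R² ≈ 0.96) and a near-zero SES; under strong salinity
selection the neutral fit collapses, community niche breadth narrows, and
the C-score SES explodes — the classic deterministic signature.

A full pipeline run (filter → rarefy → occupancy → salinity levels →
diversity → assembly per level → networks per level with βw and
robustness) is driven by a YAML config:

```sh
brackish run --config examples/demo.yaml --out-dir results/run1
```

See `brackish --help` for the stage-by-stage subcommands (`simulate`,
`filter`, `rarefy`, `classify`, `diversity`, `ncm`, `nullmodel`,
`network`, `robustness`).

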