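# gibbonwalk

Movement-strategy inference for gibbon GPS trajectories.

Arboreal primates foraging in patchy tropical forest are expected to switch
between *intensive search* (short, sinuous within-patch movement) and
*extensive search* (long, directionally persistent travel between patches).
Given 15-min GPS relocations of habituated groups, `gibbonwalk` builds
step-length/turning-angle series, fits four competing random-walk models,
selects among them, and reports the behavioral-state quantities ecologists
compare across habitats and dietary seasons. It ships a synthetic
field-campaign generator so the entire pipeline is testable without field
data.

## Models

For each step *t*, the data are the step length *L\_t* (Euclidean distance
between consecutive projected fixes) and the turning angle
*θ\_t ∈ (−π, π]* (wrapped difference of consecutive headings
*φ\_t = atan2(Δy, Δx)*). The candidates:

| model | step lengths | turning angles | phase switching |
|-------|--------------|----------------|-----------------|
| BW    | exponential φ(l) | circular uniform v₀(h) | — |
| TLW   | truncated Pareto w(l) on [a, b] | circular uniform | — |
| CCRWo | exponential per phase | uniform (I), von Mises v(h) (E) | 2-state HMM (geometric dwell) |
| CCRWp | Weibull per phase | wrapped Cauchy per phase | 2-state HSMM (shifted-Poisson dwell) |

Fitting is by maximum likelihood (scaled forward algorithms for the latent
models; the HSMM runs as a dwell-expanded HMM initialized at the stationary
phase/dwell-age equilibrium). Model comparison uses AICc
(−2ℓ + 2k + 2k(k+1)/(n−k−1)) with Akaike weights; absolute fit is checked
with a G-test on one-step-ahead uniform pseudo-residuals, separately for
step lengths (SL-p), turning angles (TA-p) and pooled (PR-p). Two-phase
fits are summarized as the stationary phase proportions (pI, pE), expected
per-phase step lengths (sI, sE) and the extensive-phase angular
concentration rE (mean resultant length).

## Worked example

Simulate a two-month field campaign (15-min fixes, 06:00–18:00, 8 observation
days per month, 10% dropout) from a two-phase regime, then run the full
analysis:

```sh
gibbonwalk simulate --preset HG --months 2 --days-per-month 8 \
    --dropout 0.1 --seed 5 --out fixes.csv
gibbonwalk report fixes.csv --out report --mode by_group --seed 2
```

which prints

```
dataset model  k       loglik         aicc  delta_aicc        weight
     HG CCRWp  8 -4962.622858  9941.460321    0.000000  9.659898e-01
     HG CCRWo  5 -4969.032142  9948.153306    6.692984  3.401022e-02
     HG    BW  1 -4999.283665 10000.573230   59.112909  1.408534e-13
     HG   TLW  1 -5373.963521 10749.932941  808.472620 2.675308e-176
dataset model       pI       pE        sI         sE       rE
     HG CCRWp 0.802399 0.197601 76.044477 172.317524 0.467502
```

The semi-Markov composite walk (CCRWp) wins decisively, and the recovered
state summary is close to the generating regime (pI = 0.78, sI = 66 m,
sE = 152 m, rE = 0.469): the group spends ~80% of steps in intensive
search with ~76 m steps, and ~20% in extensive search with ~172 m steps and
strong directional persistence. `report/` additionally contains the
segmentation log, the diagnostics table (PR-p/SL-p/TA-p), fitted parameters
as JSON, and optional step/angle histogram plots (`--plots`).

Real relocation tables are CSVs with columns `group_id, timestamp, lon, lat`
(projected to UTM in-package; zone configurable, default 49N) or
`group_id, timestamp, x, y` in planar metres. Preprocessing removes
duplicate-timestamp and speed-implausible fixes and keeps trajectory
segments with ≥ 4 consecutive fixes spanning ≥ 60 min (gaps ≤ 45 min by
default). Datasets can be partitioned per group, pooled per dietary period
(fruit-eating April–September vs mixed October–March), or both.

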