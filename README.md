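# filokin

Stochastic models of filopodial kinetics and synapse formation in
developing *Drosophila* R7 photoreceptor axon terminals.

During the second half of pupal development an R7 terminal explores its
target layer with dozens of short-lived filopodia, stabilizes only one or
two of them at a time into bulbous-tipped "synaptogenic" filopodia, and
matures those bulbs one by one into synapses — about 20–25 over 50 hours.
Autophagy tunes this process: loss of autophagy (e.g. *atg6*, *atg7*
mutants) raises the number of concurrent synaptogenic filopodia to three
or four and inflates synapse counts, while autophagy upregulation
destabilizes them.  `filokin` implements the two stochastic models that
make this quantitative, together with the full parameter-estimation
pipeline, a synthetic-data generator that stands in for the (unreleased)
live-imaging tables, and a command-line pipeline.

## The models

**Developmental model.**  A time-inhomogeneous Markov jump process over
copy numbers (sF, ℓF, sB, synB, S): short/long-lived filopodia, transient
and stabilized bulbous tips, and synapses, with reactions

```
∅ → sF        rate f_F(t)·c1_sF         sF → ∅   rate sF·c2_sF
∅ → ℓF        rate f_F(t)·c1_ℓF         ℓF → ∅   rate ℓF·c2_ℓF
F → sB        rate c3·(sF+ℓF)·f1(synB,B50)·f_FB(t)
sB → ∅        rate c4·sB                sB → synB  rate c5·sB
synB → S      rate c6·synB
```

where f_FB is a tanh ramp with half-time 1000 min, f1 = B50/(synB+B50) is
saturating auto-inhibition (competition for limited seeding factors), and
f_F is a slow polynomial drive on filopodial generation.  Simulation is
exact (thinning against per-window bounds on the time-dependent factors).

**Estimation.**  c2 from inverse mean lifetimes split at 8 min; c1 from
the Poisson-distributed per-time-instance counts (λ = c1·f_F/c2); c4 fixed
at 1/120 min⁻¹; c6 from the steepest synapse-accumulation slope divided by
the mean bulb count; (c5, B50, r3) by minimizing the Kullback–Leibler
divergence between observed bulb-count distributions and the stationary
marginals of a truncated 2-D Markov chain over (sB, synB), obtained as the
zero-eigenvalue eigenvector of the transposed generator matrix; c3 by
inverting r3 = c3·(sF+ℓF)·f_FB at P60.

**Mechanistic (winner-takes-all) model.**  Filopodia compete for a
conserved pool of synaptic seeding factors; holding i seeds lowers the
retraction hazard to 1/i, a positive feedback that lets one or a few
filopodia win the pool.  Genotypes differ only in pool size
(`round(n·B̄(P60))`, n = 120 states); autophagy upregulation is modeled by
removing the competitive advantage (constant retraction hazard).

## Worked example

```python
from filokin import (gen_track_table, gen_bulb_observations,
                     DevelopmentalModel)

# synthetic live-imaging data with known ground truth
tracks, snaps, manifest = gen_track_table(duration=2000.0, n_terminals=4, seed=7)
sB, synB, _ = gen_bulb_observations(r3=0.019, c4=1/120, c5=0.05, c6=1/132,
                                    B50=2.0, total_time=500_000.0, seed=8)

model = DevelopmentalModel.from_dataframes(
    tracks, snaps, obs_sB=sB["frequency"], obs_synB=synB["frequency"],
    fixed={"c6": 1/132}, genotype_label="control")
res = model.fit()
print(res.summary())
```

```
Developmental model fit — genotype 'control'
==========================================================
parameter                            value  provenance
----------------------------------------------------------
c1_sF (1/min)                      3.76119  estimated
c1_lF (1/min)                     0.180152  estimated
c2_sF (1/min)                     0.533495  estimated
c2_lF (1/min)                    0.0353633  estimated
c3 (1/min/filopodium)           0.00201779  estimated
c4 (1/min)                      0.00833333  fixed
c5 (1/min)                       0.0492691  estimated
c6 (1/min)                      0.00757576  fixed
B50 (count)                        2.06643  estimated
t_half (min)                          1000  fixed
----------------------------------------------------------
lambda_sF                           7.0501
lambda_lF                          5.09433
dispersion_sF                     0.945747
dispersion_lF                      1.02394
kl_total                       0.000188236
r3_P60                           0.0188327
```

The generating values were c2_sF = 0.5, c2_ℓF = 0.0333, c5 = 0.05,
B50 = 2, r3 = 0.019: every free constant is recovered within a few
percent, the dispersion diagnostics confirm Poisson snapshot counts, and
the KL residual is at the sampling-noise floor.  Simulating the fitted
model over the full course (P40 → P90, 3000 min):

```python
traj = res.simulate(t_end=3000.0, seed=1)
print(traj.final_state())
# DevState(t=3000.0, sF=7, lF=3, sB=0, synB=0, S=22)
```

— 22 synapses, inside the 20–25 band a wild-type terminal builds over
those 50 hours.

The same pipeline is available from the shell:

```
filokin synth --preset control --seed 7 --out synth_out
filokin estimate --tracks synth_out/tracks.csv --snapshots synth_out/snapshots.csv \
    --obs-sb synth_out/obs_sB.csv --obs-synb synth_out/obs_synB.csv --out est_out
filokin simulate-mech --preset atg-mutant --seed 1 --out mech_out
```

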