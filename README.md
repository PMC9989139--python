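# threatnet

Dynamic oscillatory-network analysis of threat processing for EEG-style
source time series: how does the brain's community structure reorganise,
millisecond by millisecond, when a stimulus signals threat — and in which
direction does information flow while it does?

The package targets instructed-threat designs (a conditioned stimulus CS+
paired with an aversive shock versus a safe CS−) with epoched,
source-reconstructed time series (90 regions of interest, 250 Hz, −0.25 to
1.5 s around stimulus onset), and implements the full analysis chain:

1. **Preprocessing** — zero-phase Butterworth band-pass, window/sub-window
   bookkeeping (baseline plus six 250 ms windows T1–T6, each split into
   five 50 ms layers), condition contrasts, and inter-trial phase coherence
   as a data-quality check.
2. **Connectivity** — theta (4–8 Hz) and alpha (8–12 Hz) power-envelope
   correlation matrices per window, thresholded over a 20-value
   proportional-density grid (0.1–0.6).
3. **Communities** — consensus Louvain modularity maximisation (resolution
   γ, sweepable 1–2.5), with multilayer modularity (inter-layer coupling ω)
   for dynamic assignments across time layers, nodal stability and
   allegiance matrices, and named-network (CEN/SN/DMN) labelling.
4. **Topology** — flexibility f_i = (label changes)/(T−1) across the 50 ms
   layers, clustering coefficient, global and local efficiency on the
   thresholded graphs, per density.
5. **Effective connectivity** — time-resolved partial directed coherence
   (TPDC): a dual-Kalman time-varying MVAR fit, per-time-point PDC
   π_{i←j}(f,t) = |Ā_ij|/√(Σ_k|Ā_kj|²), band/window summaries, and a
   time-reversal surrogate test with uni/bi-directionality calls.
6. **Statistics** — paired t-tests, two-way within-subject ANOVA
   (condition × time) with Mauchly/Greenhouse–Geisser handling, post hoc
   contrasts, and Bonferroni-corrected Pearson correlations against
   behaviour (threat ratings, heart rate).

Because no public dataset accompanies this design, the package ships a
first-class synthetic cohort generator (`threatnet.synthdata`): damped
AR(2) oscillators per ROI, community structure planted through hidden
per-community driver oscillators, Markov community switching at
condition-specific rates, directed lagged couplings with an optional
stimulation-like perturbation at 1000 ms, and behaviour correlated with the
planted switching — all seeded and bit-reproducible, with full ground truth
for recovery testing.

## Worked example

The numbered drivers under `analysis/` run the study on a demonstration
cohort (8 subjects, 36 ROIs in three communities, CS+ switching rate 0.4
versus CS− 0.2):

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_network_dynamics.py --seed 0
```

which prints (abridged):

```
CS+: planted switch rate 0.449 (range 0.310-0.544), realized flexibility 0.439, rating 5.43, heart rate 79.0 bpm
CS-: planted switch rate 0.249 (range 0.110-0.344), realized flexibility 0.243, rating 3.39, heart rate 70.9 bpm
condition x window repeated-measures ANOVA (theta band):
  flexibility        condition            F(1,7) =   29.51, p = 0.00097
  flexibility        window               F(6,42) =   13.32, p = 2.2e-08
  clustering         condition            F(1,7) =   49.29, p = 0.00021
  global_efficiency  condition            F(1,7) =   32.92, p = 0.00071
```

The planted difference in community switching (0.4 vs 0.2) surfaces as a
strong condition effect on network flexibility — the measured values are
attenuated relative to the planted rates (theta-band filter memory outlasts
the 50 ms layers; see `docs/methods.md`) but the inference is unambiguous.
The effective-connectivity driver recovers a planted directed coupling:

```bash
python analysis/03_effective_connectivity.py --seed 0
```

```
planted coupling: x -> y, coefficient 0.5 in the theta band
observed TPDC x->y: 0.920 (null threshold 0.889)
observed TPDC y->x: 0.426 (null threshold 0.514)
directionality call: uni(i->j)
```

The x→y summary exceeds its time-reversal null while the reverse direction
does not, so the pair is called uni-directional with the planted
orientation.  `analysis/04_behaviour_statistics.py` adds the behavioural
tests and correlations, and `analysis/05_method_validation.py` runs quick
versions of the recovery studies.

A configurable end-to-end pipeline with a manifest and idempotent stage
re-runs is available both as a library call
(`threatnet.pipeline.run_pipeline`) and a CLI:

```bash
threatnet run-all config.yaml     # simulate -> ... -> stats
```

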