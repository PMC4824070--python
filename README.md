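# termcouple

Quantification and stochastic modelling of how transcription–translation
coupling tunes the efficiency of Rho-independent (intrinsic) terminators in
bacteria.

## The problem

An intrinsic terminator is a GC-rich RNA hairpin followed by a U-tract that
ejects RNAP without protein factors — but only if the hairpin can fold. In
bacteria the pioneer ribosome translates the nascent mRNA right behind
RNAP, and a ribosome sitting too close to the hairpin sequence blocks
folding. The result: the same terminator is almost silent a few bp after a
stop codon and fully active 30+ bp away. This package implements the full
quantitative analysis of that effect for people measuring or engineering
terminator efficiency (TE) with dual-fluorescence reporter operons:

* **quantification** — plate-reader OD₆₀₀/fluorescence time series → per-cell
  synthesis rates P = μf(1 + μτ/ln2) → TE, with fluorophore-maturation
  correction and replicate statistics;
* **coupling model** — TE(d) = TE₀·[1 − CDF(α, d + c)], where d is the
  stop-codon-to-hairpin spacer length, α the ribosome occlusion threshold
  (27 nt in the reference system), the Poisson mean d + c the ribosome–
  hairpin distance at RNAP arrival, and TE₀ the maximal efficiency (0.9 for
  tR2); evaluation, exhaustive-grid least-squares fitting (also available
  as a scikit-learn estimator, `TerminationCouplingModel`), bootstrap CIs;
* **elongation simulator** — a Gillespie simulation of one RNAP + the pioneer
  ribosome with steric exclusion, the mechanistic oracle behind the Poisson
  approximation;
* **synthetic data** — generators for construct panels, growth curves with
  known ground-truth TE, and noisy TE–distance tables;
* **spacer design** — low-GC, low-structure spacer sequences for setting TE
  by distance.

## Worked example

```python
import termcouple as tc

params = tc.tr2_reference_params()          # TE0=0.9, alpha=27, c_W=15, c_R=7
for d in (5, 18, 30, 45):
    print(f"TE_W({d:2d}) = {tc.predict_te(d, 'W', params):.3f}   "
          f"TE_R({d:2d}) = {tc.predict_te(d, 'R', params):.3f}")

# fit the model to a synthetic TE-distance table (sd 0.02, 3 replicates)
noise = tc.NoiseModel(te_gaussian_sigma=0.02, replicates=3, seed=1)
table = tc.make_te_table(params, distances={"W": range(5, 49), "R": range(9, 60)},
                         noise=noise)
fit = tc.fit_coupling(table)
p = fit.params
print(f"fitted: te0={p.te0:.3f} alpha={p.alpha} "
      f"c_W={p.offsets['W']} c_R={p.offsets['R']} rss={fit.rss:.4f}")

# mechanistic check: simulate 10^4 RNAP/ribosome trajectories
te, se = tc.te_from_simulation(tc.standard_config(5, n_traj=10_000, seed=7))
print(f"simulated TE at d=5: {te:.3f} +/- {se:.3f}")
```

prints

```
TE_W( 5) = 0.047   TE_R( 5) = 0.000
TE_W(18) = 0.747   TE_R(18) = 0.270
TE_W(30) = 0.898   TE_R(30) = 0.851
TE_W(45) = 0.900   TE_R(45) = 0.900
fitted: te0=0.897 alpha=27 c_W=15 c_R=7 rss=0.0975
simulated TE at d=5: 0.004 +/- 0.001
```

Reading: a terminator 5 nt after the stop codon is almost fully repressed
(<5% TE — the ribosome parked on the stop codon occludes the hairpin), TE
rises smoothly with spacer length, and both construct series plateau at
TE₀ ≈ 0.9 once the closest possible ribosome is beyond α. The grid fit
recovers the generating parameters from noisy data, and the mechanistic
simulator reproduces strong proximal repression without assuming the
Poisson form.

## Command line

Every stage is also a `termcouple` subcommand; stochastic commands record
their seed in the output header:

```
termcouple synth te-table --sigma 0.02 --replicates 3 --seed 11 --out te.csv
termcouple fit --te-table te.csv --alpha-range 0:60 --c-range -10:40 --out fit.json
termcouple predict --params fit.json --d 0:100 --series W --out curve.csv
termcouple synth growth --panel W,R --noise 0.02 --replicates 3 --seed 11 --out-dir fixtures/
termcouple quantify --measurements fixtures/measurements.csv \
    --constructs fixtures/constructs.csv --tau-gfp 15 --tau-rfp 40 --out te_meas.csv
termcouple simulate --config sim.json --n 10000 --seed 7 --out samples.csv
termcouple design-spacer --length 30 --hairpin hairpin.fa --seed 3 --out spacer.fa
```

CSV schemas: measurements are long-format
(`construct_id,replicate,time_min,od600,f_rfp,f_gfp`); construct tables are
(`construct_id,series,distance_nt,rfp_modified,translation_coupled,is_reference`);
TE tables are (`construct_id,series,distance_nt,te,te_se,method,n_replicates`).
Metadata rides in `#`-prefixed header lines.

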