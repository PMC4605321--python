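# rloopkmc

Kinetic Monte Carlo modelling of CRISPR-Cas9 **R-loop dynamics**, with the
downstream analyses that connect R-loop stability to off-target cleavage and
single-molecule binding statistics.

When Cas9 engages a DNA site next to an NGG PAM, its guide RNA invades the
protospacer duplex base by base, displacing one DNA strand as an R-loop.
`rloopkmc` models the R-loop length *m* (number of invaded positions, counted
1..N from the PAM) as a continuous-time random walk whose rates are set by
nearest-neighbour hybridization thermodynamics:

```
v_f(m) = k0 · exp(−ΔΔG(m+1) / 2RT)        (invasion,     m → m+1)
v_r(m) = k0 · exp(+ΔΔG(m)   / 2RT)        (re-annealing, m → m−1)

ΔΔG(m) = ΔG°37(m)_RNA:DNA − ΔG°37(m)_DNA:DNA
```

The symmetric ½ split satisfies detailed balance, so the equilibrium law is
Boltzmann in the cumulative exchange energy G(m) = Σ_{j≤m} ΔΔG(j). Trajectories
are generated exactly with a Gillespie algorithm (numba-compiled kernels, one
RNG stream per replicate).

The package is aimed at people studying guide-RNA specificity: it answers
questions like *how stably does a guide stay invaded at the PAM-distal
positions that gate cleavage?*, *how much does a 5′ truncation or a single
rG·dG / rC·dC / rA·dA / rU·dT mismatch destabilize the R-loop?*, and *does
simulated R-loop stability predict measured cleavage frequencies better than
total binding energy?*

## What's inside

| module | contents |
| --- | --- |
| `thermo` | nearest-neighbour ΔG°37 tables (DNA:DNA, RNA:DNA hybrid, canonical mismatches; JSON data, swappable), per-position exchange energies, duplex binding energies |
| `invasion_kmc` | rate tables, exact Gillespie simulation, residency ensembles; absorbing (guide fall-off) or reflecting boundary at m = 0 |
| `observables` | occupancy profiles, threshold occupancies with SEM, first-passage lifetimes, fall-off probabilities with exact binomial CIs, re-trap counts |
| `specificity` | mismatch annotation, PAM-distal single-mismatch dataset filter, per-pair stability metrics, Pearson/Spearman correlation with permutation p-values (exact enumeration for tiny n) |
| `binding_model` | 1/k-weighted binding histograms, empirical Gaussian peak fits (μ, w = √2σ with CIs), occupancy-based Kd/Ka estimators |
| `synthetic_data` | ground-truth generators: random guide/target pairs with injected mismatches, cleavage datasets with a controlled stability→frequency link, binding-event tables with Gaussian-broadened footprints |
| `cli_io`, `cli` | FASTA/TSV/BED I/O, run configuration with provenance records, and the `rloopkmc` command (`simulate`, `profile`, `specificity`, `fit-binding`, `synth`) |

## Worked example

```python
import rloopkmc as rk

model = rk.load_energy_model()
pair = rk.GuideTargetPair(guide=rk.AAVS1_SGRNA, protospacer=rk.AAVS1_PROTOSPACER)

rates = rk.build_rate_table(pair, model)
ens = rk.simulate_residency(rates, m0=20, max_t=10_000.0, reps=100, seed=1)
occ = rk.threshold_occupancy(ens, 19)
print(f"fraction of time invaded to >= position 19: {occ.mean_frac:.3f} +/- {occ.sem:.3f}")

tru = rk.GuideTargetPair(guide=rk.AAVS1_TRU_GRNA, protospacer=rk.AAVS1_PROTOSPACER)
sg_life = rk.lifetime_to_below(rates, 20, 16, reps=2000, max_t=1e5, seed=2)
tru_life = rk.lifetime_to_below(rk.build_rate_table(tru, model), 18, 16,
                                reps=2000, max_t=1e5, seed=3)
print(f"mean lifetime to re-anneal below 16:  sgRNA {sg_life.mean:8.1f}   tru-gRNA {tru_life.mean:6.1f}")
print(f"lifetime ratio: {sg_life.mean / tru_life.mean:.0f}x")

print(f"hybridization free energy: {rk.duplex_binding_energy(pair, model):.2f} kcal/mol")
kd = rk.overall_kd(theta=0.5, n_bound=1, protein0=50.0, dna0=2.5)
print(f"overall Kd: {kd.value:.1f} nM")
```

Output:

```
fraction of time invaded to >= position 19: 0.956 +/- 0.001
mean lifetime to re-anneal below 16:  sgRNA    975.8   tru-gRNA   29.0
lifetime ratio: 34x
hybridization free energy: -39.90 kcal/mol
overall Kd: 47.5 nM
```

Reading the numbers: the 20-nt guide on its matched AAVS1 target stays invaded
to at least the 19th protospacer position ~96% of the time at equilibrium,
while truncating two 5′ nucleotides (an 18-nt "tru-gRNA") shortens the lifetime
of the PAM-distal contacts (full invasion down to below position 16) by more
than an order of magnitude — the R-loop-volatility effect behind
truncated-guide specificity. The Kd line is the molecule-counting estimator:
with half the DNA molecules carrying one protein at 50 nM protein and 2.5 nM
DNA, the apparent dissociation constant is 47.5 nM.

The same stages are available from the shell, e.g.

```bash
rloopkmc simulate --guide GGGGCCACUAGGGACAGGAU --target GGGGCCACTAGGGACAGGAT \
    --m0 20 --max-t 10000 --reps 100 --boundary reflecting --seed 1 --out traj.tsv
rloopkmc profile --traj traj.tsv --thresholds 10:20 --max-t 10000 --out profile.tsv
rloopkmc synth cleavage --seed 1 --out data/
rloopkmc specificity --in data/cleavage_observed.tsv --out run/ --seed 7
```

To analyse an externally assembled cleavage dataset (e.g. published
single-mismatch guide/target pairs with measured cutting frequencies), put it
in a TSV with columns `guide_id`, `guide_seq`, `target_seq`,
`cutting_frequency` and run the `specificity` subcommand; the filter keeps
single, isolated, PAM-distal (position ≥ 10) mismatches of the four
parameterized classes.

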