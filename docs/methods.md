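# Methods

## Model

Strand invasion of a protospacer duplex by a guide RNA is modelled as a
one-dimensional birth–death process on the R-loop length m ∈ {0, …, N},
where N is the guide length (20 nt for a full single-guide RNA, 18 nt for a
2-nt 5′-truncated guide) and positions are counted from the PAM-proximal
end. Each forward step exchanges one DNA:DNA base pair for one RNA:DNA base
pair; each reverse step re-anneals it. To first order the rates depend only
on the local exchange free energy

    ΔΔG(m) = ΔG°37(m)_RNA:DNA − ΔG°37(m)_DNA:DNA      [kcal/mol]

through

    v_f(m) = k0 · exp(−ΔΔG(m+1)/2RT),   v_r(m) = k0 · exp(+ΔΔG(m)/2RT).

Splitting the exponent symmetrically enforces detailed balance,
v_f(m)/v_r(m+1) = exp(−ΔΔG(m+1)/RT), so on a reflecting chain the
stationary law is Boltzmann: π(m) ∝ exp(−G(m)/RT) with
G(m) = Σ_{j≤m} ΔΔG(j). Trajectories are simulated exactly (continuous time,
discrete state): the waiting time at m is exponential with rate
v_f(m)+v_r(m) and the next state is chosen proportionally to the rates.
Time is in arbitrary units (k0 = 1 by default); no physical time constants
are inferred.

**Assumptions.** m(t) is the only dynamical variable: PAM search, 3-D
diffusion, supercoiling and protein conformational states are outside the
model. The nearest-neighbour decomposition is taken as exact, step energies
are independent of m's history, and the prefactor is sequence-independent.

## Energy attribution

Nearest-neighbour parameters are defined on doublets, not positions. We
attribute the stack spanning positions (m−1, m) to position m; position 1
carries no stack energy (duplex initiation is handled by a separate term).
This makes the cumulative energy telescope exactly:
Σ_m ΔΔG(m) = ΔG_hybrid,total − ΔG_duplex,total, an identity asserted to
1e-12 in the tests. A mismatch at position p perturbs the two stacks it
participates in (those attributed to p and p+1); the underlying genomic
DNA:DNA duplex is always Watson–Crick, so only the hybrid side changes.

## Parameter tables

All ΔG°37 values refer to 1 M NaCl, 37 °C, and live in
`src/rloopkmc/data/nn_params.json` (the code treats them as data; pass
`load_energy_model(path)` to swap sets):

* DNA:DNA — the unified nearest-neighbour set of SantaLucia (1998), 10
  unique doublets, other orientations via reverse-complement identity.
* RNA:DNA hybrids — Sugimoto et al. (1995), 16 doublets keyed by the RNA
  strand 5′→3′.
* Mismatch-containing hybrid doublets (rG·dG, rC·dC, rA·dA, rU·dT against
  each Watson–Crick neighbour, 32 contexts) — **representative values**,
  constructed to reproduce the published summary behaviour of these
  mismatches (small mean destabilization, equivalent to ~1.7 °C of melting
  temperature; rG·dG nearly neutral to stabilizing; rC·dC most
  destabilizing). Sequence-context measurements exist in the literature but
  were not available for transcription here; users with access to them
  should drop them into the JSON. None of the repository's quantitative
  checks depend on the exact mismatch values.
* Duplex initiation: −3.1 kcal/mol, applied once per duplex in the total
  hybridization energy. Note the sign: initiation corrections are
  conventionally positive penalties, and this default is deliberately kept
  negative to match the binding-energy scale the analysis was built
  against. It is a constant offset that affects no ΔΔG, rate, or
  correlation — only absolute binding energies — and is configurable
  (`dg_init`).

R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and T = 310.15 K by default.

## Boundaries and key settings

* m = N is always reflecting (no forward move at full invasion).
* m = 0 is **absorbing by default** (reaching 0 models guide fall-off and
  the walk stops; post-absorption time is booked at m = 0 so time-fraction
  observables stay normalized over [0, max_t] — note this deliberately
  lowers stability metrics of dissociating ensembles). A reflecting mode is
  provided for equilibrium studies; for stable matched guides the two are
  indistinguishable because absorption from full invasion is astronomically
  rare.
* Equilibrium stability runs: m0 = N, max_t = 10 000, ≥100 replicates.
* Invasion-mode stability metric (the specificity pipeline's statistic):
  fraction of time m ≥ 16, initiated at m0 = 10, 1000 replicates,
  max_t = 100, absorbing boundary.
* Censoring at max_t holds the last state to the horizon for
  time-weighting; SEMs are computed across replicates (replicates are
  i.i.d.; within-trajectory times are autocorrelated).
* Seeds: every ensemble derives per-replicate 31-bit seeds from its master
  seed via `numpy.random.SeedSequence`; the specificity pipeline derives
  per-record seeds from (master seed, CRC32 of the record id), so adding
  records never changes existing metrics. Identical inputs reproduce
  trajectories bit-for-bit.

## Off-target correlation analysis

Datasets of guide/target pairs with measured cutting frequencies are
filtered to single, isolated, PAM-distal (position ≥ 10) mismatches of the
four parameterized classes (per-reason rejection counts are logged; note
m0 = 10 pre-invades position 10, so a position-10 mismatch sits exactly at
the initiation front). For each surviving pair the stability metric above
is simulated, and its association with cutting frequency is summarized by
the Pearson correlation coefficient (Spearman available via flag; raw
frequencies by default, transforms are the caller's choice) with a
two-sided permutation p-value: the pairing is permuted n_perm times
(default 100 000) and p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + n_perm). The +1
smoothing avoids p = 0; when n! ≤ n_perm the test switches to exhaustive
enumeration and p is the exact tail fraction. The external single-mismatch
cleavage dataset that motivates this pipeline is not redistributed; the
loader accepts any TSV with `guide_id`, `guide_seq`, `target_seq`,
`cutting_frequency`.

## Binding statistics

Extracted protein footprints (1-based inclusive bp intervals from the
labelled substrate end) are reduced two ways: `binding_histogram` spreads
each protein's 1/k contact weight over every covered bp (a coverage
profile), while `center_histogram` places the 1/k mass at the bp nearest
each contact's midpoint, so its total mass equals the protein count exactly
for any contact configuration. Peak fitting and occupancy counting use the
center histogram: footprint-convolved coverage inflates the fitted width by
√(1 + L²/(24σ²)) for footprint length L and makes neighbouring bins
strongly correlated, which invalidates least-squares confidence intervals.

Peaks are fit to the empirical Gaussian A·exp(−((x−μ)/w)²), w = √2σ, with
amplitude as a free nuisance parameter; 95% CIs come from the asymptotic
covariance. For raw count histograms `counting_noise=True` weights bins by
√max(y,1) on an absolute scale, which keeps the μ CI calibrated under
heteroscedastic Poisson noise (coverage is checked by simulation in the
test suite); a bootstrap option covers low-count data.

Affinities follow the single-molecule counting formulas: overall
Kd = (1−Θ)([P]₀ − n[D]₀)/Θ from the fraction Θ of DNA molecules carrying
protein and the mean proteins per molecule n; site-specific
Ka,ss = Kd,ss⁻¹ with Kd,ss = (1−Θ_ss)[P]free/Θ_ss, where "at the site"
means within one peak width (|x−μ| ≤ w) of the fitted peak. The same
free-protein term ([P]₀ − n[D]₀) is used for every Kd flavour, including
the site-restricted one. On a single-site substrate the overall and site formulas
coincide identically (tested), not just in the dilute limit.

## Synthetic data

The generators replace the study's experimental inputs with controlled
ground truth:

* Guide/target pairs: uniformly random guides at a chosen GC fraction
  (default 0.5), exact-complement targets with a random NGG PAM. A single
  canonical mismatch is injected by mutating the bound strand to the guide
  base's identity letter, so each position admits exactly one of the four
  classes.
* Cleavage datasets (default n = 60): cutting frequency =
  logistic(−3 + 6·s) + N(0, 0.1), where s is the pair's true simulated
  stability (its own seed stream, standard KMC settings); noise is redrawn
  while negative (truncation, not censoring — this slightly biases the
  extreme lower tail and is documented for that reason). Slope 0 gives an
  exact null. The logistic slope/intercept place typical stabilities on the
  informative part of the curve; an identity link is available for
  degenerate checks.
* Binding datasets: per molecule, each site is occupied with probability
  Ka[P]free/(1+Ka[P]free) at the self-consistently depleted free
  concentration; footprint centers get Gaussian position noise
  (σ default 40 bp, inside the 36–60 bp range typical of single-molecule
  footprint peaks), footprints span 78 bp, and a Poisson background binds
  uniformly. Default substrate: 989 bp with a site at bp 144–167 and input
  concentrations 50 nM protein / 2.5 nM DNA.

What the generators do **not** emulate: real sequence composition biases,
multi-mismatch energetics (not parameterized), correlated measurement noise,
tip-convolution of footprint shapes, or PAM-density backgrounds. Passing
tests therefore demonstrate that the estimators recover what the model
generates under the stated noise — not that the model captures every
feature of experimental data.

## Problem sizes used in the repeated checks

The power check runs 100 generator seeds (n = 60 pairs each) and the null
calibration 200 seeds, with n_perm = 2000 inside these loops (p resolution
5×10⁻⁴, ample against the 0.01 threshold; single analyses default to
100 000 permutations). Oracle-equivalence runs use ~10⁶ Gillespie events
per landscape and 20 000 replicates for absorption probabilities. These
sizes give Monte-Carlo errors well below every margin tested.

## Known limitations

* The mismatch parameter table is representative, not measured (see above).
* Stability metrics in [0,1] pile up at 0 for guides that dissociate from
  m0 = 10 under the absorbing boundary; Pearson correlations on such mixed
  discrete/continuous distributions are well-defined but not optimal.
* The AAVS1 sequences shipped as constants are the standard "T2" target of
  that locus; other AAVS1 guides will give different landscapes.
* First-passage means are reported over uncensored replicates only, with
  the censored fraction alongside; with heavy censoring they are biased low
  and the censored fraction must be consulted.
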