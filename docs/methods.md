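# Methods

## Scope and data model

`qsipx` analyses a 2 × 3 factorial climate manipulation — temperature
(ambient `T0` / warmed `T+`) × precipitation (50% reduced `-P` / natural
`nP` / 50% enhanced `+P`) — in which soil from each treatment is incubated
in parallel with natural-abundance water (¹⁶O) and 98 atom% H₂¹⁸O for
*t* = 2 days, density-fractionated, and assayed per fraction by qPCR
(total 16S copies) and amplicon sequencing (per-taxon relative abundance).
The raw measurement object is the fraction table: one row per
(tube, fraction) with buoyant density, total copies, and taxon relative
abundances (wide TSV; row sums may be < 1, the remainder being unclassified
reads that never enter per-taxon copy computation).

## The qSIP growth chain

Per taxon and treatment:

1. copies per fraction = relative abundance × qPCR total;
2. WAD = Σ_f density_f · copies_f / Σ_f copies_f over the retained density
   window (closed interval);
3. GC = (W_LIGHT − 1.646057) × (1/0.083506), clamped to [0, 1] with a
   warning;
4. M_LIGHT = 0.496·GC + 307.691; M_HEAVY = M_LIGHT + 12.07747;
   M_LAB = M_LIGHT · (W_LAB / W_LIGHT);
5. EAF = (M_LAB − M_LIGHT)/(M_HEAVY − M_LIGHT) × (1 − 0.002000429);
6. N_LIGHT = N_TOTAL (M_HEAVY − M_LAB)/(M_HEAVY − M_LIGHT);
   g = ln(N_TOTAL/N_LIGHT)/t; dN/dt = N_TOTAL (1 − e^(−g t))/t.

The six constants of steps 3–5 (GC–density calibration, molecular-weight
relation, maximal ¹⁸O mass gain, natural ¹⁸O abundance) are the standard
qSIP calibration values; they live in one overridable `QsipConstants`
object so an alternative calibration swaps in end to end.

Estimation choices:

- **Baselines.** W_LIGHT is the mean WAD over the ¹⁶O replicate tubes *of
  the same treatment* (each treatment has its own ¹⁶O controls); W_LAB the
  mean over the ¹⁸O tubes; N_TOTAL the mean of the ¹⁸O tubes' summed
  window copies. N_TOTAL is taken from the labeled tubes only — they are
  the incubation whose endpoint abundance the growth equations describe.
- **Presence rule.** A taxon is retained when it has positive copies in at
  least `min_fractions_present` (default 2) window fractions in at least
  two tubes of each isotope set; single-fraction WADs are numerically
  unstable. Excluded taxa are logged, not errored.
- **Uncertainty.** Percentile bootstrap, B = 1000, resampling replicate
  tubes with replacement independently within the ¹⁶O and ¹⁸O sets and
  re-running the whole chain. A taxon is an incorporator iff the lower 95%
  bound of g exceeds zero (the g and EAF bounds agree in sign; g is used).
- Negative EAF/g estimates are retained unclamped; clamping would bias the
  bootstrap distribution. No multiple-testing correction is applied to
  incorporator calls; each taxon carries its own 95% CI.
- Phylum-level cumulative growth sums member-taxon dN/dt within each
  bootstrap draw, so phylum totals inherit a CI.

### Known calibration limitation of the tube bootstrap

With three replicate tubes per isotope set, the bootstrap distribution of a
tube mean is supported on the observed tube range (its extreme atoms are
the all-min and all-max resamples, each with probability 1/27 > 2.5%), so
the 95% percentile CI can never extend beyond that range. For near-normal
errors the range of three draws covers the estimand about 75% of the time,
and that is what simulation shows here: nominal 95% CIs for g cover the
generator truth in ≈76% of cases, and the one-sided incorporator test
rejects a true-zero EAF in ≈10% of taxon × treatment cells rather than
2.5%. This is a structural property of percentile resampling at n = 3, not
of the growth model; incorporator lists at n = 3 should be read as
moderately anticonservative. The procedure is kept as-is because it is the
standard qSIP uncertainty treatment for this replication structure;
re-simulation confirms the point estimates themselves are unbiased.

## Effect sizes

Effects are computed on per-replicate absolute growth rates dN/dt: each
¹⁸O tube yields one replicate rate, using that tube's WAD and N_TOTAL
against the treatment-mean ¹⁶O baseline (the design does not pair ¹⁶O and
¹⁸O tubes; an explicit pairing column is accepted but not required).

- **lnRR** = ln(X_t/X_c) of the group means, for the three single-factor
  treatments (T⁺nP, T⁰−P, T⁰+P) and the two combined treatments (T⁺−P,
  T⁺+P), all against T⁰nP. lnRR needs positive rates; taxa with a
  non-positive group mean in a comparison are skipped there and logged.
- **Hedges' d_I** = [(X_AB − X_A) − (X_B − X_c)]/(2s) · J(m) per scenario
  (warming × drought uses (c, A, B, AB) = (T⁰nP, T⁺nP, T⁰−P, T⁺−P);
  warming × wet analogously), with the four-group pooled sd and
  J(m) = 1 − 3/(4(n_c+n_A+n_B+n_AB−4) − 1).
- Both get percentile bootstrap CIs (B = 1000) resampling replicates within
  groups; draws with non-positive lnRR means or zero pooled sd are redrawn
  (bounded at 10× the draw budget). Significance = CI excludes zero.

## Interaction typing

The additive null is raw-scale additivity, X_AB = X_A + X_B − X_c — the
quantity d_I tests directly. The decision tree, in order:

1. d_I CI contains 0 → **additive**;
2. d_I CI above 0 with both single effects positive, or below 0 with both
   negative or of opposite sign → **synergistic** (overshoot of the
   additive expectation in the direction the singles point);
3. otherwise **antagonistic**, sub-typed on |lnRR| point estimates with
   precedence neutralizing → strong → weak:
   - **neutralizing**: combined lnRR not significant while at least one
     single effect is;
   - **strong**: |lnRR_AB| below both single magnitudes and significant;
   - **weak**: min(|lnRR_A|, |lnRR_B|) ≤ |lnRR_AB| < |lnRR_A + lnRR_B|
     (ties resolve toward weak);
   - an antagonistic call matching no sub-category (possible when the
     singles have opposite signs, whose magnitude comparison no convention
     fully defines, or when the combined effect reaches the additive
     magnitude) is reported as strong with an `audit_flag` rather than
     silently re-binned.

Intensity scores: synergistic −1, additive 0, weak 1, strong 2,
neutralizing 3. Community antagonism is the call-proportion-weighted mean
intensity (bounded in [−1, 3]). Scenario comparison intersects the taxon
sets of the two scenarios, tabulates (type, type) pairs and counts taxa
whose antagonism ranks higher under warming × wet. Responder direction uses
the point dN/dt (negative iff below control; ties count positive).

## Phylogenetic clustering (MNTD / NTI)

For each (scenario × interaction type) group of incorporators, MNTD is the
mean over members of the cophenetic distance to the nearest other member.
The null draws `n_null` (default 999) equal-size tip sets from all tips of
the supplied tree; NTI = −(MNTD_obs − null mean)/null sd with the sample
(n−1) sd, and p = (#{null ≤ obs} + 1)/(n_null + 1). When the number of
distinct subsets does not exceed the draw budget the null is enumerated
exactly (each subset once) — on small tip pools sampling with replacement
of subsets converges to the population sd and systematically overstates
|NTI| relative to the exact enumeration, so exactness is preferred whenever
affordable. Verdicts follow the usual bands: clustered iff NTI > 0 and
p < 0.05; overdispersed iff NTI < 0 and p > 0.95; otherwise random. A
group equal to the whole tip pool has a degenerate (zero-sd) null and is
reported as an error naming the group.

## The simulator

The generator emulates the experiment's measurement geometry: 6 treatments
× 3 replicates × 2 isotopes, 20 equal-width density fractions spanning
1.66–1.78 g ml⁻¹.

Ground truth: GC ~ U[0.3, 0.7]; baseline abundances ~ Dirichlet(1) scaled
to 10⁹ 16S copies g⁻¹ soil; control growth rates lognormal (median
0.15 day⁻¹, σ = 0.25), giving control EAFs around 0.2–0.4 over a 2-day
incubation — the range typical of active soil taxa. Designed interaction
types are realised as dN/dt multipliers relative to control: single-factor
multipliers U[0.55, 0.60] (suppressive; lnRR ≈ −0.5 to −0.6), with the
combined multiplier constructed per type — exactly additive on the raw
scale; overshooting the additive expectation by 35% (synergistic, with
growth-*enhancing* singles U[1.4, 1.6], because with suppressive singles
the raw additive expectation is already near zero and an overshoot below it
is neither attainable with positive rates nor detectable); |lnRR_AB|
midway between the smaller single magnitude and their sum (weak); at 0.75×
the smaller single magnitude (strong); or exactly the control rate
(neutralizing). Type proportions are realised exactly by largest-remainder
allocation, independently per scenario except that synergists keep their
label in both scenarios (their warming response is one shared treatment).
An optional `inactive_fraction` of taxa has zero EAF everywhere, for
false-positive calibration. Realised (possibly capped) values are recorded
as truth, and recovery is always measured against realised truth.

Measurement model per tube: a tube-specific gradient offset
(sd 0.002 g ml⁻¹) shifts the fraction grid; each taxon's copy mass is a
Normal centred on its effective WAD — the GC-predicted unlabeled density
times (1 + f_new·ΔM/M_LIGHT), with f_new the fraction of new DNA implied by
its true EAF — with sd 0.006 g ml⁻¹, integrated over the fraction bins
(tail mass collects in the edge bins, conserving copies); per-replicate
biological variation multiplies f_new by a mean-one lognormal (CV 0.1);
per-fraction qPCR totals get mean-one lognormal noise (CV 0.1); relative
abundances are multinomial draws of 10,000 reads per fraction. The
within-taxon density spread is physical dispersion, not noise: the
"noise-free" configuration zeroes the offset, qPCR and replicate terms but
keeps the spread, since collapsing it degenerates every WAD to a bin
centre. The analysis retains the density window holding essentially all
(>99%) copies of each sample; for the simulated gradient that window is
the full grid, which is therefore the synthetic design's default window,
while empirical-data designs default to 1.703–1.727 g ml⁻¹.

What the simulator does **not** emulate: PCR/primer bias, chimeras,
compositional coupling between taxa beyond the shared sequencing depth,
gradient asymmetries, isotope cross-feeding, and death/turnover (only
growth labels DNA here). Passing recovery tests therefore demonstrates
correctness of the estimation chain under the stated measurement model,
not robustness to those real-data artefacts.

A companion random phylogeny (sequential random attachment, Exponential
mean-1 branch lengths) supplies tips for the NTI stage; it carries no
relationship to the designed types, so pipeline-level NTI results on
simulated data exercise the machinery rather than encode an expected
clustering signal.

## Numerical and reproducibility choices

- All randomness flows from one seed through named `SeedSequence` children
  (simulation, estimation bootstrap, effects bootstrap, NTI null), so
  every run is exactly reproducible from its config.
- Percentile CIs use linear interpolation on the sorted draws
  (numpy default); degenerate bootstrap distributions (identical
  replicates) collapse to zero-width CIs rather than erroring.
- Validation sizes: the equation-chain oracle runs 5 taxa × 7 fractions
  noiseless; parameter recovery 20 studies × 50 taxa; bootstrap calibration
  500 studies × 20 taxa (20% inactive); designed-type recovery 10 studies ×
  50 taxa; the end-to-end demonstration 100 taxa. These sizes give stable
  aggregate statistics (thousands of taxon × treatment cells per check)
  while each stage's cost stays dominated by vectorised array work.

## Known limitations

- The bootstrap calibration deficit at n = 3 described above.
- lnRR is undefined for non-positive rates; strongly suppressed taxa can
  drop out of single comparisons, slightly biasing type proportions toward
  taxa with positive rates in all six treatments.
- The weak/strong magnitude rules compare |lnRR| point estimates, not CIs;
  near the min-single and additive-expectation boundaries, calls are
  sensitive to sampling error (visible as weak↔strong confusion in
  recovery runs).
- Only the ¹⁸O chain is implemented (¹³C/¹⁵N density shifts would need
  their own molecular-weight relations), and death rates are out of scope.
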