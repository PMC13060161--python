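# Methods

## The model

`seglift` simulates polygenic adaptation to two alternating seasonal
environments under the *segregation lift* mechanism and measures its
footprint on the variance effective population size (Ne).

Each of L seasonal loci carries four parameters: summer and winter dominance
coefficients `d_s, d_w ∈ [0, 1]` and summer and winter effect sizes
`Δ_s, Δ_w > 0`. In the current season a locus contributes to an individual's
seasonal score

| genotype (summer-allele dosage) | summer | winter |
|---|---|---|
| 0 (winter homozygote) | 0 | Δ_w |
| 1 (heterozygote)      | Δ_s·d_s | Δ_w·d_w |
| 2 (summer homozygote) | Δ_s | 0 |

The score is the sum over loci, `z = Σ_l c_l`, and fitness is the power
transformation `w(z) = (1 + z)^y`. The exponent y (the *epistasis
intensity*) induces diminishing-returns interactions among loci; `y = 1` is
the additive boundary. Polymorphism is stabilised by *dominance reversal*:
only loci with mean dominance `(d_s + d_w)/2 > 0.5` are retained, so
heterozygotes sit closer to the favoured homozygote in both seasons and the
heterozygote is the best year-round genotype.

Locus parameters are drawn from the model's generating distributions:
dominance coefficients independently Uniform(0, 1) per season with rejection
of candidates failing the mean-dominance rule (so a requested locus count is
met exactly), and effect sizes as exponentiated draws from a bivariate
normal with mean 0, unit standard deviation and correlation 0.9 between the
summer and winter components (correlated log-normal effects; balanced loci
are the ones that persist).

## Forward simulation

Diploid Wright–Fisher dynamics with non-overlapping generations and *soft
selection*: the census trajectory is dictated entirely by the demography
schedule (constant, seasonal boom–bust, or custom), and each offspring draws
two distinct parents with probability proportional to current-season
fitness. Selection therefore only redistributes reproductive success; every
Ne reduction measured here is attributable to inflated variance (and
temporal autocorrelation) in offspring number. Seasons flip every `g_s`
generations, starting in summer. No mutation, migration or selfing.

All loci and neutral markers start at exactly 50% frequency by assigning the
allele to exactly N of the 2N haplotypes at random, eliminating insertion
binomial noise from the temporal variance.

Two genome modes:

* **unlinked** (default, and the fast path): every locus assorts
  independently; state is an (N × L) dosage matrix. The per-generation
  kernel (scores, fitness-proportional parent sampling via a Fenwick tree,
  Mendelian transmission) is JIT-compiled. Loci that fix are dropped from
  the matrix but keep contributing their now-constant score term, which
  leaves relative fitnesses unchanged and matches simulating the fixed
  allele in every individual.
* **linked**: loci live at basepair positions on chromosome arms (default
  geometry approximates the two major D. melanogaster autosomes: 2L 23.5 Mb,
  2R 25.3 Mb, 3L 28.1 Mb, 3R 32.1 Mb; arm 3R carries no seasonal loci so its
  markers are unlinked to selection). Crossovers per chromosome are Poisson
  with mean equal to the genetic map length, positions placed by the
  cumulative map; arms default to a uniform 2 cM/Mb-scale rate
  (2×10⁻⁸/bp/generation) and a BED-like piecewise map can be supplied.
  Chromosomes assort freely. Marker counts on a given grid are emergent from
  the configured arm lengths, not forced.

**Offspring cap.** Optionally no parent may contribute to more than `cap`
offspring per generation (counting appearances in either parent slot).
Parent slots are filled sequentially; a draw of a full parent is rejected
and an alternate parent allocated fitness-proportionally among those under
quota — implemented exactly (not by repeated rejection) with a weighted
Fenwick tree that removes a parent's mass the moment its quota fills.

**Downscaling.** A scenario can be divided by an integer factor: census
sizes, generations per season, total generations and the offspring cap all
shrink by the factor while selection parameters (y, Δ, d) are untouched;
the pre-scaling values are carried as an annotation for reporting. This
preserves the products N·s-like quantities that govern the dynamics and is
how cluster-scale parameterisations are brought to desk scale.

## Effective-size estimation

Neutral markers inserted at 0.5 drift for g generations; each marker's
standardised variance is `F = (p_g − 0.5)² / 0.25` and the variance
effective size is `Ne = −g / (2 ln(1 − F))`, with F averaged across markers
*before* the transformation (per arm group in linked mode: arms with
seasonal loci vs the selection-free arm). The headline window is one full
seasonal cycle (`g = 2·g_s`). Baselines: census size under constant
demography, harmonic mean of the per-generation sizes over the measurement
window otherwise; the reported reduction is `1 − Ne/baseline`.

Two diagnostic modes mirror the headline estimate: a within-cycle series
(markers inserted fresh each generation, estimated at g = 1, removed) that
localises the reduction to the generations right after a season transition,
and a 30-generation curve Ne(g) restricted to markers still segregating
after three complete cycles, which quantifies the downward-magnitude bias of
very short estimation windows: single-generation estimates do not capture
the autocorrelated drift accumulating across a season, so their implied
reductions are systematically milder than full-cycle estimates.

## Amplitude statistics

A locus's seasonal amplitude is the within-cycle frequency range averaged
over (by default) three consecutive cycles ending at the sampling
timepoint. Summaries (mean, median, maximum, 90th percentile, segregating
count, identity of the maximum-amplitude locus) are computed over loci
segregating at the timepoint; the 90th percentile uses linear interpolation
between order statistics. Segregating means strictly inside (0, 1).

## Regression calibration

Three fixed-coefficient linear models link observables to parameters
(coefficients are package constants; the same functional forms can be
refitted to any simulation grid with OLS via statsmodels, including the
with/without-interaction F-test):

* `log10(y) = −0.197 + 1.32·log10(n) + 0.721·log10(x) + 0.199·log10(n)·log10(x)`
  maps n segregating loci of mean amplitude x to an epistasis intensity.
  The log base is 10: it reproduces every published derived value, natural
  logs do not.
* `l = 5.133 + 1.149·n + 0.399·y + 0.009·n·y` maps (n, y) to the initial
  locus count whose decay leaves n segregating.
* `reduction = 0.056 − 1.209·(maximum amplitude)`, with negative values
  read as the fractional Ne shortfall below census.

Derived y values are reported at half-integer resolution using a *ceiling*
convention (round up to the next 0.5). This was chosen because it is the
unique half-integer rule consistent with all five published derived values
(raw back-calculations 10.85, 14.63, 9.03, 1.93, 4.44 print as 11, 15, 9.5,
2, 4.5); nearest-half rounding fails on two of them. The initial-loci model
is applied to the rounded y (reproducing the published chain); raw-chained
values are reported alongside.

## Synthetic data and oracles

Three generators make every stage testable without long simulations:
binomial-drift trajectories at known N (the estimator's oracle — under pure
drift `E[F] = 1 − (1 − 1/2N)^g`), square-wave or sinusoidal periodic
trajectories of exactly known amplitude (the amplitude oracle; square is the
default as seasonal dynamics are step-like), and the deterministic
single-locus recursion `p' = p(p·w_SS + q·w_SW)/w̄` under Hardy–Weinberg
proportions — the infinite-N expectation of the simulator, valid as an
oracle only for one locus (multi-locus recursions would need linkage
disequilibrium under epistasis and are deliberately not offered). What the
generators do not emulate: linked selection, realistic site-frequency
spectra, sequencing noise. Tests passing on them validate the estimators'
arithmetic and the simulator's neutral and single-locus limits, not the
realism of multilocus dynamics for any particular species.

## Numerical and design choices

* Parent pairs are distinct (no selfing), drawn independently per offspring
  with replacement across offspring; chosen for biological plausibility in
  insects.
* Random streams: one master generator per simulation; the transmission and
  parent-sampling kernels draw from a compiled-side RNG reseeded each
  generation from the master stream, so identical config + seed reproduces
  outputs bit for bit. Pipeline stages spawn independent substreams from
  the run seed, so adding a stage never perturbs earlier stages.
* `F = 0` maps to `Ne = ∞` (flagged, not an error); `F ≥ 1` is unestimable
  and returned as NaN. The F denominator is hard-coded to 0.25; a warning
  fires if the insertion frequency is not 0.5.
* Degenerate configs (all fitnesses zero, infeasible cap
  `cap·N < 2·N_offspring`, loci exceeding positions) raise immediately.
* Frequencies serialise at 6 decimals; trajectory tables are TSV.

## Scale of the shipped validation runs

The validation scenario for the headline reduction uses the strongest
published parameter combination (127 initial loci, y = 15) at a census of
20,000 diploids — within the range where the reduction is insensitive to
census size — with 10 generations per season, a 2,000-generation burn-in
(amplitudes stabilise well before that at this census), 200 unlinked
neutral markers and a one-cycle (20-generation) estimation window, averaged
over 5 seeded replicates. The offspring-capped variant uses the cap value
the published capped experiments actually simulated (10, i.e. 20 before the
factor-2 downscaling of that study design). Cluster-scale grids
(10⁶-equivalent populations, tens of thousands of generations, 20
replicates per cell) and the published fitted r² values are out of scope;
the functional forms, fitting machinery and reduced-scale qualitative
behaviour are what this package validates.

## Known limitations

* No mutation: segregating-locus counts only decay; long runs end monomorphic.
* The linked-genome mode is a faithful but slow reference implementation
  (per-individual crossover loop); use the unlinked mode for large censuses.
* Variance-Ne estimates assume the insertion frequency is exact; finite
  marker counts leave sampling noise on mean F that is not corrected beyond
  averaging.
* Boom–bust contractions resample parents fitness-proportionally
  (soft-selection down-sampling); no carry-over of individual identity.
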