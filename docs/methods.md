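# Methods

`invcross` analyses first-backcross (BC1) populations of *Arabidopsis
thaliana* genotyped at genome-wide SNP markers, with special machinery for a
population segregating a large pericentric inversion on chromosome 3.  A BC1
plant reveals exactly one parental gamete of the F1, so each marker call is
binary (recurrent homozygote vs heterozygote, plus missing), and a crossover
(CO) is an allele switch between consecutive informative calls along a
chromosome.

## Crossover landscapes

**CO counting.** Switches are scored between nearest non-missing flanking
calls.  A switch whose flanks are separated by missing markers is assigned
one CO at the leftmost spanned interval (minimum-recombination convention;
the choice biases all populations identically).  A chromosome with fewer
than two informative calls yields an undefined (NaN) count, never zero.
The per-cell mean CO number is `2 * total / n`: a gamete carries on average
half the chiasmata of the bivalent.

**Genetic maps.** Each adjacent-marker recombination fraction r is the
recombinant proportion among individuals called at both flanks, converted by
Kosambi's function `d = 25 ln((1+2r)/(1-2r))` cM (inverse
`r = tanh(d/50)/2`).  r is clamped at 0.4999 before the transform so
degenerate fixtures keep finite maps.  Marker order is taken from the marker
table (reference order); multipoint re-ordering is out of scope.  Marey
tracks report the piecewise slope `Δ cM / Δ Mbp`.

**Segregation distortion.** Per marker, the heterozygote frequency among
informative calls is compared with 0.5; the marker is flagged when the
deviation exceeds `k_sd` (default 2) binomial standard deviations
`sqrt(0.25/n)`.  At the default the null flag rate is the two-sided normal
~4.6%.

**Distribution comparison.** CO-count histograms of two populations are
compared with the standard 2×k contingency chi-square (both-zero bins
dropped).  Note that a goodness-of-fit chi-square of one population against
expectations derived from the other gives far smaller p-values on the same
counts; the contingency form is the symmetric, conventional choice.

## Two-point linkage

For a marker pair with R recombinants among n pairwise-complete individuals
(`r = min(R/n, 0.5)`):

    LOD = R log10(2r) + (n - R) log10(2(1 - r)),

the binomial likelihood ratio against free recombination, with
`0·log10 0 = 0` so complete linkage gives `n log10 2`.  Estimates above 0.5
are clamped (repulsion has no expectation in a backcross).  Missing data are
handled by pairwise deletion; with fully informative BC1 calls EM would add
nothing.

Anomaly flagging reports (i) interchromosomal pairs with LOD ≥ 5 and (ii)
long-range intrachromosomal pairs (≥ 10 Mbp) that remain *tightly* linked
(LOD ≥ 5 and r̂ ≤ 0.25).  The r̂ condition matters: ordinary chromosomes
show LOD > 3 at 10 Mbp simply because linkage persists, whereas markers
flanking an inversion stay locked near r̂ = 0.  The LOD = 5 default keeps
expected multiple-testing false positives over ~10⁴ pairs below ~0.1.

## The inversion heterozygote model

One region of the rearranged chromosome pairs per meiosis — the short arm
outside the inversion (region 1), the inverted segment (region 2) or the
long arm outside it (region 3) — with probabilities `(P1, P2, P3)` summing
to 1.  Conditional on pairing, the paired region receives a Poisson number
of gamete COs (intensity λᵢ, no interference), spread uniformly over the
region's marker intervals.  Gametes with an odd CO count inside the
inversion carry duplications/deficiencies and are eliminated; the viable
fraction is `Z = 1 − P2 (1 − e^{−2λ₂})/2`.  For Poisson counts,
`P(even) = (1+e^{−2λ})/2`, `P(even ∧ ≥2) = (1+e^{−2λ})/2 − e^{−λ}` and
`E[N; even] = λ(1−e^{−2λ})/2` — the closed forms that relate pre- and
post-selection rates and that only exist without interference.

The two breakpoint-spanning marker intervals belong to no region; COs there
are tallied separately and excluded from calibration.

**Observables.** Marker data see parities, not counts: an interval switches
iff it received an odd number of COs, and a viable gamete always shows an
even number of switched inversion intervals.  The model therefore works at
the interval level (per-interval odd-probability q with
`λ = −k ln(1−2q)/2` for k equal intervals), which keeps the estimator
consistent with what genotypes can show.

**Calibration.** Individuals fall into observable classes: COs exclusively
in region 1 / the inversion / region 3, or no COs in any region (the pairing
region then unknown).  For each candidate `(P1, P2)` on the simplex grid
(step 0.01) the intensities are profiled out by requiring the model's
post-selection per-region switch rates to equal the observed ones; the
candidate is scored by least squares between observed and expected
[pairing shares among CO-carrying individuals] plus [the zero-CO
probability], and the best grid point is refined by Nelder-Mead.
Alternative objectives (4-class multinomial likelihood, absolute class
frequencies) are selectable, and the full grid surface is returned in the
fit report.

*Identifiability caveat.*  The objective surface has a flat valley: the
distal pairing probability P3 is well determined, but the data barely
separate P1 from P2 (any of them can be traded against its profiled
intensity with almost no change in fit).  Different defensible objectives
move P1 and P2 by several hundredths while P3 stays put.  Consumers should
read the fit report's surface, not just the point estimate.  On real
data, a real meiosis also carries interference and an obligate CO, which
the Poisson model lacks; the model systematically under-predicts
single-CO classes by a few percent, another reason the non-P3 components
are soft.

**Forward simulation.** Rejection sampling: draw the pairing region, the
Poisson count and uniform interval placements, discard odd-inversion
gametes, repeat until n viable gametes exist (the analysed population size
is fixed post-selection).  Start phase is Bernoulli(1/2).  The simulation
aborts if the survival probability falls below 10⁻⁶.

**Recovery behaviour (measured).**  Calibrating populations simulated from
the model at `(0.2, 0.3, 0.5)` with informative intensities recovers the
simplex with per-component sampling error ≈ 0.01–0.05 at n = 10⁴ per
replicate; the mean of 20 replicate estimates is within 0.005 of truth.
Tests therefore assert mean-recovery (consistency), not per-replicate
precision.

## Two-pathway gamma interference

Chiasmata on the four-chromatid bundle come from an interfering stationary
gamma renewal process (shape ν, intensity `2(1−p)` per Morgan; ν = 1 is
Poisson, larger ν regularises spacing) superposed with a non-interfering
Poisson pathway (intensity `2p`).  Each chiasma reaches the gamete
independently with probability 1/2 (no chromatid interference), making the
gamete CO intensity exactly 1 per Morgan: expected gamete CO count = map
length in Morgans for every (ν, p).  Stationarity uses the equilibrium
(length-biased) first-interval distribution, sampled by numerical inverse
CDF.

**Fitting.** Genotypes reduce each gamete to binary interval switches.  For
every (ν, p) on a grid (defaults ν ∈ {1, 1.5, …, 15}, p ∈ {0, 0.05, …,
0.3}) the model's switch-pattern distribution is tabulated from simulated
gametes (default 10⁴) binned into the observed marker intervals, with
add-one smoothing: the joint state of every interval pair plus the gamete's
total switch count (capped at 6; the count component carries the
underdispersion signal).  Data are scored by the summed composite
log-likelihood; the arg-max is the estimate.  Because a composite
likelihood is not a likelihood, the 95% profile interval for ν uses a
deviance threshold calibrated by parametric bootstrap (default 100
replicates) at the fitted point.  Population comparisons bootstrap
individuals within each population (default 200 resamples, mid-p for grid
ties).

*Information caveat (measured).*  At n ≈ 2000 gametes on a ~1.2 Morgan
chromosome, binary switch data identify ν only coarsely: point estimates at
true ν = 3 spread over roughly 1.5–10 and the calibrated intervals are
wide (though they typically exclude ν = 1).  Contrasts of the size
published for this system (e.g. ν 5 vs 3.5) are genuinely below the
detection limit at these sample sizes; the power test in the suite uses a
contrast (8 vs 1.5) where power is real.

## Synthetic BC1 generator

Defaults reproduce the study design: 143 markers on 5 chromosomes
(chromosome 3 carries 27 markers with the breakpoint-flanking anchors at
their true physical coordinates; others evenly spaced at ~0.8 Mb), four
populations Mctr/Mmut/Fctr/Fmut of 414/418/416/419 plants.  Control genetic
lengths per gamete derive from the observed per-cell CO means (male
1.17/0.67/0.91/0.755/1.015 Morgans for chromosomes 1–5, female
0.788/0.621/0.56/0.625/0.681), giving per-cell totals ≈ 9.0 (male) and
6.55 (female) — per-cell means rather than summed Kosambi cM, which include
map-function inflation.  Interference presets: male (ν = 3, p = 0.10),
female (ν = 6, p = 0.05), within the published range for this species with
female interference markedly stronger.  Mutant males boost chromosomes
1/2/5 by 1.13/1.21/1.22 (the interchromosomal effect); females get no
boost.  The mutant chromosome 3 is generated by the pairing/selection model
with probabilities (0.08, 0.17, 0.75) male and (0.06, 0.19, 0.75) female
and intensities profiled from the observed region rates.  Missing calls are
injected independently per cell (default 2%), never blanking a whole
individual.

What the generator does **not** emulate: centromeric CO suppression (flat
cM/Mbp within chromosomes), COs in the breakpoint-spanning intervals (the
pairing model places none there, so synthetic mutant chromosome-3 totals
sit ~0.1 per cell below the real ones), the anomalous chromosome 3–4
linkage of the real mutant, and segregation distortion beyond what
selection induces.  Passing tests on synthetic data therefore validate the
estimators under the model's assumptions, not the full messiness of real
genotypes.

Ground truth (true CO counts per gamete and the paired region) is logged
beside the marker-visible switch counts; a double CO inside one marker
interval is invisible in genotypes, and tests use the log to separate
process truth from observable truth.  Identical scenario + seed gives
byte-identical outputs.

## Numerical choices

- Intensity profiling roots are bracketed and solved by Brent's method
  (xtol 10⁻¹⁴–10⁻¹⁵); the simplex refinement uses Nelder-Mead with xatol
  10⁻¹⁰.
- Simulation sizes in tests are chosen to keep the default suite within a
  few minutes: recovery studies use 10⁴ gametes × 20 seeds, interference
  reference tables 10⁴ gametes per grid point, conservation checks 10⁵
  gametes with 3-standard-error bounds.
- QC drops individuals with strictly more than 50% uncalled markers
  (boundary cases are retained).
- r̂ = 0.4999 cap, `0·log 0 = 0` conventions as above; LOD pairs with no
  pairwise-complete individual are NaN.

## Known limitations

- The pairing calibration's non-distal components (P1, P2) are weakly
  identified from class counts alone; see the caveat above.
- The interference estimator's intervals are honest but wide at realistic
  sample sizes.
- The chromosome 3–4 interaction seen in real mutant data is out of scope
  (its structural basis is unresolved); chromosome 4 carries no special
  model.
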