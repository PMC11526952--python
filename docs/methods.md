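# Methods

## The moment system

The state of the model is the matrix of expected pairwise nucleotide
diversities π_ij: the expected per-site number of differences between one
lineage sampled in deme *i* and one in deme *j* of a lattice
metapopulation. Under Wright-Fisher reproduction (N diploids per occupied
deme), backward nearest-neighbor migration (a lineage's parent lived in a
given adjacent occupied deme with probability *m* per neighbor), and
infinite-sites mutation at per-site rate μ, the first and second moments of
allele frequencies close on themselves, giving a linear ODE in the
D(D+1)/2 distinct entries of π:

    dπ_ij/dt = 2μ − δ_ij π_ii/(2N_i)
               + Σ_k m_ik (π_kj − π_ij) + Σ_k m_jk (π_ik − π_ij)

Reading: every pair of lineages accumulates differences at 2μ per
generation; a pair sampled in the same deme coalesces at rate 1/(2N); and
each lineage's deme of origin diffuses over the landscape by migration.
Migration mass aimed at unoccupied cells stays in place (the conservative
choice for a lattice with holes). The system reproduces the standard
anchors exactly: one deme equilibrates at π = 4Nμ, and the symmetric
two-deme system at π_w = 8Nμ, π_b = 8Nμ + μ/m — these closed forms are the
independent oracles in the unit tests.

Numerics: equilibria solve the sparse linear system A x = −b (x = upper
triangle of π) by a direct sparse LU solve; for a 10×10 lattice that is
5,050 unknowns with ~9 entries per row, well inside desk scale. Transients
use the action of the matrix exponential on the affine system (augmented
[[A, b], [0, 0]] trick, Krylov/Taylor `expm_multiply`), which also handles
disconnected landscapes, where between-fragment entries grow linearly
(rate 2μ) without bound. Because no equilibrium exists in that case,
`equilibrium_diversity` refuses disconnected landscapes with a component
diagnosis, and scenario "long-term" summaries fall back to a finite
13,800-generation horizon. Evolved states are clipped at zero (Krylov
round-off can produce −1e-20-scale entries).

## Parameters and the two canonical scales

| parameter | meaning | default | why |
|---|---|---|---|
| μ | per-site mutation rate / generation | 1e-8 | typical genomic point-mutation rate |
| θ = 4·N_total·μ | species-scale diversity | 1e-4 | the headline study condition |
| N (sim scale) | diploids per deme | 25 | θ = 1e-4 with μ = 1e-8 on 100 demes ⇒ N_e,total = 2,500 |
| N (theory scale) | diploids per deme | 1,000 | makes near-panmictic F_ST reachable (below) |
| m | backward migration per neighbor | tuned | chosen to hit a target mean pairwise F_ST |
| horizons | generations after loss | 2,200 / 13,800 | medium / long reporting times |

Two deme sizes appear because the 4-neighbor scheme caps m at 1/4
(outflow ≤ 1), and mean pairwise Hudson F_ST at the cap scales like
1/(8Nm): with 25 diploids per deme the most panmictic achievable 10×10
landscape has F_ST ≈ 0.026, so F_ST targets of 0.005–0.01 need larger
demes. Equilibrium π is proportional to μ, and loss *fractions* at a fixed
achieved F_ST depend on (N, m) essentially through Nm, so the choice of
deme size does not move the loss ratios; it only moves the reachable F_ST
range and the relaxation timescale (2N_total generations). Fragmentation
results, by contrast, are genuinely timescale-dependent (below) and use
the simulation scale.

F_ST is summarized as the mean over deme pairs of the Hudson-style
1 − ((π_ii + π_jj)/2)/π_ij, and `tune_migration` root-finds m on
[1e-8, 0.25] (F_ST is monotone decreasing in m); unreachable targets
return the nearest bracket endpoint flagged unconverged.

## Scenarios and horizons

*Edge contraction* removes ⌊loss·D⌋ cells column-by-column from a fixed
(west, configurable) edge — deterministic. *Fragmentation* removes random
square blocks (default one cell, 1/100 of the landscape) without
replacement until the target fraction is met; the realized fraction is
recorded since blocks are discrete. *Gradual* loss interleaves removal (1%
of the original habitat per generation by default; the alternative 1%-per-
11-generations cadence is `rate = 1/11/100`) with single-generation
evolution; its time 0 is the end of the loss phase so summaries are
comparable with instantaneous losses, and it provably shares the
instantaneous scenario's long-term equilibrium (same surviving landscape).
*Restoration* contracts, equilibrates the reduced range, re-occupies the
lost cells, and tracks recovery; new demes are founded either from their
nearest surviving deme ("natural" colonization: π rows copied from the
source deme) or landscape-wide ("translocation": within-deme π set to the
current species-wide π, cross terms to column means). Both initializations
are deliberate approximations of founding events; translocation seeds more
within-deme diversity whenever between-deme exceeds within-deme π.

Summaries are fractional losses of species-wide π (Σ w_i w_j π_ij, uniform
weights — demes are equal-sized) and local π (mean diagonal) relative to
the pre-loss equilibrium; negative losses are inflation. Short = the
instantaneous restriction (survivors keep their allele frequencies);
medium = 2,200 generations; long = the reduced equilibrium for connected
survivors, else the 13,800-generation horizon.

The Wahlund inflation of pooled π after heavy fragmentation is
timescale-driven: isolated fragments diverge at 2μ per generation while
within-fragment diversity decays toward its small local equilibrium, so
the relative inflation at the long horizon is governed by
2μ·t / π_before ≈ t/(2N_e,total·(1+structure)). At the simulation scale
(N_e,total = 2,500) the 13,800-generation horizon gives per-map increases
of roughly 130–170% at ~90% loss — inside the 100–263% range the
continuous-space simulations report, without reproducing their upper tail.
At the theory scale the same horizon is a small fraction of a relaxation
time and medium-term losses barely exceed short-term ones; medium-term
loss-table values built at theory scale are therefore conservative.

## The forward simulator

The Monte Carlo oracle evolves L independent biallelic loci: deterministic
migration mixing of deme frequencies, binomial resampling of 2N gametes,
and symmetric recurrent mutation at rate μ per gamete, with burn-in
20·(2N_total) generations. Recurrent biallelic mutation approximates
infinite sites while the per-locus θ ≪ 1; the approximation biases
heterozygosity down by order θ per locus and saturates at very long
horizons. Two consequences shape the validation design. First, per-locus
heterozygosity at small θ is a rare-event variable with CV ≈ 1/√(3θ), so
the Monte Carlo error of a panel mean is ≈ 1/√(3θL) — the number that
actually controls regression R², which is why the moments-vs-simulation
test uses θ_locus = 0.015 with 4,500 loci. Second, runtime scales as
demes × loci × generations, so the 81-run (9 loss levels × 9 replicates)
comparison runs on a 4×4 lattice of 16-diploid demes with horizons at the
study's dimensionless times t/(2N_total) = 0.44 and 2.76 — the same
dynamics at desk scale. Replicates share one burn-in and then decorrelate
for 2N_total generations under independent RNG streams before the loss
event. The simulator deliberately omits the age structure, overlapping
generations, and continuous space of individual-based frameworks: it
validates the moment system's own assumptions, and passing tests say
nothing about those further complexities.

## Power laws and genotype panels

MAR/GDAR exponents are ordinary least squares of log(diversity) on
log(area fraction) — standard species-area practice, stable at small n;
zero-diversity rows are dropped with a logged count, and ≥ 3 usable points
are required. The loss predictor is 1 − remaining^z. In-silico extinction
on geo-referenced panels bins individuals into a bounding-box grid
(half-open cells, last cell closed; lowest resolution reaching ≥ 10
occupied cells by default), then removes cells uniformly at random or
north-to-south (descending latitude rank, seeded tie-break). π uses the
unbiased estimator (n/(n−1))·(1/L)·Σ 2p̂(1−p̂) with per-locus
(pairwise-complete) sample sizes; richness is the polymorphic-locus count.
Panels read from VCF (biallelic SNPs) or PLINK .ped/.map text, capped at
10,000 loci by seeded downsampling. F_ST attached to panels is the
grid-cell Hudson-style average — a deliberate, simpler substitute for
model-based clustering estimates, not claimed equivalent. The synthetic
panel generator is Balding-Nichols on a coarse deme grid with an optional
latitudinal cline; it reproduces spatial clustering and differentiation
but not linkage, isolation-by-distance decay, or SNP ascertainment, so
power-law exponents fitted to synthetic panels are illustrative only.

## Indicator projections

Red List categories map to population/area-loss ranges via the A-criteria
decline thresholds (LC/NT 0–25%, VU 30–50%, EN 50–80%, CR 80–95%, extinct
95–100%), midpoint = arithmetic mean. LPI-style census series give
1 − N_latest/N_earliest per population (clipped to [0, 1]), averaged over
populations; non-declining species are flagged excluded. The GBF pair
combines populations already lost with survivors below N_e = 500 treated
as committed: lost + (1 − lost)·below. Percent display truncates toward
zero (0.396 → 39%); raw fractions are kept in all data outputs.
Population decline stands in for area loss, and N_e = 0.1·N_c where a
conversion is needed — both assumptions are recorded in output metadata.
Species without genetic data draw F_ST from Normal(0.270, 0.211) truncated
to [0.01, 0.99] and z exponents uniformly from [0.01, 0.8], the ranges
observed across species with data. Loss tables are bilinear in
(F_ST, area loss) per horizon, clamped at the grid edges; node lookups
reproduce the generating scenario runs exactly. The synthetic species
table reproduces requested category tallies exactly (defaults: 2,240 VU,
1,621 EN, 916 CR, 1,688 LC) with Beta-distributed LPI declines
(mean 0.64, quartiles ≈ 0.40/0.90) and GBF pairs (means ≈ 0.18/0.27).
Aggregate projections on synthetic tables exercise the computation and its
orderings; the published global averages depend on the real Red List, LPI,
and GEOBON compositions, which this package does not ship.

## Known limitations

* No selection, linkage, age structure, or continuous space; lattice
  4-neighbor migration only, equal deme sizes.
* Long-term summaries for disconnected landscapes are horizon-dependent by
  construction (infinite-sites divergence has no equilibrium).
* Near-panmictic F_ST targets require large demes (m ≤ 1/4 cap); at the
  simulation scale the reachable F_ST floor on a 10×10 lattice is ≈ 0.026.
* The long-term dependence of edge-contraction loss on F_ST is weak in
  this parameterization (fractions of a percentage point) though its sign
  matches expectation; the short-term dependence is strong.
* Continuous-time moment dynamics vs. discrete-generation simulation
  differ at O(m²) and O(θ_locus) per step; regression slopes between the
  two sit a few percent below 1.
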