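# Methods

## The model

`odrift` simulates neutral allele dynamics of organelle DNA (oDNA) in the
stem-cell niche of a monocot shoot apical meristem. The population is a
constant set of `N = 20` stem cells in two meristematic layers — tunica (L1)
and corpus (L2) — each layer holding two rows of five cells with periodic row
boundaries. Every cell carries `n` oDNA replicons: 40 for the mitochondrial
genome and 216 for the plastid genome (coverage-based estimates for
*Zostera marina* meristem tissue). Plastid mode adds the intracellular
hierarchy: `n_pt = 12` plastids of `n_rep = 18` ptDNA copies each. The
mitochondrial pool is modelled as one well-mixed pool per cell because
regular fusion/fission erases intra-organellar structure.

One time unit is one stem-cell division: a uniformly chosen cell doubles
every oDNA pool exactly (no relaxed replication) and deals the copies into
two daughters in equal numbers (hypergeometric sampling). With probability
`P_sym = 0.01` the division is symmetric and the second daughter replaces a
neighbour chosen by the stratification scheme: a tunica cell replaces a
within-layer neighbour (weight 10) or the vertically aligned corpus cell
(weight 1, periclinal); a corpus cell only replaces within the corpus.
Otherwise the division is asymmetric: one daughter (chosen uniformly) stays a
stem cell, the other differentiates and leaves the niche.

In plastid mode every plastid first divides into two sisters (intra-plastid
hypergeometric split), and the `2 n_pt` sisters are then partitioned between
the daughters. Each sister pair co-segregates into the same daughter with the
partitioning-error probability `E_part`, else the sisters split one to each
daughter; the assignment is redrawn until both daughters hold exactly `n_pt`
plastids. At `E_part = 0.5` this conditioned draw is exactly uniform over all
equal partitions of the `2 n_pt` plastids (random segregation; the
implementation samples that case directly), and at `E_part = 0` partition is
error-free. The calibrated plastid default is `E_part = 0.00065`, the
midpoint of the window fitted against observed plastid heteroplasmy counts.

### Bottlenecks

Two deterministic clocks reduce the population: a sexual bottleneck (one
uniformly chosen corpus cell survives, mimicking seed formation) every
`B_sex` years and a branching bottleneck (one tunica row plus its vertically
aligned corpus row survive) every `B_branch` years, with 1 year = `N*G = 800`
divisions (`G = 40` divisions per cell per year). Named regimes: strict
(3 yr, 1/4 yr), clone (1000 yr, 1/4 yr), relaxed (100 yr, 1 yr), no
(both disabled). The branching clock is offset by half its interval so that
no event falls inside the other's regrowth window, which keeps the
homoplasmic-phase state reconstruction at mutation-injection time exact.
After a bottleneck the population proliferates back to `N` by symmetric
growth divisions; each counts as a time unit. Growth daughters fill empty
slots in the divider's own layer whenever one is free — stem cells divide
preferentially within their layer — and cross layers only when the own layer
is full, which is how the single corpus survivor of a sexual bottleneck
reseeds the tunica. Layer-preserving regrowth matters: it is what lets a
layer-confined allele survive branching events, and without it the
stratification effects on segregation time largely vanish.

### Mutation supply and the experiment loop

Mutations are single-copy, neutral, and arise only while the population is
homoplasmic (mutation rates are so low that concurrent heteroplasmies are
negligible). The waiting time between mutations is geometric with success
probability

    p = (1 - (1 - mu)^n) * (1 - F_asym + F_asym/2),

    F_asym = (B_sex - N + 1)(B_branch - N/2)(1 - P_sym) / (B_sex * B_branch)

with the bottleneck intervals in division units; the bracket terms remove
exactly the `N-1` and `N/2` symmetric regrowth divisions per cycle, and the
`(1 - F_asym/2)` factor accounts for the even chance that a mutant copy
born at an asymmetric division leaves with the differentiating daughter — so
no extra coin is flipped at injection. The injected copy lands in a
uniformly chosen cell (and plastid) at the phase of the bottleneck cycle the
global clock dictates; if that phase lies inside a regrowth window, the
reconstruction replays the bottleneck and its regrowth divisions first.

An experiment runs until `n * N * M_fix` mutations have been injected and
absorbed (lost or fixed). After every division the tissue allele frequency
is the (sequencing-scheme-weighted, default equal) mean of per-cell mutant
frequencies; it is detectable when both alleles are at frequency `>= L`
(boundary inclusive; default `L = 0.05`). The headline observable is
`P = T_det / T_total`, the detectable fraction of simulated time, whose SEM
is taken over per-mutation detectable spans. `P` times the number of neutral
positions screened in a cohort gives the expected heteroplasmic-site count.

The engine skips runs of content-preserving divisions (a wild-type cell
dividing asymmetrically changes nothing) by drawing their count from the
corresponding geometric law — an exact acceleration, not an approximation.

## Calibrations

*Mutation rate.* The observed mean genetic distances (56.7 mitochondrial and
22.5 plastid SNPs between the Atlantic and Alaskan populations over 121,502
and 58,721 neutral positions) give 2.3e-4 and 1.9e-4 accumulated mutations
per bp over the 243,300-year divergence. Simulated substitution counts are
linear in `mu`, so `calibrate_mu` probes a few rates and inverts the
through-origin line. Package defaults: `mu = 4.5e-11` (mt) and `3.7e-11`
(pt) per bp per replicon per division, midpoints of the fitted windows.

*Partitioning error.* `fit_epart` exploits that `P` is monotone
non-increasing in `E_part` (a stricter partition prolongs segregation): a
log-spaced grid scan brackets the target `P`, then log-space bisection
refines it with an SEM-aware stopping rule. The full-precision calibration
(target `P = 1.8e-6` from six plastid heteroplasmic sites over 3.28 Mbp of
neutral positions) needs cluster-scale runs; the package carries the
resulting window (5.8e-4 to 7.3e-4) as the plastid default.

## Segregation-time statistics

`collect_event_times` injects one mutation per replicate at a uniformly
random phase of the joint bottleneck cycle and records first-passage times
of: a fully mutant plastid, a fully mutant cell, and "no plastid internally
heteroplasmic". By default times are conditional on the event occurring
(most single-copy mutations are simply lost); `conditional=False` lets lost
replicates contribute their loss time, under which "no internally
heteroplasmic plastid" is an absorbing condition every replicate reaches.
Under random partition the conditional statistics land at 560–770 divisions
(first homoplasmic plastid) and 1,200–1,600 divisions (first homoplasmic
cell) across regimes; under strict active partition the conditional
resolution of intra-plastid heteroplasmy takes 1,300–1,450 divisions while
cell-level fixation slows by orders of magnitude — the hierarchy-decoupling
at the heart of the plastid story.

Heteroplasmy ages: every detectable division contributes one observation
with age = divisions since injection / 800 years. The distribution is
length-biased by construction, exactly like sequencing at a random time.

## Synthetic cohorts

`synthetic_data` emulates the tabular shape of the empirical stage:
per-sample, per-position coverage and base counts for a 187,048 bp
mitochondrial and 143,968 bp plastid genome, two sample groups separated by
planted fixed divergence SNPs (defaults 57 mt / 23 pt, matching the observed
mean distances), planted heteroplasmies at the observed allele frequencies,
negative-binomial coverage around per-sample medians (defaults 985x mt /
6,966x pt, lognormal spread across samples, dispersion 100 giving ~10%
coverage noise), a symmetric per-base sequencing-error rate (1e-3), and
planted artifact classes: 3x coverage inflation over shared-DNA regions
(tripping the coverage-proportion QC), repeat-halo candidates (removed by
the neutral mask), clustered candidate pairs (removed by the 2-nt cluster
filter), and positions whose reference-allele coverage alone exceeds the
segment median (removed by the reference-coverage filter). Default group
sizes are a compact 5+5; tests use smaller explicit configs.

What the generator does *not* model: read-level effects (mapping quality,
strand bias, indels), position-correlated coverage waves, contamination, and
linkage between sites. Passing the round-trip tests therefore shows the
filters remove exactly the artifact classes they were designed for — not
that the pipeline is robust to every failure mode of real short-read data.

## Empirical-stage conventions

Annotations are BED-style 0-based half-open intervals; reported positions
are 1-based. Neutral masks: both analysis modes exclude coding regions and
mononucleotide repeats longer than 8 bp with a 2 bp halo; fixed-mutation
mode additionally excludes mtptDNA on the mitochondrial genome; heteroplasmy
mode excludes all shared DNA (NUMT/NUPT/mtptDNA), curated imperfect-repeat
intervals (a user-supplied channel, not auto-detected; absent means no
exclusion), and the plastid inverted repeats. QC: mitochondrial samples with
median coverage < 50 are dropped; mitochondrial positions need coverage
>= 150 and coverage proportion (position coverage over its genome-segment
median, shared DNA excluded from the median) within [0.3, 1.5]; plastid
positions need coverage proportion >= 0.3. Calls: fixed at variant AF
>= 0.75 (deliberately permissive to tolerate dilution by shared-region
reads), heteroplasmic at 0.05 <= AF <= 0.95; AFs in [0.75, 0.95] belong to
both ranges and both memberships are reported. The clustered-candidate
filter removes all candidates within 2 nt of each other per sample. The
reference-coverage filter removes a position cohort-wide when, in a sample
carrying the candidate, the reference-allele reads alone exceed the segment
median — the literal any-sample variant of this rule would trigger on
roughly half of all positions under any realistic coverage noise, because in
non-carrier samples reference coverage equals total coverage. Tri-allelic
positions are flagged and reported, never called. Pairwise genetic distance
counts differing fixed genotypes at the intersection of positions passing QC
in both samples; the group distance is the mean over all cross-group pairs,
and the substitution rate is `distance / (2 * N_neutral * T_divergence)`.

## Numerical choices and scaled-down sizes

All randomness flows through one `numpy` PCG64 generator per run (or per
acceptance target, spawned from the script seed). `1 - (1-mu)^n` is
evaluated via `expm1`/`log1p` to survive `mu ~ 1e-11`. Lifecycles carry an
assertion-only cap of 1e9 divisions — never a silent truncation.

Default problem sizes in the test suite and `scripts/acceptance.py` are
scaled for a single CPU: 12,000–45,000 mutations per experiment point
(the full-scale stop criterion `n*N*M_fix` with `M_fix` of 200–2,000
corresponds to millions), 400 replicates for per-mutation segregation
means, and ~110 conditional replicates for rare-event means. At these sizes
`P` carries a 5–15% relative SEM, which the acceptance comparisons
accommodate; tail quantities below ~1e-3 per observation (e.g. the fraction
of clone-regime mitochondrial heteroplasmy observations older than a
century, printed elsewhere as 2–3%) are not resolvable and are reported as
the (near-)zero values actually measured.

## Known limitations

- Single locus, no linkage, no concurrent heteroplasmies, no selection, no
  mtDNA recombination or relaxed replication.
- The meristem geometry is a fixed two-layer, two-row lattice; `N` must be a
  multiple of 4 (the default 20 matches the biology; sweeps use 8–32).
- The neighbour topology (2 row-adjacent slots plus the same-column slot of
  the other row, periodic rows) and the layer-preferential regrowth rule are
  reconstructions of under-specified tissue mechanics; both satisfy the
  stated symmetry (uniform replacement pressure within a layer, periclinal
  flow only tunica->corpus at constant phase).
- Whether plastid division during regrowth differs from constant phase is
  unknown; the implementation treats them identically.
- The conditional strict-partition intra-plastid resolution time is
  sensitive to how replicates are conditioned (survival-biased conditioning
  is much weaker under strict partition than under random partition);
  both conditioning variants are exposed.
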