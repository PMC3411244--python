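# Methods

## Model

The package treats the two input sequences as a sample of size two from a
coalescent population. At a homologous site pair, the time to the most
recent common ancestor T is exponential with mean 1 (coalescent units),
and given T a site carries a mismatch with probability πT, where π is the
expected number of mismatches per site. Assuming no recombination falls
inside a match, the homologous match length X starting at a site survives
as P{X > x | T} = e^(−πTx); integrating out T gives the heavy-tailed
marginal P{X > x} = 1/(1 + πx). This distribution has no finite mean —
the conditional excess E[X − x | X > x] diverges — which is why the whole
length distribution, rather than its mean, is the basis of the estimator.

Matches against the 2ℓ_S non-homologous subject positions are modelled as
matches between i.i.d. random words with P(G) = P(C) = p and
P(A) = P(T) = 1/2 − p. The maximal such match is at most x with
probability

    w_{p,ℓS}(x) = Σ_{k=0}^{x} 2^x C(x,k) p^k (1/2−p)^{x−k}
                  (1 − p^k (1/2−p)^{x−k})^{2ℓS},

which reduces to (1 − 4^(−x))^{2ℓS} at p = 1/4 and concentrates near
log₄(2ℓ_S). The shustring length at a position is the larger of the
homologous and background match lengths plus one, so its CDF factorises:

    F_π(x) = w_{p,ℓS}(x) · πx/(1 + πx),      p_π(x) = F_π(x) − F_π(x−1).

The observed counts f(1), …, f(ξ) along a doubled query of single-strand
length ℓ_Q are treated as independent Poisson variables with means
2·p_π(x)·ℓ_Q. Because Σ_x p_π(x) = 1, the π-dependent part of the Poisson
log-likelihood is exactly Σ_x f(x) log p_π(x); maximising it gives the
distribution-based estimator π̂_d. The legacy estimator π̂_m is the
reciprocal of the mean shustring length and presumes a single T for the
whole comparison.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| p | half GC-content of the background model | observed subject GC / 2 | overridable (`--gc` supplies 2p) |
| ℓ_S, ℓ_Q | single-strand lengths of subject and query/window | from input | strand doubling supplies the factors 2 |
| window, step | scan geometry (bp) | 100 000 / 10 000 | windows fully contained, starts at multiples of step |
| max_pi | missing-data peak-density threshold | 0.06 | per-window new-shustring starts vs window·max_pi |
| π search bounds | optimiser box on π | [1e−8, 0.75] | bounded Brent on log π, xatol 1e−6 |
| min_total | minimum histogram size for a fit | 100 positions | below this a fit is refused |

## Shustring computation

Matching statistics are computed with a suffix automaton built over the
reversed subject (both strands, contigs concatenated without separators);
scanning the reversed query yields, per query position, the longest
prefix of its suffix occurring anywhere in the subject. Construction and
scan are linear in sequence length (numba-compiled). The shustring length
is that matching statistic plus one, capped at the distance to the query
end; capped positions are flagged and kept in the histogram at their
capped value. Contig borders are not sentinelled, so shustrings can span
them and a heavily fragmented assembly acquires an excess of short
shustrings and a correspondingly inflated π̂_d — the fragmentation test in
the CLI suite demonstrates this deliberately retained behaviour.

## Numerical choices

- w_{p,ℓS}(x) underflows double precision for small x (e.g. 0.75^(2·10⁵)),
  so the likelihood is evaluated entirely in log space: log w is finite
  and π-independent, and log p_π(x) is formed as
  log F(x) + log(1 − e^(−(log F(x) − log F(x−1)))), which is stable both
  in the deep-underflow region and on the w ≈ 1 plateau.
- The general-p sum is evaluated with exact binomial coefficients and
  compensated summation where it is representable, and by logsumexp
  otherwise; it is saturated to exactly 1 beyond the x where it differs
  from 1 by less than ~1e−18. Agreement with the equiprobable closed form
  is ~1e−14.
- The pmf is clamped at zero against 1-ulp cancellation; the survival
  1/(1+πx) implies 99.9% of mass only by x ≈ 1000/π, so tail sums use
  that cutoff.
- Degenerate inputs: a histogram whose every position is capped (e.g.
  identical sequences) is reported not-converged with a diagnostic, as is
  an optimum sticking to the search bounds.

## Missing-data heuristic

Query windows without a full homolog in the subject consist of random
matches and would be assigned a large spurious π̂_d. The scanner counts
new-shustring starts — strict rises of the length profile — on the
window's forward strand and flags the window as missing when the count
exceeds window·max_pi. Strict rises are used rather than the
non-decreasing ("peak") count exposed as `count_peaks`: at the random
background floor (length ≈ log₄ of the doubled subject) the profile
jitters between equal values, and counting those steps inflates the
statistic to roughly six times the polymorphism density, which would trip
the 0.06 threshold even for well-matched windows at π = 0.01. Measured
densities of strict rises: ≈0.034 for homologous 100-kb windows at
π = 0.01, ≈0.28 for unrelated random windows — a comfortable margin on
both sides of the threshold.

## Simulator

`simulate_pair` generates aligned pairs with known truth under the SMC'
approximation of the two-sample coalescent with recombination: the TMRCA
is Exp(1) at the first site; breakpoints arise along the sequence at rate
ρT per site (ρ is per-site, on the same scale as π); at a breakpoint the
recombining lineage detaches at a uniform height and re-coalesces at rate
2 below the old TMRCA (half of those rejoin the same branch and leave T
unchanged) and rate 1 above. SMC' preserves the Exp(1) marginal at every
site exactly. Given the local T, sites mismatch independently with
probability min(πT, 0.95); clamping events are counted and warned about
above 0.1% of sites. Mismatched bases are redrawn conditional on
differing, so E[mismatch fraction] = π exactly. The per-pair mismatch
count distribution is indistinguishable from msprime's exact ancestral
recombination graph at matching rates (two-sample KS test in the suite).

What the generator does not emulate: finite-sites multiple hits and back
mutations (a Jukes–Cantor-type saturation would lower realised divergence
below nominal π at π ≳ 0.04), indels, rearrangements, gene duplication,
base-composition heterogeneity and CpG effects. Passing tests therefore
establish nothing about those features of real genomes; the real-data caveats
(duplications and compositional dependence lengthen shustrings and bias
π̂_d downward) remain.

## Known limitations

- Estimator bias under recombination. The model neglects recombination
  inside a match; at ρ ≈ π the exact coalescent compresses the
  match-length distribution (averaging T along a tract lowers
  E[e^(−πxT̄)]), and π̂_d overshoots by ≈10% at ρ = π = 0.01 (verified
  independently on msprime-generated pairs). The bias grows with ρ
  (≈+37% at ρ = 0.08) — the estimator is meant for ρ ≲ π.
- Single-tree regime. With no recombination the whole pair shares one T;
  the T-integrated family fitted to such single-rate data maximises at
  π̂ ≈ 1.67·πT (the stationarity condition r·e^r·E1(r) = 1/2 with
  r = πT/π̂), so at ρ = 0 the estimator is accurate per realisation only
  up to that factor and its replicate mean sits near 1.6π with a large
  spread. π̂_m is the better tool at ρ = 0.
- Distribution fit. For the same reason, the closed-form pmf deviates
  from the empirical shustring-length distribution of recombining pairs
  by a total-variation distance of ≈0.03–0.04 at ρ = π = 0.01; the
  discrepancy is a property of the approximation, not of the sampler.
- Window averages amplify realisation noise: per-window π̂_d responds
  superlinearly to local diversity, so window-averaged estimates scatter
  about three times wider than alignment-based window averages.

## Scale of the shipped analyses

The test suite and the acceptance script use 100-kb replicate pairs
(200 and 100 replicates respectively), 1-Mb pairs for sliding-window
scans (20 and 5 seeds), and 100/50 random-window draws for the
missing-data rate; these sizes make the full suite run in a few minutes
on one CPU while keeping Monte-Carlo standard errors of replicate means
near 2·10⁻⁴ on π.
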