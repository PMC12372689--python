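# Methods

## The model and its assumptions

`invfate` models the evolutionary fate of a new, intrinsically neutral
chromosomal inversion in a diploid, randomly mating population with discrete
generations and genetic sex determination (X–Y; relabel for Z–W). The life
cycle is fertilization, mutation, selection, meiosis. The inversion's only
fitness consequences are indirect: it freezes a random sample of the
partially recessive deleterious variation segregating at the `ntot` selected
loci of the pseudoautosomal region (PAR), and thereafter suppresses
recombination with non-inverted homologs over the region it spans.

Assumptions inherited from the underlying theory: deleterious alleles
segregate independently at mutation–selection balance (q̂ = μ/(hs)) with no
epistasis and no prior linkage disequilibrium; mutation μ, selection s and
dominance h are identical across loci; fitness is multiplicative over loci;
inversions arise rarely enough that each evolves alone; inverted and
non-inverted arrangements exchange nothing over the inverted region (no gene
conversion or double crossovers); loci inside the ancestral SLR contribute
nothing. A regime guard warns (never errors) when s ≤ 10μ, h ≤ μ/s or
q̂ ≥ 0.1, since the strongly recessive corner is deliberately explorable.

## Deterministic engines

**SLR engine** (`slr.py`). Four chromosome classes matter: X's in eggs (Xf),
X's in sperm (Xm), non-inverted Y's and inverted Y's, crossed with two locus
categories — D loci (inversion captured a deleterious allele; the inverted-Y
frequency there is identically 1) and W loci (captured wild type; the
inverted-Y frequency qYIW starts at 0 and climbs by new mutation). With
multiplicative fitness and independent per-locus transmission, every
sex × arrangement class stays at linkage equilibrium across loci, so the
whole system reduces to the inversion frequency among Y's plus seven scalar
class frequencies. Selection on whole Y haplotypes uses the per-locus
factors: for the inverted Y, (1 − s(h·pXfD + qXfD))^d at D loci — captured
alleles are expressed as homozygotes exactly as often as the maternal X
carries them — and the analogous W factor involving qYIW; the non-inverted Y
pairs both its factors with the X background. The Y-pool mean of these two
whole-haplotype fitnesses drives the inversion-frequency update.

**Census convention.** State frequencies are gametic, pre-mutation; a step
applies mutation (per allele copy), then selection evaluated at the
post-mutation state, then meiosis. This is algebraically the same recursion
as mutating zygotes after fertilization, and it makes the
inversion-frequency update equal the whole-haplotype fitness-ratio formula
at machine precision (asserted in tests by transcribing the formula
independently).

**Transmission rules.** Mothers transmit each locus from either X with
probability 1/2 (recombination among X's does not alter haplotype
frequencies at linkage equilibrium); fathers pass the X to daughters and the
Y or inverted Y to sons. PAR loci exchange between X and a *non-inverted* Y
at a per-locus rate r, default r = 1/2 (free recombination) — the main
theory fixes only that X × inverted-Y exchange is zero, so r is exposed as a
parameter and a CLI sensitivity sweep rather than hard-coded; at the
inversion-free equilibrium all classes sit at the same frequency for every
r, so r shapes only transients.

**Autosomal engine** (`autosomal.py`). The exact three-karyotype system
(inverted homozygote, heterokaryotype, standard homozygote) with the same
census, mutation and meiosis conventions; like arrangements recombine
freely, unlike ones not at all in the spanned region. The heterokaryotype
fitness at a D locus is 1 − s(h·P + Q) with P, Q the wild-type/deleterious
frequencies on non-inverted haplotypes — at such a locus the heterokaryotype
is Aa with probability P and aa with probability Q. An alternative form with
2h in that term circulates in print; it is available via
`doubled_het_dominance=True` (applied consistently to fitness and to the
allele-frequency update), but the h form is the one that matches the
genotype oracle exactly and is the default.

**Initial conditions.** Backgrounds start at the analytic q̂, or, with
`equilibrate=True`, at the numerically exact inversion-free fixed point
(which deviates from q̂ by O(q̂·s); 3.3 × 10⁻⁶ at the benchmark h = 0.25
parameters). Default initial frequencies are single-copy: 2/N among Y's,
1/(2N) among autosomes. Trajectories stop at a configurable extinction
threshold (default 10⁻⁵), at numerical convergence (sup-norm state change
below 10⁻¹⁴) or at a generation cap.

**Perturbation measurements.** The inversion-induced perturbations of
background frequencies are tiny (the transient excess of qXfW above
equilibrium is ~10⁻¹¹ at the d = 1, h = 0.25 benchmark) — smaller than the
offset between q̂ and the true equilibrium. Tests and analyses therefore
difference each run against a matched inversion-free twin run, which
isolates the perturbation exactly.

## Genotype oracle

`oracle.py` is the independent correctness standard: it enumerates every
haplotype (arrangement × allele vector) for n ≤ 2 loci and iterates exact
gamete-pool frequencies through the full life cycle with no
linkage-equilibrium or class-marginalization shortcuts. Its recombination
convention matches the engines (independent per-locus inheritance, rate r
between X and non-inverted Y; free between like arrangements). Both engines
agree with it to ~10⁻¹⁶ per generation over 500 generations across an
(h, s, d) grid for n ∈ {1, 2}; this agreement is what licenses the
class-based reduction, and is also how the heterokaryotype dominance
question above was settled. The oracle is deliberately unoptimized and
capped at n = 2.

## Wright–Fisher fixation simulator

`wright_fisher.py` estimates fixation probabilities of single-copy
inversions from 200 × N replicates by default. Per-locus drift is not
simulated; instead the indirect selection on the inversion is precomputed
deterministically under a pinned-background approximation: X and
non-inverted backgrounds are held at equilibrium while the inverted
haplotype's W-locus frequency returns to equilibrium from 0 following its
single-class recursion (mutation, then selection against a partner pinned at
q̂). Each replicate draws its own (n, d); because the W-locus return
trajectory is independent of n and d, all replicates share two per-locus
log-fitness series and a replicate's fitness ratio at generation t is
exp(d·const + (n − d)·series[t]) — exact and cheap, so batches are fully
vectorized. Sampling is binomial over the N/2 Y chromosomes (SLR) or
multinomial over the N adult karyotypes (autosomal), with the expected
frequency computed from the frequency-dependent mean fitness each
generation. Replicates that neither fix nor are lost by the cap (default
20·N generations) are counted as censored and reported, never dropped;
estimates carry exact (Clopper–Pearson) 95% intervals and a per-d breakdown.

Two numerical choices matter here. First, backgrounds are pinned at the
numerically exact fixed point of the pinned single-class recursion rather
than at q̂ itself; the difference is O(μ), but it makes unloaded (d = 0)
inversions *exactly* neutral at the asymptote, so absorption is guaranteed
rather than approximate. Second, the fitness series is truncated once the
inverted-haplotype frequency is within a tolerance (default 10⁻¹²) of its
asymptote and held constant thereafter.

The pinned approximation is validated two ways: the relative-fitness
sequence matches the full SLR engine run at vanishing inversion frequency to
better than 10⁻⁴ over 5,000 generations, and its integrated advantage
Σ_t log w_rel(t) for d = 0 equals Ux/(hs) to ~0.4% — the identity behind the
effective initial frequency q\* = q0·e^{Ux/(hs)}.

**What q\* does and does not predict.** q\* is a large-population
approximation for the conditional fixation probability of mutation-free
inversions. The simulator (cross-checked against an exact iteration of the
full count distribution, which it matches within Monte Carlo error) shows
that at moderate N the conditional estimate falls short of q\*: drift during
the ~1/(hs)-generation decay of the transient advantage erodes it, with
relative shortfall of order n·s·h·q̂/((hs)²·N/2) — roughly half the
advantage at N = 10³ and ~10% at N = 10⁴ for the benchmark parameters.
Likewise, near-total suppression of inversions carrying d ≥ 1 captured
alleles requires the population-scaled load N·s·h·q̂·d ≫ 1: it holds cleanly
at N = 10⁴ (no d ≥ 1 fixation in >10⁶ replicates) but only partially at
N = 10³. The headline qualitative results — overall fixation probability at
or below the neutral single-copy baseline for every inversion length, with a
bias toward small inversions in small or heavily loaded populations — hold
at every scale tested.

## Synthetic inputs and realism

All inputs are generated internally: backgrounds at mutation–selection
balance and captured loads sampled from the Poisson–binomial model. Defaults
follow the benchmark conditions s = 0.01, U = 0.02, x = 0.2, ntot = 10⁴,
h ∈ {0.25, 0.1, 0.05} (captured-load means 1.6, 4, 8) and h = 0.25 for
fixation grids. What this world omits relative to real data: variation in s
and h across loci, linkage disequilibrium and drift at the selected loci
themselves, gene conversion across inversion breakpoints, direct fitness
effects of inversions, and multiple co-segregating inversions. Passing tests
therefore certify the recursion systems and the sampling machinery under the
stated idealizations, not those wider phenomena.

## Problem sizes

Default experiment scales are chosen to run on a single CPU in minutes:
deterministic trajectories to convergence (10³–10⁵ generations of scalar
recursions), oracle validation over 500 generations at n ≤ 2, and fixation
grids at N = 500–10³ with 200 × N replicates (plus a 4 × 10⁵-replicate
N = 10⁴ run for the large-N suppression check). Larger population sizes and
denser grids are reachable through the same API and CLI flags.

## Known limitations

The Wright–Fisher mode treats indirect selection deterministically while the
inversion drifts — a strong assumption at small N·s, where full
individual-based simulation would be needed. The autosomal fitness
trajectory uses the rare-inversion (heterokaryotype) return-to-equilibrium
recursion; at high inversion frequencies homozygote selection would alter
the trajectory of its captured-load frequencies. The O(N⁻²) correction to
q\* is not reconstructed. The exact algebraic forms published for the seven
SLR class recursions are not reproduced verbatim anywhere public; the
derivation contract (life cycle + transmission rules above) plus exact
oracle agreement stands in for them.
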