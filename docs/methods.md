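# Methods

## Model

A CpG island is a 1D chain of `L` CpG dyads (default `L = 80`, roughly a 1 kb
island), each in one of three states: unmethylated (`u`), hemimethylated
(`h`, one strand methylated) or fully methylated (`m`). Twelve reactions
interconvert the states by single methyl-group steps:

* four non-collaborative reactions `u+` (de novo methylation, u→h), `h+`
  (maintenance methylation, h→m), `h-` (h→u) and `m-` (m→h);
* four collaborative methylations `u+m`, `u+h`, `h+m`, `h+h` and four
  collaborative demethylations `m-u`, `m-h`, `h-u`, `h-h`, where the
  superscript names the state a mediator CpG must be in for the reaction to
  proceed (modelling recruitment of a methylase or demethylase by a CpG in
  that state).

The four "self-destruction" combinations — u-mediated methylation and
m-mediated demethylation, in which a state would recruit the enzymes that
destroy it — are excluded from the catalogue.

Rates are interpreted as **per-attempt selection probabilities**. Each
reaction attempt draws one reaction with probability equal to its rate (the
remainder `1 - Σ rates` is a no-op), a uniform random target CpG, and, for
collaborative reactions, a uniform random mediator CpG distinct from the
target. The target changes iff its state (and the mediator's) matches the
reaction. This is the only reading under which `u+ = 1e-4` with `N_t = 100`
attempts per CpG per generation yields a 1% de novo probability per u site
per generation, and it makes the per-rate maximum `1 - u+` meaningful; it
forces `Σ rates ≤ 1`, which `make_scheme` enforces (the scanner resamples
violating schemes rather than renormalising, which would silently rescale
the favoured rate values).

A cell generation is: semiconservative **replication** (u→u, m→h, and h→h or
h→u with probability 1/2, following one daughter duplex), then `N_t · L`
reaction attempts (`N_t = 100` by default; a `poisson` attempt-count mode
with the same mean is available but indistinguishable in practice at
`N_t · L = 8000`). Counts are recorded at the end of each generation, just
before the next replication, which is where the quoted steady densities
live. Single-lineage runs follow one daughter; `population_run` retains both
daughters at every division (resolving each daughter's h-coin independently)
and returns all `2^divisions` leaves.

The island's collective state is summarised by the methylation level
`f = (2 n_m + n_h) / (2L)` (fraction of methylated strand-sites) and
classified U below 0.4, M above 0.6, intermediate between. The thresholds
are symmetric around the mixed state `f ≈ 1/2` into which non-collaborative
schemes converge, so they separate the two basins of a bistable scheme; the
qualitative results are insensitive to the exact values because bistable
schemes avoid the whole intermediate band and transitions cross it within a
generation.

## Why the standard model fails

For non-collaborative schemes the sites are independent, and the expected
dynamics follow the mean-field recursion implemented in
`analysis.meanfield_trajectory` (replication map `(u,h,m) → (u+h/2, h/2+m,
0)` followed by `N_t` Euler substeps of the per-site master equation; the
substep transfer is at most the largest rate, so the discretisation error is
negligible for the rates of interest, and the engine cross-check agrees to
better than 0.02 per component). With any de novo noise `u+ > 0`, each u
site leaves u with probability `≈ N_t · u+` per generation, so a
hypomethylated state survives at most `1/(N_t · u+)` generations in
expectation — 100 generations at the floor `u+ = 1e-4`. Both inits converge
to one fixed point: there is no bistability to inherit.

## Stochastic kernels and reproducibility

The attempt loops are numba kernels operating on int8 state vectors; a
single seeded `numpy.random.Generator` is shared between Python and kernel
code, so a (seed, config, scheme) triple reproduces a trajectory bit for
bit. Scans give every sampled scheme its own child stream
(`SeedSequence(entropy=seed, spawn_key=(i,))`), making results independent
of evaluation order and of how samples might be distributed over workers,
and making pass-sets nested across horizons (the same scheme replays the
same trajectory prefix under a longer horizon).

A small-instance oracle validates the kernel: for a 2-site island the exact
one-attempt 9×9 transition matrix is enumerated independently from the
catalogue and compared with the kernel's empirical frequencies.

## Scanning, assays and refinement

`sample_scheme` draws `u+` first, log-uniformly on `[1e-4, 0.5]`, then every
other free rate log-uniformly on `[1e-4, 1 - u+]`; `u+` and `h+` keep the
1e-4 noise floor so no scheme escapes de novo noise. Log-uniform is the
natural scale for rates spanning four decades; the original scan's exact
sampling distribution is unpublished, so absolute pass fractions here are
qualitative (the tests assert which motifs can and cannot pass, not a pass
percentage).

`bistability_assay` runs replicate pairs from all-m and all-u with a
flip stop-rule; a scheme passes at horizon G iff no replicate flips.
Replicates (default 3) guard against certifying a lucky single run.
`distinction_persistence` measures how long paired runs keep their
*own* classifications — the quantity behind "distinct M and U states could
not be sustained beyond the mean-field bound".

Lifetimes are estimated from (possibly censored) first-flip times by the
constant-hazard maximum-likelihood estimator, total observed time divided by
observed flips. Flips are rapid, rare and memoryless (approximately
geometric waiting times), for which this censoring-aware estimator is the
natural choice; with zero observed flips it reports the censoring horizon as
an explicit lower bound. `refine` hill-climbs on the corresponding survival
score, multiplying free rates by `exp(ε)` with small uniform `ε`, accepting
non-decreasing scores, and doubling the assay horizon whenever the incumbent
is fully censored. Certification horizons are capped at 10^4 generations in
the shipped tests; the million-generation regime is reachable by the same
schedule but is outside desk scale, and this package makes no claim about
it beyond the mechanism.

## Preset schemes

* `standard` (`u+ 1e-4, h+ 0.9, h- = m- = 1e-3`): the classical maintenance
  regime; converges to a mixed state from either init.
* `full_feedback` (`u+m = h+m = h+h = 0.2`, `h-u = m-u = 0.05`,
  `u+ = h+ = 1e-4`, `h- = m- = 0.03`): collaborative methylation and
  demethylation at their favoured strengths. The non-collaborative
  demethylation noise is deliberately substantial: measured U-state
  lifetimes rise from ~4×10^3 generations at `h- = m- = 1e-3` to beyond
  1.8×10^5 at 0.03 (no flip observed), because this noise clears the stray
  h/m sites from which methylation feedback could nucleate a flip, while the
  20-fold stronger collaborative methylation keeps the M state unharmed
  (no M flip in 6×10^4 generations; at 0.05 the M state collapses, mean
  lifetime ~5×10^3). Collaborative systems tolerating high demethylation
  noise is itself a characteristic of this model family. The preset's
  M-state densities (u ≈ 0.02, h ≈ 0.14, m ≈ 0.84) sit near hairpin-bisulfite
  observations of methylated islands.
* `minimal` (`u+m = 0.12, h+m = 0.3, h+h = 0.2`, non-collaborative
  demethylation `h- = 0.02, m- = 0.12`): the smallest bistable motif, with
  the U state maintained by noise demethylation alone. Its window is narrow
  and asymmetric — the U state needs `m-` high enough to clear methylation
  nuclei before `u+m` amplifies them, while the M state cannot afford `h-`
  draining the post-replication h pool that `h+h` must re-methylate — so the
  rates sit inside that window rather than at the favoured peaks, and the
  preset's measured stability (M state flip-free over ~3×10^4 generations,
  U state over 2.5×10^3 per replicate; occasional band exits beyond
  generation ~1500) is an order of magnitude below the full-feedback
  preset's, mirroring the reported rarity of minimal-motif bistability.
* `spatial_default` (`u+m = h+m = h+h = 0.2` acting locally,
  `h-u = m-u = 0.15` distance-decayed and island-restricted, noise
  `u+ = h+ = 1e-4`, `h- = m- = 1e-3`): tuned for the island-in-a-sea
  geometry (below).

## The spatial model

Geometry: 80 island CpGs at DNA distance 1 apart, then 240 sea CpGs at
distance 10 apart (the island/sea boundary gap also 10 — the sea spacing
reflects low CpG density immediately outside the island). Collaborative
methylation is local: the mediator is the nearest-neighbour CpG on either
side (probability 1/2 each, crossing the island/sea boundary freely).
Collaborative demethylation contacts a site drawn over the whole chain with
probability proportional to `1/(x + α)`, `α = 20` (about one nucleosome of
DNA stiffness); the attempt completes only if the contacted site is in the
mediator state and — the CpG-density assumption — inside the island.
Contact-then-check is essential: normalising the weights over currently
eligible mediators would make the completion probability 1 whenever any
eligible site exists, erasing the distance dependence entirely and with it
the spatial pattern this model exists to produce.

The `spatial_default` rates were chosen by a coarse grid over the two
collaborative strengths against the target phenotype: (i) a U island defends
its edge (methylation invasion needs two steps, u→h→m, each fighting
distance-weighted demethylation whose contact probability is ~8× higher at
the island edge than deep in the sea, plus the replication h→u coin); (ii)
the sea stays methylated because per-generation demethylation leakage on
replication-produced h sites scales as `r_demeth / r_meth` times the contact
probability, so local methylation must outweigh demethylation
(`0.2` vs `0.15`; at ratio ~3 the island is invaded instead, at inverse
ratios the sea demethylates); (iii) the M-state boundary recovers ≈ 20 sea
sites from the island edge (measured crossover of time-averaged m density
through 0.5: 22 sea sites, stable across seeds), with a pronounced
hemimethylation maximum in the boundary zone (h ≈ 0.13 vs ≈ 0.001 inside the
U island and ≈ 0.05 in the deep sea). With the island restriction disabled,
sea u sites mediate demethylation everywhere and the regional difference is
destroyed (the sea itself demethylates) — spatial restriction, not a
boundary element, is what demarcates the pattern.

## Synthetic inputs and what the tests show

There is no external data: all inputs are generated (initial states all-u /
all-m / random; schemes from presets or the sampler). The simulator *is* the
study object, so passing tests certify properties of the model — the
mean-field bound, bistability of the collaborative presets, essentiality of
the three collaborative methylation reactions, the spatial pattern — not
properties of any biological dataset. Where the tests quote experimental
densities (u = 0.15, h = 0.07, m = 0.78 in methylated islands; m + h < 0.01
in unmethylated ones) they are fixed reference numbers used as
classification anchors, not fitted data.

## Numerical choices and scaled problem sizes

* Default island `L = 80`, `N_t = 100` attempts per CpG per generation;
  fixed attempt counts for reproducible budgets.
* Scans in tests and the acceptance script use 10^2–10^3 samples and
  horizons of 10^2–5×10^3 generations; stability claims are therefore
  certified at these scales (the package's choice of desk-scale problem
  sizes), with censored survival estimates making the lower-bound character
  explicit. The original >10^8-sample scans, the 0.015% pass likelihood
  (whose value depends on the unpublished sampling law) and 10^6-generation
  certification are out of scope.
* Spatial runs average positions over ≥1100 post-burn-in generations
  (burn-in 300–400); the boundary zone fluctuates on century timescales, so
  shorter averages move the measured crossover by a few sites.
* Degenerate inputs: `L ≥ 2` is required (mediator selection needs a second
  site); zero-rate schemes are valid and yield pure replication dynamics;
  an all-censored lifetime estimate is flagged `is_lower_bound` rather than
  passed off as a point estimate.

## Known limitations

* Abstract reactions: no enzyme identities, no explicit two-strand
  chemistry beyond the three dyad states, no chromatin context.
* The spatial kernel is the bare `1/(x + α)` contact law; no polymer looping
  model, nucleosome positions or boundary elements.
* Pass fractions from the sampler are not comparable in absolute terms to
  the original scan (unknown sampling law); only motif-level conclusions
  (which reactions are essential, which removable) transfer.
* The mean-field companion covers non-collaborative schemes only;
  collaborative schemes are analysed by simulation.
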