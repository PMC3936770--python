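"""Numba kernels for the hot attempt loop.

State vectors are int8 arrays with codes u=0, h=1, m=2.  All kernels take a
``numpy.random.Generator`` whose state is shared with the caller, so a single
seeded stream drives an entire run and results are bit-reproducible.

Reaction tables (cumulative rates, target/product/mediator codes) are in the
canonical order of :data:`cpgsim.model_core.REACTION_IDS`: indices 0-3 are the
non-collaborative reactions, 4-7 collaborative methylation, 8-11 collaborative
demethylation.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def replicate_inplace(state, rng):
    """Semiconservative replication: u->u, m->h, h->h or u with probability 1/2."""
    for i in range(state.size):
        s = state[i]
        if s == 2:
            state[i] = 1
        elif s == 1:
            if rng.random() < 0.5:
                state[i] = 0


@njit(cache=True)
def run_attempts(state, cum_rates, targets, products, mediators,
                 n_attempts, rng, completions):
    """Global-collaboration attempt loop (well-mixed island).

    Per attempt: pick a reaction by its rate (no-op with the leftover
    probability), a uniform random target site, and — for collaborative
    reactions — a uniform random mediator site distinct from the target.
    The target changes iff target (and mediator) states match the reaction.
    ``completions[k]`` counts completed reactions per catalogue index.
    """
    L = state.size
    for _ in range(n_attempts):
        r = rng.random()
        k = -1
        for j in range(12):
            if r < cum_rates[j]:
                k = j
                break
        if k < 0:
            continue
        t = rng.integers(0, L)
        if state[t] != targets[k]:
            continue
        if mediators[k] >= 0:
            j = rng.integers(0, L - 1)
            if j >= t:
                j += 1
            if state[j] != mediators[k]:
                continue
        state[t] = products[k]
        completions[k] += 1


@njit(cache=True)
def run_attempts_spatial(state, cum_rates, targets, products, mediators,
                         cum_weights, weight_totals, island_mask,
                         restrict_demethylation, n_attempts, rng,
                         completions, position_completions):
    """Spatially restricted attempt loop for the island-plus-sea model.

    Collaborative methylation (indices 4-7) is local: the mediator is the
    left or right nearest-neighbour CpG (probability 1/2 each; chain ends use
    their unique neighbour).  Collaborative demethylation (indices 8-11)
    contacts a site drawn with probability proportional to 1/(x + alpha) in
    DNA distance (``cum_weights`` holds the per-target cumulative weights);
    the attempt completes only if the contacted site matches the mediator
    state and, when ``restrict_demethylation`` is set, lies inside the island.
    """
    L = state.size
    for _ in range(n_attempts):
        r = rng.random()
        k = -1
        for j in range(12):
            if r < cum_rates[j]:
                k = j
                break
        if k < 0:
            continue
        t = rng.integers(0, L)
        if state[t] != targets[k]:
            continue
        if k < 4:
            pass
        elif k < 8:
            if L < 2:
                continue
            if t == 0:
                j = 1
            elif t == L - 1:
                j = L - 2
            else:
                j = t - 1 if rng.random() < 0.5 else t + 1
            if state[j] != mediators[k]:
                continue
        else:
            x = rng.random() * weight_totals[t]
            j = np.searchsorted(cum_weights[t], x, side="right")
            if state[j] != mediators[k]:
                continue
            if restrict_demethylation and not island_mask[j]:
                continue
        state[t] = products[k]
        completions[k] += 1
        position_completions[t, k] += 1
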