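"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimizer and classifier code
paths: the maxent oracle is an iterative-zoom exhaustive grid search
over the weight space, and the wasted-dispersal oracle is a naive
double loop over piles and species.
"""

import numpy as np
from scipy.special import logsumexp


def regularized_objective(lam, Fp, Fb, beta):
    """The L1-regularised maxent negative log-likelihood, written plainly."""
    lam = np.asarray(lam, dtype=float)
    return (
        -float(np.mean(Fp @ lam))
        + float(logsumexp(Fb @ lam))
        + float(np.sum(beta * np.abs(lam)))
    )


def grid_search_maxent(Fp, Fb, beta, span=6.0, points=25, rounds=7):
    """Exhaustive grid minimiser of the maxent objective (<= 3 features).

    Starts on a coarse grid over [-span, span]^J and repeatedly zooms
    onto the best cell; final resolution ~ span * (2/(points-1))^rounds.
    """
    J = Fp.shape[1]
    center = np.zeros(J)
    half = span
    best = None
    for _ in range(rounds):
        axes = [np.linspace(c - half, c + half, points) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        grid = np.stack([m.ravel() for m in mesh], axis=1)
        vals = np.array([regularized_objective(g, Fp, Fb, beta) for g in grid])
        best = grid[vals.argmin()]
        center = best
        half *= 2.0 / (points - 1)
    return best


def brute_force_wasted_flags(piles, surface, limit, species):
    """Naive per-pile loop: seeds present AND suitability strictly below limit."""
    flags = []
    for pile in piles:
        suit = float(surface.value_at(np.array([pile.x]), np.array([pile.y]))[0])
        has_seeds = pile.seed_counts.get(species, 0) > 0
        flags.append(bool(has_seeds and suit < limit))
    return np.array(flags)
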