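"""Independent brute-force oracles used by the aggregation tests.

These deliberately use nested Python loops and no shared code with the
package's vectorised implementations.
"""

from __future__ import annotations

import numpy as np


def crude_loop(surface, pop, members):
    """(n_draws, n_years) crude prevalence by explicit loops."""
    N = surface.n_draws
    out = np.zeros((N, len(surface.years)))
    for yi, year in enumerate(surface.years):
        for d in range(N):
            num = den = 0.0
            for c in members:
                ci = surface.countries.index(c)
                for ai, band in enumerate(surface.age_groups):
                    w = pop.count(c, year, surface.sex, band)
                    num += surface.values[d, ci, yi, ai] * w
                    den += w
            out[d, yi] = num / den
    return out


def age_standardised_loop(surface, std, pop, members):
    """(n_draws, n_years) age-standardised prevalence: standardise within
    country, then weight countries by 18+ population."""
    N = surface.n_draws
    weights = {tuple(b): w for b, w in zip(std.age_groups, std.weights)}
    out = np.zeros((N, len(surface.years)))
    for yi, year in enumerate(surface.years):
        for d in range(N):
            num = den = 0.0
            for c in members:
                ci = surface.countries.index(c)
                std_val = 0.0
                adult = 0.0
                for ai, band in enumerate(surface.age_groups):
                    std_val += weights[tuple(band)] * surface.values[d, ci, yi, ai]
                    adult += pop.count(c, year, surface.sex, band)
                num += std_val * adult
                den += adult
            out[d, yi] = num / den
    return out


def combine_sexes_loop(male, female, pop):
    """Cell-wise both-sex surface by explicit loops."""
    out = np.empty_like(male.values)
    for d in range(male.n_draws):
        for ci, c in enumerate(male.countries):
            for yi, year in enumerate(male.years):
                for ai, band in enumerate(male.age_groups):
                    pm = pop.count(c, year, "male", band)
                    pf = pop.count(c, year, "female", band)
                    out[d, ci, yi, ai] = (
                        male.values[d, ci, yi, ai] * pm + female.values[d, ci, yi, ai] * pf
                    ) / (pm + pf)
    return out
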