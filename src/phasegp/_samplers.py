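"""Numba inner loops for the single-site Gibbs updates of marker effects.

The kernels are deterministic given their inputs: all random variates are
drawn outside (numpy Generator) and passed in, so chains are bit-reproducible
for a fixed seed.  Design matrices are expected in Fortran order so column
slices are contiguous.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def update_effects_gaussian(X, e, beta, x2, prior_var, sigma2e, z):
    """One sweep of scalar Gibbs updates under independent Gaussian priors.

    beta_j | rest ~ N(rhs/C, sigma2e/C) with C = x'x + sigma2e/prior_var_j.
    Residual vector ``e`` and ``beta`` are updated in place.
    """
    n, m = X.shape
    for j in range(m):
        if prior_var[j] <= 0.0:
            continue
        rhs = x2[j] * beta[j]
        for i in range(n):
            rhs += X[i, j] * e[i]
        C = x2[j] + sigma2e / prior_var[j]
        new = rhs / C + z[j] * math.sqrt(sigma2e / C)
        diff = new - beta[j]
        for i in range(n):
            e[i] -= X[i, j] * diff
        beta[j] = new


@njit(cache=True)
def update_effects_spike_slab(X, e, beta, delta, x2, slab_var, sigma2e,
                              logit_in, z, u):
    """One sweep of spike-and-slab updates (point mass at zero + Gaussian slab).

    The inclusion indicator delta_j is drawn from its full conditional with
    beta_j integrated out; log BF(include/exclude) =
    0.5 * (rhs^2/(sigma2e*C) - log(slab_var_j*C/sigma2e)).
    """
    n, m = X.shape
    for j in range(m):
        rhs = x2[j] * beta[j]
        for i in range(n):
            rhs += X[i, j] * e[i]
        C = x2[j] + sigma2e / slab_var[j]
        log_odds = logit_in + 0.5 * (
            rhs * rhs / (sigma2e * C) - math.log(slab_var[j] * C / sigma2e)
        )
        if log_odds > 35.0:
            p_in = 1.0
        elif log_odds < -35.0:
            p_in = 0.0
        else:
            p_in = 1.0 / (1.0 + math.exp(-log_odds))
        if u[j] < p_in:
            new = rhs / C + z[j] * math.sqrt(sigma2e / C)
            delta[j] = 1
        else:
            new = 0.0
            delta[j] = 0
        diff = new - beta[j]
        if diff != 0.0:
            for i in range(n):
                e[i] -= X[i, j] * diff
        beta[j] = new
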