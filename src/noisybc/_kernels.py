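"""Numba-compiled simulation kernels.

All hot-loop arithmetic lives here.  Functions take ``np.random.Generator``
objects directly, so the Python layer controls seeding and stream
separation: each run uses one stream for partner selection and an
independent stream for noise draws.  With the noise level at zero no draw
is consumed from the noise stream, which makes every noise type reproduce
the noiseless trajectory bit-for-bit under the same pairing stream.

Opinions live on [0, 1].  Truncation of any noisy quantity is done by
resampling the deviation until the result is in range — never by clipping.
"""

import numpy as np
from numba import njit

# noise-type codes
NONE = 0
AMBIGUITY = 1
SELECTIVITY = 2
ADAPTATION = 3
EXOGENOUS = 4

# noise-distribution codes
GAUSSIAN = 0
BOUNDED_UNIFORM = 1

# communication-regime codes
ONE_TO_ONE = 0
MANY_TO_ONE = 1
ONE_TO_MANY = 2

# Defensive bound on truncation-by-resampling.  For an anchor inside [0, 1]
# each attempt succeeds with probability >= 1/2, so the cap is unreachable
# in practice.
RESAMPLE_CAP = 1_000_000


@njit(cache=True)
def bc_update(x_i, m_j, epsilon, mu):
    """Bounded-confidence assimilation: move toward the message iff it lies
    within the confidence bound (non-strict comparison)."""
    if abs(m_j - x_i) <= epsilon:
        return x_i + mu * (m_j - x_i)
    return x_i


@njit(cache=True)
def draw_deviation(nu, dist, rng):
    if dist == GAUSSIAN:
        return rng.normal(0.0, nu)
    return rng.uniform(-nu, nu)


@njit(cache=True)
def truncated_shift(anchor, nu, dist, rng):
    """anchor + deviation, resampling the deviation until the result is in
    [0, 1].  Shared by ambiguity messages, adaptation shifts and exogenous
    jumps.  nu == 0 returns the anchor exactly, consuming no draw."""
    if nu == 0.0:
        return anchor
    for _ in range(RESAMPLE_CAP):
        v = anchor + draw_deviation(nu, dist, rng)
        if 0.0 <= v <= 1.0:
            return v
    raise RuntimeError("noise resampling attempt cap exceeded")


@njit(cache=True)
def selectivity_accept(x_r, x_s, epsilon, nu, dist, rng):
    """Perturbed-bound acceptance: |x_s - x_r| <= epsilon + xi_se.
    A negative effective bound always rejects (|gap| >= 0)."""
    xi_se = 0.0
    if nu > 0.0:
        xi_se = draw_deviation(nu, dist, rng)
    return abs(x_s - x_r) <= epsilon + xi_se


@njit(cache=True)
def receive(x_r, x_s, mu, epsilon, noise, nu, dist, rng):
    """One direction of social influence: receiver at x_r hears from a
    sender at x_s and returns its updated opinion."""
    if noise == AMBIGUITY:
        m = truncated_shift(x_s, nu, dist, rng)
        return bc_update(x_r, m, epsilon, mu)
    if noise == SELECTIVITY:
        if selectivity_accept(x_r, x_s, epsilon, nu, dist, rng):
            return x_r + mu * (x_s - x_r)
        return x_r
    if noise == ADAPTATION:
        if abs(x_s - x_r) <= epsilon:
            return truncated_shift(x_r + mu * (x_s - x_r), nu, dist, rng)
        return x_r
    # none / exogenous: exact message, deterministic acceptance
    return bc_update(x_r, x_s, epsilon, mu)


@njit(cache=True)
def exogenous_sweep(x, nu, dist, rng):
    """Independent opinion jumps: each agent jumps with probability
    omega = nu, adding a truncated deviation of scale nu.

    Implemented by geometric gap-sampling over agent indices, which is
    exactly equivalent to an independent Bernoulli(nu) per agent.
    """
    if nu <= 0.0:
        return
    n = x.shape[0]
    i = rng.geometric(nu) - 1
    while i < n:
        x[i] = truncated_shift(x[i], nu, dist, rng)
        i += rng.geometric(nu)


@njit(cache=True)
def sample_distinct(scratch, exclude, k, rng):
    """Partial Fisher-Yates: place k indices drawn uniformly without
    replacement from {0..n-1} \\ {exclude} in scratch[:k]."""
    n = scratch.shape[0]
    for idx in range(n):
        scratch[idx] = idx
    scratch[exclude] = n - 1
    scratch[n - 1] = exclude
    for t in range(k):
        r = t + rng.integers(0, n - 1 - t)
        tmp = scratch[t]
        scratch[t] = scratch[r]
        scratch[r] = tmp


@njit(cache=True)
def step(x, mu, epsilon, noise, nu, dist, regime, k, edges,
         pair_rng, noise_rng, counts, scratch):
    """Advance the state one time step in place.

    counts accumulates per-agent interaction participations; scratch is an
    int64 work array of length n used for without-replacement sampling.
    """
    n = x.shape[0]
    if regime == ONE_TO_ONE:
        if edges.shape[0] > 0:
            e = pair_rng.integers(0, edges.shape[0])
            i = edges[e, 0]
            j = edges[e, 1]
        else:
            i = pair_rng.integers(0, n)
            j = pair_rng.integers(0, n - 1)
            if j >= i:
                j += 1
        counts[i] += 1
        counts[j] += 1
        xi = x[i]
        xj = x[j]
        # both members update from each other's pre-step opinions, with
        # independent noise draws per direction
        x[i] = receive(xi, xj, mu, epsilon, noise, nu, dist, noise_rng)
        x[j] = receive(xj, xi, mu, epsilon, noise, nu, dist, noise_rng)
    elif regime == MANY_TO_ONE:
        i = pair_rng.integers(0, n)
        sample_distinct(scratch, i, k, pair_rng)
        counts[i] += 1
        xi = x[i]
        acc_sum = 0.0
        acc_cnt = 0
        for t in range(k):
            j = scratch[t]
            counts[j] += 1
            xj = x[j]
            if noise == AMBIGUITY:
                m = truncated_shift(xj, nu, dist, noise_rng)
                ok = abs(m - xi) <= epsilon
            elif noise == SELECTIVITY:
                m = xj
                ok = selectivity_accept(xi, xj, epsilon, nu, dist, noise_rng)
            else:
                m = xj
                ok = abs(xj - xi) <= epsilon
            if ok:
                acc_sum += m
                acc_cnt += 1
        if acc_cnt > 0:
            new = xi + mu * (acc_sum / acc_cnt - xi)
            if noise == ADAPTATION:
                new = truncated_shift(new, nu, dist, noise_rng)
            x[i] = new
    else:  # ONE_TO_MANY
        j = pair_rng.integers(0, n)
        sample_distinct(scratch, j, k, pair_rng)
        counts[j] += 1
        xj = x[j]
        # the broadcast is a single signal: one message draw shared by all
        # receivers under ambiguity noise
        if noise == AMBIGUITY:
            m = truncated_shift(xj, nu, dist, noise_rng)
        else:
            m = xj
        for t in range(k):
            i = scratch[t]
            counts[i] += 1
            xi = x[i]
            if noise == SELECTIVITY:
                ok = selectivity_accept(xi, xj, epsilon, nu, dist, noise_rng)
            else:
                ok = abs(m - xi) <= epsilon
            if ok:
                new = xi + mu * (m - xi)
                if noise == ADAPTATION:
                    new = truncated_shift(new, nu, dist, noise_rng)
                x[i] = new
    if noise == EXOGENOUS:
        exogenous_sweep(x, nu, dist, noise_rng)


@njit(cache=True)
def run(x0, steps, mu, epsilon, noise, nu, dist, regime, k, edges,
        snap_steps, pair_rng, noise_rng):
    """Run a full simulation, recording the state at each step listed in
    snap_steps (sorted, must start at 0 and end at steps).

    Returns (snapshots, interaction_counts).
    """
    n = x0.shape[0]
    x = x0.copy()
    counts = np.zeros(n, np.int64)
    scratch = np.empty(n, np.int64)
    snaps = np.empty((snap_steps.shape[0], n), np.float64)
    si = 0
    if snap_steps[0] == 0:
        snaps[0] = x
        si = 1
    for t in range(1, steps + 1):
        step(x, mu, epsilon, noise, nu, dist, regime, k, edges,
             pair_rng, noise_rng, counts, scratch)
        if si < snap_steps.shape[0] and snap_steps[si] == t:
            snaps[si] = x
            si += 1
    return snaps, counts
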