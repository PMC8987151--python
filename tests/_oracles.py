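"""Independent brute-force oracles, written as naive transcriptions of
the estimator definitions; deliberately loop-based and separate from the
package's vectorized implementations."""

import math

import numpy as np


def km_survival_naive(times, events, t):
    """Product-limit S(t) by iterating distinct death days (censored
    subjects stay at risk for same-day deaths)."""
    times = np.asarray(times)
    events = np.asarray(events, dtype=bool)
    s = 1.0
    for day in sorted(set(times[events])):
        if day > t:
            break
        at_risk = np.sum(times >= day)
        deaths = np.sum((times == day) & events)
        if at_risk > 0:
            s *= 1.0 - deaths / at_risk
    return s


def kmsa_naive(times, events, at_risk, outcome):
    """Direct transcription of sum_k S(t_{k-1}) * Cbar_k with loops.

    at_risk, outcome: (n, K) arrays; interval k starts at 30*(k-1).
    """
    n, K = outcome.shape
    total = 0.0
    for k in range(K):
        s = km_survival_naive(times, events, 30 * k)
        members = [i for i in range(n) if at_risk[i, k]]
        cbar = sum(outcome[i, k] for i in members) / len(members) if members else 0.0
        total += s * cbar
    return total


def breslow_loglik(beta, times, events, x):
    """Breslow-tie Cox partial log-likelihood, written out directly."""
    ll = 0.0
    for day in sorted(set(times[events.astype(bool)])):
        dead = (times == day) & events.astype(bool)
        risk = times >= day
        ll += beta * x[dead].sum() - dead.sum() * math.log(
            np.exp(beta * x[risk]).sum()
        )
    return ll


def annual_cost_numeric(h_day, monthly_mean, spike, n_intervals=12, width=30):
    """Expected counted annual cost under the generator's discrete-day
    process, by enumerating claim days: a day-d claim (uniform intensity
    monthly_mean/width) is counted iff the exponential death time exceeds
    max(d-1, interval start)."""
    total = spike
    for k in range(n_intervals):
        s = width * k
        for dday in range(s, s + width):
            total += (monthly_mean / width) * math.exp(-h_day * max(dday - 1, s))
    return total
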