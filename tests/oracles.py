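"""Independent brute-force oracles for the survival machinery.

These walk risk sets explicitly, sample by sample, and are kept free of any
code from the package under test.
"""

from __future__ import annotations

import numpy as np


def km_brute(time, event):
    """Product-limit estimate by direct iteration over distinct times.

    Returns (times, survival) at every distinct observed time; a sample
    censored at an event time stays at risk through that time.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    ts, Ss = [], []
    for t in np.unique(time):
        n_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        if d > 0:
            s *= 1.0 - d / n_risk
        ts.append(t)
        Ss.append(s)
    return np.array(ts), np.array(Ss)


def logrank_brute_two_group(time, event, group):
    """Two-sample log-rank statistic by explicit O/E/V accumulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    g1 = group == np.unique(group)[0]
    O = E = V = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        N = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        O += d1
        E += d * n1 / N
        if N > 1:
            V += d * (n1 / N) * (1 - n1 / N) * (N - d) / (N - 1)
    if V == 0:
        return 0.0
    return (O - E) ** 2 / V


def cox_loglik_brute(X, beta, time, event):
    """Efron partial log-likelihood by explicit risk-set loops."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T
    beta = np.asarray(beta, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    lp = X @ beta
    ll = 0.0
    for t in np.unique(time[event == 1]):
        tied = (time == t) & (event == 1)
        d = int(tied.sum())
        risk = time >= t
        S0 = np.exp(lp[risk]).sum()
        s0 = np.exp(lp[tied]).sum()
        ll += lp[tied].sum()
        for j in range(d):
            ll -= np.log(S0 - (j / d) * s0)
    return ll


def concordance_brute(time, event, risk):
    """Harrell's C by explicit pair enumeration (higher risk = earlier
    event); tied risks count 1/2.  Assumes untied event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    risk = np.asarray(risk, float)
    num = den = 0.0
    n = len(time)
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if j == i or time[j] <= time[i]:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den
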