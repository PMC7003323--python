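"""Independent brute-force oracles for the survival machinery.

Everything here is written directly from the defining formulas — explicit
risk-set loops, exhaustive grids, hypergeometric tabulation — sharing no
code with the package implementation, so agreement is evidence of
correctness rather than repetition.
"""

import itertools

import numpy as np


def brute_partial_loglik(beta, Z, time, event, ties_method="efron"):
    """Log partial likelihood by explicit risk-set summation.

    For each death group D at time t with risk set R = {i : t_i >= t}:
    Efron subtracts log(sum_R w - (l/d) sum_D w) for l = 0..d-1; Breslow
    uses l = 0 throughout.  No vectorisation, no shared code.
    """
    beta = np.asarray(beta, float)
    Z = np.asarray(Z, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    w = [np.exp(float(np.dot(Z[i], beta))) for i in range(len(time))]
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        deaths = [i for i in range(len(time)) if time[i] == t and event[i] == 1]
        risk = [i for i in range(len(time)) if time[i] >= t]
        d = len(deaths)
        sum_risk = sum(w[i] for i in risk)
        sum_death = sum(w[i] for i in deaths)
        for i in deaths:
            ll += float(np.dot(Z[i], beta))
        for l in range(d):
            frac = l / d if ties_method == "efron" else 0.0
            ll -= np.log(sum_risk - frac * sum_death)
    return ll


def grid_search_cox(Z, time, event, ties_method="efron",
                    bound=5.0, coarse=0.5, refine_rounds=8):
    """Maximise the brute-force partial likelihood on a shrinking grid.

    Coarse full grid over [-bound, bound]^k, then repeated 5^k local
    refinements halving the step until it falls below 0.005 — a
    derivative-free maximiser independent of the Newton path.
    """
    Z = np.asarray(Z, float)
    k = Z.shape[1]

    def ll(beta):
        return brute_partial_loglik(beta, Z, time, event, ties_method)

    axes = [np.arange(-bound, bound + 1e-9, coarse)] * k
    best, best_ll = None, -np.inf
    for beta in itertools.product(*axes):
        v = ll(beta)
        if v > best_ll:
            best, best_ll = np.array(beta), v
    step = coarse
    for _ in range(refine_rounds):
        step /= 2.0
        offsets = [np.array(o) * step
                   for o in itertools.product((-2, -1, 0, 1, 2), repeat=k)]
        improved = True
        while improved:
            improved = False
            for off in offsets:
                cand = best + off
                v = ll(cand)
                if v > best_ll:
                    best, best_ll = cand, v
                    improved = True
        if step < 0.005:
            break
    return best, best_ll


def logrank_oracle(time, event, group):
    """Two-group log-rank chi-square by direct O/E/V tabulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    levels = sorted(set(group))
    assert len(levels) == 2
    O = E = V = 0.0
    for t in sorted(set(time[event == 1])):
        risk = time >= t
        n = risk.sum()
        n1 = (risk & (group == levels[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == levels[0])).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V if V > 0 else 0.0
    return chi2


def km_oracle(time, event):
    """Product-limit estimate as (event_times, survival) by direct loop."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    out_t, out_s = [], []
    for t in sorted(set(time[event == 1])):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / n
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def bh_oracle(pvals):
    """Benjamini–Hochberg adjusted p-values from the defining formula."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


def wilcoxon_exact_oracle(x, y):
    """Two-sided exact rank-sum p by exhaustive enumeration (no ties)."""
    x, y = list(x), list(y)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle assumes no ties"
    m = len(x)
    obs = sum(combined.index(v) + 1 for v in x)
    stats_all = []
    for ranks in itertools.combinations(range(1, len(combined) + 1), m):
        stats_all.append(sum(ranks))
    mean = m * (len(combined) + 1) / 2
    extreme = sum(1 for s in stats_all if abs(s - mean) >= abs(obs - mean))
    return extreme / len(stats_all)
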