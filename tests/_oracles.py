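"""Independent brute-force reference implementations.

Everything here is written as explicit double loops straight from the
defining formulas, deliberately sharing no code with the package's
vectorized implementations.  Sizes are tiny (n <= 20), so clarity beats
speed.
"""

import math

import numpy as np


def step_surv(grid, s_row, t):
    """Right-continuous step evaluation of one survival curve."""
    if t < grid[0]:
        return 1.0
    value = s_row[0]
    for tk, sk in zip(grid, s_row):
        if tk <= t:
            value = sk
        else:
            break
    return value


def km_oracle(time, status):
    """Hand product-limit estimator: dict {event time: S(t)}."""
    times = sorted(set(t for t, d in zip(time, status) if d == 1))
    out, s = {}, 1.0
    for tj in times:
        d = sum(1 for t, dd in zip(time, status) if t == tj and dd == 1)
        n_risk = sum(1 for t in time if t >= tj)
        s *= 1.0 - d / n_risk
        out[tj] = s
    return out


def harrell_oracle(crank, time, status):
    conc = ties = comp = 0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and status[i] == 1:
                comp += 1
                if crank[i] > crank[j]:
                    conc += 1
                elif crank[i] == crank[j]:
                    ties += 1
    return (conc + 0.5 * ties) / comp


def uno_c_oracle(crank, time, status, G, tau):
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if status[i] == 1 and time[i] < time[j] and time[i] < tau:
                w = 1.0 / float(G.survival_left([time[i]])[0]) ** 2
                den += w
                if crank[i] > crank[j]:
                    num += w
                elif crank[i] == crank[j]:
                    num += 0.5 * w
    return num / den


def _pointwise_ipcw(grid, S, time, status, G, t, loss_dead, loss_alive):
    n = len(time)
    total = 0.0
    for i in range(n):
        s_it = step_surv(grid, S[i], t)
        if time[i] <= t and status[i] == 1:
            total += loss_dead(s_it) / float(G.survival_left([time[i]])[0])
        elif time[i] > t:
            total += loss_alive(s_it) / float(G.survival([t])[0])
        # censored by t: contributes nothing
    return total / n


def _integrate(values, times):
    if len(times) == 1 or times[-1] == times[0]:
        return sum(values) / len(values)
    area = 0.0
    for k in range(1, len(times)):
        area += 0.5 * (values[k] + values[k - 1]) * (times[k] - times[k - 1])
    return area / (times[-1] - times[0])


def graf_oracle(grid, S, time, status, G, eval_times):
    vals = [
        _pointwise_ipcw(grid, S, time, status, G, t,
                        lambda s: s ** 2, lambda s: (1 - s) ** 2)
        for t in eval_times
    ]
    return _integrate(vals, eval_times)


def logloss_oracle(grid, S, time, status, G, eval_times, eps=1e-15):
    def clamp(s):
        return min(max(s, eps), 1 - eps)
    vals = [
        _pointwise_ipcw(grid, S, time, status, G, t,
                        lambda s: -math.log(1 - clamp(s)),
                        lambda s: -math.log(clamp(s)))
        for t in eval_times
    ]
    return _integrate(vals, eval_times)


def schmid_oracle(grid, S, time, status, G, eval_times):
    vals = [
        _pointwise_ipcw(grid, S, time, status, G, t,
                        lambda s: s, lambda s: 1 - s)
        for t in eval_times
    ]
    return _integrate(vals, eval_times)


def uno_auc_oracle(marker, time, status, G, t):
    num = den = 0.0
    n = len(time)
    for i in range(n):
        if time[i] <= t and status[i] == 1:
            w = 1.0 / float(G.survival_left([time[i]])[0])
            for j in range(n):
                if time[j] > t:
                    den += w
                    if marker[i] > marker[j]:
                        num += w
                    elif marker[i] == marker[j]:
                        num += 0.5 * w
    return num / den


def random_instance(rng, n_max=20):
    """A random censored test-set with a random valid distribution."""
    n = int(rng.integers(4, n_max + 1))
    time = np.round(rng.exponential(1.0, n) + 0.05, 3)
    status = rng.integers(0, 2, n)
    if status.sum() == 0:
        status[int(rng.integers(0, n))] = 1
    m = int(rng.integers(2, 8))
    grid = np.sort(rng.uniform(0.05, 3.0, m))
    while len(np.unique(grid)) < m:
        grid = np.sort(rng.uniform(0.05, 3.0, m))
    S = np.sort(rng.uniform(0, 1, (n, m)), axis=1)[:, ::-1]
    crank = rng.standard_normal(n)
    return time, status, grid, S, crank
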