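"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle is deliberately naive (explicit Python loops, direct
definitions) and shares no code with the implementation it checks.
"""

import numpy as np

from radsurv.features.texture import DIRECTIONS_13


def glcm_brute(levels: np.ndarray, n_levels: int, directions=DIRECTIONS_13):
    """Pairwise enumeration of co-occurring levels, symmetrized, normalized."""
    C = np.zeros((n_levels, n_levels))
    for v in np.argwhere(levels > 0):
        for d in directions:
            w = v + d
            if all(0 <= w[k] < levels.shape[k] for k in range(3)) and levels[tuple(w)] > 0:
                a, b = levels[tuple(v)] - 1, levels[tuple(w)] - 1
                C[a, b] += 1
                C[b, a] += 1
    return C / C.sum() if C.sum() else C


def glrl_brute(levels: np.ndarray, n_levels: int, directions=DIRECTIONS_13):
    """Walk every maximal run explicitly."""
    R = np.zeros((n_levels, max(levels.shape)))
    for d in directions:
        for v in [tuple(t) for t in np.argwhere(levels > 0)]:
            prev = tuple(np.array(v) - d)
            if (
                all(0 <= prev[k] < levels.shape[k] for k in range(3))
                and levels[prev] == levels[v]
            ):
                continue  # not a run start
            length = 1
            cur = np.array(v)
            while True:
                nxt = cur + d
                if (
                    all(0 <= nxt[k] < levels.shape[k] for k in range(3))
                    and levels[tuple(nxt)] == levels[v]
                ):
                    length += 1
                    cur = nxt
                else:
                    break
            R[levels[v] - 1, length - 1] += 1
    return R


def harrell_c_brute(lp, times, events):
    """O(n^2) pair counting straight from the definition."""
    num = 0.0
    den = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i]:
                den += 1
                if lp[i] > lp[j]:
                    num += 1.0
                elif lp[i] == lp[j]:
                    num += 0.5
    return num / den


def bh_brute(p):
    """Benjamini-Hochberg step-up, straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        val = min(prev, p[idx] * m / rank)
        adjusted[idx] = val
        prev = val
    return adjusted


def efron_partial_loglik(beta, times, events, x):
    """Hand-coded Efron-corrected Cox partial log-likelihood, 1 covariate."""
    ll = 0.0
    for t in np.unique(times[events]):
        D = np.where((times == t) & events)[0]
        R = np.where(times >= t)[0]
        sD = np.exp(beta * x[D]).sum()
        sR = np.exp(beta * x[R]).sum()
        ll += beta * x[D].sum()
        for ell in range(len(D)):
            ll -= np.log(sR - ell / len(D) * sD)
    return ll


def correlation_components_brute(table, r_threshold):
    """Transitive closure of the thresholded correlation matrix."""
    cols = list(table.columns)
    corr = table.corr().to_numpy()
    n = len(cols)
    adj = (corr > r_threshold) & ~np.eye(n, dtype=bool)
    # transitive closure by repeated boolean multiplication
    reach = adj | np.eye(n, dtype=bool)
    for _ in range(n):
        reach = reach | (reach @ reach)
    groups = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = sorted(j for j in range(n) if reach[i, j])
        seen.update(comp)
        groups.append([cols[j] for j in comp])
    return groups
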