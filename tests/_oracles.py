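"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle is deliberately naive (explicit loops, dense linear algebra,
exhaustive enumeration) and shares no code with the implementation paths it
checks.
"""

import numpy as np


def bioclim_oracle_cell(tmin, tmax, prec):
    """All 19 bioclim values for one cell, by exhaustive window search.

    tmin/tmax/prec are 12-vectors. Quarters are every 3-consecutive-month
    window with wraparound; ties resolved to the earliest start month (the
    first maximizer found scanning start months 0..11).
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    prec = np.asarray(prec, dtype=float)
    tavg = (tmin + tmax) / 2.0
    qt, qp = [], []
    for m in range(12):
        idx = [m % 12, (m + 1) % 12, (m + 2) % 12]
        qt.append(tavg[idx].mean())
        qp.append(prec[idx].sum())
    qt, qp = np.array(qt), np.array(qp)
    wet, dry = int(np.argmax(qp)), int(np.argmin(qp))
    warm, cold = int(np.argmax(qt)), int(np.argmin(qt))
    out = {}
    out["bio01"] = tavg.mean()
    out["bio02"] = (tmax - tmin).mean()
    out["bio04"] = 100.0 * tavg.std(ddof=1)
    out["bio05"] = tmax.max()
    out["bio06"] = tmin.min()
    out["bio07"] = out["bio05"] - out["bio06"]
    out["bio03"] = 100.0 * out["bio02"] / out["bio07"] if out["bio07"] != 0 else np.nan
    out["bio08"] = qt[wet]
    out["bio09"] = qt[dry]
    out["bio10"] = qt[warm]
    out["bio11"] = qt[cold]
    out["bio12"] = prec.sum()
    out["bio13"] = prec.max()
    out["bio14"] = prec.min()
    p1 = prec + 1.0
    out["bio15"] = 100.0 * p1.std(ddof=1) / p1.mean()
    out["bio16"] = qp[wet]
    out["bio17"] = qp[dry]
    out["bio18"] = qp[warm]
    out["bio19"] = qp[cold]
    return out


def dense_grid_network(resistance, neighbours=8):
    """Dense Laplacian of the raster network, built with explicit loops.

    Edge conductance = mean of the two cell conductances; diagonal steps
    scaled by 1/sqrt(2). Returns (L, edges) with edges as (a, b, g) triples.
    """
    nr, nc = resistance.shape
    n = nr * nc
    L = np.zeros((n, n))
    edges = []
    steps = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighbours == 8:
        steps += [(1, 1, 1.0 / np.sqrt(2)), (1, -1, 1.0 / np.sqrt(2))]
    for r in range(nr):
        for c in range(nc):
            if np.isnan(resistance[r, c]):
                continue
            for dr, dc, w in steps:
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nr and 0 <= c2 < nc):
                    continue
                if np.isnan(resistance[r2, c2]):
                    continue
                a, b = r * nc + c, r2 * nc + c2
                g = w * (1.0 / resistance[r, c] + 1.0 / resistance[r2, c2]) / 2.0
                L[a, a] += g
                L[b, b] += g
                L[a, b] -= g
                L[b, a] -= g
                edges.append((a, b, g))
    return L, edges


def effective_resistance_dense(resistance, cell_a, cell_b, neighbours=8):
    """Two-point effective resistance via the Laplacian pseudoinverse."""
    nr, nc = resistance.shape
    L, _ = dense_grid_network(resistance, neighbours)
    # the Laplacian has exactly one zero eigenvalue; the cutoff must sit
    # between it (numerically ~1e-14) and the Fiedler value (~1e-3 here)
    Lp = np.linalg.pinv(L, rcond=1e-8)
    a = cell_a[0] * nc + cell_a[1]
    b = cell_b[0] * nc + cell_b[1]
    return Lp[a, a] + Lp[b, b] - 2 * Lp[a, b]


def max_sss_bruteforce(scores, labels):
    """Best threshold by scanning midpoints and observed values exhaustively."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.sort(np.unique(scores))
    cands = list(uniq)
    cands += list((uniq[:-1] + uniq[1:]) / 2.0)
    best_t, best_s = None, -np.inf
    for t in sorted(cands):
        sens = np.mean(scores[labels == 1] >= t)
        spec = np.mean(scores[labels == 0] < t)
        if sens + spec > best_s + 1e-12:
            best_s = sens + spec
            best_t = t
    return best_t, best_s


def auc_pairs_bruteforce(scores, labels):
    """AUC by enumerating every presence/absence pair (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
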