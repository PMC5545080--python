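"""Naive reference implementations used as independent oracles.

Everything here is written with plain Python loops over sequence pairs and
sites, deliberately sharing no code path with the package's vectorised
implementations.
"""

import math


def brute_pair_stats(a, b):
    valid = ts = tv = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            valid += 1
            if x != y:
                if {x, y} in ({"A", "G"}, {"C", "T"}):
                    ts += 1
                else:
                    tv += 1
    return valid, ts, tv


def brute_distance(a, b, model="raw"):
    """Pairwise distance or None when undefined."""
    valid, ts, tv = brute_pair_stats(a, b)
    if valid == 0:
        return None
    if model == "raw":
        return (ts + tv) / valid
    P, Q = ts / valid, tv / valid
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


def brute_matrix(seqs, model="raw"):
    n = len(seqs)
    return [
        [0.0 if i == j else brute_distance(seqs[i], seqs[j], model)
         for j in range(n)]
        for i in range(n)
    ]


def _neighbours(dist_row, i):
    return [j for j in range(len(dist_row)) if j != i and dist_row[j] is not None]


def brute_near_neighbour(seqs, species, model="raw"):
    """Outcome list: 'correct' / 'incorrect' / 'undefined' (optimistic ties)."""
    d = brute_matrix(seqs, model)
    out = []
    for i in range(len(seqs)):
        js = _neighbours(d[i], i)
        if not js:
            out.append("undefined")
            continue
        dmin = min(d[i][j] for j in js)
        nearest = [j for j in js if d[i][j] == dmin]
        out.append(
            "correct" if any(species[j] == species[i] for j in nearest)
            else "incorrect"
        )
    return out


def brute_best_close_match(seqs, species, t, model="raw"):
    d = brute_matrix(seqs, model)
    out = []
    for i in range(len(seqs)):
        js = _neighbours(d[i], i)
        if not js:
            out.append("undefined")
            continue
        within = [j for j in js if d[i][j] < t]
        if not within:
            out.append("no_id")
            continue
        dmin = min(d[i][j] for j in within)
        best = [j for j in within if d[i][j] == dmin]
        consp = [species[j] == species[i] for j in best]
        if all(consp):
            out.append("correct")
        elif not any(consp):
            out.append("incorrect")
        else:
            out.append("ambiguous")
    return out


def brute_thresh_id(seqs, species, t, model="raw"):
    d = brute_matrix(seqs, model)
    out = []
    for i in range(len(seqs)):
        js = _neighbours(d[i], i)
        if not js:
            out.append("undefined")
            continue
        within = [j for j in js if d[i][j] < t]
        if not within:
            out.append("no_id")
            continue
        consp = [species[j] == species[i] for j in within]
        if all(consp):
            out.append("correct")
        elif not any(consp):
            out.append("incorrect")
        else:
            out.append("ambiguous")
    return out


def brute_window_metrics(seqs, species, start0, width, model="k2p"):
    """(mean_distance, prop_zero_cells, prop_zero_noncon) for one window."""
    sub = [s[start0:start0 + width] for s in seqs]
    n = len(sub)
    dists, zeros, noncon_dists = [], 0, []
    for i in range(n):
        for j in range(i + 1, n):
            dij = brute_distance(sub[i], sub[j], model)
            if dij is None:
                continue
            dists.append(dij)
            if species[i] != species[j]:
                noncon_dists.append(dij)
    mean_d = sum(dists) / len(dists) if dists else None
    prop_zero = (
        sum(1 for x in dists if x == 0.0) / len(dists) if dists else None
    )
    prop_zero_noncon = (
        sum(1 for x in noncon_dists if x == 0.0) / len(noncon_dists)
        if noncon_dists
        else None
    )
    return mean_d, prop_zero, prop_zero_noncon


def brute_diagnostic_columns(seqs, species):
    """Set of 0-based columns diagnostic for at least one species."""
    L = len(seqs[0])
    by_species = {}
    for s, sp in zip(seqs, species):
        by_species.setdefault(sp, []).append(s)
    cols = set()
    for c in range(L):
        for sp, members in by_species.items():
            states = {m[c] for m in members}
            if len(states) != 1:
                continue
            state = next(iter(states))
            if state not in "ACGT":
                continue
            others = [
                m[c]
                for osp, oms in by_species.items()
                if osp != sp
                for m in oms
            ]
            if state not in others:
                cols.add(c)
                break
    return cols
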