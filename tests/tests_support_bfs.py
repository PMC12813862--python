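"""Brute-force BFS oracle for connected components in the cluster bin space.

Kept independent of the package's sparse-matrix clustering path: neighbors
are enumerated directly from the dimension-step definition.
"""

import numpy as np


def brute_force_components(active, neighbor_fn):
    active = set(np.flatnonzero(active))
    comps = []
    while active:
        seed = active.pop()
        comp, frontier = {seed}, [seed]
        while frontier:
            cur = frontier.pop()
            for nb in neighbor_fn(cur):
                if nb in active:
                    active.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


def _common_neighbors(flat, space):
    nf, nt, _ = space.shape
    f, t, u = np.unravel_index(flat, space.shape)
    out = []
    if f > 0:
        out.append(np.ravel_multi_index((f - 1, t, u), space.shape))
    if f < nf - 1:
        out.append(np.ravel_multi_index((f + 1, t, u), space.shape))
    if t > 0:
        out.append(np.ravel_multi_index((f, t - 1, u), space.shape))
    if t < nt - 1:
        out.append(np.ravel_multi_index((f, t + 1, u), space.shape))
    return out, (f, t, u)


def neighbor_fn_3d(space, neighbors):
    def fn(flat):
        out, (f, t, u) = _common_neighbors(flat, space)
        for u2 in neighbors[u]:
            out.append(np.ravel_multi_index((f, t, u2), space.shape))
        return out

    return fn


def neighbor_fn_4d(space, neighbors):
    pairs = space.pairs
    index = {(int(a), int(b)): k for k, (a, b) in enumerate(pairs)}

    def fn(flat):
        out, (f, t, u) = _common_neighbors(flat, space)
        a, b = (int(v) for v in pairs[u])
        for a2 in neighbors[a]:
            key = (min(a2, b), max(a2, b))
            if a2 != b and key in index:
                out.append(np.ravel_multi_index((f, t, index[key]), space.shape))
        for b2 in neighbors[b]:
            key = (min(a, b2), max(a, b2))
            if b2 != a and key in index:
                out.append(np.ravel_multi_index((f, t, index[key]), space.shape))
        return out

    return fn
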