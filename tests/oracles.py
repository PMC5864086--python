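"""Brute-force reference implementations used as independent test oracles."""

import numpy as np


def lattice_coords(shape):
    return (
        np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
        .reshape(-1, 3)
        .astype(float)
    )


def flood_fill_components(mask, shape):
    """Exhaustive 6-connected components on a flattened lattice."""
    mask3 = mask.reshape(shape)
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask3)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            p = stack.pop()
            comp.append(np.ravel_multi_index(p, shape))
            for axis in range(3):
                for step in (-1, 1):
                    q = list(p)
                    q[axis] += step
                    q = tuple(q)
                    if all(0 <= q[i] < shape[i] for i in range(3)):
                        if mask3[q] and not seen[q]:
                            seen[q] = True
                            stack.append(q)
        comps.append(frozenset(comp))
    return set(comps)


def bh_stepup(p, q):
    """Literal Benjamini-Hochberg definition: largest k with p_(k) <= kq/m."""
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject
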