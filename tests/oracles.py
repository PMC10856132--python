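"""Vectorized brute-force oracles used by the test suite.

These recompute results with all-pairs dense linear algebra, independent of
the neighbor-search implementations they check.
"""

import numpy as np


def pairwise_displacements(a, b, box=None):
    d = b[None, :, :] - a[:, None, :]
    if box is not None:
        box = np.asarray(box, float)
        d = d - box * np.round(d / box)
    return d


def brute_force_hbonds_dense(frame, criteria):
    """All-pairs hydrogen-bond detection via dense distance matrices."""
    coords = frame.coords
    box = frame.box
    is_h = frame.elements == "H"
    heavy_idx = np.flatnonzero(~is_h)
    h_idx = np.flatnonzero(is_h)
    events = set()
    if not len(h_idx) or not len(heavy_idx):
        return events
    # hydrogen -> nearest heavy within 1.2 A
    d_hh = np.linalg.norm(
        pairwise_displacements(coords[h_idx], coords[heavy_idx], box), axis=-1)
    nearest = d_hh.argmin(axis=1)
    parent = {}
    for k, h in enumerate(h_idx):
        if d_hh[k, nearest[k]] <= 1.2:
            parent[int(h)] = int(heavy_idx[nearest[k]])
    n_h_on = {}
    for h, par in parent.items():
        n_h_on[par] = n_h_on.get(par, 0) + 1
    acc_mask = frame.elements == "O"
    for i in np.flatnonzero(frame.elements == "N"):
        if n_h_on.get(int(i), 0) >= 2:
            acc_mask[i] = True
    is_no = np.isin(frame.elements, ("N", "O"))
    acceptors = np.flatnonzero(acc_mask)
    cos_min = np.cos(np.deg2rad(criteria.dha_angle_min))
    for h, d_heavy in parent.items():
        if not is_no[d_heavy]:
            continue
        disp_da = pairwise_displacements(coords[[d_heavy]], coords[acceptors],
                                         box)[0]
        dist_da = np.linalg.norm(disp_da, axis=-1)
        u = pairwise_displacements(coords[[h]], coords[[d_heavy]], box)[0, 0]
        va = pairwise_displacements(coords[[h]], coords[acceptors], box)[0]
        cosang = (va @ u) / (np.linalg.norm(va, axis=-1)
                             * np.linalg.norm(u) + 1e-300)
        for k, a in enumerate(acceptors):
            if a == d_heavy:
                continue
            if (frame.chains[a] == frame.chains[d_heavy]
                    and frame.resids[a] == frame.resids[d_heavy]):
                continue
            if dist_da[k] <= criteria.heavy_distance_cutoff \
                    and cosang[k] <= cos_min + 1e-12:
                events.add((d_heavy, h, int(a)))
    return events
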