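"""Independent oracles used across the test suite.

These deliberately avoid the code paths they check: the range-model
likelihood is summed by exhaustive enumeration over all internal-node
state assignments, marginals by the same enumeration, and ancestral
Brownian states by solving the tree-Laplacian least-squares problem
directly.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from orodiversify.biogeography import anagenetic_Q, cladogenesis_table


def brute_force_geo(tree, coding, space, params, family, plus_j):
    """(lnL, per-node marginals) by full enumeration over internal-node
    state assignments; feasible for <= 4 tips and <= 3 areas."""
    Q = anagenetic_Q(space, params.d, params.e)
    clado = cladogenesis_table(space, family, params.j, plus_j)
    P = {n.id: expm(Q * n.duration) for n in tree.postorder() if n.parent}
    S = space.n_states
    internals = tree.internal_nodes()
    tipstate = {t.id: space.index[coding.ranges[t.id]] for t in tree.tips()}
    post = {n.id: np.zeros(S) for n in tree.postorder()}
    total = 0.0
    for assign in itertools.product(range(S), repeat=len(internals)):
        st = dict(tipstate)
        for node, s in zip(internals, assign):
            st[node.id] = s
        like = 1.0 / S  # uniform root prior
        for v in internals:
            iL, iR, p = clado[st[v.id]]
            c1, c2 = v.children
            like *= float(
                np.sum(p * P[c1.id][iL, st[c1.id]] * P[c2.id][iR, st[c2.id]])
            )
        total += like
        for n in tree.postorder():
            post[n.id][st[n.id]] += like
    lnL = np.log(total) if total > 0 else -np.inf
    marginals = {k: v / v.sum() if v.sum() > 0 else v for k, v in post.items()}
    return lnL, marginals


def gls_root_mean(tree, traits):
    """Root estimate via the explicit GLS formula (1'C^-1 x)/(1'C^-1 1)
    with C built from root-to-tip shared path lengths."""
    tips = [t.id for t in tree.tips()]
    n = len(tips)
    depth = {}
    for node in tree.preorder():
        depth[node.id] = 0.0 if node.parent is None else (
            depth[node.parent.id] + max(node.duration, 1e-8)
        )
    tipsets = tree.clade_tipsets()
    C = np.zeros((n, n))
    for node in tree.postorder():
        if node.parent is None:
            continue
        below = tipsets[node.id]
        idx = [i for i, t in enumerate(tips) if t in below]
        blen = max(node.duration, 1e-8)
        for i in idx:
            for k in idx:
                C[i, k] += blen
    x = np.array([traits[t] for t in tips])
    one = np.ones(n)
    Ci1 = np.linalg.solve(C, one)
    return float(one @ np.linalg.solve(C, x)) / float(one @ Ci1)


def laplacian_bm_states(tree, traits):
    """Joint-mode ancestral states: minimise sum((x_u - x_v)^2 / t_uv)
    over internal values with tips clamped — a sparse linear solve on
    the tree graph, independent of the re-rooting construction."""
    nodes = [n.id for n in tree.postorder()]
    idx = {nid: i for i, nid in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for node in tree.postorder():
        if node.parent is None:
            continue
        w = 1.0 / max(node.duration, 1e-8)
        i, k = idx[node.id], idx[node.parent.id]
        W[i, k] += w
        W[k, i] += w
    L = np.diag(W.sum(axis=1)) - W
    tips = {t.id for t in tree.tips()}
    free = [i for i, nid in enumerate(nodes) if nid not in tips]
    clamped = [i for i, nid in enumerate(nodes) if nid in tips]
    xc = np.array([traits[nodes[i]] for i in clamped])
    A = L[np.ix_(free, free)]
    b = -L[np.ix_(free, clamped)] @ xc
    xf = np.linalg.solve(A, b)
    out = dict(traits)
    for i, v in zip(free, xf):
        out[nodes[i]] = float(v)
    return out


def random_geo_instance(rng, max_tips=4, max_areas=3):
    """A random small tree + area coding + parameters for oracle checks."""
    from orodiversify.biogeography import GeoParams, build_state_space
    from orodiversify.io_model import AreaCoding
    from orodiversify.synthetic_data import simulate_time_tree

    n_tips = int(rng.integers(2, max_tips + 1))
    n_areas = int(rng.integers(2, max_areas + 1))
    tree = simulate_time_tree(n_tips, birth_rate=1.0, seed=int(rng.integers(2**31)))
    areas = tuple("ABCDE"[:n_areas])
    space = build_state_space(areas)
    coding = AreaCoding(
        areas,
        {t: space.states[int(rng.integers(space.n_states))] for t in tree.taxa},
    )
    params = GeoParams(
        d=float(rng.uniform(0.02, 0.8)),
        e=float(rng.uniform(0.01, 0.5)),
        j=float(rng.uniform(0.0, 2.0)),
    )
    return tree, coding, space, params
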