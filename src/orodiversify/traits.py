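"""Brownian-motion ancestral reconstruction of a continuous trait.

Under Brownian motion with rate sigma^2 the tip values are multivariate
normal with covariance sigma^2 * C, where C[i, j] is the shared
root-to-tip path length of tips i and j.  The root estimate is the GLS
mean (1' C^-1 x) / (1' C^-1 1); each internal node's ML estimate is
obtained by re-rooting the tree at that node and taking the same GLS
mean there, which equals the conditional ML value.  sigma^2 is the ML
(1/n) estimate from the root-tree residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import TimeTree, TreeNode

__all__ = ["AncTraitResult", "anc_bm", "elevation_paths"]

#: zero-length branches are nudged by this before inverting C
_ZERO_BRANCH = 1e-8


@dataclass
class AncTraitResult:
    """Per-node ML trait estimates and conditional variances, plus the
    ML Brownian rate (trait units^2 / Ma)."""

    estimates: dict[str, float]
    variances: dict[str, float]
    sigma2: float
    root_estimate: float


def _branch_durations(tree: TimeTree) -> dict[str, float]:
    return {
        n.id: max(n.duration, _ZERO_BRANCH)
        for n in tree.postorder()
        if n.parent is not None
    }


def _distances_from(tree: TimeTree, origin: TreeNode, blen: Mapping[str, float]) -> dict[str, float]:
    """Path length from ``origin`` to every node, treating the tree as
    an unrooted graph."""
    adj: dict[str, list[tuple[str, float]]] = {n.id: [] for n in tree.postorder()}
    for n in tree.postorder():
        if n.parent is not None:
            w = blen[n.id]
            adj[n.id].append((n.parent.id, w))
            adj[n.parent.id].append((n.id, w))
    dist = {origin.id: 0.0}
    stack = [origin.id]
    while stack:
        cur = stack.pop()
        for nxt, w in adj[cur]:
            if nxt not in dist:
                dist[nxt] = dist[cur] + w
                stack.append(nxt)
    return dist


def _gls_mean(dists: Mapping[str, float], pairdist: Mapping[tuple[str, str], float],
              tips: list[str], x: np.ndarray) -> tuple[float, float]:
    """GLS mean and 1/(1' C^-1 1) for the tree rooted at the origin of
    ``dists``; C[i,j] = (d(o,i) + d(o,j) - d(i,j)) / 2."""
    n = len(tips)
    C = np.empty((n, n))
    for i, a in enumerate(tips):
        C[i, i] = dists[a]
        for k in range(i + 1, n):
            b = tips[k]
            C[i, k] = C[k, i] = 0.5 * (dists[a] + dists[b] - pairdist[(a, b)])
    one = np.ones(n)
    Ci_one = np.linalg.solve(C, one)
    Ci_x = np.linalg.solve(C, x)
    denom = float(one @ Ci_one)
    return float(one @ Ci_x) / denom, 1.0 / denom


def anc_bm(tree: TimeTree, traits: Mapping[str, float]) -> AncTraitResult:
    """ML ancestral states of a continuous trait under Brownian motion.

    Every tip must have a finite trait value.  Tip estimates are the
    observations themselves (variance 0); internal estimates come from
    the re-rooting construction described in the module docstring.
    """
    tips = [t.id for t in tree.tips()]
    missing = [t for t in tips if t not in traits]
    if missing:
        raise KeyError(f"tips without trait values: {missing}")
    x = np.array([float(traits[t]) for t in tips])
    if not np.all(np.isfinite(x)):
        raise ValueError("trait values must be finite")
    blen = _branch_durations(tree)

    # tip-to-tip patristic distances (via root distances once per tip)
    tip_dists = {t.id: _distances_from(tree, t, blen) for t in tree.tips()}
    pairdist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            pairdist[(a, b)] = pairdist[(b, a)] = tip_dists[a][b]

    estimates: dict[str, float] = {}
    cond_factor: dict[str, float] = {}
    for node in tree.postorder():
        if node.is_tip:
            estimates[node.id] = float(traits[node.id])
            cond_factor[node.id] = 0.0
        else:
            dists = _distances_from(tree, node, blen)
            mean, factor = _gls_mean(dists, pairdist, tips, x)
            estimates[node.id] = mean
            cond_factor[node.id] = factor

    # ML sigma^2 from the original rooting
    root_dists = _distances_from(tree, tree.root, blen)
    n = len(tips)
    C = np.empty((n, n))
    for i, a in enumerate(tips):
        C[i, i] = root_dists[a]
        for k in range(i + 1, n):
            b = tips[k]
            C[i, k] = C[k, i] = 0.5 * (root_dists[a] + root_dists[b] - pairdist[(a, b)])
    resid = x - estimates[tree.root.id]
    sigma2 = float(resid @ np.linalg.solve(C, resid)) / n
    sigma2 = max(sigma2, 0.0)

    variances = {nid: sigma2 * f for nid, f in cond_factor.items()}
    return AncTraitResult(
        estimates=estimates,
        variances=variances,
        sigma2=sigma2,
        root_estimate=estimates[tree.root.id],
    )


def elevation_paths(
    tree: TimeTree,
    result: AncTraitResult,
    tags: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One traitgram segment per branch: (parent age, parent estimate)
    -> (child age, child estimate).

    ``tags`` optionally maps tip ids to lineage labels; a branch takes
    a label when all tips below it share it, else ``"other"``, so the
    labels partition the branches.
    """
    tipsets = tree.clade_tipsets()
    rows = []
    for node in tree.postorder():
        if node.parent is None:
            continue
        tag = ""
        if tags is not None:
            below = {tags.get(t, "other") for t in tipsets[node.id]}
            tag = below.pop() if len(below) == 1 else "other"
        rows.append(
            dict(
                branch_id=node.id,
                parent_age=node.parent.age,
                parent_value=result.estimates[node.parent.id],
                child_age=node.age,
                child_value=result.estimates[node.id],
                tag=tag,
            )
        )
    return pd.DataFrame(rows)
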