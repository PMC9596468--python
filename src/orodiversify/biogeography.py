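"""Maximum-likelihood historical biogeography: DEC and DIVALIKE, ±J.

Geographic ranges are non-empty subsets of a small ordered area set.
Range evolution has two layers:

* **anagenesis** along branches — a continuous-time Markov chain in
  which an unoccupied area is gained at rate ``d`` and an occupied area
  is lost at rate ``e`` (losses that would empty the range are
  forbidden; the empty range is not modelled);
* **cladogenesis** at nodes — the ancestral range is partitioned
  between the two daughters according to the model family.  DEC allows
  narrow sympatry, subset sympatry and single-area vicariance;
  DIVALIKE allows narrow sympatry and unrestricted vicariance.  The
  optional founder-event ("jump", +J) class lets one daughter start in
  a single area outside the ancestral range.

Per enumerated daughter pair the weight is ``(3 - j) / 3`` for the
sympatry/vicariance classes and ``j`` for jumps, normalised per
ancestral state — the canonical +J parameterisation, so ``j = 0``
recovers the base model exactly.

The likelihood is computed by Felsenstein pruning with per-branch
transition matrices ``exp(Q t)`` and cladogenetic mixing at nodes; the
root state prior is uniform over allowed states.  Marginal ancestral
ranges come from a combined up/down pass conditioning on all tips.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from .io_model import AreaCoding, TimeTree

__all__ = [
    "GeoStateSpace",
    "GeoParams",
    "GeoFitResult",
    "build_state_space",
    "anagenetic_Q",
    "cladogenesis_table",
    "geo_likelihood",
    "fit_geo_model",
    "ancestral_ranges",
    "compare_models",
]

FAMILIES = ("DEC", "DIVALIKE")


@dataclass(frozen=True)
class GeoStateSpace:
    """All non-empty ranges over an ordered area set, indexed stably
    (sorted by range size, then lexicographically by area indices)."""

    areas: tuple[str, ...]
    max_range_size: int
    states: tuple[frozenset[str], ...]
    index: Mapping[frozenset[str], int]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def label(self, i: int) -> str:
        return "".join(a for a in self.areas if a in self.states[i])


def build_state_space(areas: Sequence[str], max_range_size: int | None = None) -> GeoStateSpace:
    areas = tuple(areas)
    n = len(areas)
    if not 1 <= n <= 5:
        raise ValueError(f"need between 1 and 5 areas, got {n}")
    m = max_range_size if max_range_size is not None else n
    if not 1 <= m <= n:
        raise ValueError(f"max_range_size {m} outside [1, {n}]")
    order = {a: i for i, a in enumerate(areas)}
    states: list[frozenset[str]] = []
    for k in range(1, m + 1):
        for combo in combinations(areas, k):
            states.append(frozenset(combo))
    states.sort(key=lambda s: (len(s), tuple(sorted(order[a] for a in s))))
    return GeoStateSpace(
        areas=areas,
        max_range_size=m,
        states=tuple(states),
        index={s: i for i, s in enumerate(states)},
    )


@dataclass
class GeoParams:
    """DEC-family rates: area gain ``d`` and loss ``e`` (events/Ma), and
    the founder-event weight ``j`` in [0, 3)."""

    d: float
    e: float
    j: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0:
            raise ValueError("rates d and e must be non-negative")
        if not 0.0 <= self.j < 3.0:
            raise ValueError("j must be in [0, 3)")


def anagenetic_Q(space: GeoStateSpace, d: float, e: float) -> np.ndarray:
    """Rate matrix over ranges: +d per addable area, +e per losable
    occupied area; losses from single-area ranges are forbidden."""
    S = space.n_states
    Q = np.zeros((S, S))
    for i, s in enumerate(space.states):
        # gains
        if len(s) < space.max_range_size:
            for a in space.areas:
                if a not in s:
                    t = s | {a}
                    if t in space.index:
                        Q[i, space.index[t]] += d
        # losses (never to the empty range)
        if len(s) > 1:
            for a in s:
                t = s - {a}
                Q[i, space.index[t]] += e
        Q[i, i] = -Q[i].sum()
    return Q


def cladogenesis_table(
    space: GeoStateSpace,
    family: str = "DEC",
    j: float = 0.0,
    plus_j: bool | None = None,
) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Enumerate cladogenetic daughter pairs per ancestral state.

    Returns ``{ancestral index: (left indices, right indices, probs)}``
    with probabilities summing to 1 per ancestral state.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    if plus_j is None:
        plus_j = j > 0
    if j > 0 and not plus_j:
        raise ValueError("j > 0 requires the +J model variant")
    w_event = (3.0 - j) / 3.0
    table: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for i, s in enumerate(space.states):
        pairs: list[tuple[int, int, float]] = []

        def add(lft: frozenset[str], rgt: frozenset[str], w: float) -> None:
            if lft in space.index and rgt in space.index:
                pairs.append((space.index[lft], space.index[rgt], w))

        if len(s) == 1:
            add(s, s, w_event)  # narrow sympatry
        else:
            members = sorted(s)
            if family == "DEC":
                for a in s:
                    sa = frozenset([a])
                    add(s, sa, w_event)  # subset sympatry
                    add(sa, s, w_event)
                # single-area vicariance: each ordered bipartition with a
                # singleton daughter, enumerated once
                for mask in range(1, 2 ** len(members) - 1):
                    lft = frozenset(
                        m for k, m in enumerate(members) if mask >> k & 1
                    )
                    if min(len(lft), len(s) - len(lft)) == 1:
                        add(lft, s - lft, w_event)
            else:  # DIVALIKE: every bipartition into two non-empty ranges
                for mask in range(1, 2 ** len(members) - 1):
                    lft = frozenset(
                        m for k, m in enumerate(members) if mask >> k & 1
                    )
                    add(lft, s - lft, w_event)
        if plus_j and j > 0:
            for a in space.areas:
                if a not in s:
                    sa = frozenset([a])
                    add(s, sa, j)
                    add(sa, s, j)
        iL = np.array([p[0] for p in pairs], dtype=int)
        iR = np.array([p[1] for p in pairs], dtype=int)
        w = np.array([p[2] for p in pairs], dtype=float)
        total = w.sum()
        if total <= 0:
            raise ValueError(f"no cladogenetic outcome for state {space.label(i)}")
        table[i] = (iL, iR, w / total)
    return table


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------

def _propagators(Q: np.ndarray, durations: Sequence[float]) -> dict[float, np.ndarray]:
    """exp(Q t) for each distinct duration, via eigendecomposition with an
    expm fallback for ill-conditioned Q."""
    uniq = sorted(set(float(t) for t in durations))
    S = Q.shape[0]
    out: dict[float, np.ndarray] = {}
    try:
        lam, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e10:
        for t in uniq:
            P = (V * np.exp(lam * t)) @ Vinv
            P = np.real(P)
            np.clip(P, 0.0, None, out=P)
            out[t] = P
    else:
        for t in uniq:
            out[t] = np.clip(expm(Q * t), 0.0, None)
    return out


def _tip_vectors(
    tree: TimeTree, coding: AreaCoding, space: GeoStateSpace
) -> dict[str, np.ndarray]:
    vecs: dict[str, np.ndarray] = {}
    for tip in tree.tips():
        if tip.id not in coding.ranges:
            raise KeyError(f"tip {tip.id!r} missing from the area coding")
        rng = coding.ranges[tip.id]
        if rng not in space.index:
            raise KeyError(
                f"observed range {sorted(rng)} of tip {tip.id!r} is not a "
                "modelled state"
            )
        v = np.zeros(space.n_states)
        v[space.index[rng]] = 1.0
        vecs[tip.id] = v
    return vecs


def _pruning_pass(
    tree: TimeTree,
    coding: AreaCoding,
    space: GeoStateSpace,
    params: GeoParams,
    family: str,
    plus_j: bool,
):
    """Shared pruning machinery: per-node conditional vectors, branch
    messages, log-scaling factors and the transition matrices."""
    Q = anagenetic_Q(space, params.d, params.e)
    clado = cladogenesis_table(space, family, params.j, plus_j=plus_j)
    props = _propagators(Q, [n.duration for n in tree.postorder() if n.parent])
    tipvec = _tip_vectors(tree, coding, space)

    L: dict[str, np.ndarray] = {}       # conditional at node (post-clado below)
    msg: dict[str, np.ndarray] = {}     # likelihood below child given start state
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_tip:
            vec = tipvec[node.id]
        else:
            c1, c2 = node.children
            m1 = props[float(c1.duration)] @ L[c1.id]
            m2 = props[float(c2.duration)] @ L[c2.id]
            msg[c1.id], msg[c2.id] = m1, m2
            vec = np.zeros(space.n_states)
            for s in range(space.n_states):
                iL, iR, p = clado[s]
                vec[s] = float(np.sum(p * m1[iL] * m2[iR]))
        top = vec.max()
        if top <= 0.0:
            return None, None, -np.inf, props, clado
        L[node.id] = vec / top
        log_scale += np.log(top)
    prior = np.full(space.n_states, 1.0 / space.n_states)
    lnL = float(np.log(prior @ L[tree.root.id]) + log_scale)
    return L, msg, lnL, props, clado


def geo_likelihood(
    tree: TimeTree,
    coding: AreaCoding,
    space: GeoStateSpace,
    params: GeoParams,
    family: str = "DEC",
    plus_j: bool | None = None,
) -> float:
    """Log-likelihood of the tip ranges under the chosen model."""
    if plus_j is None:
        plus_j = params.j > 0
    _, _, lnL, _, _ = _pruning_pass(tree, coding, space, params, family, plus_j)
    return lnL


def ancestral_ranges(
    tree: TimeTree,
    coding: AreaCoding,
    space: GeoStateSpace,
    params: GeoParams,
    family: str = "DEC",
    plus_j: bool | None = None,
) -> dict[str, np.ndarray]:
    """Marginal state probabilities at every node, conditioning on all
    tips (up/down pass).  Each node's vector sums to 1."""
    if plus_j is None:
        plus_j = params.j > 0
    L, msg, lnL, props, clado = _pruning_pass(
        tree, coding, space, params, family, plus_j
    )
    if not np.isfinite(lnL):
        raise ValueError("data have zero likelihood under these parameters")
    S = space.n_states
    U: dict[str, np.ndarray] = {tree.root.id: np.full(S, 1.0 / S)}
    for node in tree.preorder():
        if node.is_tip:
            continue
        c1, c2 = node.children
        for child, sib in ((c1, c2), (c2, c1)):
            left = child is c1
            # weight arriving at each daughter-start state a of `child`
            start = np.zeros(S)
            for s in range(S):
                iL, iR, p = clado[s]
                own = iL if left else iR
                oth = iR if left else iL
                contrib = p * msg[sib.id][oth] * U[node.id][s]
                np.add.at(start, own, contrib)
            u = start @ props[float(child.duration)]
            tot = u.sum()
            U[child.id] = u / tot if tot > 0 else u
    marginals: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        m = U[node.id] * L[node.id]
        marginals[node.id] = m / m.sum()
    return marginals


# ---------------------------------------------------------------------------
# model fitting and comparison
# ---------------------------------------------------------------------------

@dataclass
class GeoFitResult:
    """A fitted range-evolution model: MLE parameters, lnL, AIC and
    (optionally) per-node marginal ancestral-range probabilities."""

    family: str
    plus_j: bool
    params: GeoParams
    lnL: float
    k: int
    aic: float
    data_key: str
    space: GeoStateSpace
    marginals: dict[str, np.ndarray] | None = None

    @property
    def model_name(self) -> str:
        return self.family + ("+J" if self.plus_j else "")


def _data_fingerprint(tree: TimeTree, coding: AreaCoding) -> str:
    tipsets = tree.clade_tipsets()
    parts = []
    for node in tree.postorder():
        parts.append(",".join(sorted(tipsets[node.id])) + f"@{node.age:.9f}")
    for taxon in sorted(coding.ranges):
        parts.append(taxon + "=" + "".join(sorted(coding.ranges[taxon])))
    blob = ";".join(parts).encode()
    return hashlib.sha1(blob).hexdigest()[:16]


_LOG_LO, _LOG_HI = np.log10(1e-6), np.log10(10.0)
_J_HI = 2.99999
_RATE_STARTS = (0.01, 0.1, 1.0)
_J_STARTS = (0.0, 0.5, 2.0)


def fit_geo_model(
    tree: TimeTree,
    coding: AreaCoding,
    family: str = "DEC",
    plus_j: bool = False,
    max_range_size: int | None = None,
    compute_marginals: bool = True,
) -> GeoFitResult:
    """Bounded deterministic ML fit from a fixed multi-start grid.

    ``d`` and ``e`` are optimised on a log10 scale in [1e-6, 10]; ``j``
    (when enabled) on [0, 2.99999].  Nelder-Mead from every grid start;
    the best optimum wins.
    """
    space = build_state_space(coding.areas, max_range_size)

    def unpack(x: np.ndarray) -> GeoParams:
        d = 10.0 ** x[0]
        e = 10.0 ** x[1]
        j = float(np.clip(x[2], 0.0, _J_HI)) if plus_j else 0.0
        return GeoParams(d=d, e=e, j=j)

    def nll(x: np.ndarray) -> float:
        lnL = geo_likelihood(tree, coding, space, unpack(x), family, plus_j)
        return -lnL if np.isfinite(lnL) else 1e12

    bounds = [(_LOG_LO, _LOG_HI), (_LOG_LO, _LOG_HI)]
    starts = [
        [np.log10(d0), np.log10(e0)] for d0 in _RATE_STARTS for e0 in _RATE_STARTS
    ]
    if plus_j:
        bounds.append((0.0, _J_HI))
        starts = [s + [j0] for s in starts for j0 in _J_STARTS]

    best = None
    for x0 in starts:
        res = minimize(
            nll,
            np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            bounds=bounds,
            options=dict(xatol=1e-6, fatol=1e-9, maxiter=2000),
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("likelihood non-finite at every start point")
    params = unpack(best.x)
    lnL = -float(best.fun)
    k = 3 if plus_j else 2
    fit = GeoFitResult(
        family=family,
        plus_j=plus_j,
        params=params,
        lnL=lnL,
        k=k,
        aic=2 * k - 2 * lnL,
        data_key=_data_fingerprint(tree, coding),
        space=space,
    )
    if compute_marginals:
        fit.marginals = ancestral_ranges(tree, coding, space, params, family, plus_j)
    return fit


def compare_models(fits: Sequence[GeoFitResult]) -> pd.DataFrame:
    """Rank fits by AIC (ascending) with a ΔAIC column; for each nested
    base/+J pair on the same family, a χ²(1 df) LRT p-value is attached
    to the +J row."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    keys = {f.data_key for f in fits}
    if len(keys) != 1:
        raise ValueError("fits were computed on different data")
    rows = []
    by_model = {(f.family, f.plus_j): f for f in fits}
    for f in fits:
        lrt_stat = lrt_p = np.nan
        if f.plus_j and (f.family, False) in by_model:
            base = by_model[(f.family, False)]
            lrt_stat = max(0.0, 2.0 * (f.lnL - base.lnL))
            lrt_p = float(chi2.sf(lrt_stat, df=1))
        rows.append(dict(model=f.model_name, family=f.family, plus_j=f.plus_j,
                         lnL=f.lnL, k=f.k, AIC=f.aic,
                         d=f.params.d, e=f.params.e, j=f.params.j,
                         lrt_stat=lrt_stat, lrt_p=lrt_p))
    df = pd.DataFrame(rows).sort_values("AIC", kind="stable").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    return df
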