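"""Synthetic-data generators for every pipeline stage.

Each generator produces inputs with exactly the statistical structure
the corresponding estimator assumes, with known ground truth, so the
whole pipeline is testable at desk scale:

* pure-birth time trees with pseudo credibility intervals on node ages;
* four-taxon site-pattern alignments with a controllable ABBA excess
  (closed-form true D);
* multi-species supermatrices with introgression planted between
  designated groups;
* forward-simulated DEC range histories (Gillespie anagenesis plus
  cladogenetic draws) with the true range recorded at every node;
* Brownian traits with true node values;
* orthogroup sets with exactly planted missingness, ambiguity and
  taxon coverage.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biogeography import GeoParams, GeoStateSpace, build_state_space, cladogenesis_table
from .dataset_builder import OrthogroupSet, Supermatrix, concatenate
from .io_model import Alignment, AreaCoding, GroupScheme, TimeTree, TreeNode

__all__ = [
    "QuartetSimSpec",
    "DECSimSpec",
    "DECHistory",
    "simulate_time_tree",
    "simulate_quartet_alignment",
    "simulate_supermatrix_with_introgression",
    "simulate_dec_history",
    "simulate_bm",
    "make_orthogroup_fixtures",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# time trees
# ---------------------------------------------------------------------------

def simulate_time_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> TimeTree:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips.

    Tips sit at age 0; every internal node gets a pseudo 95% interval
    of +/-10% of its age, standing in for dating uncertainty.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    node_counter = iter(range(10**9))
    serial_counter = iter(range(10**9))
    root = TreeNode(id=f"node{next(node_counter)}")
    depth = {root.id: 0.0}
    serial: dict[str, int] = {}

    def new_leaf(parent: TreeNode) -> TreeNode:
        child = TreeNode(id=f"tmp{next(serial_counter)}", parent=parent)
        serial[child.id] = len(serial)
        parent.children.append(child)
        return child

    active = [new_leaf(root), new_leaf(root)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.id = f"node{next(node_counter)}"
        depth[node.id] = t
        active.extend([new_leaf(node), new_leaf(node)])
    present = t + rng.exponential(1.0 / (birth_rate * n_tips))
    for i, tip in enumerate(sorted(active, key=lambda n: serial[n.id])):
        tip.id = f"t{i}"
        depth[tip.id] = present

    def set_ages(node: TreeNode) -> None:
        node.age = present - depth[node.id]
        if not node.is_tip:
            node.hpd = (0.9 * node.age, 1.1 * node.age)
        for c in node.children:
            set_ages(c)

    set_ages(root)
    return TimeTree(root)


# ---------------------------------------------------------------------------
# quartet site patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuartetSimSpec:
    """Multinomial site-class mixture for a 4-taxon alignment.

    Class probabilities must sum to 1; the implied true D is
    (p_abba - p_baba) / (p_abba + p_baba).
    """

    n_sites: int
    p_abba: float
    p_baba: float
    p_other_biallelic: float
    p_invariant: float
    seed: int = 0
    taxa: tuple[str, str, str, str] = ("P1", "P2", "P3", "O")

    def __post_init__(self) -> None:
        probs = (self.p_abba, self.p_baba, self.p_other_biallelic,
                 self.p_invariant)
        if any(p < 0 for p in probs):
            raise ValueError("negative class probability")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")

    @property
    def true_d(self) -> float:
        denom = self.p_abba + self.p_baba
        return 0.0 if denom == 0 else (self.p_abba - self.p_baba) / denom


# masks over (P1, P2, P3, O): bit k set => taxon k carries the derived base.
# A mask and its complement give the same observable site pattern (which of
# the two bases is "derived" is invisible), so the complements of the
# ABBA/BABA masks are excluded from the "other biallelic" class too.
_ABBA_MASK = 0b0110
_BABA_MASK = 0b0101
_OTHER_MASKS = np.array(
    [
        m
        for m in range(1, 15)
        if m not in (_ABBA_MASK, _BABA_MASK, _ABBA_MASK ^ 0xF, _BABA_MASK ^ 0xF)
    ],
    dtype=int,
)


def _sites_from_masks(masks: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Realise per-site derived/ancestral masks as bases: ancestral base
    x and derived base y drawn per site with x != y.  Returns (4, n)."""
    n = masks.size
    x = rng.integers(0, 4, size=n)
    y = (x + rng.integers(1, 4, size=n)) % 4
    out = np.empty((4, n), dtype=np.uint8)
    for k in range(4):
        derived = (masks >> k & 1).astype(bool)
        out[k] = np.where(derived, _BASES[y], _BASES[x])
    return out


def simulate_quartet_alignment(spec: QuartetSimSpec) -> Alignment:
    """Draw a 4-taxon alignment from the multinomial site-class mix."""
    rng = np.random.default_rng(spec.seed)
    classes = rng.choice(
        4,
        size=spec.n_sites,
        p=[spec.p_abba, spec.p_baba, spec.p_other_biallelic, spec.p_invariant],
    )
    masks = np.zeros(spec.n_sites, dtype=int)
    masks[classes == 0] = _ABBA_MASK
    masks[classes == 1] = _BABA_MASK
    n_other = int((classes == 2).sum())
    masks[classes == 2] = rng.choice(_OTHER_MASKS, size=n_other)
    sites = _sites_from_masks(masks, rng)
    seqs = {t: sites[k].tobytes().decode() for k, t in enumerate(spec.taxa)}
    return Alignment(list(spec.taxa), seqs)


# ---------------------------------------------------------------------------
# supermatrix with planted introgression
# ---------------------------------------------------------------------------

def simulate_supermatrix_with_introgression(
    scheme: GroupScheme,
    gamma: float,
    n_sites: int = 20000,
    seed: int = 0,
    p_invariant: float = 0.80,
    p_baseline: float = 0.02,
    p_flow: float = 0.06,
    noise: float = 0.005,
) -> tuple[Supermatrix, GroupScheme]:
    """Multi-species matrix with a P2-P3 ABBA excess proportional to
    ``gamma``.

    Site classes are drawn at the group level (all members of a group
    share the class base) with pABBA = p_baseline + gamma * p_flow and
    pBABA = p_baseline, so gamma = 0 yields exchangeable ABBA/BABA.
    Independent per-taxon noise substitutions decorrelate quartets.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p_abba = p_baseline + gamma * p_flow
    p_baba = p_baseline
    p_other = max(0.0, 1.0 - p_invariant - p_abba - p_baba)
    taxa = sorted(scheme.p1 | scheme.p2 | scheme.p3) + [scheme.outgroup]
    group_of = {t: 0 for t in scheme.p1}
    group_of.update({t: 1 for t in scheme.p2})
    group_of.update({t: 2 for t in scheme.p3})
    group_of[scheme.outgroup] = 3

    classes = rng.choice(4, size=n_sites, p=[p_abba, p_baba, p_other, p_invariant])
    masks = np.zeros(n_sites, dtype=int)
    masks[classes == 0] = _ABBA_MASK
    masks[classes == 1] = _BABA_MASK
    n_other = int((classes == 2).sum())
    masks[classes == 2] = rng.choice(_OTHER_MASKS, size=n_other)
    group_sites = _sites_from_masks(masks, rng)  # (4 groups, n_sites)

    seqs: dict[str, str] = {}
    for t in taxa:
        row = group_sites[group_of[t]].copy()
        flip = rng.random(n_sites) < noise
        row[flip] = _BASES[rng.integers(0, 4, size=int(flip.sum()))]
        seqs[t] = row.tobytes().decode()
    aln = Alignment(taxa, seqs)
    ogs = OrthogroupSet({"sim_gene": aln}, level="species")
    return concatenate(ogs), scheme


# ---------------------------------------------------------------------------
# DEC forward histories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DECSimSpec:
    """Forward-simulation settings for a range-evolution history."""

    areas: tuple[str, ...]
    params: GeoParams
    family: str = "DEC"
    plus_j: bool = False
    n_tips: int = 20
    birth_rate: float = 1.0
    seed: int = 0
    tree: TimeTree | None = None
    max_range_size: int | None = None


@dataclass
class DECHistory:
    """A simulated range history with full ground truth."""

    tree: TimeTree
    space: GeoStateSpace
    coding: AreaCoding
    node_ranges: dict[str, frozenset[str]]

    def planted_events(self, focal_area: str) -> list[dict]:
        """Derive the true event list from the true node ranges.

        Independent inline logic (not the classifier module): in situ
        diversification once per internal node whose range touches the
        focal area and with >= 1 daughter touching it; colonization per
        branch from a non-touching parent to a touching child.
        """
        touches = {
            nid: focal_area in rng for nid, rng in self.node_ranges.items()
        }
        events: list[dict] = []
        for node in self.tree.postorder():
            if node.is_tip:
                continue
            kids_in = [c for c in node.children if touches[c.id]]
            if touches[node.id] and kids_in:
                events.append(dict(branch_id=node.id, type="in_situ",
                                   age=node.age))
            if not touches[node.id]:
                for child in kids_in:
                    events.append(dict(branch_id=child.id, type="colonization",
                                       age=(node.age + child.age) / 2.0))
        events.sort(key=lambda ev: (ev["age"], ev["branch_id"]))
        return events


def _gillespie_branch(
    state: frozenset[str],
    duration: float,
    space: GeoStateSpace,
    params: GeoParams,
    rng: np.random.Generator,
) -> frozenset[str]:
    """Anagenesis along one branch: gains at rate d per addable area,
    losses at rate e per occupied area (singletons cannot go extinct)."""
    t = 0.0
    while True:
        gains = (
            [a for a in space.areas if a not in state]
            if len(state) < space.max_range_size
            else []
        )
        losses = sorted(state) if len(state) > 1 else []
        total = params.d * len(gains) + params.e * len(losses)
        if total <= 0:
            return state
        t += rng.exponential(1.0 / total)
        if t >= duration:
            return state
        u = rng.random() * total
        if u < params.d * len(gains):
            area = gains[int(u / params.d)] if params.d > 0 else gains[0]
            state = state | {area}
        else:
            u -= params.d * len(gains)
            area = losses[int(u / params.e)]
            state = state - {area}


def simulate_dec_history(spec: DECSimSpec) -> DECHistory:
    """Forward-simulate a range history on a (given or simulated) tree.

    The root range is drawn from the uniform state prior; cladogenetic
    outcomes are drawn from the model's cladogenesis table; anagenesis
    follows the Gillespie algorithm matching the anagenetic generator.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree or simulate_time_tree(
        spec.n_tips, spec.birth_rate, seed=int(rng.integers(2**31))
    )
    space = build_state_space(spec.areas, spec.max_range_size)
    clado = cladogenesis_table(space, spec.family, spec.params.j, spec.plus_j)
    node_ranges: dict[str, frozenset[str]] = {}

    root_state_i = int(rng.integers(space.n_states))
    node_ranges[tree.root.id] = space.states[root_state_i]

    def descend(node: TreeNode) -> None:
        if node.is_tip:
            return
        s_i = space.index[node_ranges[node.id]]
        iL, iR, p = clado[s_i]
        k = rng.choice(len(p), p=p)
        for child, start_i in zip(node.children, (iL[k], iR[k])):
            start = space.states[int(start_i)]
            node_ranges[child.id] = _gillespie_branch(
                start, child.duration, space, spec.params, rng
            )
            descend(child)

    descend(tree.root)
    coding = AreaCoding(
        areas=spec.areas,
        ranges={t.id: node_ranges[t.id] for t in tree.tips()},
    )
    return DECHistory(tree=tree, space=space, coding=coding,
                      node_ranges=node_ranges)


# ---------------------------------------------------------------------------
# Brownian traits
# ---------------------------------------------------------------------------

def simulate_bm(
    tree: TimeTree, sigma2: float, root_value: float, seed: int = 0
) -> tuple[dict[str, float], dict[str, float]]:
    """Brownian motion down the tree: Gaussian increments with variance
    sigma^2 * branch duration.  Returns (tip traits, all node values)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {tree.root.id: float(root_value)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        sd = np.sqrt(sigma2 * node.duration)
        values[node.id] = values[node.parent.id] + rng.normal(0.0, sd)
    tips = {t.id: values[t.id] for t in tree.tips()}
    return tips, values


# ---------------------------------------------------------------------------
# orthogroup fixtures with planted metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFixtureSpec:
    """Planted per-gene quality levels for one fixture gene."""

    missing: float = 0.0
    ambiguous: float = 0.0
    n_absent_taxa: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing <= 1.0 or not 0.0 <= self.ambiguous <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
        if self.missing + self.ambiguous > 1.0:
            raise ValueError("missing + ambiguous exceed the cell count")


def make_orthogroup_fixtures(
    specs: Sequence[GeneFixtureSpec],
    taxa: Sequence[str],
    length: int = 120,
    seed: int = 0,
    groups: Mapping[str, str] | None = None,
    divergence: float = 0.0,
) -> tuple[OrthogroupSet, pd.DataFrame]:
    """Build genes whose missing/ambiguous fractions and taxon coverage
    are planted exactly, and record the realised per-gene metrics.

    With ``groups`` (e.g. a sample->species map), taxa of one group
    share a base sequence and each copy is then mutated at rate
    ``divergence`` per site, mimicking near-identical conspecific
    consensus sequences; without it every taxon draws an independent
    random sequence.  The returned frame holds, per gene, the realised
    ``missing``, ``ambiguous`` and ``coverage`` fractions recounted
    directly from the constructed cells (the construction record used
    as an oracle for the filter).
    """
    rng = np.random.default_rng(seed)
    taxa = list(taxa)
    genes: dict[str, Alignment] = {}
    rows = []
    for g, spec in enumerate(specs):
        gid = f"gene{g:04d}"
        present = taxa[: len(taxa) - spec.n_absent_taxa]
        if not present:
            raise ValueError("at least one taxon must remain present")
        if groups is None:
            mat = _BASES[rng.integers(0, 4, size=(len(present), length))]
        else:
            group_ids = sorted({groups.get(t, t) for t in present})
            group_seq = {
                gr: rng.integers(0, 4, size=length) for gr in group_ids
            }
            rows_ = []
            for t in present:
                codes = group_seq[groups.get(t, t)].copy()
                flip = rng.random(length) < divergence
                codes[flip] = (codes[flip] + rng.integers(1, 4, int(flip.sum()))) % 4
                rows_.append(_BASES[codes])
            mat = np.stack(rows_)
        cells = len(present) * length
        n_missing = round(spec.missing * cells)
        n_ambig = round(spec.ambiguous * cells)
        flat = rng.permutation(cells)
        miss_idx, amb_idx = flat[:n_missing], flat[n_missing:n_missing + n_ambig]
        view = mat.reshape(-1)
        view[miss_idx] = ord("N")
        view[amb_idx] = ord("R")
        seqs = {t: mat[i].tobytes().decode() for i, t in enumerate(present)}
        genes[gid] = Alignment(present, seqs)
        covered = sum(
            1 for t in present if any(c not in "-N" for c in seqs[t])
        )
        rows.append(
            dict(
                gene=gid,
                missing=n_missing / cells,
                ambiguous=n_ambig / cells,
                coverage=covered / len(taxa),
            )
        )
    record = pd.DataFrame(rows).set_index("gene")
    return OrthogroupSet(genes, level="individual"), record
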