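"""Shared data model and file I/O.

Defines the containers every downstream stage consumes — sequence
alignments, time-calibrated trees, taxon-grouping schemes, geographic
range codings and continuous trait tables — together with readers and
writers for the plain-text formats they live in (FASTA, Newick/NEXUS,
TSV).

Conventions
-----------
* Node ages increase into the past and are measured in Ma before
  present; extant tips sit at age 0.
* A geographic range is a non-empty frozenset of area codes.
* 95% credibility intervals on node ages (HPDs) may arrive either as
  BEAST-style node comments ``[&95%HPD={lo,hi}]`` or as a sidecar TSV
  keyed by the sorted tip set of each clade; the sidecar wins when both
  are present.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "TreeNode",
    "TimeTree",
    "GroupScheme",
    "AreaCoding",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_time_tree",
    "write_time_tree",
    "read_group_scheme",
    "read_area_coding",
    "read_trait_map",
    "read_sample_map",
]

#: nucleotide alphabet handled throughout: the four bases, IUPAC
#: ambiguity codes, gap and missing symbols.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}
BASES = frozenset("ACGT")
MISSING = frozenset("-N")
VALID_CHARS = frozenset(IUPAC_SETS) | frozenset("-")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A multiple sequence alignment with uniquely named rows.

    Sequences are upper-case strings over A/C/G/T, IUPAC ambiguity
    codes, ``-`` (gap) and ``N`` (missing); ``?`` is normalised to ``N``
    on construction.
    """

    taxa: list[str]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise FormatError(f"duplicate taxon ids: {dupes}")
        norm = {}
        length = None
        for t in self.taxa:
            s = self.sequences[t].upper().replace("?", "N")
            bad = set(s) - VALID_CHARS
            if bad:
                raise FormatError(f"invalid characters {sorted(bad)} in sequence {t!r}")
            if length is None:
                length = len(s)
            elif len(s) != length:
                raise FormatError(
                    f"unequal sequence lengths: {t!r} has {len(s)}, expected {length}"
                )
            norm[t] = s
        self.sequences = norm

    @property
    def length(self) -> int:
        """Number of aligned sites."""
        if not self.taxa:
            return 0
        return len(self.sequences[self.taxa[0]])

    @property
    def ntaxa(self) -> int:
        return len(self.taxa)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.taxa == other.taxa and self.sequences == other.sequences

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        missing = [t for t in taxa if t not in self.sequences]
        if missing:
            raise KeyError(f"taxa absent from alignment: {missing}")
        return Alignment(list(taxa), {t: self.sequences[t] for t in taxa})


def read_fasta(path: str | Path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    taxa = [r.id for r in records]
    seqs = {r.id: str(r.seq) for r in records}
    if len(set(taxa)) != len(taxa):
        raise FormatError(f"duplicate taxon ids in {path}")
    return Alignment(taxa, seqs)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(aln.sequences[t]), id=t, description="") for t in aln.taxa]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Time tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of a :class:`TimeTree`.

    ``age`` is in Ma before present; ``hpd`` the optional 95%
    credibility interval of the age.
    """

    id: str
    age: float = 0.0
    hpd: tuple[float, float] | None = None
    label: str | None = None
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def duration(self) -> float:
        """Length of the branch subtending this node, in Ma."""
        if self.parent is None:
            return 0.0
        return self.parent.age - self.age


class TimeTree:
    """A rooted, binary, time-calibrated tree.

    Invariants: parent age >= child age on every branch; when an HPD is
    present it brackets the node age.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._index: dict[str, TreeNode] = {}
        for node in self.postorder():
            if node.id in self._index:
                raise FormatError(f"duplicate node id {node.id!r}")
            self._index[node.id] = node
        self.validate()

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        def walk(n: TreeNode) -> Iterator[TreeNode]:
            for c in n.children:
                yield from walk(c)
            yield n

        yield from walk(self.root)

    def preorder(self) -> Iterator[TreeNode]:
        def walk(n: TreeNode) -> Iterator[TreeNode]:
            yield n
            for c in n.children:
                yield from walk(c)

        yield from walk(self.root)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_tip]

    def node(self, node_id: str) -> TreeNode:
        return self._index[node_id]

    @property
    def taxa(self) -> list[str]:
        return [t.id for t in self.tips()]

    def validate(self) -> None:
        for node in self.postorder():
            if not node.is_tip and len(node.children) != 2:
                raise FormatError(
                    f"tree is not binary: node {node.id!r} has "
                    f"{len(node.children)} children"
                )
            if node.parent is not None and node.parent.age < node.age - 1e-9:
                raise FormatError(
                    f"parent younger than child at node {node.id!r}: "
                    f"{node.parent.age} < {node.age}"
                )
            if node.hpd is not None:
                lo, hi = node.hpd
                if not (lo - 1e-9 <= node.age <= hi + 1e-9):
                    raise FormatError(
                        f"age {node.age} outside HPD [{lo}, {hi}] at node {node.id!r}"
                    )

    def clade_tipsets(self) -> dict[str, frozenset[str]]:
        """Map node id -> set of tip ids below it (tips map to themselves)."""
        out: dict[str, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_tip:
                out[node.id] = frozenset([node.id])
            else:
                out[node.id] = frozenset().union(*(out[c.id] for c in node.children))
        return out


_HPD_RE = re.compile(r"95%?\s*HPD\s*[_a-z]*\s*=?\s*\{([^}]+)\}", re.IGNORECASE)


def _parse_hpd_comment(comments: Iterable[str]) -> tuple[float, float] | None:
    for comment in comments:
        m = _HPD_RE.search(comment)
        if m:
            parts = m.group(1).split(",")
            lo, hi = float(parts[0]), float(parts[1])
            return (min(lo, hi), max(lo, hi))
    return None


def read_time_tree(
    path: str | Path,
    dialect: str = "auto",
    hpd_table: str | Path | None = None,
) -> TimeTree:
    """Read a rooted binary time tree from Newick or NEXUS.

    Branch lengths are interpreted as durations in Ma and node ages are
    computed with tips at age 0.  HPD intervals are taken from
    BEAST-style node comments when present; a sidecar TSV
    (columns ``tips`` — comma-joined, sorted — ``lo``, ``hi``)
    overrides them.
    """
    path = Path(path)
    if dialect == "auto":
        head = path.read_text().lstrip()[:6].lower()
        dialect = "nexus" if head.startswith("#nexus") else "newick"
    if dialect not in {"newick", "nexus"}:
        raise ValueError(f"unknown tree dialect {dialect!r}")
    dtree = dendropy.Tree.get(
        path=str(path),
        schema=dialect,
        preserve_underscores=True,
        extract_comment_metadata=False,
        suppress_internal_node_taxa=True,
    )
    return _from_dendropy(dtree, hpd_table=hpd_table)


def _from_dendropy(
    dtree: "dendropy.Tree", hpd_table: str | Path | None = None
) -> TimeTree:
    seed = dtree.seed_node
    if len(seed.child_nodes()) != 2:
        raise FormatError(
            f"tree is unrooted or non-binary at the root: {len(seed.child_nodes())} "
            "children (expected 2)"
        )
    for dnode in dtree.preorder_node_iter():
        kids = dnode.child_nodes()
        if kids and len(kids) != 2:
            label = dnode.taxon.label if dnode.taxon else (dnode.label or "<unnamed>")
            raise FormatError(f"non-binary node {label!r} with {len(kids)} children")
        if dnode.edge.length is not None and dnode.edge.length < 0:
            raise FormatError(f"negative branch length {dnode.edge.length}")

    # depth from root, then age = max tip depth on the path below
    depth: dict[int, float] = {id(seed): 0.0}
    for dnode in dtree.preorder_node_iter():
        if dnode is seed:
            continue
        blen = dnode.edge.length if dnode.edge.length is not None else 0.0
        depth[id(dnode)] = depth[id(dnode.parent_node)] + blen
    height: dict[int, float] = {}
    for dnode in dtree.postorder_node_iter():
        kids = dnode.child_nodes()
        if not kids:
            height[id(dnode)] = 0.0
        else:
            height[id(dnode)] = max(
                height[id(k)] + (k.edge.length or 0.0) for k in kids
            )

    counter = iter(range(10**9))

    def build(dnode: "dendropy.Node", parent: TreeNode | None) -> TreeNode:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            if not name:
                raise FormatError("tip without a label")
            node = TreeNode(id=name, age=0.0, parent=parent)
        else:
            node = TreeNode(id=f"node{next(counter)}", age=height[id(dnode)],
                            parent=parent, label=dnode.label)
        hpd = _parse_hpd_comment(dnode.comments or [])
        if hpd is not None:
            node.hpd = hpd
        for kid in dnode.child_nodes():
            node.children.append(build(kid, node))
        return node

    root = build(seed, None)
    tree = TimeTree(root)
    if hpd_table is not None:
        _apply_hpd_sidecar(tree, hpd_table)
        tree.validate()
    return tree


def _apply_hpd_sidecar(tree: TimeTree, path: str | Path) -> None:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"tips", "lo", "hi"}
    if not required.issubset(df.columns):
        raise FormatError(f"HPD sidecar must have columns {sorted(required)}")
    tipsets = {v: k for k, v in tree.clade_tipsets().items()}
    for _, row in df.iterrows():
        key = frozenset(str(row["tips"]).split(","))
        if key not in tipsets:
            raise FormatError(
                f"HPD sidecar tip-set {sorted(key)} matches no clade in the tree"
            )
        node = tree.node(tipsets[key])
        node.hpd = (float(row["lo"]), float(row["hi"]))


def write_time_tree(tree: TimeTree, path: str | Path) -> None:
    """Write Newick with branch lengths and ``[&95%HPD={lo,hi}]`` comments."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip:
            core = node.id
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.hpd is not None:
            core += f"[&95%HPD={{{node.hpd[0]:.10g},{node.hpd[1]:.10g}}}]"
        if node.parent is not None:
            core += f":{node.duration:.10g}"
        return core

    Path(path).write_text(fmt(tree.root) + ";\n")


# ---------------------------------------------------------------------------
# Configuration tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupScheme:
    """Taxon groups for the four-taxon gene-flow test roles.

    ``p1``/``p2``/``p3`` are pairwise-disjoint taxon sets; ``outgroup``
    is a single taxon belonging to none of them.  ``subgroups`` offers
    optional named subsets (e.g. one genus) used to restrict surveys.
    """

    p1: frozenset[str]
    p2: frozenset[str]
    p3: frozenset[str]
    outgroup: str
    subgroups: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = {"P1": self.p1, "P2": self.p2, "P3": self.p3}
        for name, grp in groups.items():
            if not grp:
                raise FormatError(f"group {name} is empty")
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = groups[a] & groups[b]
                if overlap:
                    raise FormatError(
                        f"taxa in both {a} and {b}: {sorted(overlap)}"
                    )
        if any(self.outgroup in g for g in groups.values()):
            raise FormatError(f"outgroup {self.outgroup!r} also assigned to a P group")


@dataclass(frozen=True)
class AreaCoding:
    """Observed geographic ranges: taxon -> non-empty subset of areas."""

    areas: tuple[str, ...]
    ranges: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.areas) > 5:
            raise FormatError("at most 5 areas supported")
        if len(set(self.areas)) != len(self.areas):
            raise FormatError("duplicate area codes")
        areaset = set(self.areas)
        for taxon, rng in self.ranges.items():
            if not rng:
                raise FormatError(f"empty range for taxon {taxon!r}")
            unknown = rng - areaset
            if unknown:
                raise FormatError(
                    f"unknown area code(s) {sorted(unknown)} for taxon {taxon!r}"
                )


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_group_scheme(path: str | Path) -> GroupScheme:
    """Read a TSV with columns ``taxon`` and ``group``.

    ``group`` is one of P1/P2/P3/outgroup, optionally suffixed with a
    named sub-group after a colon (``P1:Eothenomys``).
    """
    df = _read_tsv(path)
    if not {"taxon", "group"}.issubset(df.columns):
        raise FormatError("group table needs columns: taxon, group")
    buckets: dict[str, set[str]] = {"P1": set(), "P2": set(), "P3": set()}
    subgroups: dict[str, set[str]] = {}
    outgroup: str | None = None
    for _, row in df.iterrows():
        taxon = row["taxon"]
        spec = row["group"]
        role, _, sub = spec.partition(":")
        if role in buckets:
            buckets[role].add(taxon)
            if sub:
                subgroups.setdefault(sub, set()).add(taxon)
        elif role.lower() in {"o", "out", "outgroup"}:
            if outgroup is not None and outgroup != taxon:
                raise FormatError("multiple outgroup taxa listed")
            outgroup = taxon
        else:
            raise FormatError(f"unknown group role {role!r} for taxon {taxon!r}")
    if outgroup is None:
        raise FormatError("no outgroup row in group table")
    return GroupScheme(
        p1=frozenset(buckets["P1"]),
        p2=frozenset(buckets["P2"]),
        p3=frozenset(buckets["P3"]),
        outgroup=outgroup,
        subgroups={k: frozenset(v) for k, v in subgroups.items()},
    )


def read_area_coding(path: str | Path, areas: Sequence[str] | None = None) -> AreaCoding:
    """Read a TSV with columns ``taxon`` and ``range``.

    ``range`` concatenates single-letter area codes (``NS`` = {N, S}).
    When ``areas`` is omitted the ordered area list is taken from a
    header comment line ``# areas: N,S,...`` or, failing that, from the
    sorted union of codes seen.
    """
    path = Path(path)
    if areas is None:
        for line in path.read_text().splitlines():
            stripped = line.strip()
            if stripped.startswith("#") and "areas:" in stripped:
                areas = [a.strip() for a in stripped.split("areas:")[1].split(",")]
                break
    df = _read_tsv(path)
    if not {"taxon", "range"}.issubset(df.columns):
        raise FormatError("area table needs columns: taxon, range")
    ranges: dict[str, frozenset[str]] = {}
    for _, row in df.iterrows():
        rng = frozenset(str(row["range"])) if pd.notna(row["range"]) else frozenset()
        ranges[row["taxon"]] = rng
    if areas is None:
        areas = sorted(frozenset().union(*ranges.values()) if ranges else set())
    return AreaCoding(areas=tuple(areas), ranges=ranges)


def read_trait_map(path: str | Path, column: str = "elevation") -> dict[str, float]:
    """Read taxon -> continuous trait (default: elevation in m).

    If ``lo``/``hi`` range columns are present instead of a single
    value column, the midpoint of the range is used.
    """
    df = _read_tsv(path)
    if "taxon" not in df.columns:
        raise FormatError("trait table needs a 'taxon' column")
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        if column in df.columns and pd.notna(row[column]):
            val = float(row[column])
        elif {"lo", "hi"}.issubset(df.columns):
            val = (float(row["lo"]) + float(row["hi"])) / 2.0
        else:
            raise FormatError(f"no {column!r} or lo/hi columns in trait table")
        if not pd.notna(val) or val in (float("inf"), float("-inf")):
            raise FormatError(f"non-finite trait for taxon {row['taxon']!r}")
        out[row["taxon"]] = val
    return out


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read sample -> species mapping (columns ``sample``, ``species``)."""
    df = _read_tsv(path)
    if not {"sample", "species"}.issubset(df.columns):
        raise FormatError("sample map needs columns: sample, species")
    dupes = df["sample"][df["sample"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"samples mapped more than once: {dupes}")
    return dict(zip(df["sample"], df["species"]))
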