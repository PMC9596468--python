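"""Supermatrix construction from per-gene CDS alignments.

Stages: merge individual samples into species consensus sequences,
apply the three per-gene quality filters (ambiguous-base fraction,
missing-data fraction, taxon coverage), concatenate surviving genes
into a partitioned supermatrix, and bin genes by a deterministic
evolutionary-rate proxy.

Filter semantics (fixed, matching the strict wording they implement):
ambiguous < max_ambiguous_fraction, missing < max_missing_fraction,
coverage >= min_taxon_fraction.  Missing counts both ``-`` and ``N``;
ambiguous counts IUPAC codes other than A/C/G/T, excluding gap and N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_model import (
    Alignment,
    BASES,
    IUPAC_SETS,
    MISSING,
    SET_TO_IUPAC,
)

__all__ = [
    "OrthogroupSet",
    "FilterThresholds",
    "Supermatrix",
    "merge_to_species",
    "count_ambiguous",
    "count_missing",
    "taxon_coverage",
    "filter_orthogroups",
    "concatenate",
    "gene_rates",
    "bin_by_rate",
]

#: default thresholds for the individual-level and species-level passes
INDIVIDUAL_LEVEL = dict(max_ambiguous_fraction=0.001,
                        max_missing_fraction=0.60,
                        min_taxon_fraction=0.95)
SPECIES_LEVEL = dict(max_ambiguous_fraction=0.001,
                     max_missing_fraction=0.40,
                     min_taxon_fraction=1.00)


@dataclass
class FilterThresholds:
    """Per-gene retention thresholds, each a fraction in [0, 1]."""

    max_ambiguous_fraction: float = 0.001
    max_missing_fraction: float = 0.60
    min_taxon_fraction: float = 0.95

    def __post_init__(self) -> None:
        for name in ("max_ambiguous_fraction", "max_missing_fraction",
                     "min_taxon_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def individual_level(cls) -> "FilterThresholds":
        return cls(**INDIVIDUAL_LEVEL)

    @classmethod
    def species_level(cls) -> "FilterThresholds":
        return cls(**SPECIES_LEVEL)


@dataclass
class OrthogroupSet:
    """Per-gene alignments keyed by gene id, plus the sample->species map."""

    genes: dict[str, Alignment]
    sample_map: Mapping[str, str] | None = None
    level: str = "individual"  # 'individual' | 'species'

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    @property
    def all_taxa(self) -> list[str]:
        taxa: set[str] = set()
        for aln in self.genes.values():
            taxa.update(aln.taxa)
        return sorted(taxa)


@dataclass
class Supermatrix:
    """Concatenated alignment with a gene partition table.

    ``partitions`` maps gene id to a 0-based half-open column interval;
    the intervals tile ``[0, alignment.length)``.
    """

    alignment: Alignment
    partitions: dict[str, tuple[int, int]]
    completeness: float = field(default=0.0)

    def __post_init__(self) -> None:
        spans = sorted(self.partitions.values())
        pos = 0
        for lo, hi in spans:
            if lo != pos:
                raise ValueError("partitions do not tile the matrix")
            pos = hi
        if pos != self.alignment.length:
            raise ValueError("partitions do not cover the full alignment")


# ---------------------------------------------------------------------------
# species merging
# ---------------------------------------------------------------------------

def _consensus_char(chars: Iterable[str]) -> str:
    """Column consensus: ignore missing; agreeing bases pass through,
    conflicts collapse to the minimal covering IUPAC code."""
    sets = [IUPAC_SETS[c] for c in chars if c not in MISSING and c != "-"]
    if not sets:
        return "N"
    union = frozenset().union(*sets)
    return SET_TO_IUPAC[union]


def merge_to_species(
    ogs: OrthogroupSet, sample_map: Mapping[str, str] | None = None
) -> OrthogroupSet:
    """Merge all individuals of each nominal species into one sequence.

    Per column the consensus ignores gaps and N; agreeing bases are kept
    and genuine conflicts become the minimal IUPAC code covering the
    observed bases.  A species with no data in a gene gets an all-``N``
    row; genes where no species has data are dropped.
    """
    smap = sample_map if sample_map is not None else ogs.sample_map
    if smap is None:
        raise ValueError("a sample->species map is required")
    merged: dict[str, Alignment] = {}
    for gid in ogs.gene_ids:
        aln = ogs.genes[gid]
        unmapped = [t for t in aln.taxa if t not in smap]
        if unmapped:
            raise KeyError(f"samples not in the species map: {unmapped}")
        species = sorted({smap[t] for t in aln.taxa})
        by_species: dict[str, list[str]] = {sp: [] for sp in species}
        for t in aln.taxa:
            by_species[smap[t]].append(aln.sequences[t])
        out: dict[str, str] = {}
        for sp in species:
            seqs = by_species[sp]
            if len(seqs) == 1:
                out[sp] = seqs[0]
            else:
                out[sp] = "".join(
                    _consensus_char(col) for col in zip(*seqs)
                )
        if all(set(s) <= {"N", "-"} for s in out.values()):
            continue  # no species carries data for this gene
        merged[gid] = Alignment(species, out)
    return OrthogroupSet(merged, sample_map=None, level="species")


# ---------------------------------------------------------------------------
# per-gene metrics and filtering
# ---------------------------------------------------------------------------

_AMBIG = frozenset(IUPAC_SETS) - BASES - frozenset("N")


def _char_fractions(aln: Alignment) -> tuple[float, float]:
    if aln.ntaxa == 0 or aln.length == 0:
        raise ValueError("empty alignment")
    total = aln.ntaxa * aln.length
    amb = 0
    miss = 0
    for t in aln.taxa:
        s = aln.sequences[t]
        miss += s.count("-") + s.count("N")
        amb += sum(s.count(c) for c in _AMBIG)
    return amb / total, miss / total


def count_ambiguous(aln: Alignment) -> float:
    """Fraction of cells that are IUPAC ambiguity codes (not A/C/G/T,
    not gap, not N)."""
    return _char_fractions(aln)[0]


def count_missing(aln: Alignment) -> float:
    """Fraction of cells that are gap or N."""
    return _char_fractions(aln)[1]


def taxon_coverage(aln: Alignment, full_taxa: Iterable[str]) -> float:
    """Fraction of the full taxon set present with >= 1 non-missing site."""
    full = sorted(set(full_taxa))
    if not full:
        raise ValueError("empty taxon set")
    present = 0
    for t in full:
        if t in aln.sequences:
            s = aln.sequences[t]
            if any(c not in "-N" for c in s):
                present += 1
    return present / len(full)


def filter_orthogroups(
    ogs: OrthogroupSet,
    thresholds: FilterThresholds | None = None,
    full_taxa: Iterable[str] | None = None,
) -> tuple[OrthogroupSet, pd.DataFrame]:
    """Apply the three per-gene filters; return survivors and a report.

    A gene is retained iff ambiguous < max_ambiguous AND
    missing < max_missing AND coverage >= min_taxon_fraction.
    The report has one row per gene with its metrics, pass flag and
    the first failing criterion.
    """
    thr = thresholds or FilterThresholds()
    taxa = sorted(set(full_taxa)) if full_taxa is not None else ogs.all_taxa
    rows = []
    kept: dict[str, Alignment] = {}
    for gid in ogs.gene_ids:
        aln = ogs.genes[gid]
        amb, miss = _char_fractions(aln)
        cov = taxon_coverage(aln, taxa)
        reason = ""
        if not amb < thr.max_ambiguous_fraction:
            reason = "ambiguous"
        elif not miss < thr.max_missing_fraction:
            reason = "missing"
        elif not cov >= thr.min_taxon_fraction:
            reason = "coverage"
        passed = reason == ""
        if passed:
            kept[gid] = aln
        rows.append(dict(gene=gid, ambiguous=amb, missing=miss,
                         coverage=cov, passed=passed, fail_reason=reason))
    report = pd.DataFrame(rows).set_index("gene")
    return OrthogroupSet(kept, sample_map=ogs.sample_map, level=ogs.level), report


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

def concatenate(ogs: OrthogroupSet) -> Supermatrix:
    """Concatenate genes (lexicographic id order) into one supermatrix.

    Taxa absent from a gene are padded with ``N`` across its partition.
    Completeness is the fraction of non-missing cells.
    """
    if not ogs.genes:
        raise ValueError("no genes to concatenate")
    taxa = ogs.all_taxa
    parts: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for gid in ogs.gene_ids:
        aln = ogs.genes[gid]
        L = aln.length
        parts[gid] = (pos, pos + L)
        pos += L
        pad = "N" * L
        for t in taxa:
            chunks[t].append(aln.sequences.get(t, pad))
    seqs = {t: "".join(chunks[t]) for t in taxa}
    aln = Alignment(taxa, seqs)
    total = aln.ntaxa * aln.length
    missing = sum(s.count("-") + s.count("N") for s in seqs.values())
    return Supermatrix(aln, parts, completeness=1.0 - missing / total)


# ---------------------------------------------------------------------------
# rate proxy and binning
# ---------------------------------------------------------------------------

def _p_distance(a: str, b: str) -> float | None:
    """Pairwise p-distance over sites where both are unambiguous bases."""
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    ok = np.zeros(256, dtype=bool)
    for c in b"ACGT":
        ok[c] = True
    mask = ok[arr_a] & ok[arr_b]
    n = int(mask.sum())
    if n == 0:
        return None
    return float((arr_a[mask] != arr_b[mask]).sum()) / n


def gene_rates(ogs: OrthogroupSet) -> dict[str, float | None]:
    """Rate proxy per gene: mean pairwise p-distance over unambiguous
    sites.  ``None`` when fewer than two comparable sequences exist."""
    out: dict[str, float | None] = {}
    for gid in ogs.gene_ids:
        aln = ogs.genes[gid]
        dists = []
        for a, b in combinations(aln.taxa, 2):
            d = _p_distance(aln.sequences[a], aln.sequences[b])
            if d is not None:
                dists.append(d)
        out[gid] = float(np.mean(dists)) if dists else None
    return out


def bin_by_rate(rates: Mapping[str, float | None], n_bins: int = 200) -> dict[str, int]:
    """Assign genes to ``n_bins`` contiguous rate-sorted bins of near-equal
    size (sizes differ by at most one).

    Genes with an undefined rate go to the median bin with a warning.
    If there are fewer genes than bins, the bin count is lowered.
    """
    defined = sorted(
        (gid for gid, r in rates.items() if r is not None),
        key=lambda g: (rates[g], g),
    )
    undefined = sorted(g for g, r in rates.items() if r is None)
    n = len(defined)
    if n == 0:
        raise ValueError("no genes with a defined rate")
    if n < n_bins:
        warnings.warn(
            f"only {n} genes with defined rates; lowering bin count from "
            f"{n_bins} to {n}"
        )
        n_bins = n
    # first (n % n_bins) bins take one extra gene
    base, extra = divmod(n, n_bins)
    assign: dict[str, int] = {}
    idx = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        for gid in defined[idx:idx + size]:
            assign[gid] = b
        idx += size
    if undefined:
        warnings.warn(
            f"{len(undefined)} gene(s) without a defined rate assigned to "
            "the median bin"
        )
        median_bin = n_bins // 2
        for gid in undefined:
            assign[gid] = median_bin
    return assign
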