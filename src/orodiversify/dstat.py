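"""Four-taxon ABBA-BABA (Patterson's D) gene-flow survey.

For a quartet (((P1, P2), P3), O) with the outgroup O carrying the
ancestral allele, biallelic sites where P2 and P3 share the derived
allele (ABBA) should be as frequent as sites where P1 and P3 share it
(BABA) under incomplete lineage sorting alone.  The D statistic

    D = (nABBA - nBABA) / (nABBA + nBABA)

measures the excess; significance is assessed with a 1-df chi-squared
goodness-of-fit test on the two counts.  A significant D > 0 indicates
P2-P3 gene flow, D < 0 indicates P1-P3 gene flow.

The survey enumerates every quartet obtainable from a group scheme
(P1 x P2 x P3 with a fixed outgroup), runs the test on each, and
aggregates detection percentages by direction, optionally restricted
to quartets whose P1 or P3 member lies in a named sub-group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .dataset_builder import Supermatrix
from .io_model import Alignment, GroupScheme

__all__ = [
    "PatternCounts",
    "DResult",
    "SurveySummary",
    "count_patterns",
    "patterson_d",
    "enumerate_quartets",
    "run_survey",
    "aggregate_survey",
]

P1_P3 = "P1-P3"
P2_P3 = "P2-P3"
NONE = "none"


@dataclass(frozen=True)
class PatternCounts:
    """ABBA/BABA tallies for one quartet.

    ``n_used`` counts biallelic sites with unambiguous bases in all
    four taxa; ``n_total`` is the alignment length.
    """

    n_abba: int
    n_baba: int
    n_used: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_abba + self.n_baba <= self.n_used <= self.n_total:
            raise ValueError("inconsistent pattern counts")


@dataclass(frozen=True)
class DResult:
    """D statistic with significance for one quartet."""

    quartet: tuple[str, str, str, str]  # (P1, P2, P3, O)
    counts: PatternCounts | None
    d: float
    chi2_stat: float
    p: float
    significant: bool
    direction: str
    undetermined: bool = False


def _encode(aln: Alignment) -> dict[str, np.ndarray]:
    return {
        t: np.frombuffer(aln.sequences[t].encode(), dtype=np.uint8)
        for t in aln.taxa
    }


_IS_BASE = np.zeros(256, dtype=bool)
for _c in b"ACGT":
    _IS_BASE[_c] = True


def _count_encoded(
    rows: Sequence[np.ndarray], n_total: int
) -> PatternCounts:
    p1, p2, p3, o = rows
    usable = _IS_BASE[p1] & _IS_BASE[p2] & _IS_BASE[p3] & _IS_BASE[o]
    # biallelic: exactly two distinct bases among the four taxa
    mx = np.maximum(np.maximum(p1, p2), np.maximum(p3, o))
    mn = np.minimum(np.minimum(p1, p2), np.minimum(p3, o))
    two_plus = mx != mn
    only_two = (
        ((p1 == mx) | (p1 == mn))
        & ((p2 == mx) | (p2 == mn))
        & ((p3 == mx) | (p3 == mn))
        & ((o == mx) | (o == mn))
    )
    used = usable & two_plus & only_two
    abba = used & (p1 == o) & (p2 == p3) & (p2 != o)
    baba = used & (p2 == o) & (p1 == p3) & (p1 != o)
    return PatternCounts(
        n_abba=int(abba.sum()),
        n_baba=int(baba.sum()),
        n_used=int(used.sum()),
        n_total=n_total,
    )


def count_patterns(
    data: Supermatrix | Alignment, quartet: Sequence[str]
) -> PatternCounts:
    """Tally ABBA/BABA site patterns for ``quartet`` = (P1, P2, P3, O).

    A site is used iff all four taxa carry an unambiguous A/C/G/T and
    exactly two distinct bases occur among them; the outgroup base is
    treated as ancestral.
    """
    aln = data.alignment if isinstance(data, Supermatrix) else data
    missing = [t for t in quartet if t not in aln.sequences]
    if missing:
        raise KeyError(f"quartet taxa absent from the alignment: {missing}")
    enc = [
        np.frombuffer(aln.sequences[t].encode(), dtype=np.uint8) for t in quartet
    ]
    return _count_encoded(enc, aln.length)


def patterson_d(
    counts: PatternCounts, alpha: float = 0.01, min_sites: int = 10,
    quartet: tuple[str, str, str, str] = ("P1", "P2", "P3", "O"),
) -> DResult:
    """D, chi-squared significance and gene-flow direction from counts.

    With nABBA + nBABA = 0 the statistic is undefined and reported as
    D = 0, not significant.  Significance additionally requires
    ``n_used >= min_sites``.
    """
    informative = counts.n_abba + counts.n_baba
    if informative == 0:
        return DResult(
            quartet=tuple(quartet), counts=counts, d=0.0, chi2_stat=0.0,
            p=1.0, significant=False, direction=NONE, undetermined=True,
        )
    d = (counts.n_abba - counts.n_baba) / informative
    stat = (counts.n_abba - counts.n_baba) ** 2 / informative
    p = float(chi2.sf(stat, df=1))
    enough = counts.n_used >= min_sites
    significant = bool(p < alpha and enough)
    if significant and d > 0:
        direction = P2_P3
    elif significant and d < 0:
        direction = P1_P3
    else:
        direction = NONE
    return DResult(
        quartet=tuple(quartet), counts=counts, d=float(d),
        chi2_stat=float(stat), p=p, significant=significant,
        direction=direction, undetermined=not enough,
    )


def enumerate_quartets(scheme: GroupScheme) -> list[tuple[str, str, str, str]]:
    """All quartets P1 x P2 x P3 with the fixed outgroup, in
    deterministic lexicographic order."""
    out = []
    for a in sorted(scheme.p1):
        for b in sorted(scheme.p2):
            for c in sorted(scheme.p3):
                out.append((a, b, c, scheme.outgroup))
    return out


def run_survey(
    data: Supermatrix | Alignment,
    scheme: GroupScheme,
    alpha: float = 0.01,
    min_sites: int = 10,
) -> list[DResult]:
    """Patterson's D for every enumerated quartet.

    Per-quartet failures (a taxon missing from the matrix) become
    undetermined entries rather than aborting the survey.
    """
    aln = data.alignment if isinstance(data, Supermatrix) else data
    enc = _encode(aln)
    results: list[DResult] = []
    for quartet in enumerate_quartets(scheme):
        if any(t not in enc for t in quartet):
            results.append(
                DResult(quartet=quartet, counts=None, d=0.0, chi2_stat=0.0,
                        p=1.0, significant=False, direction=NONE,
                        undetermined=True)
            )
            continue
        counts = _count_encoded([enc[t] for t in quartet], aln.length)
        results.append(
            patterson_d(counts, alpha=alpha, min_sites=min_sites, quartet=quartet)
        )
    return results


@dataclass
class SurveySummary:
    """Detection percentages over a (possibly restricted) quartet set."""

    n_total: int
    n_significant: int
    n_p1_p3: int
    n_p2_p3: int
    n_undetermined: int
    percent_detected: float
    percent_p1_p3: float
    percent_p2_p3: float

    def to_dict(self) -> dict[str, float]:
        return dict(
            n_total=self.n_total,
            n_significant=self.n_significant,
            n_p1_p3=self.n_p1_p3,
            n_p2_p3=self.n_p2_p3,
            n_undetermined=self.n_undetermined,
            percent_detected=self.percent_detected,
            percent_p1_p3=self.percent_p1_p3,
            percent_p2_p3=self.percent_p2_p3,
        )


def aggregate_survey(
    results: Sequence[DResult],
    restrict_p1: Iterable[str] | None = None,
    restrict_p3: Iterable[str] | None = None,
) -> SurveySummary:
    """Percentages of quartets with detected gene flow, by direction.

    ``restrict_p1`` / ``restrict_p3`` limit the denominator to quartets
    whose P1 (resp. P3) taxon lies in the given sub-group.
    """
    if not results:
        raise ValueError("no survey results to aggregate")
    subset = list(results)
    if restrict_p1 is not None:
        allowed = frozenset(restrict_p1)
        if not allowed:
            raise ValueError("empty P1 restriction")
        subset = [r for r in subset if r.quartet[0] in allowed]
    if restrict_p3 is not None:
        allowed = frozenset(restrict_p3)
        if not allowed:
            raise ValueError("empty P3 restriction")
        subset = [r for r in subset if r.quartet[2] in allowed]
    if not subset:
        raise ValueError("restriction leaves no quartets")
    n = len(subset)
    n_sig = sum(1 for r in subset if r.significant)
    n13 = sum(1 for r in subset if r.direction == P1_P3)
    n23 = sum(1 for r in subset if r.direction == P2_P3)
    n_und = sum(1 for r in subset if r.undetermined)
    return SurveySummary(
        n_total=n,
        n_significant=n_sig,
        n_p1_p3=n13,
        n_p2_p3=n23,
        n_undetermined=n_und,
        percent_detected=round(100.0 * n_sig / n, 1),
        percent_p1_p3=round(100.0 * n13 / n, 1),
        percent_p2_p3=round(100.0 * n23 / n, 1),
    )


def survey_frame(results: Sequence[DResult]) -> pd.DataFrame:
    """Tabulate survey results (one row per quartet)."""
    rows = []
    for r in results:
        c = r.counts
        rows.append(
            dict(
                p1=r.quartet[0], p2=r.quartet[1], p3=r.quartet[2],
                out=r.quartet[3],
                n_abba=c.n_abba if c else 0,
                n_baba=c.n_baba if c else 0,
                n_used=c.n_used if c else 0,
                d=r.d, chi2=r.chi2_stat, p=r.p,
                significant=r.significant, direction=r.direction,
                undetermined=r.undetermined,
            )
        )
    return pd.DataFrame(rows)
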