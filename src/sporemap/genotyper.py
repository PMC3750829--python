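"""Scaffold-level genotype calling by simple majority vote.

Each scaffold acts as one genetic marker: for every isolate its mapped,
non-artifact reads each cast one parental vote (A = identical to reference,
B = carries parent-B SNP alleles) and the scaffold genotype is the majority —
'A' or 'B', 'X' on a tie with at least one vote, '-' when no read maps.

The module also provides the within-scaffold "turning point" scan: an
exhaustive change-point search over the position-ordered voting reads that
flags scaffolds where the dominant genotype switches internally, i.e. a
crossover fell inside the scaffold and the whole-scaffold majority call may
misrepresent individual loci on it.  Locus-restricted recalling
(``call_locus``) implements the curation step such a flag invites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .readclass import ReadObservation

__all__ = [
    "CODES",
    "GenotypeCall",
    "GenotypeMatrix",
    "TurningPoint",
    "call_genotype",
    "build_matrix",
    "scan_turning_point",
    "call_locus",
    "votes_from_observations",
    "split_markers_at_turning_points",
]

CODES = ("A", "B", "X", "-")


def call_genotype(n_a: int, n_b: int) -> str:
    """Majority vote over one scaffold's reads: A, B, X (tie) or '-' (no reads)."""
    if n_a < 0 or n_b < 0:
        raise ValueError("vote counts must be non-negative")
    if n_a == 0 and n_b == 0:
        return "-"
    if n_a > n_b:
        return "A"
    if n_b > n_a:
        return "B"
    return "X"


@dataclass
class GenotypeCall:
    isolate: str
    scaffold: str
    n_a: int
    n_b: int

    @property
    def code(self) -> str:
        return call_genotype(self.n_a, self.n_b)


@dataclass
class GenotypeMatrix:
    """Markers (scaffolds) x isolates grid of codes with the vote counts behind them."""

    codes: pd.DataFrame  # values in CODES
    n_a: pd.DataFrame
    n_b: pd.DataFrame
    scaffold_lengths: pd.Series | None = None

    @property
    def markers(self) -> list[str]:
        return list(self.codes.index)

    @property
    def isolates(self) -> list[str]:
        return list(self.codes.columns)

    def success_rate(self) -> pd.Series:
        """Fraction of isolates per marker with a usable (A or B) call."""
        return self.codes.isin(["A", "B"]).mean(axis=1)

    def informative(self) -> pd.DataFrame:
        return self.codes.isin(["A", "B"])

    def swapped_labels(self) -> "GenotypeMatrix":
        flip = {"A": "B", "B": "A"}
        return GenotypeMatrix(
            codes=self.codes.replace(flip),
            n_a=self.n_b.copy(),
            n_b=self.n_a.copy(),
            scaffold_lengths=self.scaffold_lengths,
        )


def votes_from_observations(
    observations: Iterable[ReadObservation], informative_only: bool = False
) -> list[ReadObservation]:
    """The subset of observations that cast a vote.

    With ``informative_only`` the vote is restricted to reads that overlap at
    least one catalog SNP site; by default SNP-free identical reads also vote
    A, faithfully reproducing the reference-based convention (and its
    documented large-scaffold failure mode).
    """
    out = []
    for o in observations:
        if o.vote is None:
            continue
        if informative_only and o.snp_sites_covered == 0:
            continue
        out.append(o)
    return out


def build_matrix(
    observations_by_isolate: Mapping[str, Iterable[ReadObservation]],
    scaffolds: Sequence[str],
    scaffold_lengths: Mapping[str, int] | None = None,
    informative_only: bool = False,
) -> GenotypeMatrix:
    """Assemble the genotype matrix from per-read observations of all isolates.

    Every (scaffold, isolate) cell is filled; duplicate read ids within an
    isolate raise, since each read must vote at most once.
    """
    if not observations_by_isolate:
        raise ValueError("need observations for at least one isolate")
    isolates = list(observations_by_isolate)
    n_a = pd.DataFrame(0, index=list(scaffolds), columns=isolates, dtype=np.int64)
    n_b = n_a.copy()
    for iso, obs in observations_by_isolate.items():
        voters = votes_from_observations(obs, informative_only)
        seen: set[str] = set()
        for o in voters:
            if o.read_id in seen:
                raise ValueError(f"duplicate read id {o.read_id!r} in isolate {iso}")
            seen.add(o.read_id)
            if o.scaffold not in n_a.index:
                continue
            if o.vote == "A":
                n_a.loc[o.scaffold, iso] += 1
            else:
                n_b.loc[o.scaffold, iso] += 1
    codes = pd.DataFrame(
        np.where(
            (n_a.values == 0) & (n_b.values == 0),
            "-",
            np.where(
                n_a.values > n_b.values, "A", np.where(n_b.values > n_a.values, "B", "X")
            ),
        ),
        index=n_a.index,
        columns=n_a.columns,
    )
    lens = None
    if scaffold_lengths is not None:
        lens = pd.Series({s: int(scaffold_lengths[s]) for s in scaffolds})
    return GenotypeMatrix(codes=codes, n_a=n_a, n_b=n_b, scaffold_lengths=lens)


@dataclass
class TurningPoint:
    """A detected within-scaffold genotype switch."""

    scaffold: str
    isolate: str
    breakpoint_bp: float  # between the flanking voting reads
    split_index: int  # reads [0, split) left, [split, n) right
    left_code: str
    right_code: str
    left_counts: tuple[int, int]  # (A, B) votes
    right_counts: tuple[int, int]
    score: int  # misclassification reduction vs the unsplit majority call


def _mis(a: int, b: int) -> int:
    # reads misclassified by a majority call over (a, b) votes
    return min(a, b)


def scan_turning_point(
    reads: Sequence[tuple[float, float, str]],
    min_segment_reads: int = 5,
    min_score: int = 3,
    scaffold: str = "",
    isolate: str = "",
) -> TurningPoint | None:
    """Exhaustive change-point search over position-ordered voting reads.

    ``reads`` is a sequence of (start, end, vote) with vote in {'A','B'},
    sorted by start.  Every split between consecutive reads is evaluated; the
    one minimising total majority-vote misclassifications across the two
    segments wins (ties to the leftmost split).  A turning point is reported
    only if both segments contain at least ``min_segment_reads`` reads, their
    majority codes differ, and the split reduces misclassifications by at
    least ``min_score`` relative to the unsplit call.
    """
    n = len(reads)
    starts = [r[0] for r in reads]
    if any(starts[i] > starts[i + 1] for i in range(n - 1)):
        raise ValueError("voting reads must be sorted by start position")
    if n < 2 * min_segment_reads:
        return None
    is_a = np.array([1 if r[2] == "A" else 0 for r in reads])
    if np.any((is_a != 0) & (is_a != 1)) or any(r[2] not in "AB" for r in reads):
        raise ValueError("votes must be 'A' or 'B'")
    pref_a = np.concatenate([[0], np.cumsum(is_a)])
    tot_a = int(pref_a[-1])
    tot_b = n - tot_a
    base_mis = _mis(tot_a, tot_b)

    best: tuple[int, int] | None = None  # (total mis, split index)
    for k in range(min_segment_reads, n - min_segment_reads + 1):
        la, lb = int(pref_a[k]), k - int(pref_a[k])
        ra, rb = tot_a - la, tot_b - lb
        lcode = "A" if la >= lb else "B"
        rcode = "A" if ra >= rb else "B"
        if lcode == rcode:
            continue
        total = _mis(la, lb) + _mis(ra, rb)
        if best is None or total < best[0]:
            best = (total, k)
    if best is None:
        return None
    total, k = best
    score = base_mis - total
    if score < min_score:
        return None
    la, lb = int(pref_a[k]), k - int(pref_a[k])
    ra, rb = tot_a - la, tot_b - lb
    left_end = max(r[1] for r in reads[:k])
    right_start = reads[k][0]
    bp = (left_end + right_start) / 2 if right_start >= left_end else (
        (reads[k - 1][0] + right_start) / 2
    )
    return TurningPoint(
        scaffold=scaffold,
        isolate=isolate,
        breakpoint_bp=float(bp),
        split_index=k,
        left_code="A" if la >= lb else "B",
        right_code="A" if ra >= rb else "B",
        left_counts=(la, lb),
        right_counts=(ra, rb),
        score=score,
    )


def call_locus(
    reads: Sequence[tuple[float, float, str]],
    interval: tuple[float, float],
    isolate: str = "",
    scaffold: str = "",
) -> GenotypeCall:
    """Majority vote restricted to reads overlapping a locus interval.

    The locus-restricted recount is the curation step for scaffolds whose
    whole-scaffold majority hides an internal crossover.
    """
    lo, hi = interval
    if hi <= lo:
        raise ValueError("empty locus interval")
    n_a = n_b = 0
    for start, end, vote in reads:
        if start < hi and end > lo:  # overlap, half-open
            if vote == "A":
                n_a += 1
            elif vote == "B":
                n_b += 1
    return GenotypeCall(isolate=isolate, scaffold=scaffold, n_a=n_a, n_b=n_b)


def observation_votes(
    observations: Iterable[ReadObservation], scaffold: str, informative_only: bool = False
) -> list[tuple[float, float, str]]:
    """Position-sorted (start, end, vote) triples for one scaffold's voting reads."""
    voters = [
        o
        for o in votes_from_observations(observations, informative_only)
        if o.scaffold == scaffold and o.start is not None
    ]
    voters.sort(key=lambda o: (o.start, o.end))
    return [(float(o.start), float(o.end), o.vote) for o in voters]


def scan_all_turning_points(
    observations_by_isolate: Mapping[str, Iterable[ReadObservation]],
    scaffolds: Sequence[str],
    min_segment_reads: int = 5,
    min_score: int = 3,
    informative_only: bool = False,
) -> list[TurningPoint]:
    """Turning-point scan over every (scaffold, isolate) cell with enough voting reads."""
    out: list[TurningPoint] = []
    for iso, obs in observations_by_isolate.items():
        obs = list(obs)
        by_scaf: dict[str, list[ReadObservation]] = {}
        for o in votes_from_observations(obs, informative_only):
            if o.scaffold is not None:
                by_scaf.setdefault(o.scaffold, []).append(o)
        for scaf in scaffolds:
            voters = by_scaf.get(scaf)
            if not voters or len(voters) < 2 * min_segment_reads:
                continue
            voters.sort(key=lambda o: (o.start, o.end))
            tp = scan_turning_point(
                [(float(o.start), float(o.end), o.vote) for o in voters],
                min_segment_reads,
                min_score,
                scaffold=scaf,
                isolate=iso,
            )
            if tp is not None:
                out.append(tp)
    return out


def split_markers_at_turning_points(
    observations_by_isolate: Mapping[str, Iterable[ReadObservation]],
    matrix: GenotypeMatrix,
    turning_points: Sequence[TurningPoint],
    informative_only: bool = False,
) -> GenotypeMatrix:
    """Replace flagged scaffolds by left/right sub-markers split at the median breakpoint.

    An opt-in alternative to manual curation: each scaffold with at least one
    detected turning point is split at the median detected breakpoint, and
    both halves are re-called per isolate by locus-restricted majority vote.
    """
    by_scaf: dict[str, list[float]] = {}
    for tp in turning_points:
        by_scaf.setdefault(tp.scaffold, []).append(tp.breakpoint_bp)
    if not by_scaf:
        return matrix
    new_markers: list[str] = []
    lengths: dict[str, int] = {}
    old_lengths = matrix.scaffold_lengths
    for scaf in matrix.markers:
        if scaf in by_scaf:
            new_markers += [f"{scaf}:L", f"{scaf}:R"]
            if old_lengths is not None:
                cut = float(np.median(by_scaf[scaf]))
                lengths[f"{scaf}:L"] = int(round(cut))
                lengths[f"{scaf}:R"] = int(old_lengths[scaf] - round(cut))
        else:
            new_markers.append(scaf)
            if old_lengths is not None:
                lengths[scaf] = int(old_lengths[scaf])
    isolates = matrix.isolates
    n_a = pd.DataFrame(0, index=new_markers, columns=isolates, dtype=np.int64)
    n_b = n_a.copy()
    for scaf in matrix.markers:
        if scaf not in by_scaf:
            n_a.loc[scaf] = matrix.n_a.loc[scaf]
            n_b.loc[scaf] = matrix.n_b.loc[scaf]
            continue
        cut = float(np.median(by_scaf[scaf]))
        end = float(old_lengths[scaf]) if old_lengths is not None else np.inf
        for iso in isolates:
            votes = observation_votes(
                observations_by_isolate.get(iso, []), scaf, informative_only
            )
            left = call_locus(votes, (0.0, cut), iso, scaf) if cut > 0 else None
            right = call_locus(votes, (cut, max(end, cut + 1)), iso, scaf)
            if left is not None:
                n_a.loc[f"{scaf}:L", iso] = left.n_a
                n_b.loc[f"{scaf}:L", iso] = left.n_b
            n_a.loc[f"{scaf}:R", iso] = right.n_a
            n_b.loc[f"{scaf}:R", iso] = right.n_b
    codes = pd.DataFrame(
        np.where(
            (n_a.values == 0) & (n_b.values == 0),
            "-",
            np.where(
                n_a.values > n_b.values, "A", np.where(n_b.values > n_a.values, "B", "X")
            ),
        ),
        index=new_markers,
        columns=isolates,
    )
    lens = pd.Series(lengths) if old_lengths is not None else None
    return GenotypeMatrix(codes=codes, n_a=n_a, n_b=n_b, scaffold_lengths=lens)
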