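"""Two-point genetic linkage map construction from a haploid genotype matrix.

Pipeline: (1) screen every marker for 1:1 segregation with a 1-df chi-square
test; (2) estimate the recombination fraction r and two-point LOD for every
retained marker pair over pairwise-complete isolates (each haploid progeny is
one informative meiosis, so the likelihood is the backcross form); (3) form
linkage groups by single-linkage closure over pairs with LOD >= 3 AND map
distance <= 25 cM; (4) order markers within each group by minimising the sum
of adjacent distances (exact Held-Karp dynamic programming for small groups,
nearest-neighbour + 2-opt above); (5) assign cumulative Kosambi positions.

Ties, X codes and missing cells are excluded from counts throughout: neither
carries a usable parental call.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genotyper import GenotypeMatrix

__all__ = [
    "MapParams",
    "SegregationResult",
    "PairwiseLinkage",
    "PairTable",
    "LinkageGroup",
    "LinkageMap",
    "segregation_screen",
    "pairwise_rf",
    "pairwise_linkage_table",
    "lod_score",
    "map_distance",
    "form_groups",
    "order_markers",
    "build_map",
]

_PENALTY_CM = 1e4  # ordering-only stand-in for unestimable pair distances


@dataclass(frozen=True)
class MapParams:
    """Thresholds of the map-construction pipeline.

    alpha: level of the 1:1 segregation chi-square screen (markers with
        P >= alpha are retained as undistorted).
    lod_min: two-point LOD required to link a pair (classical threshold 3).
    max_gap_cm: maximum adjacent map distance tolerated inside a group.
    n_min: informative isolates required before a pair's LOD is trusted.
    min_group_span_cm: groups spanning no more than this are reported
        separately from the headline groups.
    mapping_function: 'kosambi' (partial interference) or 'haldane'.
    """

    alpha: float = 0.05
    lod_min: float = 3.0
    max_gap_cm: float = 25.0
    n_min: int = 5
    min_group_span_cm: float = 20.0
    mapping_function: str = "kosambi"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if min(self.lod_min, self.max_gap_cm, self.n_min) <= 0:
            raise ValueError("thresholds must be positive")
        if self.mapping_function not in ("kosambi", "haldane"):
            raise ValueError("mapping_function must be 'kosambi' or 'haldane'")


@dataclass
class SegregationResult:
    marker: str
    count_a: int
    count_b: int
    chi2: float
    p_value: float
    retained: bool


def segregation_screen(matrix: GenotypeMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square 1:1 segregation test per marker (X and '-' codes excluded).

    A marker is retained when its A:B ratio is consistent with the 1:1
    expected of haploid progeny (P >= alpha); markers with fewer than two
    informative calls are uninformative and never retained.
    """
    codes = matrix.codes
    count_a = (codes == "A").sum(axis=1).astype(int)
    count_b = (codes == "B").sum(axis=1).astype(int)
    n = count_a + count_b
    e = n / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(n > 0, (count_a - e) ** 2 / e + (count_b - e) ** 2 / e, np.nan)
    p = np.where(n > 0, stats.chi2.sf(chi2, df=1), np.nan)
    retained = (n >= 2) & (p >= alpha)
    return pd.DataFrame(
        {
            "marker": codes.index,
            "count_A": count_a.values,
            "count_B": count_b.values,
            "chi2": chi2,
            "p_value": p,
            "retained": retained,
        }
    ).set_index("marker")


def lod_score(n: int, r_count: int) -> float:
    """Two-point LOD of linkage at the MLE r̂ = R/N versus free recombination.

    Backcross-equivalent likelihood: LOD = R log10(2r̂) + (N-R) log10(2(1-r̂)),
    with boundary terms dropped under the 0·log 0 = 0 convention, so LOD at
    R = 0 is exactly N·log10 2.
    """
    if n <= 0:
        return 0.0
    r = r_count / n
    lod = 0.0
    if r_count > 0:
        lod += r_count * math.log10(2.0 * r)
    if r_count < n:
        lod += (n - r_count) * math.log10(2.0 * (1.0 - r))
    return lod


@dataclass
class PairwiseLinkage:
    marker_i: str
    marker_j: str
    n: int  # informative isolates (both calls in {A, B})
    r_count: int  # recombinants
    r_hat: float
    lod: float


def pairwise_rf(
    matrix: GenotypeMatrix, marker_i: str, marker_j: str, n_min: int = 5
) -> PairwiseLinkage:
    """Recombination fraction and LOD for one marker pair.

    N counts isolates where both markers have a parental call; R counts those
    with discordant parental origin.  The LOD is reported as 0 when fewer
    than ``n_min`` informative isolates exist.
    """
    for m in (marker_i, marker_j):
        if m not in matrix.codes.index:
            raise KeyError(f"marker {m!r} absent from matrix")
    gi = matrix.codes.loc[marker_i]
    gj = matrix.codes.loc[marker_j]
    ok = gi.isin(["A", "B"]) & gj.isin(["A", "B"])
    n = int(ok.sum())
    r_count = int((gi[ok] != gj[ok]).sum())
    r_hat = r_count / n if n else float("nan")
    lod = lod_score(n, r_count) if n >= n_min else 0.0
    return PairwiseLinkage(marker_i, marker_j, n, r_count, r_hat, lod)


@dataclass
class PairTable:
    """All-pairs linkage statistics over a marker subset (dense matrices)."""

    markers: list[str]
    n: np.ndarray
    r_count: np.ndarray
    r_hat: np.ndarray  # nan where n == 0
    lod: np.ndarray  # 0 where n < n_min

    def index(self, marker: str) -> int:
        return self.markers.index(marker)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        m = self.markers
        for i in range(len(m)):
            for j in range(i + 1, len(m)):
                rows.append(
                    (m[i], m[j], int(self.n[i, j]), int(self.r_count[i, j]),
                     float(self.r_hat[i, j]), float(self.lod[i, j]))
                )
        return pd.DataFrame(
            rows, columns=["marker_i", "marker_j", "n", "r_count", "r_hat", "lod"]
        )


def pairwise_linkage_table(
    matrix: GenotypeMatrix, markers: Sequence[str] | None = None, n_min: int = 5
) -> PairTable:
    """Vectorised all-pairs recombination fractions and LODs."""
    markers = list(markers) if markers is not None else matrix.markers
    codes = matrix.codes.loc[markers]
    a = (codes == "A").to_numpy(dtype=np.float64)
    b = (codes == "B").to_numpy(dtype=np.float64)
    valid = a + b
    n = valid @ valid.T
    # discordant = one marker A where the other is B
    r_count = a @ b.T + b @ a.T
    with np.errstate(divide="ignore", invalid="ignore"):
        r_hat = np.where(n > 0, r_count / n, np.nan)
    R, N = r_count, n
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(R > 0, R * np.log10(np.maximum(2 * r_hat, 1e-300)), 0.0)
        t2 = np.where(N - R > 0, (N - R) * np.log10(np.maximum(2 * (1 - r_hat), 1e-300)), 0.0)
    lod = np.where(n >= n_min, t1 + t2, 0.0)
    np.fill_diagonal(lod, 0.0)
    return PairTable(
        markers=markers,
        n=n.astype(np.int64),
        r_count=r_count.astype(np.int64),
        r_hat=r_hat,
        lod=lod,
    )


def map_distance(r: float, mapping_function: str = "kosambi") -> float:
    """Map distance in cM for a recombination fraction.

    Kosambi: d = 25 ln((1+2r)/(1-2r)); Haldane: d = -50 ln(1-2r).
    r >= 0.5 means free recombination — reported as infinite, never grouped.
    """
    if r < 0:
        raise ValueError("recombination fraction must be >= 0")
    if r >= 0.5 or math.isnan(r):
        return float("inf")
    if mapping_function == "kosambi":
        return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))
    if mapping_function == "haldane":
        return -50.0 * math.log(1 - 2 * r)
    raise ValueError(f"unknown mapping function {mapping_function!r}")


def _distance_matrix(pairs: PairTable, params: MapParams) -> np.ndarray:
    k = len(pairs.markers)
    d = np.full((k, k), _PENALTY_CM)
    for i in range(k):
        d[i, i] = 0.0
        for j in range(i + 1, k):
            if pairs.n[i, j] >= params.n_min and pairs.r_hat[i, j] < 0.5:
                d[i, j] = d[j, i] = map_distance(
                    float(pairs.r_hat[i, j]), params.mapping_function
                )
    return d


def form_groups(
    pairs: PairTable, params: MapParams | None = None
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage clustering into linkage groups.

    Two markers are directly linked when their two-point LOD >= lod_min AND
    their map distance <= max_gap_cm; groups are the transitive closure.
    Returns (groups with >= 2 markers, ungrouped singletons), each group's
    members sorted by name, groups sorted by smallest member, so the
    partition is invariant to marker input order.
    """
    params = params or MapParams()
    k = len(pairs.markers)
    d = _distance_matrix(pairs, params)
    adj = (pairs.lod >= params.lod_min) & (d <= params.max_gap_cm)
    np.fill_diagonal(adj, False)
    g = nx.from_numpy_array(adj.astype(int))
    comps = [sorted(pairs.markers[i] for i in comp) for comp in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    groups = [c for c in comps if len(c) >= 2]
    singletons = sorted(m for c in comps if len(c) == 1 for m in c)
    return groups, singletons


def _sarf(order: Sequence[int], d: np.ndarray) -> float:
    return float(sum(d[order[k], order[k + 1]] for k in range(len(order) - 1)))


def _held_karp_path(d: np.ndarray) -> list[int]:
    """Exact minimum Hamiltonian path by subset dynamic programming."""
    n = d.shape[0]
    full = 1 << n
    dp = np.full((full, n), np.inf)
    back = np.full((full, n), -1, dtype=np.int64)
    for i in range(n):
        dp[1 << i, i] = 0.0
    for mask in range(full):
        for last in range(n):
            cur = dp[mask, last]
            if not np.isfinite(cur) or not (mask >> last) & 1:
                continue
            for nxt in range(n):
                if (mask >> nxt) & 1:
                    continue
                nm = mask | (1 << nxt)
                cand = cur + d[last, nxt]
                if cand < dp[nm, nxt]:
                    dp[nm, nxt] = cand
                    back[nm, nxt] = last
    end = int(np.argmin(dp[full - 1]))
    order = [end]
    mask = full - 1
    while back[mask, order[-1]] >= 0:
        prev = int(back[mask, order[-1]])
        mask ^= 1 << order[-1]
        order.append(prev)
    order.reverse()
    return order


def _nn_two_opt(d: np.ndarray) -> list[int]:
    """Nearest-neighbour construction from every start, then 2-opt refinement."""
    n = d.shape[0]
    best_order, best_cost = None, np.inf
    for s in range(n):
        order = [s]
        left = set(range(n)) - {s}
        while left:
            last = order[-1]
            nxt = min(left, key=lambda j: d[last, j])
            order.append(nxt)
            left.remove(nxt)
        c = _sarf(order, d)
        if c < best_cost:
            best_order, best_cost = order, c
    order = list(best_order)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                if i == 0 and j == n - 1:
                    continue  # full reversal, same path
                # reversing order[i..j] changes only the boundary adjacencies
                delta = 0.0
                if i > 0:
                    delta += d[order[i - 1], order[j]] - d[order[i - 1], order[i]]
                if j < n - 1:
                    delta += d[order[i], order[j + 1]] - d[order[j], order[j + 1]]
                if delta < -1e-12:
                    order[i : j + 1] = reversed(order[i : j + 1])
                    improved = True
    return order


def order_markers(
    group: Sequence[str],
    pairs: PairTable,
    params: MapParams | None = None,
    exact_limit: int = 12,
) -> tuple[list[str], list[float]]:
    """Order a linkage group's markers and assign cumulative cM positions.

    The objective is the sum of adjacent map distances (SARF).  Groups up to
    ``exact_limit`` markers are solved exactly by Held-Karp dynamic
    programming; larger groups use nearest-neighbour construction with 2-opt
    refinement.  The order's reversal is equivalent; the orientation placing
    the lexicographically smaller terminal marker first is reported.
    Positions are cumulative adjacent distances from 0.
    """
    params = params or MapParams()
    group = list(group)
    if len(group) < 2:
        raise ValueError("ordering needs a group of >= 2 markers")
    idx = [pairs.index(m) for m in group]
    d_full = _distance_matrix(pairs, params)
    d = d_full[np.ix_(idx, idx)]
    # the group must be connected through estimable, groupable distances
    finite = (d < _PENALTY_CM) & ~np.eye(len(group), dtype=bool)
    g = nx.from_numpy_array(finite.astype(int))
    if not nx.is_connected(g):
        comp = sorted(nx.connected_components(g), key=len)[0]
        names = [group[i] for i in comp]
        raise ValueError(f"disconnected distance data within group at {names}")
    if len(group) <= exact_limit:
        order = _held_karp_path(d)
    else:
        order = _nn_two_opt(d)
    if group[order[-1]] < group[order[0]]:
        order = order[::-1]
    ordered = [group[i] for i in order]
    positions = [0.0]
    for k in range(len(order) - 1):
        positions.append(positions[-1] + float(d[order[k], order[k + 1]]))
    return ordered, positions


@dataclass
class LinkageGroup:
    name: str
    markers: list[str]
    positions: list[float]  # cumulative cM from the first marker

    @property
    def span_cm(self) -> float:
        return self.positions[-1] if self.positions else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class LinkageMap:
    """Ordered linkage groups plus the markers that did not group."""

    groups: list[LinkageGroup]
    ungrouped: list[str]
    params: MapParams = field(default_factory=MapParams)

    def headline_groups(self) -> list[LinkageGroup]:
        """Groups exceeding the headline span threshold."""
        return [g for g in self.groups if g.span_cm > self.params.min_group_span_cm]

    def minor_groups(self) -> list[LinkageGroup]:
        return [g for g in self.groups if g.span_cm <= self.params.min_group_span_cm]

    @property
    def total_length_cm(self) -> float:
        return float(sum(g.span_cm for g in self.groups))


def build_map(matrix: GenotypeMatrix, params: MapParams | None = None) -> LinkageMap:
    """Full pipeline: segregation screen -> pairwise linkage -> groups -> order.

    Groups are named LG1, LG2, ... in order of decreasing genetic span.
    """
    params = params or MapParams()
    seg = segregation_screen(matrix, params.alpha)
    retained = list(seg.index[seg.retained])
    if len(retained) < 2:
        raise ValueError("fewer than 2 markers survive the segregation screen")
    pairs = pairwise_linkage_table(matrix, retained, params.n_min)
    raw_groups, singles = form_groups(pairs, params)
    ordered: list[LinkageGroup] = []
    for g in raw_groups:
        markers, positions = order_markers(g, pairs, params)
        ordered.append(LinkageGroup(name="", markers=markers, positions=positions))
    ordered.sort(key=lambda lg: (-lg.span_cm, lg.markers[0]))
    for i, lg in enumerate(ordered):
        lg.name = f"LG{i + 1}"
    return LinkageMap(groups=ordered, ungrouped=singles, params=params)
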