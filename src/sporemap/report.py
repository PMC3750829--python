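"""Map summary statistics, physical anchoring metrics and genotype concordance.

Conventions mirror the standard per-group map table: a group's length is the
cM position of its last marker, its average spacing divides the length over
(n_markers - 1) gaps, its physical size is the summed scaffold lengths of its
member markers, and the physical-to-genetic ratio is kbp per cM.  Map-wide
averages are unweighted over groups, except the overall marker spacing which
pools gaps: total length / (total markers - n_groups).  Values are carried at
full precision and rounded (half-even, one decimal) only at the report
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotyper import GenotypeMatrix, call_locus
from .linkmap import LinkageMap

__all__ = [
    "GroupSummary",
    "MapSummary",
    "ConcordanceResult",
    "group_summary",
    "summarize_groups",
    "summarize_map",
    "concordance",
    "truth_accuracy",
    "round1",
    "summary_table",
]


def round1(x: float) -> float:
    """One-decimal rounding, half to even (report-boundary convention)."""
    return float(np.round(x, 1))


@dataclass
class GroupSummary:
    group: str
    length_cm: float
    n_markers: int
    avg_spacing_cm: float  # length / (n_markers - 1)
    physical_kbp: float
    ratio_kbp_per_cm: float  # physical / length


@dataclass
class MapSummary:
    total_length_cm: float
    n_groups: int
    total_markers: int
    avg_group_length_cm: float
    avg_markers_per_group: float
    overall_avg_spacing_cm: float  # total length / (total markers - n_groups)
    total_physical_kbp: float
    avg_physical_kbp: float
    avg_ratio_kbp_per_cm: float  # unweighted mean of per-group ratios
    genome_coverage_pct: float | None = None


def group_summary(group: str, length_cm: float, n_markers: int, physical_kbp: float) -> GroupSummary:
    if n_markers < 2:
        raise ValueError(f"group {group}: spacing needs >= 2 markers")
    if length_cm <= 0:
        raise ValueError(f"group {group}: ratio undefined for zero genetic length")
    return GroupSummary(
        group=group,
        length_cm=float(length_cm),
        n_markers=int(n_markers),
        avg_spacing_cm=length_cm / (n_markers - 1),
        physical_kbp=float(physical_kbp),
        ratio_kbp_per_cm=physical_kbp / length_cm,
    )


def summarize_groups(
    groups: Iterable[tuple[str, float, int, float]],
    genome_size_bp: float | None = None,
) -> tuple[list[GroupSummary], MapSummary]:
    """Per-group and map-wide statistics from (id, length cM, n markers, physical kbp) rows."""
    per_group = [group_summary(*row) for row in groups]
    if not per_group:
        raise ValueError("no groups to summarise")
    total_len = sum(g.length_cm for g in per_group)
    n_groups = len(per_group)
    total_markers = sum(g.n_markers for g in per_group)
    total_phys = sum(g.physical_kbp for g in per_group)
    coverage = None
    if genome_size_bp is not None:
        coverage = 100.0 * total_phys / (genome_size_bp / 1000.0)
    summary = MapSummary(
        total_length_cm=total_len,
        n_groups=n_groups,
        total_markers=total_markers,
        avg_group_length_cm=total_len / n_groups,
        avg_markers_per_group=total_markers / n_groups,
        overall_avg_spacing_cm=total_len / (total_markers - n_groups),
        total_physical_kbp=total_phys,
        avg_physical_kbp=total_phys / n_groups,
        avg_ratio_kbp_per_cm=float(np.mean([g.ratio_kbp_per_cm for g in per_group])),
        genome_coverage_pct=coverage,
    )
    return per_group, summary


def summarize_map(
    linkage_map: LinkageMap,
    scaffold_lengths: Mapping[str, int],
    genome_size_bp: float | None = None,
    headline_only: bool = True,
) -> tuple[list[GroupSummary], MapSummary]:
    """Summarise a built map, anchoring each group by its members' scaffold lengths."""
    groups = linkage_map.headline_groups() if headline_only else linkage_map.groups
    rows = []
    for lg in groups:
        for m in lg.markers:
            if m not in scaffold_lengths:
                raise KeyError(f"no scaffold length for marker {m!r}")
        phys_kbp = sum(scaffold_lengths[m] for m in lg.markers) / 1000.0
        rows.append((lg.name, lg.span_cm, lg.n_markers, phys_kbp))
    return summarize_groups(rows, genome_size_bp)


def summary_table(per_group: Sequence[GroupSummary], summary: MapSummary) -> pd.DataFrame:
    """Report-boundary table with one-decimal rounding (map-table convention)."""
    rows = [
        {
            "group": g.group,
            "length_cM": round1(g.length_cm),
            "n_markers": g.n_markers,
            "avg_spacing_cM": round1(g.avg_spacing_cm),
            "physical_kbp": round1(g.physical_kbp),
            "ratio_kbp_per_cM": round1(g.ratio_kbp_per_cm),
        }
        for g in per_group
    ]
    rows.append(
        {
            "group": "Total",
            "length_cM": round1(summary.total_length_cm),
            "n_markers": summary.total_markers,
            "avg_spacing_cM": np.nan,
            "physical_kbp": round1(summary.total_physical_kbp),
            "ratio_kbp_per_cM": np.nan,
        }
    )
    rows.append(
        {
            "group": "Average",
            "length_cM": round1(summary.avg_group_length_cm),
            "n_markers": round1(summary.avg_markers_per_group),
            "avg_spacing_cM": round1(summary.overall_avg_spacing_cm),
            "physical_kbp": round1(summary.avg_physical_kbp),
            "ratio_kbp_per_cM": round1(summary.avg_ratio_kbp_per_cm),
        }
    )
    return pd.DataFrame(rows)


@dataclass
class ConcordanceResult:
    """Agreement between pipeline genotype calls and experimental determinations."""

    n_compared: int
    n_concordant: int
    discordant: list[dict] = field(default_factory=list)

    @property
    def accuracy_pct(self) -> float:
        if self.n_compared == 0:
            raise ValueError("no comparisons made")
        return 100.0 * self.n_concordant / self.n_compared


def concordance(
    matrix: GenotypeMatrix,
    experimental: pd.DataFrame,
    observations_by_isolate: Mapping[str, Iterable] | None = None,
    turning_points: Sequence | None = None,
) -> ConcordanceResult:
    """Compare called genotypes with an experimental genotype table.

    ``experimental`` needs columns isolate, marker, expected (codes 'A'/'B'),
    and optionally gene, locus_start, locus_end.  When a locus interval is
    given and per-read observations are available, the comparison uses the
    locus-restricted majority call instead of the whole-scaffold call.
    Discordances are enumerated, annotated with any turning-point record
    detected on the same (scaffold, isolate) cell.
    """
    from .genotyper import observation_votes

    tp_index = {}
    for tp in turning_points or []:
        tp_index[(tp.scaffold, tp.isolate)] = tp
    n = n_ok = 0
    discordant: list[dict] = []
    for row in experimental.itertuples(index=False):
        iso, marker, expected = row.isolate, row.marker, row.expected
        if iso not in matrix.codes.columns:
            raise KeyError(f"experimental table references unknown isolate {iso!r}")
        if marker not in matrix.codes.index:
            raise KeyError(f"experimental table references unknown marker {marker!r}")
        has_interval = (
            hasattr(row, "locus_start")
            and hasattr(row, "locus_end")
            and not pd.isna(row.locus_start)
        )
        if has_interval and observations_by_isolate is not None:
            votes = observation_votes(observations_by_isolate.get(iso, []), marker)
            called = call_locus(
                votes, (float(row.locus_start), float(row.locus_end)), iso, marker
            ).code
        else:
            called = matrix.codes.loc[marker, iso]
        n += 1
        if called == expected:
            n_ok += 1
        else:
            rec = {
                "isolate": iso,
                "marker": marker,
                "gene": getattr(row, "gene", ""),
                "expected": expected,
                "called": called,
            }
            tp = tp_index.get((marker, iso))
            if tp is not None:
                rec["turning_point"] = (
                    f"{tp.left_code}->{tp.right_code} at ~{tp.breakpoint_bp:.0f} bp "
                    f"(votes {tp.left_counts}|{tp.right_counts})"
                )
            discordant.append(rec)
    return ConcordanceResult(n_compared=n, n_concordant=n_ok, discordant=discordant)


def truth_accuracy(matrix: GenotypeMatrix, truth_parent: pd.DataFrame) -> ConcordanceResult:
    """Called codes versus simulated truth over cells with a parental call."""
    common_m = [m for m in matrix.markers if m in truth_parent.index]
    common_i = [i for i in matrix.isolates if i in truth_parent.columns]
    codes = matrix.codes.loc[common_m, common_i]
    truth = truth_parent.loc[common_m, common_i]
    usable = codes.isin(["A", "B"])
    n = int(usable.values.sum())
    ok = int(((codes == truth) & usable).values.sum())
    return ConcordanceResult(n_compared=n, n_concordant=ok)
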