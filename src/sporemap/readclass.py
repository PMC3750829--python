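"""Per-read classification against the parental SNP catalog.

Each mapped read of a haploid isolate is turned into one genotype vote:
reads identical to the reference (parent A) vote A, reads carrying
high-quality parent-B SNP alleles vote B.  Chimeric, repetitive and unmapped
reads are recognised and excluded from voting, mirroring the filtering a
reference mapper performs before genotyping.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "ReadClass",
    "ClassifierParams",
    "SnpCatalog",
    "ReadObservation",
    "IsolateSummary",
    "UnknownScaffoldError",
    "classify_read",
    "classify_isolate",
]


class ReadClass(str, Enum):
    IDENTICAL = "IDENTICAL"  # matches reference -> parent-A vote
    VARIANT = "VARIANT"  # carries parent-B alleles -> parent-B vote
    CHIMERIC = "CHIMERIC"
    REPETITIVE = "REPETITIVE"
    UNMAPPED = "UNMAPPED"
    AMBIGUOUS = "AMBIGUOUS"  # too many off-catalog mismatches to trust


class UnknownScaffoldError(KeyError):
    """Alignment refers to a scaffold absent from the catalog's reference."""


@dataclass(frozen=True)
class ClassifierParams:
    """Quality thresholds for read classification.

    min_base_quality: Phred floor for a parent-B allele observation to count
        as a "high-quality SNP" (the vendor mapper's criterion is not public;
        20 = 1% error is the conventional choice).
    min_mapq: below this mapping quality a read is REPETITIVE.
    max_nonsnp_mismatches: off-catalog mismatches tolerated before a read that
        would vote A is demoted to AMBIGUOUS.
    chimera_min_distance: a split alignment to the same scaffold further than
        this is chimeric evidence (other-scaffold splits always are).
    """

    min_base_quality: int = 20
    min_mapq: int = 1
    max_nonsnp_mismatches: int = 10
    chimera_min_distance: int = 1000

    def __post_init__(self) -> None:
        if min(self.min_base_quality, self.min_mapq, self.max_nonsnp_mismatches) < 0:
            raise ValueError("thresholds must be >= 0")


class SnpCatalog:
    """Biallelic diagnostic positions distinguishing parent A from parent B.

    Positions are stored per scaffold as sorted 0-based arrays for fast range
    queries.  ``reference_scaffolds`` optionally lists every scaffold of the
    reference (including SNP-free ones) so alignments to unknown scaffolds
    can be rejected.
    """

    def __init__(
        self,
        entries: Iterable[tuple[str, int, str, str]],
        reference_scaffolds: Iterable[str] | None = None,
    ) -> None:
        by_scaf: dict[str, list[tuple[int, str, str]]] = {}
        for scaffold, pos1, a, b in entries:
            if a == b:
                raise ValueError(f"alleles must differ at {scaffold}:{pos1}")
            if len(a) != 1 or len(b) != 1:
                raise ValueError(f"non-SNP alleles at {scaffold}:{pos1}")
            by_scaf.setdefault(scaffold, []).append((pos1 - 1, a.upper(), b.upper()))
        self._pos: dict[str, np.ndarray] = {}
        self._a: dict[str, np.ndarray] = {}
        self._b: dict[str, np.ndarray] = {}
        for scaf, rows in by_scaf.items():
            rows.sort()
            self._pos[scaf] = np.array([r[0] for r in rows], dtype=np.int64)
            self._a[scaf] = np.array([r[1] for r in rows])
            self._b[scaf] = np.array([r[2] for r in rows])
        self.reference_scaffolds = (
            set(reference_scaffolds) if reference_scaffolds is not None else None
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, reference_scaffolds=None) -> "SnpCatalog":
        """Build from a frame with columns scaffold, pos (1-based), allele_A, allele_B."""
        return cls(
            frame[["scaffold", "pos", "allele_A", "allele_B"]].itertuples(index=False),
            reference_scaffolds,
        )

    def __len__(self) -> int:
        return int(sum(p.size for p in self._pos.values()))

    @property
    def scaffolds(self) -> set[str]:
        return set(self._pos)

    def knows(self, scaffold: str) -> bool:
        if self.reference_scaffolds is not None:
            return scaffold in self.reference_scaffolds
        return True  # without a reference list, any scaffold is accepted

    def sites_in(self, scaffold: str, start0: int, end0: int):
        """(positions, allele_A, allele_B) for catalog sites in [start0, end0)."""
        pos = self._pos.get(scaffold)
        if pos is None:
            e = np.array([], dtype=np.int64)
            return e, np.array([]), np.array([])
        i, j = np.searchsorted(pos, [start0, end0])
        return pos[i:j], self._a[scaffold][i:j], self._b[scaffold][i:j]

    def swapped(self) -> "SnpCatalog":
        """Catalog with allele_A and allele_B exchanged (label-symmetry checks)."""
        out = SnpCatalog([], self.reference_scaffolds)
        out._pos = {k: v.copy() for k, v in self._pos.items()}
        out._a = {k: v.copy() for k, v in self._b.items()}
        out._b = {k: v.copy() for k, v in self._a.items()}
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (scaf, int(p) + 1, a, b)
            for scaf in sorted(self._pos)
            for p, a, b in zip(self._pos[scaf], self._a[scaf], self._b[scaf])
        ]
        return pd.DataFrame(rows, columns=["scaffold", "pos", "allele_A", "allele_B"])


@dataclass
class ReadObservation:
    """Classification of one read with its allele tallies."""

    read_id: str
    scaffold: str | None
    start: int | None  # 0-based half-open span on the scaffold
    end: int | None
    read_class: ReadClass
    snp_sites_covered: int = 0
    a_allele_matches: int = 0
    b_allele_matches: int = 0

    @property
    def vote(self) -> str | None:
        """'A', 'B' or None — chimeric/repetitive/unmapped/ambiguous reads do not vote."""
        if self.read_class is ReadClass.IDENTICAL:
            return "A"
        if self.read_class is ReadClass.VARIANT:
            return "B"
        return None


@dataclass
class IsolateSummary:
    """Per-class tallies for one isolate's alignments."""

    n_records: int
    n_reads: int  # primary records only (a chimera is one read, two records)
    record_counts: Counter
    read_counts: Counter

    @property
    def proportions(self) -> dict[str, float]:
        if self.n_reads == 0:
            return {}
        return {k.value: v / self.n_reads for k, v in sorted(self.read_counts.items())}


def _has_distant_split(aln: pysam.AlignedSegment, params: ClassifierParams) -> bool:
    if not aln.has_tag("SA"):
        return False
    for part in str(aln.get_tag("SA")).rstrip(";").split(";"):
        fields = part.split(",")
        if len(fields) < 2:
            continue
        rname, pos = fields[0], int(fields[1])
        if rname != aln.reference_name:
            return True
        if abs(pos - 1 - aln.reference_start) > params.chimera_min_distance:
            return True
    return False


def classify_read(
    aln: pysam.AlignedSegment,
    catalog: SnpCatalog,
    params: ClassifierParams | None = None,
) -> ReadObservation:
    """Classify one alignment record into a read class and allele tallies.

    Decision order: UNMAPPED, then REPETITIVE (low MAPQ / reported
    multi-mapping), then CHIMERIC (supplementary or distant split alignment),
    else the catalog sites under the aligned span are tallied.  A base equal
    to allele_B with quality >= min_base_quality is a B match; a base equal to
    allele_A is an A match.  The read votes B on a strict B majority;
    otherwise it votes A (ties included, and reads covering no SNP site are
    A votes by construction of the reference-based method) unless it shows
    more than ``max_nonsnp_mismatches`` off-catalog mismatches, which makes
    it AMBIGUOUS.
    """
    params = params or ClassifierParams()
    rid = aln.query_name or ""
    if aln.is_unmapped:
        return ReadObservation(rid, None, None, None, ReadClass.UNMAPPED)
    scaffold = aln.reference_name
    if not catalog.knows(scaffold):
        raise UnknownScaffoldError(f"alignment to unknown scaffold {scaffold!r}")
    start, end = aln.reference_start, aln.reference_end
    if end is None:  # malformed CIGAR
        raise ValueError(f"read {rid}: alignment without a usable CIGAR")
    if aln.mapping_quality < params.min_mapq or (
        aln.has_tag("NH") and int(aln.get_tag("NH")) > 1
    ):
        return ReadObservation(rid, scaffold, start, end, ReadClass.REPETITIVE)
    if aln.is_supplementary or aln.is_secondary or _has_distant_split(aln, params):
        return ReadObservation(rid, scaffold, start, end, ReadClass.CHIMERIC)

    pos, a_all, b_all = catalog.sites_in(scaffold, start, end)
    a_n = b_n = covered = 0
    mismatch_at_snp = 0
    if pos.size:
        seq = aln.query_sequence or ""
        quals = aln.query_qualities
        # ref->query map; simple M-only CIGAR gets the fast path
        cig = aln.cigartuples or []
        if len(cig) == 1 and cig[0][0] == 0:
            qidx = pos - start
        else:
            lookup = {r: q for q, r in aln.get_aligned_pairs(matches_only=True)}
            qidx = np.array([lookup.get(int(p), -1) for p in pos], dtype=np.int64)
        for k in range(pos.size):
            qi = int(qidx[k])
            if qi < 0 or qi >= len(seq):
                continue
            covered += 1
            base = seq[qi].upper()
            q = quals[qi] if quals is not None else params.min_base_quality
            if base == a_all[k]:
                a_n += 1
            elif base == b_all[k]:
                mismatch_at_snp += 1
                if q >= params.min_base_quality:
                    b_n += 1
            else:
                mismatch_at_snp += 1
    nonsnp = 0
    if aln.has_tag("NM"):
        nonsnp = max(0, int(aln.get_tag("NM")) - mismatch_at_snp)
    if b_n > a_n:
        cls = ReadClass.VARIANT
    elif nonsnp <= params.max_nonsnp_mismatches:
        cls = ReadClass.IDENTICAL
    else:
        cls = ReadClass.AMBIGUOUS
    return ReadObservation(rid, scaffold, start, end, cls, covered, a_n, b_n)


def classify_isolate(
    sam: str | Path | Iterable[pysam.AlignedSegment],
    catalog: SnpCatalog,
    params: ClassifierParams | None = None,
) -> tuple[list[ReadObservation], IsolateSummary]:
    """Classify every record of one isolate's SAM stream.

    Returns record-level observations (every record classified exactly once)
    and a summary whose class proportions are per read — supplementary
    records corroborate their primary's chimera call rather than counting as
    extra reads.  Records with unusable CIGARs are skipped and counted in a
    warning.
    """
    params = params or ClassifierParams()
    if isinstance(sam, (str, Path)):
        handle = pysam.AlignmentFile(str(sam), "r", check_sq=False)
        records: Iterator[pysam.AlignedSegment] = handle.fetch(until_eof=True)
    else:
        records = iter(sam)
    observations: list[ReadObservation] = []
    record_counts: Counter = Counter()
    read_counts: Counter = Counter()
    n_records = n_reads = n_skipped = 0
    for aln in records:
        try:
            obs = classify_read(aln, catalog, params)
        except ValueError:
            n_skipped += 1
            continue
        n_records += 1
        observations.append(obs)
        record_counts[obs.read_class] += 1
        if not (aln.is_supplementary or aln.is_secondary):
            n_reads += 1
            read_counts[obs.read_class] += 1
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} records with malformed CIGARs", stacklevel=2)
    if n_records == 0:
        warnings.warn("empty SAM stream: no reads classified", stacklevel=2)
    return observations, IsolateSummary(n_records, n_reads, record_counts, read_counts)


def observations_frame(observations: Iterable[ReadObservation]) -> pd.DataFrame:
    """Tabular form of per-read observations (the per-read TSV payload)."""
    rows = [
        (
            o.read_id,
            o.scaffold if o.scaffold is not None else "*",
            -1 if o.start is None else o.start,
            -1 if o.end is None else o.end,
            o.read_class.value,
            o.snp_sites_covered,
            o.a_allele_matches,
            o.b_allele_matches,
        )
        for o in observations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "scaffold",
            "start",
            "end",
            "class",
            "snp_sites_covered",
            "a_matches",
            "b_matches",
        ],
    )
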