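"""Standard-format readers and writers shared by all pipeline stages.

FASTA/FASTQ go through Bio.SeqIO, SAM through pysam; the VCF subset used for
the SNP catalog (CHROM/POS/REF/ALT, biallelic SNPs only) is written and
parsed directly so malformed or multiallelic records can be rejected with
file/line/reason messages.  All external coordinates are 1-based inclusive
(SAM/VCF convention); everything internal is 0-based half-open, converted
here at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotyper import GenotypeMatrix, TurningPoint
from .linkmap import LinkageMap
from .readclass import ReadClass, ReadObservation, SnpCatalog
from .simdata import BASES, SimRead, TruthTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_vcf_catalog",
    "write_vcf_catalog",
    "write_truth_sam",
    "write_reads_fastq",
    "read_matrix_csv",
    "write_matrix_csv",
    "write_votes_csv",
    "read_observations_tsv",
    "write_observations_tsv",
    "write_turning_points_tsv",
    "write_map_tsv",
    "write_mstmap_input",
    "write_mapchart_text",
    "write_truth_tsv",
    "write_scaffold_map_tsv",
    "read_scaffold_map_tsv",
]

_DEFAULT_QUAL = 40  # Phred score written for simulated bases


def _decode(seq: np.ndarray | str) -> str:
    if isinstance(seq, np.ndarray):
        return BASES[seq].tobytes().decode()
    return seq


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, "np.ndarray | str"], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(_decode(seq)), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]))
    return out


def write_fastq(records: Iterable[tuple[str, str, Sequence[int]]], path: str | Path) -> None:
    seqrecs = []
    for name, seq, quals in records:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        seqrecs.append(rec)
    SeqIO.write(seqrecs, str(path), "fastq")


# -- SNP catalog (minimal VCF subset) ----------------------------------------



def write_vcf_catalog(
    catalog: pd.DataFrame | SnpCatalog,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write the parental SNP catalog as a minimal VCF (REF = allele A, ALT = allele B)."""
    frame = catalog.to_frame() if isinstance(catalog, SnpCatalog) else catalog
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=sporemap\n")
        for name, ln in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={name},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.scaffold}\t{row.pos}\t.\t{row.allele_A}\t{row.allele_B}\t.\tPASS\t.\n"
            )


def read_vcf_catalog(path: str | Path, reference_scaffolds=None) -> SnpCatalog:
    """Parse a minimal VCF into a SnpCatalog, rejecting non-biallelic-SNP records."""
    entries: list[tuple[str, int, str, str]] = []
    contigs: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##contig="):
                for field in line[len("##contig=<") :].rstrip(">").split(","):
                    if field.startswith("ID="):
                        contigs.append(field[3:])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: VCF record with < 5 columns")
            chrom, pos, _, ref, alt = fields[:5]
            if "," in alt:
                raise ValueError(
                    f"{path}:{lineno}: multiallelic record at {chrom}:{pos} not supported"
                )
            if len(ref) != 1 or len(alt) != 1 or alt == ".":
                raise ValueError(
                    f"{path}:{lineno}: non-SNP record at {chrom}:{pos} not supported"
                )
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad POS {pos!r}") from exc
            if pos_i < 1:
                raise ValueError(f"{path}:{lineno}: POS must be >= 1 at {chrom}:{pos}")
            entries.append((chrom, pos_i, ref, alt))
    if reference_scaffolds is None and contigs:
        reference_scaffolds = contigs
    return SnpCatalog(entries, reference_scaffolds)


# -- simulated reads ----------------------------------------------------------


def _sam_header(reference_lengths: Mapping[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": int(l)} for n, l in reference_lengths.items()],
        }
    )


def write_truth_sam(
    reads: Sequence[SimRead], reference_lengths: Mapping[str, int], path: str | Path
) -> None:
    """Write truth alignments: MAPQ 0 marks repetitive reads, supplementary
    records with SA tags mark the two loci of chimeric reads, and a ZC tag
    records the simulated category for validation."""
    header = _sam_header(reference_lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.name
            a.query_sequence = r.seq_str()
            a.query_qualities = pysam.qualitystring_to_array(
                chr(_DEFAULT_QUAL + 33) * len(r.seq)
            )
            a.reference_name = r.scaffold
            a.reference_start = r.start
            a.mapping_quality = 0 if r.category == "repeat" else 60
            a.set_tag("ZC", r.category)
            if r.category == "chimera":
                l1, l2 = r.length, int(r.length2)
                a.flag = 0
                a.cigarstring = f"{l1}M{l2}S"
                a.set_tag("NM", r.nm)
                a.set_tag("SA", f"{r.scaffold2},{r.start2 + 1},+,{l1}S{l2}M,60,{r.nm2};")
                out.write(a)
                b = pysam.AlignedSegment(header)
                b.query_name = r.name
                b.query_sequence = r.seq_str()
                b.query_qualities = pysam.qualitystring_to_array(
                    chr(_DEFAULT_QUAL + 33) * len(r.seq)
                )
                b.reference_name = r.scaffold2
                b.reference_start = r.start2
                b.flag = 2048  # supplementary
                b.mapping_quality = 60
                b.cigarstring = f"{l1}S{l2}M"
                b.set_tag("NM", r.nm2)
                b.set_tag("ZC", r.category)
                b.set_tag("SA", f"{r.scaffold},{r.start + 1},+,{l1}M{l2}S,60,{r.nm};")
                out.write(b)
            else:
                a.flag = 0
                a.cigarstring = f"{r.length}M"
                a.set_tag("NM", r.nm)
                out.write(a)


def write_reads_fastq(reads: Sequence[SimRead], path: str | Path) -> None:
    write_fastq(
        ((r.name, r.seq_str(), [_DEFAULT_QUAL] * len(r.seq)) for r in reads), path
    )


def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    """Truth genotype table: isolate, scaffold, parent, breakpoint list."""
    rows = []
    for iso in truth.isolates:
        for scaf in truth.scaffolds:
            bps = truth.breakpoints.get(iso, {}).get(scaf, [])
            bp_str = ";".join(f"{chrom}:{cm:.4f}:{bp}" for chrom, cm, bp in bps)
            rows.append((iso, scaf, truth.parent.loc[scaf, iso], bp_str))
    pd.DataFrame(rows, columns=["isolate", "scaffold", "parent", "breakpoints"]).to_csv(
        path, sep="\t", index=False
    )


def write_scaffold_map_tsv(scaffold_map: pd.DataFrame, path: str | Path) -> None:
    scaffold_map.to_csv(path, sep="\t")


def read_scaffold_map_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# -- observations / genotype matrix -------------------------------------------


def write_observations_tsv(observations: Iterable[ReadObservation], path: str | Path) -> None:
    from .readclass import observations_frame

    observations_frame(observations).to_csv(path, sep="\t", index=False)


def read_observations_tsv(path: str | Path) -> list[ReadObservation]:
    frame = pd.read_csv(path, sep="\t", dtype={"read_id": str, "scaffold": str})
    out = []
    for row in frame.to_dict("records"):
        out.append(
            ReadObservation(
                read_id=row["read_id"],
                scaffold=None if row["scaffold"] == "*" else row["scaffold"],
                start=None if row["start"] < 0 else int(row["start"]),
                end=None if row["end"] < 0 else int(row["end"]),
                read_class=ReadClass(row["class"]),
                snp_sites_covered=int(row["snp_sites_covered"]),
                a_allele_matches=int(row["a_matches"]),
                b_allele_matches=int(row["b_matches"]),
            )
        )
    return out


def write_matrix_csv(matrix: GenotypeMatrix, path: str | Path) -> None:
    matrix.codes.to_csv(path, index_label="marker")


def read_matrix_csv(
    path: str | Path, scaffold_lengths: Mapping[str, int] | None = None
) -> GenotypeMatrix:
    codes = pd.read_csv(path, index_col="marker", dtype=str)
    bad = set(np.unique(codes.values)) - {"A", "B", "X", "-"}
    if bad:
        raise ValueError(f"{path}: invalid genotype codes {sorted(bad)}")
    n_a = (codes == "A").astype(np.int64)
    n_b = (codes == "B").astype(np.int64)
    lens = None
    if scaffold_lengths is not None:
        lens = pd.Series({s: int(scaffold_lengths[s]) for s in codes.index})
    return GenotypeMatrix(codes=codes, n_a=n_a, n_b=n_b, scaffold_lengths=lens)


def write_votes_csv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Long-form vote counts: marker, isolate, n_A, n_B."""
    rows = []
    for marker in matrix.markers:
        for iso in matrix.isolates:
            rows.append(
                (marker, iso, int(matrix.n_a.loc[marker, iso]), int(matrix.n_b.loc[marker, iso]))
            )
    pd.DataFrame(rows, columns=["marker", "isolate", "n_A", "n_B"]).to_csv(path, index=False)


def write_turning_points_tsv(turning_points: Sequence[TurningPoint], path: str | Path) -> None:
    rows = [
        (
            tp.scaffold,
            tp.isolate,
            f"{tp.breakpoint_bp:.1f}",
            tp.left_code,
            tp.right_code,
            f"{tp.left_counts[0]}:{tp.left_counts[1]}",
            f"{tp.right_counts[0]}:{tp.right_counts[1]}",
            tp.score,
        )
        for tp in turning_points
    ]
    pd.DataFrame(
        rows,
        columns=[
            "scaffold",
            "isolate",
            "breakpoint_bp",
            "left_code",
            "right_code",
            "left_votes_A:B",
            "right_votes_A:B",
            "score",
        ],
    ).to_csv(path, sep="\t", index=False)


# -- map outputs ---------------------------------------------------------------


def write_map_tsv(linkage_map: LinkageMap, path: str | Path) -> None:
    rows = []
    for lg in linkage_map.groups:
        for rank, (m, pos) in enumerate(zip(lg.markers, lg.positions), 1):
            rows.append((lg.name, rank, m, f"{pos:.3f}"))
    for m in linkage_map.ungrouped:
        rows.append(("ungrouped", 0, m, ""))
    pd.DataFrame(rows, columns=["group", "rank", "marker", "position_cM"]).to_csv(
        path, sep="\t", index=False
    )


def write_mstmap_input(
    matrix: GenotypeMatrix,
    path: str | Path,
    population_name: str = "sporemap",
    cut_off_p_value: float = 1e-6,
) -> None:
    """Genotype matrix in MSTMap input format for external cross-validation.

    Haploid progenies are encoded as a doubled-haploid (DH) population; X
    and '-' codes both map to the missing symbol 'U'.
    """
    codes = matrix.codes.replace({"X": "U", "-": "U"})
    with open(path, "w") as fh:
        fh.write("population_type DH\n")
        fh.write(f"population_name {population_name}\n")
        fh.write("distance_function kosambi\n")
        fh.write(f"cut_off_p_value {cut_off_p_value}\n")
        fh.write("no_map_dist 15.0\n")
        fh.write("no_map_size 0\n")
        fh.write("missing_threshold 1.00\n")
        fh.write("estimation_before_clustering no\n")
        fh.write("detect_bad_data yes\n")
        fh.write("objective_function ML\n")
        fh.write(f"number_of_loci {len(codes.index)}\n")
        fh.write(f"number_of_individual {len(codes.columns)}\n\n")
        fh.write("locus_name\t" + "\t".join(codes.columns) + "\n")
        for marker in codes.index:
            fh.write(marker + "\t" + "\t".join(codes.loc[marker]) + "\n")


def write_mapchart_text(linkage_map: LinkageMap, path: str | Path) -> None:
    """Linkage groups in MapChart-compatible text (group blocks of marker/position)."""
    with open(path, "w") as fh:
        for lg in linkage_map.groups:
            fh.write(f"group {lg.name}\n")
            for m, pos in zip(lg.markers, lg.positions):
                fh.write(f"{m}\t{pos:.2f}\n")
            fh.write("\n")


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
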