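"""Synthetic dikaryon-derived haploid mapping populations with low-coverage shotgun reads.

The generator emulates the experimental design of genotyping single-spore
isolates (SSIs) of a basidiomycete by shallow whole-genome resequencing:

* two parental nuclear haplotypes (A = the assembled reference, B = the
  reference plus Poisson-placed biallelic SNPs),
* haploid meiotic progeny produced by a Poisson (no-interference) crossover
  process along each chromosome,
* shotgun reads drawn uniformly over each isolate's mosaic genome at a target
  fold-coverage, with substitution errors and the two read artifacts the
  mapping step has to discard — chimeric (split) reads and repetitive
  (multi-mapping) reads.

Every read carries its true origin in a truth SAM, and every (isolate,
scaffold) cell has a truth genotype, so downstream classification, majority
voting and map construction can be validated against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "ParentGenomes",
    "TruthTable",
    "SimRead",
    "simulate_parents",
    "simulate_meiosis",
    "simulate_reads",
    "truth_to_matrix",
    "true_marker_span_cm",
    "BASES",
]

# nucleotide alphabet used for all integer-coded sequences (values 0..3)
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated mapping experiment.

    Defaults describe a desk-scale version of the regime the method was
    designed for: a dikaryon with 8 chromosomes, ~1x coverage per isolate,
    454-like ~378 bp reads, 14.3% chimeric and 5.3% repetitive reads, and a
    SNP density of ~4.6 per kbp between the two parental haplotypes.
    """

    n_chromosomes: int = 8
    chrom_genetic_lengths: tuple[float, ...] = (80.0,) * 8  # cM
    n_scaffolds: int = 200
    scaffold_lengths: int | tuple[int, ...] = 10_000  # bp; scalar broadcasts
    snp_rate: float = 4.6e-3  # SNPs per bp between parents
    n_isolates: int = 20
    coverage: float = 1.0  # mean fold-coverage per isolate
    read_length_mean: float = 378.0  # bp
    read_length_sd: float = 60.0  # bp
    min_read_length: int = 50  # bp, truncation floor
    error_rate: float = 0.0  # substitutions per base
    chimera_fraction: float = 0.143
    repeat_fraction: float = 0.053
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_scaffolds < 1 or self.n_isolates < 1:
            raise ValueError("counts must be positive")
        if len(self.chrom_genetic_lengths) != self.n_chromosomes:
            raise ValueError("need one genetic length per chromosome")
        if any(l <= 0 for l in self.chrom_genetic_lengths):
            raise ValueError("chromosome genetic lengths must be > 0")
        lens = self.scaffold_length_array()
        if np.any(lens <= 0) or lens.sum() == 0:
            raise ValueError("scaffold lengths must be positive")
        if self.snp_rate < 0:
            raise ValueError("snp_rate must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        for name in ("chimera_fraction", "repeat_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.chimera_fraction + self.repeat_fraction >= 1:
            raise ValueError("artifact fractions must sum to < 1")
        if self.error_rate < 0 or self.error_rate >= 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length_mean <= 0 or self.read_length_sd < 0:
            raise ValueError("read length parameters must be positive")

    def scaffold_length_array(self) -> np.ndarray:
        if isinstance(self.scaffold_lengths, (int, np.integer)):
            return np.full(self.n_scaffolds, int(self.scaffold_lengths), dtype=np.int64)
        arr = np.asarray(self.scaffold_lengths, dtype=np.int64)
        if arr.size != self.n_scaffolds:
            raise ValueError("scaffold_lengths length must equal n_scaffolds")
        return arr

    def scaffold_names(self) -> list[str]:
        width = max(3, len(str(self.n_scaffolds)))
        return [f"S{i + 1:0{width}d}" for i in range(self.n_scaffolds)]

    def isolate_names(self) -> list[str]:
        width = max(2, len(str(self.n_isolates)))
        return [f"I{i + 1:0{width}d}" for i in range(self.n_isolates)]


@dataclass
class ParentGenomes:
    """The two parental haplotypes plus the diagnostic SNP catalog.

    ``reference`` is parent A; ``alt`` is parent B, identical except at the
    catalog positions.  Sequences are integer-coded (0..3 indexing ``BASES``).
    ``scaffold_map`` anchors every scaffold on a chromosome, with physical
    offsets and a genetic interval [cm_start, cm_end) obtained by spreading
    the chromosome's genetic length uniformly over its physical length.
    """

    reference: dict[str, np.ndarray]
    alt: dict[str, np.ndarray]
    catalog: "pd.DataFrame"  # columns: scaffold, pos (1-based), allele_A, allele_B
    scaffold_map: pd.DataFrame  # index scaffold; chrom, length_bp, cm_start, cm_end, cm_mid

    def genome_size(self) -> int:
        return int(sum(len(s) for s in self.reference.values()))


@dataclass
class TruthTable:
    """Ground truth of one simulated progeny.

    ``parent``: scaffold x isolate frame of 'A'/'B' — the haplotype occupying
    the larger share of the scaffold (scaffolds are wholly inherited unless a
    crossover lands inside them, in which case the within-scaffold switch is
    recorded in ``breakpoints``).
    ``segments``: per isolate, per scaffold, list of (start_bp, end_bp, parent)
    half-open runs making up the mosaic sequence.
    ``crossovers``: per isolate, list of (chromosome index, genetic pos cM).
    """

    parent: pd.DataFrame
    segments: dict[str, dict[str, list[tuple[int, int, str]]]]
    breakpoints: dict[str, dict[str, list[tuple[int, float, int]]]]
    crossovers: dict[str, list[tuple[int, float]]] = field(default_factory=dict)

    @property
    def isolates(self) -> list[str]:
        return list(self.parent.columns)

    @property
    def scaffolds(self) -> list[str]:
        return list(self.parent.index)


@dataclass
class SimRead:
    """One simulated shotgun read with its true origin.

    ``category`` is 'normal', 'chimera' or 'repeat'.  Chimeras join two loci:
    (scaffold, start, length) describe the first (primary) segment and
    ``scaffold2``/``start2``/``length2`` the supplementary one.  ``nm`` holds
    edit distance to the reference over the primary segment.
    """

    name: str
    seq: np.ndarray  # integer-coded, full read
    scaffold: str
    start: int  # 0-based on scaffold
    length: int
    category: str = "normal"
    nm: int = 0
    scaffold2: str | None = None
    start2: int | None = None
    length2: int | None = None
    nm2: int = 0

    def seq_str(self) -> str:
        return BASES[self.seq].tobytes().decode()


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[stream])


def simulate_parents(config: SimConfig, rng: np.random.Generator | None = None) -> ParentGenomes:
    """Draw the reference (parent A), parent B and the SNP catalog.

    Parent B differs from the reference at Poisson-placed biallelic SNPs at
    ``snp_rate`` per bp.  Scaffolds are laid contiguously onto chromosomes
    (round-robin balanced by count), and genetic coordinates interpolate
    linearly within a chromosome.  Scaffolds that receive no SNP trigger a
    warning: they can never be genotyped 'B' from SNP evidence.
    """
    rng = _rng(config, 0) if rng is None else rng
    names = config.scaffold_names()
    lens = config.scaffold_length_array()

    # balanced contiguous assignment of scaffolds to chromosomes
    chrom_of = np.array_split(np.arange(config.n_scaffolds), config.n_chromosomes)
    rows = []
    reference: dict[str, np.ndarray] = {}
    alt: dict[str, np.ndarray] = {}
    cat_rows: list[tuple[str, int, str, str]] = []
    for ci, idxs in enumerate(chrom_of):
        phys = int(lens[idxs].sum()) if len(idxs) else 0
        gl = config.chrom_genetic_lengths[ci]
        cm_per_bp = gl / phys if phys else 0.0
        off = 0
        for si in idxs:
            name, L = names[si], int(lens[si])
            seq = rng.integers(0, 4, size=L, dtype=np.uint8)
            reference[name] = seq
            bseq = seq.copy()
            n_snp = rng.poisson(config.snp_rate * L)
            n_snp = min(n_snp, L)
            if n_snp == 0 and config.snp_rate > 0:
                warnings.warn(
                    f"scaffold {name} carries no SNP and will be genotype-uninformative",
                    stacklevel=2,
                )
            if n_snp:
                pos = np.sort(rng.choice(L, size=n_snp, replace=False))
                shift = rng.integers(1, 4, size=n_snp, dtype=np.uint8)
                bseq[pos] = (bseq[pos] + shift) % 4
                for p in pos:
                    cat_rows.append(
                        (name, int(p) + 1, chr(BASES[seq[p]]), chr(BASES[bseq[p]]))
                    )
            alt[name] = bseq
            rows.append(
                {
                    "scaffold": name,
                    "chrom": ci,
                    "length_bp": L,
                    "offset_bp": off,
                    "cm_start": off * cm_per_bp,
                    "cm_end": (off + L) * cm_per_bp,
                }
            )
            off += L
    smap = pd.DataFrame(rows).set_index("scaffold")
    smap["cm_mid"] = (smap.cm_start + smap.cm_end) / 2
    catalog = pd.DataFrame(cat_rows, columns=["scaffold", "pos", "allele_A", "allele_B"])
    return ParentGenomes(reference=reference, alt=alt, catalog=catalog, scaffold_map=smap)


def _parent_at(xs: np.ndarray, start: int, g: float) -> int:
    """Parent index (0=A, 1=B) at genetic position g given sorted crossovers."""
    return (start + int(np.searchsorted(xs, g, side="right"))) % 2


def simulate_meiosis(
    config: SimConfig,
    scaffold_map: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Produce independent haploid meiotic products.

    Crossovers on each chromosome follow a Poisson process with mean
    (genetic length)/100 Morgans — i.e. Haldane's no-interference model —
    and the starting haplotype is a fair coin, so two loci d cM apart are
    recombinant with probability (1 - exp(-2d/100))/2.
    """
    rng = _rng(config, 1) if rng is None else rng
    isolates = config.isolate_names()
    scaffolds = list(scaffold_map.index)
    parent = pd.DataFrame(index=scaffolds, columns=isolates, dtype=object)
    segments: dict[str, dict[str, list[tuple[int, int, str]]]] = {}
    breakpoints: dict[str, dict[str, list[tuple[int, float, int]]]] = {}
    crossovers: dict[str, list[tuple[int, float]]] = {}

    by_chrom = {ci: sub for ci, sub in scaffold_map.groupby("chrom")}
    for iso in isolates:
        segments[iso] = {}
        breakpoints[iso] = {}
        xo: list[tuple[int, float]] = []
        for ci in range(config.n_chromosomes):
            gl = config.chrom_genetic_lengths[ci]
            n_co = rng.poisson(gl / 100.0)
            xs = np.sort(rng.uniform(0.0, gl, size=n_co))
            start = int(rng.integers(0, 2))
            xo.extend((ci, float(x)) for x in xs)
            sub = by_chrom.get(ci)
            if sub is None:
                continue
            for name, row in sub.iterrows():
                c0, c1, L = row.cm_start, row.cm_end, int(row.length_bp)
                inside = xs[(xs > c0) & (xs < c1)]
                if inside.size == 0:
                    p = "AB"[_parent_at(xs, start, (c0 + c1) / 2)]
                    parent.loc[name, iso] = p
                    segments[iso][name] = [(0, L, p)]
                    breakpoints[iso][name] = []
                    continue
                # within-scaffold switch(es): map cM -> bp linearly
                span = c1 - c0
                bps = [int(round((x - c0) / span * L)) for x in inside]
                bps = [min(max(b, 1), L - 1) for b in bps]
                cuts = [0] + bps + [L]
                segs: list[tuple[int, int, str]] = []
                share = {"A": 0, "B": 0}
                g_probe = np.concatenate(([c0], inside, [c1]))
                for k in range(len(cuts) - 1):
                    gmid = (g_probe[k] + g_probe[k + 1]) / 2
                    p = "AB"[_parent_at(xs, start, gmid)]
                    if cuts[k + 1] > cuts[k]:
                        segs.append((cuts[k], cuts[k + 1], p))
                        share[p] += cuts[k + 1] - cuts[k]
                segments[iso][name] = segs
                breakpoints[iso][name] = [
                    (ci, float(x), b) for x, b in zip(inside, bps)
                ]
                parent.loc[name, iso] = "A" if share["A"] >= share["B"] else "B"
        crossovers[iso] = xo
    return TruthTable(
        parent=parent, segments=segments, breakpoints=breakpoints, crossovers=crossovers
    )


def _haplotype(genomes: ParentGenomes, segs: list[tuple[int, int, str]], name: str) -> np.ndarray:
    if len(segs) == 1 and segs[0][2] == "A":
        return genomes.reference[name]
    if len(segs) == 1 and segs[0][2] == "B":
        return genomes.alt[name]
    parts = [
        (genomes.reference if p == "A" else genomes.alt)[name][a:b] for a, b, p in segs
    ]
    return np.concatenate(parts)


def _apply_errors(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or seq.size == 0:
        return seq
    n = rng.binomial(seq.size, rate)
    if n == 0:
        return seq
    seq = seq.copy()
    pos = rng.choice(seq.size, size=min(n, seq.size), replace=False)
    seq[pos] = (seq[pos] + rng.integers(1, 4, size=pos.size, dtype=np.uint8)) % 4
    return seq


def simulate_reads(
    config: SimConfig,
    truth: TruthTable,
    genomes: ParentGenomes,
    rng: np.random.Generator | None = None,
) -> dict[str, list[SimRead]]:
    """Draw shotgun reads for every isolate over its mosaic genome.

    Read count per isolate is Poisson with mean coverage * G / mean length;
    starts are uniform over the genome (scaffolds weighted by length), lengths
    Normal(mean, sd) truncated at ``min_read_length`` and at the scaffold end.
    A ``chimera_fraction`` of reads join two random loci and a
    ``repeat_fraction`` emulate multi-mapping reads (their truth alignments
    get mapping quality 0).  Substitution errors are applied at
    ``error_rate``; ``nm`` records the edit distance to the reference.
    """
    rng = _rng(config, 2) if rng is None else rng
    names = list(genomes.reference)
    lens = np.array([len(genomes.reference[n]) for n in names], dtype=np.int64)
    weights = lens / lens.sum()
    G = int(lens.sum())
    out: dict[str, list[SimRead]] = {}

    for iso in truth.isolates:
        haps = {n: _haplotype(genomes, truth.segments[iso][n], n) for n in names}
        n_reads = int(rng.poisson(config.coverage * G / config.read_length_mean))
        if n_reads == 0:
            warnings.warn(f"isolate {iso} received 0 reads at this coverage", stacklevel=2)
            out[iso] = []
            continue

        def sample_locus() -> tuple[str, int, int]:
            si = rng.choice(len(names), p=weights)
            name = names[si]
            L = int(lens[si])
            rl = int(round(rng.normal(config.read_length_mean, config.read_length_sd)))
            rl = max(config.min_read_length, rl)
            rl = min(rl, L)
            start = int(rng.integers(0, L - rl + 1))
            return name, start, rl

        reads: list[SimRead] = []
        u = rng.random(n_reads)
        for ri in range(n_reads):
            rid = f"{iso}_r{ri:06d}"
            if u[ri] < config.chimera_fraction:
                n1, s1, l1 = sample_locus()
                n2, s2, l2 = sample_locus()
                l1, l2 = max(config.min_read_length // 2, l1 // 2), max(
                    config.min_read_length // 2, l2 // 2
                )
                seg1 = _apply_errors(haps[n1][s1 : s1 + l1], config.error_rate, rng)
                seg2 = _apply_errors(haps[n2][s2 : s2 + l2], config.error_rate, rng)
                reads.append(
                    SimRead(
                        name=rid,
                        seq=np.concatenate([seg1, seg2]),
                        scaffold=n1,
                        start=s1,
                        length=l1,
                        category="chimera",
                        nm=int(np.count_nonzero(seg1 != genomes.reference[n1][s1 : s1 + l1])),
                        scaffold2=n2,
                        start2=s2,
                        length2=l2,
                        nm2=int(np.count_nonzero(seg2 != genomes.reference[n2][s2 : s2 + l2])),
                    )
                )
                continue
            name, start, rl = sample_locus()
            seq = _apply_errors(haps[name][start : start + rl], config.error_rate, rng)
            cat = "repeat" if u[ri] < config.chimera_fraction + config.repeat_fraction else "normal"
            reads.append(
                SimRead(
                    name=rid,
                    seq=seq,
                    scaffold=name,
                    start=start,
                    length=rl,
                    category=cat,
                    nm=int(np.count_nonzero(seq != genomes.reference[name][start : start + rl])),
                )
            )
        out[iso] = reads
    return out


def truth_to_matrix(truth: TruthTable, scaffold_lengths: Mapping[str, int] | None = None):
    """Full-information genotype matrix straight from the truth table.

    Used for parameter-recovery experiments where genotyping noise is not
    under study: every cell carries its true parental code with a nominal
    single supporting vote.
    """
    from .genotyper import GenotypeMatrix

    codes = truth.parent.copy()
    n_a = (codes == "A").astype(int)
    n_b = (codes == "B").astype(int)
    lens = None
    if scaffold_lengths is not None:
        lens = pd.Series({s: int(scaffold_lengths[s]) for s in codes.index})
    return GenotypeMatrix(codes=codes, n_a=n_a, n_b=n_b, scaffold_lengths=lens)


def true_marker_span_cm(scaffold_map: pd.DataFrame) -> float:
    """Total genetic span between first and last marker midpoints per chromosome."""
    spans = scaffold_map.groupby("chrom")["cm_mid"].agg(lambda s: s.max() - s.min())
    return float(spans.sum())
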