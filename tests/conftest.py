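"""Shared fixtures: a small simulated mapping experiment used across modules."""

from __future__ import annotations

import warnings

import pysam
import pytest

from sporemap import io as sio
from sporemap.readclass import SnpCatalog, classify_isolate
from sporemap.genotyper import build_matrix
from sporemap.simdata import SimConfig, simulate_meiosis, simulate_parents, simulate_reads


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Desk-scale slice of the study regime: 2 chromosomes, 1.5x coverage."""
    return SimConfig(
        n_chromosomes=2,
        chrom_genetic_lengths=(60.0, 60.0),
        n_scaffolds=20,
        scaffold_lengths=8_000,
        n_isolates=10,
        coverage=1.5,
        error_rate=0.005,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_bundle(tiny_config):
    """(genomes, truth, reads) simulated once for the whole session."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        genomes = simulate_parents(tiny_config)
        truth = simulate_meiosis(tiny_config, genomes.scaffold_map)
        reads = simulate_reads(tiny_config, truth, genomes)
    return genomes, truth, reads


@pytest.fixture(scope="session")
def catalog(sim_bundle) -> SnpCatalog:
    genomes, _, _ = sim_bundle
    ref_lens = {n: len(s) for n, s in genomes.reference.items()}
    return SnpCatalog.from_frame(genomes.catalog, ref_lens)


@pytest.fixture(scope="session")
def sam_dir(sim_bundle, tmp_path_factory):
    """Truth SAM files, one per isolate."""
    genomes, _, reads = sim_bundle
    ref_lens = {n: len(s) for n, s in genomes.reference.items()}
    d = tmp_path_factory.mktemp("sams")
    for iso, rs in reads.items():
        sio.write_truth_sam(rs, ref_lens, d / f"{iso}.sam")
    return d


@pytest.fixture(scope="session")
def obs_by_isolate(sim_bundle, sam_dir, catalog):
    _, truth, _ = sim_bundle
    out = {}
    for iso in truth.isolates:
        obs, _ = classify_isolate(sam_dir / f"{iso}.sam", catalog)
        out[iso] = obs
    return out


@pytest.fixture(scope="session")
def genotype_matrix(sim_bundle, obs_by_isolate):
    genomes, _, _ = sim_bundle
    return build_matrix(
        obs_by_isolate,
        list(genomes.scaffold_map.index),
        genomes.scaffold_map["length_bp"].to_dict(),
    )


@pytest.fixture()
def sam_header(catalog, sim_bundle):
    genomes, _, _ = sim_bundle
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": n, "LN": len(s)} for n, s in genomes.reference.items()],
        }
    )


def make_record(
    header,
    name: str,
    scaffold: str | None,
    start: int,
    seq: str,
    mapq: int = 60,
    flag: int = 0,
    quals: str | None = None,
    tags: dict | None = None,
):
    """Hand-build one SAM record for classifier unit tests."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array(quals or ("I" * len(seq)))
    a.flag = flag
    if scaffold is not None:
        a.reference_name = scaffold
        a.reference_start = start
        a.mapping_quality = mapq
        a.cigarstring = f"{len(seq)}M"
    for k, v in (tags or {}).items():
        a.set_tag(k, v)
    return a
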