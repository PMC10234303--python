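import numpy as np
import pytest

from mutaccum import genome_context as gcm
from mutaccum.synthetic_data import (
    SimConfig, design_from_config, simulate_genome, simulate_ma_experiment,
)

# desk-scale study system shared across the suite: 250-kb genome, the
# study's rates and design (39 lines, 40 transfers, 25.375 mitoses/transfer)
TINY_LENGTHS = (150_000, 100_000)


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=11, contig_lengths=TINY_LENGTHS)


@pytest.fixture(scope="session")
def sim_annotation(sim_cfg):
    ann, _ = simulate_genome(sim_cfg)
    return ann


@pytest.fixture(scope="session")
def sim_design(sim_cfg):
    return design_from_config(sim_cfg)


@pytest.fixture(scope="session")
def sim_mutations(sim_cfg, sim_annotation):
    muts, sidecar = simulate_ma_experiment(sim_annotation, sim_cfg)
    return muts, sidecar


@pytest.fixture(scope="session")
def sim_annotated(sim_mutations, sim_annotation):
    muts, _ = sim_mutations
    return gcm.annotate_mutations(muts, sim_annotation)


@pytest.fixture(scope="session")
def sim_composition(sim_annotation):
    return gcm.trinucleotide_census(sim_annotation)


@pytest.fixture(scope="session")
def sim_windows(sim_annotation):
    return gcm.make_windows(sim_annotation)


@pytest.fixture(scope="session")
def sim_catalog(sim_annotation):
    return gcm.find_homopolymers(sim_annotation)


def write_fasta(path, contigs: dict):
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")


def write_bed(path, rows):
    with open(path, "w") as fh:
        for contig, s, e in rows:
            fh.write(f"{contig}\t{s}\t{e}\n")


@pytest.fixture
def mini_genome(tmp_path):
    """1-contig toy genome with K9 [200,400), cen [250,300), K27 [500,600)."""
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    fa = tmp_path / "g.fa"
    write_fasta(fa, {"chr1": seq})
    k9 = tmp_path / "k9.bed"
    k27 = tmp_path / "k27.bed"
    cen = tmp_path / "cen.bed"
    write_bed(k9, [("chr1", 200, 400)])
    write_bed(k27, [("chr1", 500, 600)])
    write_bed(cen, [("chr1", 250, 300)])
    return {"fasta": fa, "k9": k9, "k27": k27, "cen": cen, "seq": seq}
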