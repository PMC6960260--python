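import numpy as np
import pytest

from enhprs.synthetic import random_genome
from enhprs.training import prs_benchmark


class DictGenome(dict):
    """Minimal genome handle: mapping chrom -> sequence string."""


@pytest.fixture(scope="session")
def toy_genome() -> DictGenome:
    """Two random 12 kb chromosomes plus one with an N-block."""
    chroms = random_genome({"chr1": 12000, "chr2": 12000}, gc=0.42, seed=42)
    g = DictGenome(chroms)
    # chrN: first 3 kb clean, then 6 kb of N, then 3 kb clean
    clean = random_genome({"c": 6000}, gc=0.42, seed=43)["c"]
    g["chrN"] = clean[:3000] + "N" * 6000 + clean[3000:]
    return g


@pytest.fixture(scope="session")
def toy_genome_fasta(tmp_path_factory, toy_genome):
    import pyfaidx

    path = tmp_path_factory.mktemp("genome") / "toy.fa"
    with open(path, "w") as fh:
        for name, seq in toy_genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    return pyfaidx.Fasta(str(path))


@pytest.fixture(scope="session")
def prs_results():
    """The desk-scale warm-start vs ab-initio comparison (5 seeds, 3
    tissues, fast 200 bp profile).  Computed once per session; this is the
    most expensive fixture in the suite."""
    return prs_benchmark(seeds=(0, 1, 2, 3, 4))
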