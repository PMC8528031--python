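import os

import numpy as np
import pytest
from hypothesis import settings

import covtally as ct
from covtally.simulate import sam_to_bam, write_fixture

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_bundle():
    """A moderately spliced, mutated paired-end fixture shared across tests."""
    return ct.generate(ct.FixtureConfig(seed=11, n_fragments=600))


@pytest.fixture(scope="session")
def fixture_paths(fixture_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(fixture_bundle, str(d))
    paths["bam"] = sam_to_bam(paths["sam"], os.path.join(str(d), "reads.bam"))
    return paths


@pytest.fixture(scope="session")
def fixture_records(fixture_paths):
    chroms, stream = ct.read_alignments(fixture_paths["sam"])
    return chroms, list(stream)


@pytest.fixture()
def random_bed(tmp_path):
    """50 random query intervals over the fixture genome, written as BED."""
    rng = np.random.default_rng(5)
    path = tmp_path / "queries.bed"
    with open(path, "w") as fh:
        for i in range(50):
            chrom = "chr1" if i % 2 else "chr2"
            s = int(rng.integers(0, 99_000))
            e = min(s + int(rng.integers(50, 2_000)), 100_000)
            fh.write(f"{chrom}\t{s}\t{e}\tq{i}\n")
    return str(path)
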