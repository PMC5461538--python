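import pytest

from ntpg.fixtures import synth_genome


@pytest.fixture(scope="session")
def small_fixture():
    """A 2x20 kb genome with 16 planted ORFs shared across tests."""
    return synth_genome(n_contigs=2, contig_len=20_000, n_orfs=16, seed=42)


@pytest.fixture()
def tmp_fasta(tmp_path):
    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
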