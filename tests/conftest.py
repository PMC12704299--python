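import pytest

from ampedit.pipeline import packaged_data
from ampedit.seqio import read_fasta


@pytest.fixture(scope="session")
def trbc_amplicon() -> tuple[str, str]:
    ((ref_id, seq),) = read_fasta(packaged_data("trbc_amplicon.fa")).items()
    return ref_id, seq


@pytest.fixture(scope="session")
def toy_mh_reference() -> str:
    # two copies of AGGC at [2,6) and [9,13) around a cut between 7 and 8
    return "TTAGGCATCAGGCTAA"
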