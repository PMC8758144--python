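import pytest

from clipscope import AlignedRead, MismatchRecord, TranscriptModel


@pytest.fixture
def model_100_300_200() -> TranscriptModel:
    """Reference toy transcript: 100 nt 5'-UTR, 300 nt CDS, 200 nt 3'-UTR."""
    return TranscriptModel("G1", "T1", len5=100, lenC=300, len3=200)


def make_read(start, end, tx="T1", strand="+", barcode="ACGTACGT", mismatches=()):
    return AlignedRead(
        transcript_id=tx,
        start=start,
        end=end,
        strand=strand,
        barcode=barcode,
        mismatches=[MismatchRecord(*m) for m in mismatches],
    )


@pytest.fixture
def read_factory():
    return make_read
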