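import pytest

from tcrrep import io
from tcrrep.types import ClonotypeRecord, RepertoireSample
from tcrrep.annotate import classify_frame, translate_junction


@pytest.fixture(scope="session")
def germline():
    return io.read_germline(io.default_germline_path())


@pytest.fixture(scope="session")
def germline_by_name(germline):
    return {s.name: s for s in germline}


@pytest.fixture(scope="session")
def patcr_db():
    return io.read_patcr_db(io.default_patcr_path())


@pytest.fixture(scope="session")
def clinical():
    return io.read_clinical_table()


def make_clonotype(cdr3_nt, v="TRBVS1", j="TRBJS1", d=None, reads=1):
    """Build a clonotype record with recomputed frame/translation."""
    return ClonotypeRecord(
        cdr3_nt=cdr3_nt,
        cdr3_aa=translate_junction(cdr3_nt),
        v_call=v,
        j_call=j,
        d_call=d,
        read_count=reads,
        frame_class=classify_frame(cdr3_nt),
    )


def make_sample(specs, sample_id="s", group="test"):
    """specs: list of (cdr3_nt, v, j, reads) tuples."""
    records = [make_clonotype(nt, v, j, reads=r) for nt, v, j, r in specs]
    return RepertoireSample(sample_id, group, records)
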