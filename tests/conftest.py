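import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # printed_values helper

from cryoerc.cohort_model import Cohort, ErcStatus, PatientRecord, VeinRecord


@pytest.fixture
def small_cohort() -> Cohort:
    """One patient with 4 veins: 3 complete, 1 missing its nadir."""
    veins = [
        VeinRecord("P1", "LSPV", tti_s=40.0, n_unsuccessful=0, nadir_temp_c=-47.0,
                   erc_status=ErcStatus.NONE),
        VeinRecord("P1", "LIPV", tti_s=55.0, n_unsuccessful=1, nadir_temp_c=-41.0,
                   erc_status=ErcStatus.DORMANT_WITH_ADENOSINE),
        VeinRecord("P1", "RIPV", tti_s=30.0, n_unsuccessful=0, nadir_temp_c=-50.0,
                   erc_status=ErcStatus.NONE),
        VeinRecord("P1", "RSPV", tti_s=35.0, n_unsuccessful=0, nadir_temp_c=None,
                   erc_status=ErcStatus.UNTESTED),
    ]
    return Cohort(patients=[PatientRecord("P1", vein_records=veins)], name="small")
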