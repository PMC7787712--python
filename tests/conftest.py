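import numpy as np
import pytest

from burrowtherm.data import Month, ObservationRecord, Sex


@pytest.fixture
def rng():
    return np.random.default_rng(20190329)


def make_record(tb=30.0, s=28.0, b=22.0, sex=Sex.female, cw=13.5,
                month=Month.may, crab_id="c1", site="marsh"):
    return ObservationRecord(
        crab_id=crab_id, sex=sex, carapace_width_mm=cw, body_temp_c=tb,
        surface_temp_c=s, burrow_temp_c=b, month=month, site=site)


CSV_HEADER = ("crab_id,site,sex,carapace_width_mm,body_temp_c,"
              "surface_temp_c,burrow_temp_c,month")


@pytest.fixture
def clean_csv(tmp_path):
    rows = [
        "c1,marsh,female,10.2,24.5,23.0,21.0,March",
        "c2,marsh,female,14.0,25.1,24.0,21.5,March",
        "c3,marsh,male,12.5,30.0,29.5,24.0,May",
        "c4,marsh,male,16.0,31.2,30.0,25.0,May",
        "c5,marsh,female,11.0,33.8,40.0,26.0,August",
    ]
    p = tmp_path / "clean.csv"
    p.write_text(CSV_HEADER + "\n" + "\n".join(rows) + "\n")
    return p
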