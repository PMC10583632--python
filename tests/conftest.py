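from datetime import date

import pytest
from hypothesis import HealthCheck, settings

import mauflow as mf

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def unit():
    return mf.UnitSpec("u", 5)


@pytest.fixture
def flat_coeffs():
    """Constant-rate world: 2 potential admissions/day, p(discharge) = 0.5."""
    adm = {"u": mf.AdmissionCoefficients(2.0)}
    dis = {"u": mf.DischargeCoefficients(0.0)}
    return adm, dis


def make_records_csv(path, rows, header="unit_id,admission_date,discharge_date,age,sex,municipality"):
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def records_csv_factory(tmp_path):
    def factory(rows, name="records.csv", **kw):
        return make_records_csv(tmp_path / name, rows, **kw)

    return factory


def stay(unit_id, adm, dis):
    return mf.AdmissionRecord(unit_id=unit_id, admission_date=adm, discharge_date=dis)


@pytest.fixture
def stay_factory():
    return stay
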