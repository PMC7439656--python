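import pandas as pd
import pytest

from fuzzyord import SEVERITY, IntervalResponse


@pytest.fixture
def scale():
    return SEVERITY


@pytest.fixture
def interval_csv(tmp_path):
    """Write an interval-survey CSV from a list of row strings."""

    def _write(rows, header="respondent_id,stratum,level,lower,upper,representative_point"):
        path = tmp_path / "survey.csv"
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write


@pytest.fixture
def qualitative_csv(tmp_path):
    def _write(rows, header="respondent_id,value,chosen_level"):
        path = tmp_path / "qual.csv"
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return _write


def make_interval(level, lower, upper, rid="r1", stratum="doctor", rp=None):
    return IntervalResponse(
        respondent_id=rid, stratum=stratum, level=level, lower=lower, upper=upper,
        representative_point=rp,
    )


@pytest.fixture
def make_response():
    return make_interval
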