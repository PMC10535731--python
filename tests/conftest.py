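import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def clonogenic_csv(tmp_path):
    """Well-formed 3-row clonogenic table."""
    path = tmp_path / "clonogenic.csv"
    path.write_text(
        "radiation_gy,drug_um,cells_plated,colonies,replicate\n"
        "0,0,200,90,0\n"
        "0,0,200,110,1\n"
        "4,0,200,26,0\n"
    )
    return path


@pytest.fixture
def caliper_csv(tmp_path):
    path = tmp_path / "caliper.csv"
    path.write_text(
        "animal_id,group,day,length_mm,width_mm,height_mm\n"
        "c1,control,7,9.0,8.0,6.0\n"
        "c1,control,14,13.0,11.0,9.0\n"
        "r1,radiation,7,7.0,6.0,5.0\n"
        "r1,radiation,14,9.0,8.0,7.0\n"
    )
    return path
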