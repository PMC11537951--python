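import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from anthro_reliability.records import ReplicateGroupSet, Stratum

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_groups(values_per_group, mode="inter", parameter="weight"):
    """Build a ReplicateGroupSet from a plain list of value lists."""
    groups = [(f"g{i}", np.asarray(v, dtype=float)) for i, v in enumerate(values_per_group)]
    return ReplicateGroupSet(mode=mode, parameter=parameter, stratum=Stratum(), groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(20240514)


@pytest.fixture
def measurement_csv(tmp_path):
    """A tiny valid long-format CSV: 2 volunteers, 2-3 raters, 2 rounds."""
    lines = ["volunteer_id,rater_id,rater_group,parameter,round,value,age_years"]
    vals = {
        ("A", "r1"): (10.0, 10.2), ("A", "r2"): (10.2, 10.2), ("A", "r3"): (10.4, 10.3),
        ("B", "r1"): (20.0, 20.1), ("B", "r2"): (20.3, 20.0),
    }
    for (vol, rater), (v1, v2) in vals.items():
        age = 1.0 if vol == "A" else 30.0
        lines.append(f"{vol},{rater},fieldworker,muac,1,{v1},{age}")
        lines.append(f"{vol},{rater},fieldworker,muac,2,{v2},{age}")
    path = tmp_path / "measurements.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
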