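"""Synthetic exercise generator: determinism, design shape, recovery."""

import numpy as np
import pandas as pd
import pytest

from anthro_reliability.icc import icc_oneway
from anthro_reliability.records import build_inter_view, build_intra_view, validate
from anthro_reliability.synth import (
    ParameterModel,
    SynthConfig,
    generate_dataset,
    study_like_config,
    study_like_dataset,
)
from anthro_reliability.tem import pooled_tem


def simple_config(
    n_vol=20,
    sigma_b=5.0,
    sigma_e=0.3,
    sigma_r=0.0,
    k_pmf=None,
    rounding=False,
    seed=0,
    mean=50.0,
):
    pm = ParameterModel(
        means={"over12": mean},
        between_sd={"over12": sigma_b},
        error_sd={"fieldworker": sigma_e},
        rater_bias_sd={"fieldworker": sigma_r},
        age_groups=("over12",),
    )
    return SynthConfig(
        parameters={"weight": pm},
        n_volunteers={("fieldworker", "over12"): n_vol},
        n_rater_pairs={"fieldworker": 46},
        raters_per_volunteer=k_pmf or {2: 1.0},
        apply_rounding=rounding,
        seed=seed,
    )


class TestGenerateDataset:
    def test_deterministic_for_fixed_seed(self):
        df1, _ = generate_dataset(simple_config(seed=5))
        df2, _ = generate_dataset(simple_config(seed=5))
        pd.testing.assert_frame_equal(df1, df2)
        df3, _ = generate_dataset(simple_config(seed=6))
        assert not df1["value"].equals(df3["value"])

    def test_noiseless_limit(self):
        df, _ = generate_dataset(simple_config(sigma_e=0.0, sigma_r=0.0, rounding=False))
        per_vol = df.groupby("volunteer_id")["value"].nunique()
        assert (per_vol == 1).all()
        intra = build_intra_view(df, "weight")
        assert pooled_tem(intra) == 0.0
        inter = build_inter_view(df, "weight")
        assert icc_oneway(inter) == 1.0

    def test_ground_truth_reliabilities(self):
        _, truth = generate_dataset(simple_config(sigma_b=5, sigma_e=0.5, sigma_r=0.5))
        key = ("weight", "fieldworker", "over12")
        tot = 25 + 0.25 + 0.25
        assert truth.rho_inter[key] == pytest.approx(25 / tot)
        assert truth.rho_intra[key] == pytest.approx(25.25 / tot)
        assert truth.tem[key] == 0.5

    def test_intra_tem_recovers_error_sd(self):
        df, truth = generate_dataset(simple_config(n_vol=500, sigma_e=0.3, seed=3))
        tem = pooled_tem(build_intra_view(df, "weight"))
        assert 0.28 <= tem <= 0.32

    def test_rounding_inflates_tem_on_paired_seeds(self):
        base, _ = generate_dataset(simple_config(n_vol=300, sigma_e=0.05, rounding=False, seed=9))
        rounded, _ = generate_dataset(simple_config(n_vol=300, sigma_e=0.05, rounding=True, seed=9))
        # identical latent draws, only the grid differs (weight grid 0.01)
        t0 = pooled_tem(build_intra_view(base, "weight"))
        t1 = pooled_tem(build_intra_view(rounded, "weight"))
        assert t1 >= t0

    def test_values_on_grid_when_rounding(self):
        df, _ = generate_dataset(simple_config(rounding=True))
        ratio = df["value"] / 0.01
        assert np.allclose(ratio, ratio.round(), atol=1e-6)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            simple_config(sigma_e=-1.0)
        with pytest.raises(ValueError):
            simple_config(k_pmf={1: 1.0})
        with pytest.raises(ValueError):
            simple_config(k_pmf={2: 0.5, 3: 0.4})


@pytest.fixture(scope="module")
def dataset():
    return study_like_dataset(42)


class TestStudyLikePreset:
    def test_validation_clean(self, dataset):
        df, truth = dataset
        df, report = validate(df)
        assert report.ok
        assert not report.off_grid

    def test_design_dimensions(self, dataset):
        df, _ = dataset
        by_group = df.groupby("rater_group")["volunteer_id"].nunique()
        assert by_group["site_lead"] == 15
        assert by_group["fieldworker"] == 75
        assert df.groupby("rater_group")["rater_id"].nunique()["fieldworker"] <= 46
        assert set(df["parameter"]) == {"weight", "length_height", "muac", "waist", "calf"}

    def test_raters_per_volunteer_in_design_range(self, dataset):
        df, _ = dataset
        for param in df["parameter"].unique():
            view = build_inter_view(df, param)
            sizes = view.group_sizes()
            assert sizes.min() >= 2 and sizes.max() <= 11

    def test_circumferences_adult_only(self, dataset):
        df, _ = dataset
        wc = df[df["parameter"].isin(["waist", "calf"])]
        assert set(wc["age_group"]) == {"over12"}

    def test_rounds_complete(self, dataset):
        df, _ = dataset
        counts = df.groupby(["volunteer_id", "rater_id", "parameter"])["round"].nunique()
        assert (counts == 2).all()
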