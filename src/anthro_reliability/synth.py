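"""Synthetic standardisation-exercise generator with known ground truth.

The generator draws from the variance-components model the reliability
statistics implicitly assume:

    x_{v,r,round} = round_to_grid( mu_v + b_r + eps ),

with volunteer true values mu_v ~ N(mu_pop, sigma_b^2), per-rater
systematic offsets b_r ~ N(0, sigma_r^2) and measurement error
eps ~ N(0, sigma_e^2), all independent, then rounded to the instrument
grid (0.01 kg for weight, 0.1 cm otherwise) unless rounding is disabled.

Under this model the population quantities the estimators target are

* intra-rater TEM             = sigma_e
* inter-rater error SD        = sqrt(sigma_r^2 + sigma_e^2)
* inter-rater reliability     rho       = sigma_b^2 / (sigma_b^2 + sigma_r^2 + sigma_e^2)
* intra-rater reliability     rho_intra = (sigma_b^2 + sigma_r^2) / (sigma_b^2 + sigma_r^2 + sigma_e^2)

returned alongside the records as :class:`GroundTruth` so parameter-
recovery tests can compare estimates with the generating values.

``study_like_dataset`` is a preset reproducing the design shape of a
two-tier national-survey training exercise: 12 site-lead pairs sharing
15 volunteers, 46 fieldworker pairs sharing 75 volunteers, five
parameters, three age strata, 2-11 raters per volunteer (median 4), two
rounds each, circumference-only-in-adults for waist and calf.  The
anthropometric means and SDs are package constants chosen to be
plausible for the target population (e.g. infant weight ~9 kg, adult
height ~165 cm); they are documented choices, not survey data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import AGE_GROUPS, PARAMETERS, PRECISION, RATER_GROUPS, ensure_age_groups

__all__ = [
    "ParameterModel",
    "SynthConfig",
    "GroundTruth",
    "generate_dataset",
    "study_like_dataset",
    "study_like_config",
    "RATERS_PER_VOLUNTEER_PMF",
]

#: Distribution of the number of raters measuring each volunteer:
#: support 2..11, median 4 — the design target of a training exercise
#: where every volunteer is measured by a handful of the teams present.
RATERS_PER_VOLUNTEER_PMF: dict[int, float] = {
    2: 0.16, 3: 0.22, 4: 0.24, 5: 0.14, 6: 0.09,
    7: 0.06, 8: 0.04, 9: 0.03, 10: 0.01, 11: 0.01,
}

#: Representative ages (years) drawn uniformly within each stratum.
_AGE_RANGES = {"under2": (0.25, 1.9), "two_to_12": (2.0, 12.0), "over12": (13.0, 65.0)}


@dataclass(frozen=True)
class ParameterModel:
    """Generating model for one anthropometric parameter.

    ``means``/``between_sd`` give the population mean and between-
    volunteer SD per age group (parameter units); ``error_sd`` the
    within-rater measurement error SD per rater group; ``rater_bias_sd``
    the SD of per-rater systematic offsets (0 = pure repeatability
    error); ``error_sd_age_scale`` multiplies the error SD in specific
    age groups (infant length is harder to measure than adult height).
    ``age_groups`` limits which strata are measured at all (waist and
    calf circumference are adult-only in the survey protocol).
    """

    means: dict[str, float]
    between_sd: dict[str, float]
    error_sd: dict[str, float]
    rater_bias_sd: dict[str, float] = field(default_factory=lambda: {g: 0.0 for g in RATER_GROUPS})
    error_sd_age_scale: dict[str, float] = field(default_factory=dict)
    age_groups: tuple[str, ...] = AGE_GROUPS

    def sigma_e(self, rater_group: str, age_group: str) -> float:
        return self.error_sd[rater_group] * self.error_sd_age_scale.get(age_group, 1.0)


@dataclass(frozen=True)
class SynthConfig:
    """Design and variance structure of a simulated exercise."""

    parameters: dict[str, ParameterModel]
    n_volunteers: dict[tuple[str, str], int]  # (rater_group, age_group) -> count
    n_rater_pairs: dict[str, int]             # rater_group -> pool size
    raters_per_volunteer: dict[int, float] = field(
        default_factory=lambda: dict(RATERS_PER_VOLUNTEER_PMF)
    )
    rounds: int = 2
    apply_rounding: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, pm in self.parameters.items():
            if name not in PARAMETERS:
                raise ValueError(f"unknown parameter {name!r}")
            for d in (pm.between_sd, pm.error_sd, pm.rater_bias_sd):
                if any(v < 0 for v in d.values()):
                    raise ValueError(f"negative SD in model for {name!r}")
            if any(m <= 0 for m in pm.means.values()):
                raise ValueError(f"non-positive mean in model for {name!r}")
        ks = sorted(self.raters_per_volunteer)
        if ks[0] < 2:
            raise ValueError("raters per volunteer must be >= 2")
        total = sum(self.raters_per_volunteer.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("raters_per_volunteer probabilities must sum to 1")


@dataclass(frozen=True)
class GroundTruth:
    """Population values implied by the generating model, per
    (parameter, rater_group, age_group) stratum."""

    sigma_b: dict[tuple[str, str, str], float]
    sigma_e: dict[tuple[str, str, str], float]
    sigma_r: dict[tuple[str, str, str], float]
    tem: dict[tuple[str, str, str], float]
    pct_tem: dict[tuple[str, str, str], float]
    rho_inter: dict[tuple[str, str, str], float]
    rho_intra: dict[tuple[str, str, str], float]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.sigma_e:
            param, rg, ag = key
            rows.append(
                {
                    "parameter": param, "rater_group": rg, "age_group": ag,
                    "sigma_b": self.sigma_b[key], "sigma_e": self.sigma_e[key],
                    "sigma_r": self.sigma_r[key], "tem": self.tem[key],
                    "pct_tem": self.pct_tem[key], "rho_inter": self.rho_inter[key],
                    "rho_intra": self.rho_intra[key],
                }
            )
        return pd.DataFrame(rows)


def _round_to_grid(values: np.ndarray, precision: float) -> np.ndarray:
    out = np.round(values / precision) * precision
    # keep values strictly positive and shed float dust from the division
    decimals = max(0, int(round(-np.log10(precision))))
    return np.maximum(np.round(out, decimals), precision)


def _sample_k(rng: np.random.Generator, pmf: dict[int, float], pool: int) -> int:
    ks = np.array(sorted(pmf))
    ps = np.array([pmf[k] for k in ks])
    ks_ok = ks[ks <= pool]
    ps_ok = ps[: ks_ok.size] / ps[: ks_ok.size].sum()
    return int(rng.choice(ks_ok, p=ps_ok))


def generate_dataset(
    config: SynthConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one synthetic exercise from the variance-components model.

    Fully reproducible: the same config (including its seed, or the
    ``seed`` override) yields an identical table.  Returns the record
    table in the canonical long format plus the :class:`GroundTruth`
    of the generating model.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[dict] = []

    sigma_b: dict = {}
    sigma_e: dict = {}
    sigma_r: dict = {}
    tem: dict = {}
    pct: dict = {}
    rho_inter: dict = {}
    rho_intra: dict = {}

    for rg in RATER_GROUPS:
        pool = config.n_rater_pairs.get(rg, 0)
        if pool == 0:
            continue
        rater_ids = [f"{rg[:2]}{i + 1:02d}" for i in range(pool)]
        # per-rater systematic offsets, drawn once per parameter
        biases = {
            pname: dict(zip(rater_ids, rng.normal(0.0, pm.rater_bias_sd.get(rg, 0.0), size=pool)))
            for pname, pm in config.parameters.items()
        }
        for ag in AGE_GROUPS:
            n_vol = config.n_volunteers.get((rg, ag), 0)
            if n_vol == 0:
                continue
            lo, hi = _AGE_RANGES[ag]
            for v in range(n_vol):
                vol_id = f"{rg[:2]}-{ag}-{v + 1:03d}"
                age = float(rng.uniform(lo, hi))
                k = _sample_k(rng, config.raters_per_volunteer, pool)
                chosen = list(rng.choice(rater_ids, size=k, replace=False))
                for pname, pm in config.parameters.items():
                    if ag not in pm.age_groups:
                        continue
                    mu_v = rng.normal(pm.means[ag], pm.between_sd[ag])
                    se = pm.sigma_e(rg, ag)
                    for rater in chosen:
                        b_r = biases[pname][rater]
                        for rnd in range(1, config.rounds + 1):
                            x = mu_v + b_r + rng.normal(0.0, se)
                            records.append(
                                {
                                    "volunteer_id": vol_id, "rater_id": rater,
                                    "rater_group": rg, "parameter": pname,
                                    "round": rnd, "value": x, "age_years": age,
                                    "site_id": "",
                                }
                            )
        for pname, pm in config.parameters.items():
            for ag in pm.age_groups:
                if config.n_volunteers.get((rg, ag), 0) == 0:
                    continue
                key = (pname, rg, ag)
                sb = pm.between_sd[ag]
                se = pm.sigma_e(rg, ag)
                sr = pm.rater_bias_sd.get(rg, 0.0)
                tot = sb**2 + sr**2 + se**2
                sigma_b[key], sigma_e[key], sigma_r[key] = sb, se, sr
                tem[key] = se
                pct[key] = 100.0 * se / pm.means[ag]
                rho_inter[key] = sb**2 / tot if tot > 0 else float("nan")
                rho_intra[key] = (sb**2 + sr**2) / tot if tot > 0 else float("nan")

    df = pd.DataFrame(records)
    if config.apply_rounding and not df.empty:
        for pname in df["parameter"].unique():
            mask = df["parameter"] == pname
            df.loc[mask, "value"] = _round_to_grid(
                df.loc[mask, "value"].to_numpy(), PRECISION[pname]
            )
    if not df.empty:
        df = ensure_age_groups(df)
    truth = GroundTruth(sigma_b, sigma_e, sigma_r, tem, pct, rho_inter, rho_intra)
    return df, truth


# --- study-shaped preset -------------------------------------------------

def study_like_config(seed: int = 0) -> SynthConfig:
    """Preset mirroring the two-tier training-exercise design.

    Dimensions: 12 site-lead pairs x 15 volunteers (5 per age stratum),
    46 fieldworker pairs x 75 volunteers (27 / 26 / 22 across strata);
    five parameters, waist and calf measured in adolescents/adults only.
    Fieldworkers carry a larger error SD than site leads (less prior
    anthropometry experience) plus a small per-rater systematic offset,
    which produces the inter > intra error ordering such exercises show;
    infant length error is doubled (restless infants, board technique).
    """
    means = {
        "weight": {"under2": 9.0, "two_to_12": 20.0, "over12": 70.0},
        "length_height": {"under2": 72.0, "two_to_12": 112.0, "over12": 165.0},
        "muac": {"under2": 14.5, "two_to_12": 17.5, "over12": 28.0},
        "waist": {"over12": 85.0},
        "calf": {"over12": 36.0},
    }
    between_sd = {
        "weight": {"under2": 1.2, "two_to_12": 5.5, "over12": 14.0},
        "length_height": {"under2": 6.0, "two_to_12": 16.0, "over12": 9.0},
        "muac": {"under2": 1.1, "two_to_12": 2.0, "over12": 3.8},
        "waist": {"over12": 12.0},
        "calf": {"over12": 3.5},
    }
    error_sd = {
        "weight": {"site_lead": 0.07, "fieldworker": 0.18},
        "length_height": {"site_lead": 0.45, "fieldworker": 0.65},
        "muac": {"site_lead": 0.40, "fieldworker": 0.45},
        "waist": {"site_lead": 1.6, "fieldworker": 1.2},
        "calf": {"site_lead": 0.35, "fieldworker": 0.70},
    }
    rater_bias_sd = {
        "weight": {"site_lead": 0.03, "fieldworker": 0.10},
        "length_height": {"site_lead": 0.20, "fieldworker": 0.35},
        "muac": {"site_lead": 0.20, "fieldworker": 0.30},
        "waist": {"site_lead": 0.9, "fieldworker": 0.7},
        "calf": {"site_lead": 0.25, "fieldworker": 0.35},
    }
    params = {}
    for pname in PARAMETERS:
        params[pname] = ParameterModel(
            means=means[pname],
            between_sd=between_sd[pname],
            error_sd=error_sd[pname],
            rater_bias_sd=rater_bias_sd[pname],
            error_sd_age_scale={"under2": 2.0} if pname == "length_height" else {},
            age_groups=("over12",) if pname in ("waist", "calf") else AGE_GROUPS,
        )
    n_volunteers = {
        ("site_lead", "under2"): 5, ("site_lead", "two_to_12"): 5, ("site_lead", "over12"): 5,
        ("fieldworker", "under2"): 27, ("fieldworker", "two_to_12"): 26, ("fieldworker", "over12"): 22,
    }
    return SynthConfig(
        parameters=params,
        n_volunteers=n_volunteers,
        n_rater_pairs={"site_lead": 12, "fieldworker": 46},
        seed=seed,
    )


def study_like_dataset(seed: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one exercise from the study-shaped preset."""
    return generate_dataset(study_like_config(seed))
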