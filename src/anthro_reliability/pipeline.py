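"""Stratified reliability report: the full analysis in one call.

``run_reliability_report`` takes a validated measurement table and an
:class:`AnalysisConfig` and produces, for every parameter x rater group
(and, where configured, age group):

* inter- and intra-rater n, TEM, %TEM, R and one-way ICC;
* an F-comparison of the two rater groups' TEMs per parameter and mode;
* pass/fail labels against the configured acceptability threshold sets.

Strata with insufficient data (no volunteers with two raters, fewer
than two replicate groups) carry NaN markers and never abort the run.
``write_report`` renders the report as full-precision CSV for machines
and 3-decimal markdown for humans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import records as rec
from .agreement import AgreementResult, bland_altman_inter, bland_altman_intra
from .icc import icc_oneway
from .records import ReplicateGroupSet, Stratum
from .tem import ReliabilityResult, TemComparison, compare_tem, reliability_result
from .thresholds import ThresholdSet, builtin_threshold_set, classify_reliability

__all__ = ["AnalysisConfig", "ReportTable", "run_reliability_report", "write_report",
           "run_agreement_analyses"]

#: Parameters age-stratified by default: those measured across all age
#: strata.  Waist and calf are measured in adolescents/adults only, so
#: an age split would duplicate the whole-sample row.
DEFAULT_AGE_SPLIT = ("weight", "length_height", "muac")


@dataclass
class AnalysisConfig:
    """What to analyse and under which conventions."""

    parameters: tuple[str, ...] = rec.PARAMETERS
    rater_groups: tuple[str, ...] = rec.RATER_GROUPS
    age_split: str | tuple[str, ...] = "auto"  # "auto" | "on" | "off" | explicit tuple
    threshold_sets: tuple[str, ...] = ("carsley2019", "icc_excellent")
    loa_multiplier: float = 2.0
    intra_sign: str = "r2-r1"
    seed: int = 0

    def split_parameters(self) -> tuple[str, ...]:
        if self.age_split == "auto":
            return tuple(p for p in self.parameters if p in DEFAULT_AGE_SPLIT)
        if self.age_split == "on":
            return tuple(self.parameters)
        if self.age_split == "off":
            return ()
        return tuple(self.age_split)

    def validate(self) -> None:
        unknown = [p for p in self.parameters if p not in rec.PARAMETERS]
        if unknown:
            raise ValueError(f"config references unknown parameter(s): {unknown}")
        unknown = [g for g in self.rater_groups if g not in rec.RATER_GROUPS]
        if unknown:
            raise ValueError(f"config references unknown rater group(s): {unknown}")
        for name in self.threshold_sets:
            builtin_threshold_set(name)  # raises on unknown name
        if self.intra_sign not in ("r2-r1", "r1-r2"):
            raise ValueError("intra_sign must be 'r2-r1' or 'r1-r2'")
        for p in self.split_parameters():
            if p not in self.parameters:
                raise ValueError(f"age-split parameter {p!r} not in analysed parameters")


def _safe_icc(view: ReplicateGroupSet) -> float:
    if view.n_groups < 2:
        return float("nan")
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        try:
            return icc_oneway(view)
        except ValueError:
            return float("nan")


@dataclass
class ReportTable:
    """The stratified report plus the underlying result objects."""

    rows: pd.DataFrame
    comparisons: pd.DataFrame
    classifications: pd.DataFrame
    results: list[ReliabilityResult] = field(default_factory=list)

    def row(self, parameter: str, rater_group: str, age_group: str = "all") -> pd.Series:
        m = (
            (self.rows["parameter"] == parameter)
            & (self.rows["rater_group"] == rater_group)
            & (self.rows["age_group"] == age_group)
        )
        sub = self.rows[m]
        if sub.empty:
            raise KeyError((parameter, rater_group, age_group))
        return sub.iloc[0]


def _result_pair(records: pd.DataFrame, parameter: str, stratum: Stratum):
    inter_view = rec.build_inter_view(records, parameter, stratum)
    intra_view = rec.build_intra_view(records, parameter, stratum)
    res_inter = reliability_result(inter_view)
    res_inter.icc = _safe_icc(inter_view)
    res_intra = reliability_result(intra_view)
    res_intra.icc = _safe_icc(intra_view)
    return inter_view, intra_view, res_inter, res_intra


def run_reliability_report(measurements: pd.DataFrame, config: AnalysisConfig | None = None) -> ReportTable:
    """Compute the full stratified reliability report.

    ``measurements`` must already have passed :func:`records.validate`
    (age groups assigned, duplicates resolved).
    """
    config = config or AnalysisConfig()
    config.validate()
    measurements = rec.ensure_age_groups(measurements)

    split = set(config.split_parameters())
    rows: list[dict] = []
    results: list[ReliabilityResult] = []
    comp_rows: list[dict] = []
    class_rows: list[dict] = []
    tsets = [builtin_threshold_set(n) for n in config.threshold_sets]

    # inter/intra error dfs of the whole-sample strata, for the F-comparison
    whole_sample: dict[tuple[str, str, str], tuple[float, int]] = {}

    for parameter in config.parameters:
        for rater_group in config.rater_groups:
            strata: list[tuple[str, Stratum]] = [("all", Stratum(rater_group, None))]
            if parameter in split:
                strata += [(ag, Stratum(rater_group, ag)) for ag in rec.AGE_GROUPS]
            for ag_label, stratum in strata:
                inter_view, intra_view, res_inter, res_intra = _result_pair(
                    measurements, parameter, stratum
                )
                n_vol = measurements[
                    (measurements["parameter"] == parameter)
                    & (measurements["rater_group"] == rater_group)
                    & ((measurements["age_group"] == ag_label) if ag_label != "all" else True)
                ]["volunteer_id"].nunique()
                rows.append(
                    {
                        "parameter": parameter,
                        "rater_group": rater_group,
                        "age_group": ag_label,
                        "n_volunteers": n_vol,
                        "inter_n": res_inter.n, "inter_tem": res_inter.tem,
                        "inter_pct_tem": res_inter.pct_tem, "inter_r": res_inter.r_coef,
                        "inter_icc": res_inter.icc,
                        "intra_n": res_intra.n, "intra_tem": res_intra.tem,
                        "intra_pct_tem": res_intra.pct_tem, "intra_r": res_intra.r_coef,
                        "intra_icc": res_intra.icc,
                    }
                )
                results.extend([res_inter, res_intra])
                if ag_label == "all":
                    whole_sample[(parameter, rater_group, "inter")] = (res_inter.tem, inter_view.error_df)
                    whole_sample[(parameter, rater_group, "intra")] = (res_intra.tem, intra_view.error_df)
                for res in (res_inter, res_intra):
                    for tset in tsets:
                        for cls in classify_reliability(res, tset):
                            class_rows.append(
                                {
                                    "parameter": parameter, "rater_group": rater_group,
                                    "age_group": ag_label, "mode": res.mode,
                                    "threshold_set": tset.name, "rule": cls.rule,
                                    "statistic": cls.statistic, "observed": cls.observed,
                                    "cutoff": cls.cutoff, "comparison": cls.comparison,
                                    "passed": "NA" if cls.passed is None else str(cls.passed).lower(),
                                }
                            )

        if {"site_lead", "fieldworker"} <= set(config.rater_groups):
            for mode in ("inter", "intra"):
                tem_a, df_a = whole_sample.get((parameter, "site_lead", mode), (float("nan"), 0))
                tem_b, df_b = whole_sample.get((parameter, "fieldworker", mode), (float("nan"), 0))
                if df_a >= 1 and df_b >= 1 and tem_a > 0 and tem_b > 0:
                    cmp = compare_tem(tem_a, df_a, tem_b, df_b)
                    comp_rows.append(
                        {
                            "parameter": parameter, "mode": mode,
                            "tem_site_lead": cmp.tem_a, "tem_fieldworker": cmp.tem_b,
                            "f_stat": cmp.f_stat, "df1": cmp.df1, "df2": cmp.df2,
                            "p_value": cmp.p_value,
                        }
                    )
                else:
                    comp_rows.append(
                        {
                            "parameter": parameter, "mode": mode,
                            "tem_site_lead": tem_a, "tem_fieldworker": tem_b,
                            "f_stat": float("nan"), "df1": df_a, "df2": df_b,
                            "p_value": float("nan"),
                        }
                    )

    return ReportTable(
        rows=pd.DataFrame(rows),
        comparisons=pd.DataFrame(comp_rows),
        classifications=pd.DataFrame(class_rows),
        results=results,
    )


_DISPLAY_COLS = (
    "inter_tem", "inter_pct_tem", "inter_r", "inter_icc",
    "intra_tem", "intra_pct_tem", "intra_r", "intra_icc",
)


def _fmt(x, nd=3) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    if isinstance(x, float):
        return f"{x:.{nd}f}"
    return str(x)


def write_report(report: ReportTable, out_dir: str | Path) -> dict[str, Path]:
    """Write the report as CSV (full precision) and markdown (3 dp).

    Returns the paths written.  Identical reports produce byte-identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report_csv": out_dir / "reliability_report.csv",
        "comparisons_csv": out_dir / "tem_comparisons.csv",
        "classifications_csv": out_dir / "threshold_classifications.csv",
        "report_md": out_dir / "reliability_report.md",
    }
    report.rows.to_csv(paths["report_csv"], index=False)
    report.comparisons.to_csv(paths["comparisons_csv"], index=False)
    report.classifications.to_csv(paths["classifications_csv"], index=False)

    lines = [
        "# Reliability report",
        "",
        "| parameter | raters | age group | n (inter) | TEM | %TEM | R | ICC "
        "| n (intra) | TEM | %TEM | R | ICC |",
        "|---|---|---|---|---|---|---|---|---|---|---|---|---|",
    ]
    for _, r in report.rows.iterrows():
        cells = [r["parameter"], r["rater_group"], r["age_group"], str(int(r["inter_n"]))]
        cells += [_fmt(r[c]) for c in _DISPLAY_COLS[:4]]
        cells.insert(8, str(int(r["intra_n"])))
        cells += [_fmt(r[c]) for c in _DISPLAY_COLS[4:]]
        lines.append("| " + " | ".join(cells) + " |")
    lines += ["", "## TEM comparisons (site leads vs fieldworkers)", "",
              "| parameter | mode | TEM site leads | TEM fieldworkers | F | p |",
              "|---|---|---|---|---|---|"]
    for _, r in report.comparisons.iterrows():
        lines.append(
            "| " + " | ".join(
                [r["parameter"], r["mode"], _fmt(r["tem_site_lead"]), _fmt(r["tem_fieldworker"]),
                 _fmt(r["f_stat"]), _fmt(r["p_value"])]
            ) + " |"
        )
    paths["report_md"].write_text("\n".join(lines) + "\n")
    return paths


def run_agreement_analyses(
    measurements: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> list[AgreementResult]:
    """Bland-Altman analyses for every parameter x rater group x mode.

    Points are pooled across raters within a stratum.  Strata with too
    few points are skipped.
    """
    config = config or AnalysisConfig()
    config.validate()
    measurements = rec.ensure_age_groups(measurements)
    out: list[AgreementResult] = []
    for parameter in config.parameters:
        for rater_group in config.rater_groups:
            stratum = Stratum(rater_group, None)
            intra_view = rec.build_intra_view(measurements, parameter, stratum)
            if intra_view.n_groups >= 2:
                res = bland_altman_intra(
                    intra_view, sign=config.intra_sign, loa_multiplier=config.loa_multiplier
                )
                res.stratum_label = stratum.label()
                out.append(res)
            inter_view = rec.build_inter_view(measurements, parameter, stratum)
            if inter_view.n_groups >= 1:
                res = bland_altman_inter(inter_view, loa_multiplier=config.loa_multiplier)
                res.stratum_label = stratum.label()
                out.append(res)
    return out
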