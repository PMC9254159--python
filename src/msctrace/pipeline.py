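"""End-to-end analysis: quantify → correct → rates → attribution → stats.

:func:`analyze_experiment` runs the full pipeline on the measurement
tables of a :class:`~msctrace.syndata.SyntheticExperiment` (or any tables
in the same dialects) and returns every intermediate table plus a summary
of the headline statistics: glucose→lactate percentage, the citrate
source panel, the reductive/oxidative split, the exogenous ¹³C₀ fractions
and the volcano discoveries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import attribution, correction, rates, stats
from .syndata import MEDIUM_SPECIES, MID_PANEL, SyntheticExperiment

__all__ = ["PipelineOptions", "PipelineResults", "analyze_experiment"]


@dataclass(frozen=True)
class PipelineOptions:
    natural_abundance_p: float = correction.NATURAL_13C_ABUNDANCE
    apply_correction: bool = True
    duration_days: float = 2.0  # pass 1.0 to report per-48h amounts
    q: float = 0.05  # FDR level for the volcano analysis
    alpha: float = 0.05
    well_volume_ml: float = 0.8
    min_total_area: float = 0.0
    provenance_denominator: str = "total"  # or "de_novo"


@dataclass
class PipelineResults:
    options: PipelineOptions
    calibration: dict[str, rates.CalibrationCurve]
    cellfree_nmol: dict[str, float]
    exchange_rates: pd.DataFrame
    rate_summary: pd.DataFrame
    glucose_to_lactate: pd.DataFrame
    corrected_mids: pd.DataFrame
    attribution_table: pd.DataFrame
    secreted_provenance: pd.DataFrame
    volcano: pd.DataFrame
    volcano_excluded: list[str]
    summary: dict = field(default_factory=dict)


def _fit_all_calibrations(standards: pd.DataFrame) -> dict[str, rates.CalibrationCurve]:
    curves = {}
    for met, grp in standards.groupby("metabolite"):
        curves[met] = rates.fit_calibration(
            grp["concentration_uM"], grp["area"], metabolite=str(met)
        )
    return curves


def _quantify_cellfree(
    cellfree: pd.DataFrame,
    curves: dict[str, rates.CalibrationCurve],
    well_volume_ml: float,
) -> dict[str, float]:
    out = {}
    for met, grp in cellfree.groupby("metabolite"):
        out[str(met)] = rates.quantify_medium(
            float(grp["area"].mean()), curves[str(met)], well_volume_ml
        )
    return out


def _correct_all_mids(
    mid_areas: pd.DataFrame, opts: PipelineOptions
) -> pd.DataFrame:
    """Long-form corrected MIDs keyed by donor, oxygen, tracer, metabolite."""
    rows = []
    keys = ["donor", "oxygen", "tracer", "metabolite"]
    for key, grp in mid_areas.groupby(keys):
        grp = grp.sort_values("mass_shift")
        areas = grp["area"].to_numpy()
        total = areas.sum()
        if total <= opts.min_total_area or total <= 0:
            continue
        if opts.apply_correction:
            mid, _ = correction.correct_mid(areas, opts.natural_abundance_p)
            state = "na_corrected"
            values = mid.values
        else:
            state = "raw"
            values = areas / total
        for shift, frac in enumerate(values):
            rows.append(dict(zip(keys, key)) | {
                "mass_shift": shift, "fraction": frac, "state": state,
            })
    return pd.DataFrame(rows)


def _mid_lookup(corrected: pd.DataFrame):
    """(donor, oxygen, tracer, metabolite) -> MID array."""
    table = {}
    for key, grp in corrected.groupby(["donor", "oxygen", "tracer", "metabolite"]):
        table[key] = grp.sort_values("mass_shift")["fraction"].to_numpy()
    return table


def analyze_experiment(
    exp: SyntheticExperiment, options: PipelineOptions | None = None
) -> PipelineResults:
    opts = options or PipelineOptions()
    curves = _fit_all_calibrations(exp.standards)
    cellfree_nmol = _quantify_cellfree(exp.cellfree, curves, opts.well_volume_ml)

    # exchange rates per donor, then condition means ± SD
    rate_table = rates.exchange_rate_table(
        exp.spent,
        cellfree_nmol,
        exp.protein,
        curves,
        well_volume_ml=opts.well_volume_ml,
        duration_days=opts.duration_days,
    )
    rate_summary = (
        rate_table.groupby(["oxygen", "metabolite"])["rate_nmol_per_ug_per_day"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )

    # glucose -> lactate conversion per donor
    g2l_rows = []
    wide = rate_table.pivot_table(
        index=["donor", "oxygen"], columns="metabolite",
        values="rate_nmol_per_ug_per_day",
    )
    for (donor, oxygen), row in wide.iterrows():
        if "GLC_med" in row and "LAC_med" in row and row["GLC_med"] < 0:
            g2l_rows.append(
                {
                    "donor": donor,
                    "oxygen": oxygen,
                    "pct_glucose_to_lactate": rates.percent_glucose_to_lactate(
                        row["GLC_med"], max(row["LAC_med"], 0.0)
                    ),
                }
            )
    glucose_to_lactate = pd.DataFrame(g2l_rows)

    corrected = _correct_all_mids(exp.mid_areas, opts)
    mids = _mid_lookup(corrected)

    # attribution per donor and oxygen condition
    attr_rows = []
    donors = sorted(exp.spent["donor"].unique())
    oxygens = sorted(exp.spent["oxygen"].unique())
    for oxygen in oxygens:
        for donor in donors:
            cit_by_tracer = {
                tr: mids.get((donor, oxygen, tr, "CIT")) for tr in exp.tracers
            }
            panel = attribution.citrate_source_panel(
                {t: m for t, m in cit_by_tracer.items() if m is not None}
            )
            for _, prow in panel.iterrows():
                attr_rows.append(
                    {
                        "donor": donor, "oxygen": oxygen, "statistic": "citrate_source",
                        "source": prow["source"], "window": prow["window"],
                        "value": prow["fraction"],
                    }
                )
            gln_cit = cit_by_tracer.get("glutamine")
            if gln_cit is not None:
                red, ox_share, defined = attribution.reductive_oxidative_split(gln_cit)
                attr_rows.append(
                    {"donor": donor, "oxygen": oxygen,
                     "statistic": "reductive_share", "source": "glutamine",
                     "window": "M5/(M4+M5)", "value": red if defined else np.nan}
                )
            glu_mid = mids.get((donor, oxygen, "glutamine", "GLU"))
            if glu_mid is not None:
                attr_rows.append(
                    {"donor": donor, "oxygen": oxygen,
                     "statistic": "exogenous_m0", "source": "glutamate_pool",
                     "window": "M0", "value": attribution.exogenous_pool_fraction(glu_mid)}
                )
            akg_mid = mids.get((donor, oxygen, "glutamine", "AKG"))
            if akg_mid is not None:
                attr_rows.append(
                    {"donor": donor, "oxygen": oxygen,
                     "statistic": "exogenous_m0", "source": "akg_pool",
                     "window": "M0", "value": attribution.exogenous_pool_fraction(akg_mid)}
                )
    attribution_table = pd.DataFrame(attr_rows)

    # secreted citrate provenance per donor (labeled arms)
    prov_rows = []
    if not exp.secreted_citrate.empty:
        for (donor, oxygen, tr), grp in exp.secreted_citrate.groupby(
            ["donor", "oxygen", "tracer"]
        ):
            areas = grp.sort_values("mass_shift")["area"].to_numpy()
            if opts.apply_correction:
                mid, _ = correction.correct_mid(areas, opts.natural_abundance_p)
                values = mid.values
            else:
                values = areas / areas.sum()
            kmin = 3 if tr == "glutamate" else 2
            contrib = attribution.secreted_citrate_provenance(
                values, tracer=str(tr), kmin=kmin, kmax=5,
                denominator="total",
            )
            prov_rows.append(
                {
                    "donor": donor, "oxygen": oxygen, "tracer": tr,
                    "window": f"{contrib.kmin}..{contrib.kmax}",
                    "labeled_fraction": contrib.fraction,
                }
            )
    secreted_provenance = pd.DataFrame(prov_rows)

    # volcano of pool intensities, 1% vs 21% oxygen
    volcano_df, excluded = pd.DataFrame(), []
    if not exp.pool_intensity.empty and len(oxygens) == 2:
        long = exp.pool_intensity.rename(
            columns={"metabolite": "feature", "donor": "unit", "oxygen": "group",
                     "intensity": "value"}
        )
        volcano_df, excluded = stats.volcano_table(
            long, group_a="21%", group_b="1%", q=opts.q
        )

    summary = _summarize(
        rate_summary, glucose_to_lactate, attribution_table,
        secreted_provenance, volcano_df, oxygens,
    )
    return PipelineResults(
        options=opts,
        calibration=curves,
        cellfree_nmol=cellfree_nmol,
        exchange_rates=rate_table,
        rate_summary=rate_summary,
        glucose_to_lactate=glucose_to_lactate,
        corrected_mids=corrected,
        attribution_table=attribution_table,
        secreted_provenance=secreted_provenance,
        volcano=volcano_df,
        volcano_excluded=excluded,
        summary=summary,
    )


def _summarize(rate_summary, g2l, attr, prov, volcano, oxygens) -> dict:
    summary: dict = {}
    for oxygen in oxygens:
        s: dict = {}
        rs = rate_summary[rate_summary["oxygen"] == oxygen].set_index("metabolite")
        for met in MEDIUM_SPECIES:
            if met in rs.index:
                s[f"rate_{met}"] = float(rs.loc[met, "mean"])
        sub = g2l[g2l["oxygen"] == oxygen]
        if not sub.empty:
            s["pct_glucose_to_lactate"] = float(sub["pct_glucose_to_lactate"].mean())
        a = attr[attr["oxygen"] == oxygen]
        red = a[(a["statistic"] == "reductive_share")]["value"]
        if not red.empty:
            s["reductive_share"] = float(red.mean())
        m0 = a[(a["statistic"] == "exogenous_m0") & (a["source"] == "glutamate_pool")]["value"]
        if not m0.empty:
            s["exogenous_glu_m0"] = float(m0.mean())
        panel = a[a["statistic"] == "citrate_source"]
        for src in ("glucose", "glutamine", "glutamate", "remainder"):
            vals = panel[panel["source"] == src]["value"].dropna()
            if not vals.empty:
                s[f"citrate_from_{src}"] = float(vals.mean())
        p = prov[(prov["oxygen"] == oxygen) & (prov["tracer"] == "glutamate")]
        if not p.empty:
            s["secreted_citrate_labeled_fraction"] = float(p["labeled_fraction"].mean())
        summary[oxygen] = s
    if not volcano.empty:
        summary["volcano_discoveries"] = int(volcano["significant"].sum())
    return summary
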