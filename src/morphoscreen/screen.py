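"""Condition-level screen read-outs and dose-response statistics.

Aggregates object-level predictions and measurements into the per-well and
per-condition quantities a screening campaign reports: phenotype yield%
(computed per well, then averaged over the n = 3 replicate wells),
class-filtered area statistics, morphotoxicity metrics (delaminated yield,
cavity-count histograms, caspase summaries), one-way-ANOVA/Dunnett many-to-one
tests against the shared control, rule-based compound effect categorization,
and ATP-luminescence (viability) table ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from morphoscreen.phantoms import PHENOTYPES

CLASS_COLUMNS = [p.value for p in PHENOTYPES]
#: classes earlier than the terminal XEn/EpiC phenotype on the continuum
EARLIER_CLASSES = [p.value for p in PHENOTYPES[1:]]
CAVITY_BINS = ["0", "1", "2", "3", "4", ">4"]


# ------------------------------------------------------------------- yields


def compute_yields(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-well phenotype yields from object-level class predictions.

    ``predictions`` needs columns ``well_id, condition, dose, replicate,
    pred_class`` and optionally ``delaminated`` (bool).  Returns one row per
    well with per-class counts, ``yield_<class>`` percentages summing to 100,
    and ``delaminated_yield`` when available.  Wells with zero objects are
    flagged ``empty`` and carry NaN yields (excluded from condition means).
    """
    rows = []
    for (wid, cond, dose, rep), grp in predictions.groupby(
            ["well_id", "condition", "dose", "replicate"], sort=True):
        total = len(grp)
        row = dict(well_id=wid, condition=cond, dose=dose, replicate=rep,
                   total=total, empty=total == 0)
        for c in CLASS_COLUMNS:
            cnt = int((grp["pred_class"] == c).sum())
            row[f"count_{c}"] = cnt
            row[f"yield_{c}"] = 100.0 * cnt / total if total else float("nan")
        if "delaminated" in grp.columns:
            row["delaminated_yield"] = (
                100.0 * grp["delaminated"].astype(bool).mean() if total else float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def condition_yield_summary(well_results: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of each class yield over replicate wells, per condition x dose."""
    ok = well_results[~well_results["empty"]]
    cols = [f"yield_{c}" for c in CLASS_COLUMNS]
    if "delaminated_yield" in ok.columns:
        cols = cols + ["delaminated_yield"]
    agg = ok.groupby(["condition", "dose"])[cols].agg(["mean", "std", "count"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()


def class_area_stats(
    features: pd.DataFrame,
    predictions: pd.DataFrame,
    target_class: str = "XEnEpiC",
    area_col: str = "Area_um2",
) -> pd.DataFrame:
    """Per-condition area distribution of objects of one phenotype class.

    One entry per object of ``target_class`` (object-level units: in area
    plots each dot is one XEn/EpiC).  Conditions with no such objects are
    returned with n = 0 and NaN statistics.
    """
    merged = predictions.merge(features, on=["well_id", "object_id"], how="inner")
    sel = merged[merged["pred_class"] == target_class]
    rows = []
    for (cond, dose), grp in merged.groupby(["condition", "dose"], sort=True):
        areas = grp.loc[grp["pred_class"] == target_class, area_col].to_numpy()
        rows.append(dict(
            condition=cond, dose=dose, n=areas.size,
            mean_area=float(areas.mean()) if areas.size else float("nan"),
            sd_area=float(areas.std(ddof=1)) if areas.size > 1 else float("nan"),
            flagged=areas.size == 0,
        ))
    return pd.DataFrame(rows), sel  # summary + per-object areas


# ------------------------------------------------------------------ Dunnett


def stars(p: float) -> str:
    """Significance stars: * p<=0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class DunnettResult:
    comparisons: pd.DataFrame  # one row per treatment vs control
    anova_F: float
    anova_p: float
    df_error: int


def dunnett_test(
    groups: dict[str, np.ndarray],
    control: str,
    n_mc: int = 200_000,
    seed: int = 0,
) -> DunnettResult:
    """Dunnett's many-to-one comparisons after one-way ANOVA.

    The adjusted two-sided p-value of each treatment is evaluated against the
    null distribution of max_j |T_j| over the treatment contrasts, with the
    equal-correlation structure implied by the group sizes, by Monte-Carlo
    simulation (``n_mc`` draws, fixed ``seed``): group means are drawn
    N(0, σ²/n_i) and the pooled variance as σ²·χ²_df/df.  Unequal replicate
    counts are allowed; zero pooled variance raises ValueError.
    """
    names = [control] + [g for g in groups if g != control]
    if control not in groups:
        raise ValueError(f"control group {control!r} not found")
    if len(names) < 2:
        raise ValueError("need at least one treatment group")
    vals = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, v in vals.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    ns = np.array([vals[g].size for g in names])
    means = np.array([vals[g].mean() for g in names])
    N = int(ns.sum())
    k = len(names)
    df = N - k
    ss_err = sum(((vals[g] - vals[g].mean()) ** 2).sum() for g in names)
    if ss_err <= 0:
        raise ValueError("zero pooled variance: Dunnett statistics undefined")
    ms_err = ss_err / df
    grand = np.concatenate([vals[g] for g in names]).mean()
    ss_trt = float((ns * (means - grand) ** 2).sum())
    F = (ss_trt / (k - 1)) / ms_err
    anova_p = float(sps.f.sf(F, k - 1, df))

    se = np.sqrt(ms_err * (1.0 / ns[1:] + 1.0 / ns[0]))
    t_obs = (means[1:] - means[0]) / se

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_mc, k)) / np.sqrt(ns)[None, :]
    s2 = rng.chisquare(df, size=n_mc) / df
    t_null = (z[:, 1:] - z[:, :1]) / np.sqrt(s2)[:, None] \
        / np.sqrt(1.0 / ns[1:] + 1.0 / ns[0])[None, :]
    max_abs = np.abs(t_null).max(axis=1)
    p_adj = np.array([(max_abs >= abs(t)).mean() for t in t_obs])
    p_adj = np.clip(p_adj, 1.0 / n_mc, 1.0)

    comp = pd.DataFrame({
        "treatment": names[1:],
        "mean_diff": means[1:] - means[0],
        "t": t_obs,
        "p_adj": p_adj,
        "stars": [stars(p) for p in p_adj],
    })
    return DunnettResult(comp, float(F), anova_p, df)


def dunnett_by_dose(
    well_results: pd.DataFrame,
    value_col: str,
    control_condition: str,
    n_mc: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett comparisons of every condition x dose against the control wells."""
    ok = well_results[~well_results["empty"]] if "empty" in well_results.columns \
        else well_results
    ctrl = ok[ok["condition"] == control_condition][value_col].dropna().to_numpy()
    groups = {"control": ctrl}
    keys = []
    for (cond, dose), grp in ok[ok["condition"] != control_condition].groupby(
            ["condition", "dose"], sort=True):
        key = f"{cond}@{dose:g}" if isinstance(dose, (int, float)) else f"{cond}@{dose}"
        groups[key] = grp[value_col].dropna().to_numpy()
        keys.append((key, cond, dose))
    res = dunnett_test(groups, control="control", n_mc=n_mc, seed=seed)
    out = res.comparisons.copy()
    meta = pd.DataFrame(keys, columns=["treatment", "condition", "dose"])
    out = out.merge(meta, on="treatment")
    out["endpoint"] = value_col
    out["anova_F"] = res.anova_F
    out["anova_p"] = res.anova_p
    return out


# ---------------------------------------------------- morphotoxicity summary


def cavity_histogram(cavity_counts: np.ndarray) -> dict[str, float]:
    """Percentages in the cavity-count categories {0, 1, 2, 3, 4, >4}
    (not-applicable objects, coded -1, are excluded)."""
    counts = np.asarray(cavity_counts)
    counts = counts[counts >= 0]
    n = counts.size
    out = {}
    for b in CAVITY_BINS:
        if b == ">4":
            c = int((counts > 4).sum())
        else:
            c = int((counts == int(b)).sum())
        out[f"cavity_{b}"] = 100.0 * c / n if n else float("nan")
    return out


def morphotoxicity_summary(
    well_results: pd.DataFrame,
    compartments: pd.DataFrame,
    control_condition: str = "control",
    n_mc: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-condition morphotoxicity aggregates with Dunnett tests vs control.

    ``compartments`` needs columns ``well_id, condition, dose`` plus the
    compartment measurements (``cavity_count``, ``caspase_integrated``,
    ``caspase_radial_cv_bin1..4``).  Delaminated yield (if present in
    ``well_results``) is tested at well level; caspase intensity per well mean.
    """
    rows = []
    for (cond, dose), grp in compartments.groupby(["condition", "dose"], sort=True):
        row = dict(condition=cond, dose=dose, n_objects=len(grp))
        row.update(cavity_histogram(grp["cavity_count"].to_numpy()))
        if "caspase_integrated" in grp.columns:
            row["caspase_integrated_mean"] = float(grp["caspase_integrated"].mean())
            for b in range(1, 5):
                col = f"caspase_radial_cv_bin{b}"
                if col in grp.columns:
                    row[f"{col}_mean"] = float(grp[col].mean())
        rows.append(row)
    summary = pd.DataFrame(rows)

    if "delaminated_yield" in well_results.columns and \
            (well_results["condition"] != control_condition).any():
        delam = dunnett_by_dose(well_results, "delaminated_yield",
                                control_condition, n_mc=n_mc, seed=seed)
        summary = summary.merge(
            delam[["condition", "dose", "p_adj", "stars"]].rename(
                columns={"p_adj": "delam_p_adj", "stars": "delam_stars"}),
            on=["condition", "dose"], how="left")
    return summary


# --------------------------------------------------------- effect categories


@dataclass
class EffectThresholds:
    """Configurable formalization of the four narrative effect groups."""

    alpha: float = 0.05
    cytotoxic_yield_floor: float = 20.0  # % XEn/EpiC at top dose
    monotone_tolerance: float = 3.0  # pp of non-monotonicity allowed


@dataclass
class EffectCall:
    category: str  # gradient | morphotoxic | no_effect | cytotoxic_morphotoxic | unclassified
    diagnostics: dict = field(default_factory=dict)


def classify_effect(dose_table: pd.DataFrame,
                    thresholds: EffectThresholds | None = None) -> EffectCall:
    """Rule-based compound effect categorization from per-dose endpoint results.

    ``dose_table`` has one row per dose (any order; sorted internally) with:

    * ``dose``, ``xen_epic_yield`` (mean %, this dose),
    * ``xen_epic_p`` — Dunnett p for the XEn/EpiC yield vs control,
    * ``earlier_p``, ``earlier_increase`` — smallest Dunnett p among
      earlier-stage class yields and whether that effect is an increase,
    * ``area_p``, ``area_decrease`` — XEn/EpiC area endpoint,
    * optional ``delam_p``, ``delam_increase``; ``multi_cavity_p``,
      ``multi_cavity_increase``; ``control_yield`` (defaults from data).

    Categories: *gradient* (significant terminal-yield decrease at the top
    dose with a monotone trend and no morphotoxicity/area change),
    *morphotoxic* (significant earlier-stage / delamination / multi-cavity
    increase or area reduction, top-dose yield above the cytotoxicity floor),
    *cytotoxic_morphotoxic* (top-dose yield at or below the floor with
    morphology flags), *no_effect*, else *unclassified*.
    """
    th = thresholds or EffectThresholds()
    required = {"dose", "xen_epic_yield", "xen_epic_p"}
    missing = required - set(dose_table.columns)
    if missing or len(dose_table) < 3:
        return EffectCall("unclassified",
                          dict(reason=f"missing endpoints: {sorted(missing)}"
                               if missing else "fewer than 3 doses"))
    t = dose_table.sort_values("dose").reset_index(drop=True)

    def sig(col, direction_col=None):
        if col not in t.columns:
            return pd.Series(False, index=t.index)
        s = t[col] <= th.alpha
        if direction_col is not None and direction_col in t.columns:
            s &= t[direction_col].astype(bool)
        return s.fillna(False)

    yield_sig_dec = sig("xen_epic_p") & (
        t["xen_epic_yield"] < t.get("control_yield", np.inf))
    earlier_sig = sig("earlier_p", "earlier_increase")
    area_sig = sig("area_p", "area_decrease")
    delam_sig = sig("delam_p", "delam_increase")
    cavity_sig = sig("multi_cavity_p", "multi_cavity_increase")
    morpho_any = bool((earlier_sig | area_sig | delam_sig | cavity_sig).any())

    top_yield = float(t["xen_epic_yield"].iloc[-1])
    diffs = np.diff(t["xen_epic_yield"].to_numpy())
    monotone_dec = bool(np.all(diffs <= th.monotone_tolerance))
    any_sig = bool(yield_sig_dec.any()) or morpho_any

    diag = dict(top_yield=top_yield, monotone_decreasing=monotone_dec,
                yield_significant=bool(yield_sig_dec.any()),
                morphotoxicity_significant=morpho_any)
    if not any_sig:
        return EffectCall("no_effect", diag)
    if top_yield <= th.cytotoxic_yield_floor and morpho_any:
        return EffectCall("cytotoxic_morphotoxic", diag)
    if morpho_any and top_yield > th.cytotoxic_yield_floor:
        return EffectCall("morphotoxic", diag)
    if bool(yield_sig_dec.iloc[-1]) and monotone_dec and not morpho_any:
        return EffectCall("gradient", diag)
    return EffectCall("unclassified", diag)


# --------------------------------------------------------------- ATP ingest


def viability_ingest(table: pd.DataFrame | str,
                     control_condition: str = "control") -> pd.DataFrame:
    """Normalize an ATP-luminescence plate table and flag recovery.

    Input columns: ``condition, dose, timepoint, luminescence`` with
    timepoints "72h" and "120h".  Each value is normalized to the mean control
    luminescence at the same timepoint (control normalized = 1).  Per
    condition x dose: flag ``irreversible`` when normalized(120h) dropped
    below normalized(72h) and below 0.5; ``recovered`` when normalized(120h)
    >= 0.9; else ``partial``.
    """
    df = pd.read_csv(table) if isinstance(table, str) else table.copy()
    required = {"condition", "dose", "timepoint", "luminescence"}
    if not required <= set(df.columns):
        raise ValueError(f"viability table must have columns {sorted(required)}")
    if (df["luminescence"] < 0).any():
        raise ValueError("negative luminescence values")
    ctrl = df[df["condition"] == control_condition]
    if ctrl.empty:
        raise ValueError(f"missing control rows for {control_condition!r}")
    ctrl_means = ctrl.groupby("timepoint")["luminescence"].mean()
    missing_tp = set(df["timepoint"]) - set(ctrl_means.index)
    if missing_tp:
        raise ValueError(f"missing control rows at timepoints {sorted(missing_tp)}")
    df["normalized"] = df.apply(
        lambda r: r["luminescence"] / ctrl_means[r["timepoint"]], axis=1)

    flags = []
    for (cond, dose), grp in df.groupby(["condition", "dose"], sort=True):
        tp = grp.groupby("timepoint")["normalized"].mean()
        n72 = tp.get("72h", np.nan)
        n120 = tp.get("120h", np.nan)
        if np.isnan(n72) or np.isnan(n120):
            flag = "incomplete"
        elif n120 < n72 and n120 < 0.5:
            flag = "irreversible"
        elif n120 >= 0.9:
            flag = "recovered"
        else:
            flag = "partial"
        flags.append(dict(condition=cond, dose=dose, normalized_72h=n72,
                          normalized_120h=n120, recovery=flag))
    return df.merge(pd.DataFrame(flags), on=["condition", "dose"])
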