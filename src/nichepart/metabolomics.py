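"""Untargeted and semi-targeted metabolomics processing.

Works from intensity tables (no raw spectra): merges technical-replicate
injections, tests time-point changes per ion with Student's t-tests and
Benjamini–Hochberg correction, classifies pollen-derived ions from a
2x-dilution series by linear regression, tallies how species-specific the
depleted ions are, and normalizes GC-MS peak areas to internal standards.

Tidy input conventions
----------------------
Ion tables: columns ``ion_id, condition, timepoint, bio_rep, tech_rep,
intensity`` (one row per injection; ``condition`` is a species name or a
control label).  Dilution series: columns ``ion_id, condition, fraction,
rep, intensity`` with ``condition`` in ``{"dilution", "undiluted",
"water"}`` and ``fraction`` the linear dilution fraction for dilution rows.
GC-MS: columns ``metabolite, timepoint, rep, area, is_internal_standard``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class IonChangeResult:
    """Per-ion time-point comparison within one species."""

    ion_id: str
    species: str
    log2fc: float
    p_raw: float
    p_adj: float
    significant_decrease: bool
    significant_change: bool
    degenerate: bool = False


@dataclass(frozen=True)
class PollenIonCall:
    """Dilution-series classification of one ion."""

    ion_id: str
    r_squared: float
    log2fc_pollen_vs_water: float
    is_pollen_derived: bool


def pseudocount(intensities) -> float:
    """Half the smallest nonzero intensity; 1.0 for an all-zero table."""
    arr = np.asarray(intensities, dtype=float)
    nonzero = arr[arr > 0]
    return float(nonzero.min()) / 2.0 if nonzero.size else 1.0


# ---------------------------------------------------------------------------
# technical replicates


def merge_technical_replicates(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average technical replicates and report their pairwise correlations.

    Returns the table with ``tech_rep`` collapsed by the arithmetic mean,
    plus a report with one row per technical-replicate pair per
    (condition, timepoint, bio_rep): the Pearson correlation of the two
    intensity vectors across ions (NaN when only one injection exists).
    """
    keys = ["condition", "timepoint", "bio_rep"]
    mean_table = (
        table.groupby(keys + ["ion_id"], as_index=False, sort=False)["intensity"]
        .mean()
    )
    report_rows = []
    for group_key, group in table.groupby(keys, sort=False):
        wide = group.pivot_table(
            index="ion_id", columns="tech_rep", values="intensity"
        )
        reps = list(wide.columns)
        if len(reps) < 2:
            report_rows.append(
                dict(zip(keys, group_key))
                | {"tech_rep_a": reps[0] if reps else None, "tech_rep_b": None,
                   "pearson_r": np.nan}
            )
            continue
        for a, b in itertools.combinations(reps, 2):
            x, y = wide[a].to_numpy(float), wide[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                r = 1.0 if np.allclose(x, y) else np.nan
            else:
                r = float(stats.pearsonr(x, y).statistic)
            report_rows.append(
                dict(zip(keys, group_key))
                | {"tech_rep_a": a, "tech_rep_b": b, "pearson_r": r}
            )
    return mean_table, pd.DataFrame(report_rows)


# ---------------------------------------------------------------------------
# time-point change testing


def _t_test(x: np.ndarray, y: np.ndarray, equal_var: bool) -> tuple[float, bool]:
    """Two-sided two-sample t-test p-value with degenerate-variance handling."""
    if np.std(x) == 0 and np.std(y) == 0:
        return (1.0, False) if math.isclose(x.mean(), y.mean()) else (0.0, True)
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.pvalue), False


def ion_change_test(
    table: pd.DataFrame,
    t0: float = 0,
    t_final: float = 16,
    alpha: float = 0.01,
    fc_cut: float = 1.0,
    species: list[str] | None = None,
    equal_var: bool = True,
    eps: float | None = None,
) -> pd.DataFrame:
    """Per-ion time-point comparison for each species.

    ``table`` must already have technical replicates merged (one intensity
    per (condition, timepoint, bio_rep, ion)).  Per species and ion, the
    biological-replicate intensities at ``t0`` and ``t_final`` are compared
    with a two-sided Student's t-test (Welch with ``equal_var=False``);
    Benjamini–Hochberg adjustment is applied within each species across all
    ions.  ``log2fc = log2(mean(t_final)+eps) - log2(mean(t0)+eps)`` with a
    pseudocount of half the smallest nonzero intensity by default.

    Flags per row: ``significant_decrease`` (log2fc <= -fc_cut and
    p_adj <= alpha) and ``significant_change`` (|log2fc| >= fc_cut and
    p_adj <= alpha).
    """
    if species is None:
        species = sorted(table["condition"].unique())
    if eps is None:
        eps = pseudocount(table["intensity"])
    frames = []
    for sp in species:
        sub = table[table["condition"] == sp]
        rows = []
        for ion, g in sub.groupby("ion_id", sort=False):
            x0 = g.loc[g["timepoint"] == t0, "intensity"].to_numpy(float)
            x1 = g.loc[g["timepoint"] == t_final, "intensity"].to_numpy(float)
            if len(x0) < 2 or len(x1) < 2:
                raise ValueError(
                    f"ion {ion!r} in {sp!r} needs >=2 biological replicates per timepoint"
                )
            p, degen = _t_test(x0, x1, equal_var)
            log2fc = math.log2(x1.mean() + eps) - math.log2(x0.mean() + eps)
            rows.append(
                {"ion_id": ion, "species": sp, "log2fc": log2fc,
                 "p_raw": p, "degenerate": degen}
            )
        df = pd.DataFrame(rows)
        df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["significant_decrease"] = (out["log2fc"] <= -fc_cut) & (out["p_adj"] <= alpha)
    out["significant_change"] = (out["log2fc"].abs() >= fc_cut) & (out["p_adj"] <= alpha)
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# pollen-derived ion classification


def classify_pollen_ion(
    fractions,
    intensities,
    undiluted,
    water,
    ion_id: str = "",
    r2_threshold: float = 0.75,
    fc_threshold: float = 2.0,
    eps: float | None = None,
    use_step_index: bool = False,
) -> PollenIonCall:
    """Classify one ion as pollen-derived from its dilution series.

    The intensity is regressed on the linear dilution fraction (ordinary
    least squares, every replicate as one point; ``use_step_index`` switches
    the regressor to the dilution-step index).  ``log2fc_pollen_vs_water``
    compares mean undiluted-pollen intensity to mean water-blank intensity
    (pseudocounted).  The ion is pollen-derived when the fit's R² exceeds
    ``r2_threshold`` and the fold change exceeds ``fc_threshold``.
    """
    x = np.asarray(fractions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >=3 distinct dilution fractions")
    if use_step_index:
        # 0 = most dilute ... k = least dilute, mirroring the fraction order
        order = {f: i for i, f in enumerate(np.unique(x))}
        x = np.asarray([order[v] for v in x], dtype=float)
    if np.all(y == 0) or np.std(y) == 0:
        r_squared = 0.0
    else:
        fit = stats.linregress(x, y)
        r_squared = 0.0 if math.isnan(fit.rvalue) else float(fit.rvalue) ** 2
    und = np.asarray(undiluted, dtype=float)
    wat = np.asarray(water, dtype=float)
    if eps is None:
        eps = pseudocount(np.concatenate([y, und, wat]))
    log2fc = math.log2(und.mean() + eps) - math.log2(wat.mean() + eps)
    return PollenIonCall(
        ion_id=ion_id,
        r_squared=r_squared,
        log2fc_pollen_vs_water=log2fc,
        is_pollen_derived=(r_squared > r2_threshold) and (log2fc > fc_threshold),
    )


def classify_pollen_ions(
    dilution_table: pd.DataFrame,
    r2_threshold: float = 0.75,
    fc_threshold: float = 2.0,
    use_step_index: bool = False,
) -> pd.DataFrame:
    """Vector version of :func:`classify_pollen_ion` over a tidy table.

    Expects columns ``ion_id, condition, fraction, rep, intensity`` with
    ``condition`` in ``{"dilution", "undiluted", "water"}``.  A single
    pseudocount (half the smallest nonzero intensity in the whole table) is
    shared across ions so fold changes are comparable.
    """
    eps = pseudocount(dilution_table["intensity"])
    rows = []
    for ion, g in dilution_table.groupby("ion_id", sort=False):
        dil = g[g["condition"] == "dilution"]
        call = classify_pollen_ion(
            dil["fraction"], dil["intensity"],
            g.loc[g["condition"] == "undiluted", "intensity"],
            g.loc[g["condition"] == "water", "intensity"],
            ion_id=str(ion), r2_threshold=r2_threshold,
            fc_threshold=fc_threshold, eps=eps, use_step_index=use_step_index,
        )
        rows.append(
            {"ion_id": call.ion_id, "r_squared": call.r_squared,
             "log2fc_pollen_vs_water": call.log2fc_pollen_vs_water,
             "is_pollen_derived": call.is_pollen_derived}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# species specificity of depleted ions


def decrease_specificity(
    results: pd.DataFrame, n_species: int | None = None
) -> tuple[pd.Series, dict[str, int]]:
    """Count in how many species each ion significantly decreases.

    ``results`` needs columns ``ion_id, species, significant_decrease`` with
    every ion tested in every species.  Ions decreasing in no species are
    excluded.  Returns the per-ion category (number of species) and summary
    counts: ``all_species`` (category == n_species), ``subset``
    (2 <= category < n_species), and ``single`` (category == 1).
    """
    pivot = results.pivot_table(
        index="ion_id", columns="species", values="significant_decrease",
        aggfunc="first",
    )
    if pivot.isna().any().any():
        raise ValueError("every ion must be tested in every species")
    if n_species is None:
        n_species = pivot.shape[1]
    category = pivot.astype(bool).sum(axis=1)
    category = category[category > 0]
    counts = {
        "all_species": int((category == n_species).sum()),
        "subset": int(((category >= 2) & (category < n_species)).sum()),
        "single": int((category == 1).sum()),
    }
    return category, counts


# ---------------------------------------------------------------------------
# GC-MS internal-standard normalization and fold changes


def normalize_to_internal_standards(records: pd.DataFrame) -> pd.DataFrame:
    """Divide each peak area by the run's geometric mean internal-standard area.

    A run is one (timepoint, rep) injection.  Runs with any zero or missing
    internal standard are flagged (``excluded=True``) and dropped from
    downstream means.
    """
    out_rows = []
    for (tp, rep), run in records.groupby(["timepoint", "rep"], sort=False):
        is_areas = run.loc[run["is_internal_standard"], "area"].to_numpy(float)
        excluded = is_areas.size == 0 or np.any(is_areas <= 0)
        geomean = float(np.exp(np.mean(np.log(is_areas)))) if not excluded else np.nan
        for _, row in run[~run["is_internal_standard"]].iterrows():
            out_rows.append(
                {"metabolite": row["metabolite"], "timepoint": tp, "rep": rep,
                 "normalized_area": row["area"] / geomean if not excluded else np.nan,
                 "excluded": excluded}
            )
    return pd.DataFrame(out_rows)


def gcms_fold_changes(
    records: pd.DataFrame,
    t0: float = 0,
    t_final: float = 24,
    fc_cut: float = 2.0,
    alpha: float = 0.01,
    equal_var: bool = True,
    eps: float | None = None,
) -> pd.DataFrame:
    """Per-metabolite log2 fold changes versus the T0 mean, significance at T24.

    Peak areas are normalized per run to the geometric mean of the internal
    standards, then each timepoint's mean normalized area is expressed as a
    log2 ratio to the mean at ``t0``.  At ``t_final`` a Student's t-test
    (T0 vs T_final, BH-corrected across metabolites) determines significance:
    ``|log2FC| >= fc_cut`` and adjusted p <= ``alpha``.
    """
    norm = normalize_to_internal_standards(records)
    norm = norm[~norm["excluded"]]
    if eps is None:
        eps = pseudocount(norm["normalized_area"])
    rows = []
    for met, g in norm.groupby("metabolite", sort=False):
        base = g.loc[g["timepoint"] == t0, "normalized_area"].to_numpy(float)
        if base.size == 0:
            raise ValueError(f"metabolite {met!r} has no T0 measurements")
        for tp in sorted(g["timepoint"].unique()):
            vals = g.loc[g["timepoint"] == tp, "normalized_area"].to_numpy(float)
            log2fc = math.log2(vals.mean() + eps) - math.log2(base.mean() + eps)
            row = {"metabolite": met, "timepoint": tp, "log2fc": log2fc,
                   "p_raw": np.nan}
            if tp == t_final:
                row["p_raw"], _ = _t_test(base, vals, equal_var)
            rows.append(row)
    out = pd.DataFrame(rows)
    final = out["timepoint"] == t_final
    out.loc[final, "p_adj"] = bh_adjust(out.loc[final, "p_raw"].to_numpy())
    out["significant"] = final & (out["log2fc"].abs() >= fc_cut) & (out["p_adj"] <= alpha)
    return out
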