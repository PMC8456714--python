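"""Absolute-abundance community dynamics for serial-passage experiments.

Strain proportions from amplicon sequencing are scaled by a total bacterial
load (CFU counts or qPCR copies) into absolute abundances.  Each replicate
carries a per-passage limit of detection — the abundance equivalent of a
single assigned read, ``total_load / assigned_read_depth`` — below which an
undetected strain may lie anywhere.  Community stability over a sliding
window of passages is the temporal mean of abundance divided by its temporal
(sample) standard deviation, i.e. the inverse coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StabilityResult:
    """Stability of one sliding window: temporal mean / temporal sample SD."""

    replicate_id: str
    window_start: int  # passage index at the window's left edge
    window_size: int
    step: int
    stability: float
    strain: str | None = None  # set in per-species mode

    @property
    def finite(self) -> bool:
        return math.isfinite(self.stability)


def absolute_abundance(
    proportions: dict[str, float] | pd.Series, total_load: float
) -> dict[str, float]:
    """Scale strain proportions by the sample's total load.

    ``abundance_s = proportion_s * total_load``; the outputs sum to the
    total load exactly (up to float rounding).
    """
    if total_load < 0:
        raise ValueError("total_load must be >= 0")
    items = proportions.items() if hasattr(proportions, "items") else proportions
    out = {strain: float(p) * float(total_load) for strain, p in items}
    if any(v < 0 for v in out.values()):
        raise ValueError("proportions must be >= 0")
    return out


def detection_limit(total_load: float, assigned_read_depth: int) -> float:
    """Abundance equivalent of one assigned read.

    A strain with zero assigned reads may be anywhere below this bound.
    Raises when the sample has no assigned reads at all (the limit is not
    evaluable, never silently zero).
    """
    if assigned_read_depth < 1:
        raise ValueError("detection limit not evaluable at zero assigned depth")
    if total_load < 0:
        raise ValueError("total_load must be >= 0")
    return float(total_load) / float(assigned_read_depth)


def mean_lod_ci(
    lods, level: float = 0.95
) -> tuple[float, float | None, float | None]:
    """Mean detection limit across replicates with a two-sided t interval.

    With a single replicate the mean is returned and the interval is
    flagged unavailable (``None`` bounds).
    """
    arr = np.asarray(list(lods), dtype=float)
    if arr.size == 0:
        raise ValueError("no detection limits supplied")
    mean = float(arr.mean())
    if arr.size < 2:
        return mean, None, None
    sem = float(arr.std(ddof=1)) / math.sqrt(arr.size)
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df=arr.size - 1))
    return mean, mean - tcrit * sem, mean + tcrit * sem


def _window_stats(values: np.ndarray) -> float:
    sd = float(values.std(ddof=1))
    mean = float(values.mean())
    if sd == 0.0:
        return math.inf if mean != 0 else math.nan
    return mean / sd


def community_stability(
    abundances: pd.DataFrame | np.ndarray,
    window: int = 5,
    step: int = 1,
    mode: str = "aggregate",
    replicate_id: str = "",
    passages: list[int] | None = None,
    strains: list[str] | None = None,
) -> list[StabilityResult]:
    """Sliding-window stability of one replicate's abundance series.

    Parameters
    ----------
    abundances
        Passages × strains matrix (rows ordered by passage).
    window, step
        Window size in passages (default 5) and step between window starts.
    mode
        ``"aggregate"`` (default): mean/SD of the summed community abundance
        within each window.  ``"per_species"``: the statistic per strain.

    A window with zero standard deviation (a constant community) yields a
    non-finite stability rather than an error.
    """
    if isinstance(abundances, pd.DataFrame):
        if passages is None:
            passages = list(abundances.index)
        if strains is None:
            strains = list(abundances.columns)
        mat = abundances.to_numpy(dtype=float)
    else:
        mat = np.asarray(abundances, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        if passages is None:
            passages = list(range(1, mat.shape[0] + 1))
        if strains is None:
            strains = [f"strain_{i}" for i in range(mat.shape[1])]
    n = mat.shape[0]
    if window < 2:
        raise ValueError("window must be >= 2")
    if n < window:
        raise ValueError(f"need >= {window} passages, got {n}")
    results: list[StabilityResult] = []
    for start in range(0, n - window + 1, step):
        block = mat[start : start + window]
        if mode == "aggregate":
            results.append(
                StabilityResult(
                    replicate_id, passages[start], window, step,
                    _window_stats(block.sum(axis=1)),
                )
            )
        elif mode == "per_species":
            for j, strain in enumerate(strains):
                results.append(
                    StabilityResult(
                        replicate_id, passages[start], window, step,
                        _window_stats(block[:, j]), strain=strain,
                    )
                )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return results


def coexistence_summary(
    abundances: pd.DataFrame,
    lods,
) -> pd.DataFrame:
    """Per-strain persistence relative to the detection limit.

    Parameters
    ----------
    abundances
        Passages × strains frame for one replicate, indexed by passage.
    lods
        Detection limit per passage (scalar, sequence, or Series sharing the
        passage axis).

    Returns a frame with, per strain: the last passage above the limit, the
    fraction of passages above it, and the final abundance; plus one
    ``__community__`` row whose ``n_above_lod_final`` column counts strains
    above the limit at the final passage.
    """
    passages = list(abundances.index)
    lod_arr = np.broadcast_to(
        np.asarray(lods, dtype=float), (len(passages),)
    ) if np.ndim(lods) == 0 else np.asarray(lods, dtype=float)
    if lod_arr.shape[0] != len(passages):
        raise ValueError("lods must share the passage axis")
    rows = []
    final_above = 0
    for strain in abundances.columns:
        vals = abundances[strain].to_numpy(dtype=float)
        above = vals > lod_arr
        last = passages[int(np.flatnonzero(above)[-1])] if above.any() else None
        if above[-1]:
            final_above += 1
        rows.append(
            {
                "strain": strain,
                "last_passage_above_lod": last,
                "fraction_above_lod": float(above.mean()),
                "final_abundance": float(vals[-1]),
                "n_above_lod_final": np.nan,
            }
        )
    rows.append(
        {
            "strain": "__community__",
            "last_passage_above_lod": None,
            "fraction_above_lod": np.nan,
            "final_abundance": float(abundances.to_numpy()[-1].sum()),
            "n_above_lod_final": final_above,
        }
    )
    return pd.DataFrame(rows).set_index("strain")


def abundance_table(
    proportions: pd.DataFrame,
    totals: pd.Series,
    depths: pd.Series,
) -> pd.DataFrame:
    """Tidy per-sample absolute abundances with detection limits.

    ``proportions`` is samples × strains; ``totals`` and ``depths`` are
    indexed by the same samples.  Returns a tidy frame (sample, strain,
    abundance, lod).
    """
    records = []
    for sample in proportions.index:
        load = float(totals.loc[sample])
        depth = int(depths.loc[sample])
        lod = detection_limit(load, depth)
        abs_ab = absolute_abundance(proportions.loc[sample], load)
        for strain, value in abs_ab.items():
            records.append(
                {"sample": sample, "strain": strain, "abundance": value, "lod": lod}
            )
    return pd.DataFrame(records)


def plot_trajectories(
    abundances: pd.DataFrame,
    lods=None,
    ax=None,
    log: bool = True,
):  # pragma: no cover - thin plotting helper
    """Plot per-strain abundance trajectories with an optional LOD band.

    On a log axis, exact zeros are displayed at LOD/2 (display only; analysis
    tables keep true zeros).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lod_arr = None
    if lods is not None:
        lod_arr = np.broadcast_to(np.asarray(lods, float), (len(abundances.index),))
    for strain in abundances.columns:
        y = abundances[strain].to_numpy(dtype=float)
        if log and lod_arr is not None:
            y = np.where(y > 0, y, lod_arr / 2.0)
        ax.plot(abundances.index, y, marker="o", label=strain)
    if lod_arr is not None:
        ax.fill_between(abundances.index, 0, lod_arr, color="0.85", label="LOD")
    if log:
        ax.set_yscale("log")
    ax.set_xlabel("passage")
    ax.set_ylabel("absolute abundance")
    ax.legend(fontsize=8)
    return ax
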