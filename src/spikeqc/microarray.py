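"""Microarray-side QC: normalisation, LOD, detection, linearity and precision.

The analysis mirrors the standard one-colour platform pipeline: raw
background-corrected intensities are log2-transformed, scaled per array to
its 75th percentile, and baselined per feature to the median across arrays.
Per-standard signals are summarised as the median of the replicate probes on
each array.  The limit of detection (LOD) is estimated from blank features
as the upper two-sided 95% confidence limit of the mean blank intensity on
the raw scale, and detection fractions, linear-range regressions and
CV-based precision metrics are computed per standard and abundance level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panels import PanelDesign
from .simulate import BACKGROUND, BLANK

__all__ = [
    "LinearFit",
    "QCError",
    "normalize_75th",
    "summarize_probes",
    "estimate_lod",
    "detection_fraction",
    "fit_linear_range",
    "auto_linear_range",
    "precision_metrics",
    "correlate_arrays",
    "MicroarrayQC",
    "MicroarrayQCResults",
]


class QCError(ValueError):
    """Raised for inputs an analysis step cannot meaningfully process."""


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of (log2) signal on log2 abundance across a dilution range."""

    slope: float
    intercept: float
    r_squared: float
    range_used: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise QCError(f"r_squared outside [0, 1]: {self.r_squared}")


def normalize_75th(table: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """75th-percentile scaling and median baselining of an intensity table.

    ``v = log2(raw_intensity + pseudocount)``; per array, subtract that
    array's 75th percentile of ``v``; then per feature, subtract the median
    across arrays.  Returns a copy of ``table`` with a ``log2_norm`` column.
    Immediately after scaling, every array's 75th percentile is 0; after
    baselining, every feature's cross-array median is 0.
    """
    required = {"feature_id", "array_id", "raw_intensity"}
    if not required <= set(table.columns):
        raise QCError(f"intensity table lacks columns {sorted(required - set(table.columns))}")
    for aid, grp in table.groupby("array_id"):
        if len(grp) < 4:
            raise QCError(f"array {aid!r} has fewer than 4 features")
        if (grp["raw_intensity"] == 0).all():
            raise QCError(f"array {aid!r} has all-zero intensities; cannot normalize")
    out = table.copy()
    v = np.log2(out["raw_intensity"].to_numpy(dtype=float) + pseudocount)
    if not np.isfinite(v).all():
        raise QCError("non-finite log2 intensities; increase pseudocount")
    out["log2_norm"] = v
    out["log2_norm"] -= out.groupby("array_id")["log2_norm"].transform(
        lambda x: np.percentile(x, 75)
    )
    out["log2_norm"] -= out.groupby("feature_id")["log2_norm"].transform("median")
    return out


def summarize_probes(
    table: pd.DataFrame, statistic: str = "median", value: str = "raw_intensity"
) -> pd.DataFrame:
    """Per (standard, array) summary of replicate-probe values.

    Collapses the replicate probes of each standard on each array with the
    chosen statistic (default median, robust to outlier probes).  Blank
    features are excluded.  Keeps the array's sample/run/labelling
    annotations.  Returns columns
    ``standard_id, array_id, sample, run, labelling_id, <value>``.
    """
    if statistic not in ("median", "mean"):
        raise QCError(f"unknown probe summary statistic {statistic!r}")
    probes = table[~table["standard_id"].isin((BLANK, BACKGROUND))]
    if "blank" in table.columns:
        probes = probes[~probes["blank"].astype(bool)]
    keys = ["standard_id", "array_id"]
    carried = [c for c in ("sample", "run", "labelling_id") if c in table.columns]
    agg = (
        probes.groupby(keys + carried, sort=False)[value]
        .agg(statistic)
        .reset_index()
    )
    return agg


def estimate_lod(blanks: np.ndarray | pd.Series) -> float:
    """LOD as the upper 95% confidence limit of the mean blank intensity.

    ``lod = mean + t_{0.975, n-1} * SD / sqrt(n)`` on raw intensities, with
    the sample SD (ddof=1).  Signals above this threshold are unlikely to be
    background.  Requires at least two blank observations.
    """
    b = np.asarray(blanks, dtype=float)
    b = b[np.isfinite(b)]
    n = b.size
    if n < 2:
        raise QCError(f"need >= 2 blank observations to estimate LOD (got {n})")
    return float(b.mean() + stats.t.ppf(0.975, n - 1) * b.std(ddof=1) / math.sqrt(n))


def detection_fraction(values: np.ndarray | pd.Series, lod: float) -> float:
    """Fraction of summary values strictly above the LOD (ties count as absent)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise QCError("detection_fraction needs at least one observation")
    return float(np.mean(v > lod))


def _ols_log2(levels: np.ndarray, values: np.ndarray) -> tuple[float, float, float]:
    x = np.log2(levels)
    if np.allclose(values, values[0]) or np.allclose(x, x[0]):
        raise QCError("degenerate fit: no variation in levels or values")
    res = stats.linregress(x, values)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return float(res.slope), float(res.intercept), r2


def fit_linear_range(
    levels: np.ndarray | list[float],
    values: np.ndarray | list[float],
    fit_range: tuple[float, float],
) -> LinearFit:
    """OLS of log2-scale signal on log2(copies/ng) inside ``fit_range``.

    ``values`` are log2-scale summaries (one per observation, paired with
    ``levels``).  A slope of 1.0 means 10-fold abundance steps are recovered
    as 10-fold signal steps — the ideal proportional response.
    """
    lv = np.asarray(levels, dtype=float)
    vv = np.asarray(values, dtype=float)
    if lv.shape != vv.shape:
        raise QCError("levels and values must align")
    if (lv <= 0).any():
        raise QCError("all levels must be > 0 for a log-log fit")
    lo, hi = float(fit_range[0]), float(fit_range[1])
    keep = (lv >= lo) & (lv <= hi)
    if len(np.unique(lv[keep])) < 3:
        raise QCError(f"fewer than 3 distinct levels inside range [{lo}, {hi}]")
    slope, intercept, r2 = _ols_log2(lv[keep], vv[keep])
    return LinearFit(slope, intercept, r2, (lo, hi), int(keep.sum()))


def auto_linear_range(
    levels: np.ndarray | list[float], values: np.ndarray | list[float]
) -> tuple[float, float]:
    """Automatic surrogate for visual linear-range selection.

    Enumerates every contiguous window of at least 4 distinct nonzero levels
    and returns the window maximising the fit R-squared; ties (within 1e-9)
    go to the wider window, then to the lower starting level.  Deterministic.
    """
    lv = np.asarray(levels, dtype=float)
    vv = np.asarray(values, dtype=float)
    distinct = np.unique(lv[lv > 0])
    if distinct.size < 4:
        raise QCError("need >= 4 distinct nonzero levels for automatic range selection")
    best: tuple[float, int, float, tuple[float, float]] | None = None
    got_fit = False
    for i in range(distinct.size):
        for j in range(i + 3, distinct.size):
            lo, hi = distinct[i], distinct[j]
            keep = (lv >= lo) & (lv <= hi) & (lv > 0)
            try:
                slope, _, r2 = _ols_log2(lv[keep], vv[keep])
            except QCError:
                continue
            got_fit = True
            cand = (r2, j - i, -lo, (float(lo), float(hi)))
            if best is None or _range_better(cand, best):
                best = cand
    if not got_fit or best is None:
        raise QCError("degenerate data: no linear window could be fitted")
    return best[3]


def _range_better(cand, best) -> bool:
    if cand[0] > best[0] + 1e-9:
        return True
    if cand[0] < best[0] - 1e-9:
        return False
    if cand[1] != best[1]:
        return cand[1] > best[1]
    return cand[2] > best[2]


def precision_metrics(
    raw_summaries: pd.DataFrame,
    norm_summaries: pd.DataFrame,
    design: PanelDesign,
) -> pd.DataFrame:
    """CV-based technical precision per (standard, abundance level).

    Columns of the result:

    * ``cv_raw_pct`` — 100 * SD/mean of raw per-array summaries across all
      arrays at that level (run-to-run technical reproducibility).
    * ``var_norm_pct`` — percentage variation of the normalised signal,
      mapped from the log2 scale as ``100 * (2**SD(log2) - 1)``.
    * ``between_run_pct`` — CV of per-run mean raw summaries.
    * ``within_run_pct`` — CV across replicate arrays within a run, averaged
      over runs (needs >= 2 arrays per run; otherwise absent).

    Groups with fewer than two observations report NaN for that metric.
    """
    raw = raw_summaries.copy()
    raw["level"] = [
        design.level_of(s, smp) for s, smp in zip(raw["standard_id"], raw["sample"])
    ]
    norm = norm_summaries.copy()
    norm["level"] = [
        design.level_of(s, smp) for s, smp in zip(norm["standard_id"], norm["sample"])
    ]
    value_raw = "raw_intensity" if "raw_intensity" in raw.columns else raw.columns[-2]
    value_norm = "log2_norm" if "log2_norm" in norm.columns else norm.columns[-2]

    rows = []
    for (sid, level), grp in raw.groupby(["standard_id", "level"]):
        x = grp[value_raw].to_numpy(dtype=float)
        cv_raw = _cv_pct(x)
        run_means = grp.groupby("run")[value_raw].mean().to_numpy()
        between = _cv_pct(run_means)
        within_vals = [
            _cv_pct(g[value_raw].to_numpy(dtype=float)) for _, g in grp.groupby("run")
        ]
        within_vals = [w for w in within_vals if not math.isnan(w)]
        within = float(np.mean(within_vals)) if within_vals else math.nan
        ngrp = norm[(norm["standard_id"] == sid) & (norm["level"] == level)]
        y = ngrp[value_norm].to_numpy(dtype=float)
        var_norm = 100.0 * (2.0 ** y.std(ddof=1) - 1.0) if y.size >= 2 else math.nan
        rows.append(
            {
                "standard_id": sid,
                "level": level,
                "n": x.size,
                "cv_raw_pct": cv_raw,
                "var_norm_pct": var_norm,
                "between_run_pct": between,
                "within_run_pct": within,
            }
        )
    return pd.DataFrame(rows).sort_values(["standard_id", "level"]).reset_index(drop=True)


def _cv_pct(x: np.ndarray) -> float:
    if x.size < 2:
        return math.nan
    m = x.mean()
    if m == 0:
        return math.nan
    return float(100.0 * x.std(ddof=1) / m)


def correlate_arrays(
    normalized: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    value: str = "log2_norm",
) -> pd.DataFrame:
    """Pairwise squared Pearson correlation between whole arrays.

    Arrays are matched feature-by-feature; by default every pair of arrays
    of the same sample is compared.  Pairs where either array has zero
    variance are reported with NaN.
    """
    wide = normalized.pivot(index="feature_id", columns="array_id", values=value)
    if wide.isna().any().any():
        raise QCError("arrays do not share the full feature set")
    if pairs is None:
        pairs = []
        if "sample" in normalized.columns:
            arr_sample = normalized.drop_duplicates("array_id").set_index("array_id")["sample"]
            for _, grp in arr_sample.groupby(arr_sample):
                ids = sorted(grp.index)
                pairs += [(a, b) for k, a in enumerate(ids) for b in ids[k + 1 :]]
        else:
            ids = sorted(wide.columns)
            pairs = [(a, b) for k, a in enumerate(ids) for b in ids[k + 1 :]]
    rows = []
    for a, b in pairs:
        x, y = wide[a].to_numpy(), wide[b].to_numpy()
        if x.std() == 0 or y.std() == 0:
            r2 = math.nan
        else:
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        rows.append({"array_a": a, "array_b": b, "r_squared": r2})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class MicroarrayQC:
    """Platform-QC model for a spike-in microarray experiment.

    Parameters
    ----------
    intensities : DataFrame
        Long-format background-corrected intensity table (see
        :func:`spikeqc.simulate.simulate_microarray` for the schema).
    design : PanelDesign
        The dosing design the arrays were hybridised against.
    pseudocount : float
        Added to raw intensities before log2 (keeps zeros finite).
    linear_range : "auto" or (lo, hi)
        Abundance window for the per-standard linearity fits.
    detection_threshold : float
        Minimum detection fraction for a level to be called detected when
        deriving the platform LOD level (default 0.5).
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        design: PanelDesign,
        pseudocount: float = 1.0,
        linear_range: str | tuple[float, float] = "auto",
        detection_threshold: float = 0.5,
    ) -> None:
        self.intensities = intensities
        self.design = design
        self.pseudocount = float(pseudocount)
        self.linear_range = linear_range
        self.detection_threshold = float(detection_threshold)

    def fit(self) -> "MicroarrayQCResults":
        """Run the full array-side QC analysis."""
        table = self.intensities
        normalized = normalize_75th(table, self.pseudocount)
        raw_sum = summarize_probes(table, value="raw_intensity")
        norm_sum = summarize_probes(normalized, value="log2_norm")

        blanks = table.loc[table["blank"].astype(bool), "raw_intensity"]
        lod = estimate_lod(blanks)

        raw_sum = raw_sum.copy()
        raw_sum["level"] = [
            self.design.level_of(s, smp)
            for s, smp in zip(raw_sum["standard_id"], raw_sum["sample"])
        ]
        det_rows = []
        for level, grp in raw_sum.groupby("level"):
            det_rows.append(
                {
                    "level": float(level),
                    "fraction_above_lod": detection_fraction(grp["raw_intensity"], lod),
                    "n": len(grp),
                }
            )
        detection = pd.DataFrame(det_rows).sort_values("level").reset_index(drop=True)

        norm_sum = norm_sum.copy()
        norm_sum["level"] = [
            self.design.level_of(s, smp)
            for s, smp in zip(norm_sum["standard_id"], norm_sum["sample"])
        ]
        fits: dict[str, LinearFit] = {}
        log2_raw = raw_sum.assign(
            log2_signal=np.log2(raw_sum["raw_intensity"] + self.pseudocount)
        )
        for sid, grp in log2_raw.groupby("standard_id"):
            grp = grp[grp["level"] > 0]
            levels = grp["level"].to_numpy(dtype=float)
            values = grp["log2_signal"].to_numpy(dtype=float)
            try:
                rng = (
                    auto_linear_range(levels, values)
                    if self.linear_range == "auto"
                    else tuple(self.linear_range)
                )
                fits[str(sid)] = fit_linear_range(levels, values, rng)
            except QCError as exc:
                warnings.warn(f"linear fit skipped for {sid}: {exc}")
        precision = precision_metrics(raw_sum, norm_sum, self.design)
        correlations = correlate_arrays(normalized)
        return MicroarrayQCResults(
            model=self,
            lod=lod,
            detection=detection,
            linear_fits=fits,
            precision=precision,
            correlations=correlations,
            normalized=normalized,
            raw_summaries=raw_sum,
            norm_summaries=norm_sum,
        )


@dataclass
class MicroarrayQCResults:
    """Fitted array-side QC metrics.

    ``lod`` is the raw-intensity detection threshold; ``detection`` the
    per-level fractions of per-standard array summaries above it;
    ``linear_fits`` per-standard log-log regressions; ``precision`` the
    CV-based reproducibility table; ``correlations`` pairwise array R^2.
    """

    model: MicroarrayQC
    lod: float
    detection: pd.DataFrame
    linear_fits: dict[str, LinearFit]
    precision: pd.DataFrame
    correlations: pd.DataFrame
    normalized: pd.DataFrame
    raw_summaries: pd.DataFrame
    norm_summaries: pd.DataFrame

    def lod_level(self) -> float:
        """Lowest nonzero abundance whose detection fraction reaches the threshold."""
        det = self.detection[self.detection["level"] > 0]
        ok = det[det["fraction_above_lod"] >= self.model.detection_threshold]
        if ok.empty:
            return math.inf
        return float(ok["level"].min())

    def summary(self) -> str:
        """Human-readable QC report."""
        from statsmodels.iolib.table import SimpleTable

        lines = [
            "Microarray spike-in QC",
            "=" * 52,
            f"Arrays: {self.normalized['array_id'].nunique()}   "
            f"Standards: {len(self.linear_fits)}   "
            f"LOD (raw a.u.): {self.lod:.2f}   "
            f"LOD level (copies/ng): {self.lod_level():g}",
            "",
            str(
                SimpleTable(
                    [
                        [f"{lv:g}", f"{fr:.2f}", str(n)]
                        for lv, fr, n in self.detection.itertuples(index=False)
                    ],
                    headers=["copies/ng", "frac>LOD", "n"],
                    title="Detection",
                )
            ),
            "",
            str(
                SimpleTable(
                    [
                        [s, f"{f.slope:.4f}", f"{f.r_squared:.4f}",
                         f"{f.range_used[0]:g}-{f.range_used[1]:g}"]
                        for s, f in sorted(self.linear_fits.items())
                    ],
                    headers=["standard", "slope", "R^2", "range"],
                    title="Linear range fits (log2 signal vs log2 copies/ng)",
                )
            ),
        ]
        return "\n".join(lines)

    def plot_response(self, ax=None):
        """Log-log response curves (median summaries vs abundance) per standard."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for sid, grp in self.raw_summaries.groupby("standard_id"):
            g = grp[grp["level"] > 0].sort_values("level")
            ax.plot(g["level"], g["raw_intensity"], "o-", alpha=0.6, label=str(sid))
        ax.axhline(self.lod, ls="--", color="k", label="LOD")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("copies/ng total RNA")
        ax.set_ylabel("median raw intensity (a.u.)")
        ax.legend(fontsize=7)
        return ax
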