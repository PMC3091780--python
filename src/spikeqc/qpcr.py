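"""RT-qPCR-side QC: efficiency, ΔCt quantification, dropout and precision.

Quantification follows the efficiency-corrected relative-Ct approach: each
Ct is referenced to the mean Ct of the highest-abundance calibrator (default
1e6 copies/ng) within the same assay and run (plate), removing run-level
shifts, and converted to a relative quantity ``Q = (1+E)^(-ΔCt)`` where *E*
is the assay's PCR efficiency (E = 1 means perfect per-cycle doubling).
Failed reactions carry an explicit UNDETERMINED state and are excluded from
means and fits; their rate is reported separately as the positive-reaction
fraction, the qPCR analogue of the array detection fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .microarray import LinearFit, QCError
from .panels import PanelDesign

__all__ = [
    "EfficiencyEstimate",
    "efficiency_from_dilution",
    "positive_fraction",
    "delta_ct",
    "relative_quantity",
    "qpcr_linear_fit",
    "qpcr_precision",
    "panel_fold_changes",
    "QpcrQC",
    "QpcrQCResults",
]

CT_COLUMNS = ["assay_id", "sample", "run", "replicate", "ct", "determined"]


@dataclass(frozen=True)
class EfficiencyEstimate:
    """PCR efficiency from a standard-curve (serial dilution) fit.

    ``slope`` is the fitted Ct change per log10 dilution step (ideally
    -3.3219 for perfect doubling); ``efficiency = 10^(-1/slope) - 1``.
    Estimates above 100% are allowed but flagged (``over_unity``), and
    above 120% rejected as pathological.
    """

    assay_id: str
    efficiency: float
    slope: float
    r_squared: float

    @property
    def over_unity(self) -> bool:
        return self.efficiency > 1.0


def _require_columns(cts: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in cts.columns]
    if missing:
        raise QCError(f"Ct table lacks columns {missing}")


def efficiency_from_dilution(cts: pd.DataFrame, assay_id: str | None = None) -> EfficiencyEstimate:
    """Estimate PCR efficiency from a serial-dilution Ct table.

    ``cts`` needs columns ``rel_input`` (relative template input, > 0),
    ``ct`` and ``determined``.  Mean determined Ct per dilution point is
    regressed on log10(rel_input); the slope must be negative (Ct falls as
    input rises) and at least 3 dilution points must have determined Cts.
    """
    _require_columns(cts, ["rel_input", "ct", "determined"])
    det = cts[cts["determined"].astype(bool)]
    pts = det.groupby("rel_input")["ct"].mean()
    if len(pts) < 3:
        raise QCError(f"need >= 3 dilution points with determined Ct (got {len(pts)})")
    res = stats.linregress(np.log10(pts.index.to_numpy(dtype=float)), pts.to_numpy())
    if res.slope >= 0:
        raise QCError(f"non-amplifying dilution data: slope {res.slope:.3f} >= 0")
    eff = 10.0 ** (-1.0 / res.slope) - 1.0
    if eff > 1.2:
        raise QCError(f"pathological efficiency estimate {eff:.3f} > 1.2")
    if assay_id is None:
        assay_id = str(cts["assay_id"].iloc[0]) if "assay_id" in cts.columns else "assay"
    return EfficiencyEstimate(
        assay_id=assay_id,
        efficiency=float(eff),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
    )


def positive_fraction(cts: pd.DataFrame) -> float:
    """Fraction of reactions with a determined Ct (the dropout complement)."""
    if len(cts) == 0:
        raise QCError("positive_fraction needs at least one reaction")
    return float(cts["determined"].astype(bool).mean())


def delta_ct(
    cts: pd.DataFrame,
    design: PanelDesign,
    reference_level: float = 1e6,
) -> pd.DataFrame:
    """Reference each Ct to the run's calibrator mean for the same assay.

    The reference for assay *a* in run *r* is the mean determined Ct of the
    samples where the design doses *a* at ``reference_level`` copies/ng
    within run *r*.  ΔCt = ct - reference mean; because the reference is
    taken within the run, any per-run additive Ct shift cancels exactly.
    UNDETERMINED reactions propagate (ΔCt stays missing).

    Returns a copy of ``cts`` with ``delta_ct`` added.
    """
    _require_columns(cts, CT_COLUMNS)
    ref_samples = {
        aid: [
            s for s in design.samples if design.level_of(aid, s) == reference_level
        ]
        for aid in design.standard_ids
    }
    unknown = set(cts["assay_id"]) - set(design.standard_ids)
    if unknown:
        raise QCError(f"assays absent from design: {sorted(unknown)}")
    out = cts.copy()
    out["delta_ct"] = np.nan
    for (aid, run), grp in cts.groupby(["assay_id", "run"]):
        refs = grp[
            grp["sample"].isin(ref_samples[aid]) & grp["determined"].astype(bool)
        ]["ct"]
        if refs.empty:
            raise QCError(
                f"no determined reference Ct at {reference_level:g} copies/ng "
                f"for assay {aid!r} in run {run!r}"
            )
        out.loc[grp.index, "delta_ct"] = grp["ct"] - refs.mean()
    out.loc[~out["determined"].astype(bool), "delta_ct"] = np.nan
    return out


def relative_quantity(
    delta_cts: pd.DataFrame | np.ndarray,
    efficiency: float | dict[str, float],
) -> pd.DataFrame | np.ndarray:
    """Efficiency-corrected relative quantity ``Q = (1+E)^(-ΔCt)``.

    ``Q = 1`` at the reference; for E = 1 each cycle earlier doubles Q.
    Accepts a plain ΔCt array with a scalar E, or a ΔCt frame (from
    :func:`delta_ct`) with a scalar or per-assay efficiency map, in which
    case a ``quantity`` column is added.  UNDETERMINED ΔCt yields missing Q.
    """

    def _check(e: float) -> float:
        if not 0 < e <= 1.2:
            raise QCError(f"efficiency must be in (0, 1.2] (got {e})")
        return float(e)

    if isinstance(delta_cts, pd.DataFrame):
        out = delta_cts.copy()
        if isinstance(efficiency, dict):
            e = out["assay_id"].map({k: _check(v) for k, v in efficiency.items()})
            if e.isna().any():
                missing = sorted(set(out.loc[e.isna(), "assay_id"]))
                raise QCError(f"no efficiency for assays: {missing}")
            e = e.to_numpy(dtype=float)
        else:
            e = _check(efficiency)
        out["quantity"] = (1.0 + e) ** (-out["delta_ct"].to_numpy(dtype=float))
        return out
    e = _check(float(efficiency))
    return (1.0 + e) ** (-np.asarray(delta_cts, dtype=float))


def qpcr_linear_fit(
    levels: np.ndarray | list[float], quantities: np.ndarray | list[float]
) -> LinearFit:
    """OLS of log2(mean Q per level) on log2(copies/ng); ideal slope 1.0.

    ``levels``/``quantities`` are per-observation; quantities are averaged
    per level before the log-log fit.  Missing quantities are ignored; at
    least 3 levels must remain usable.
    """
    lv = np.asarray(levels, dtype=float)
    qv = np.asarray(quantities, dtype=float)
    keep = np.isfinite(qv) & (lv > 0)
    if not keep.any():
        raise QCError("no usable (level, quantity) observations")
    means = pd.Series(qv[keep]).groupby(pd.Series(lv[keep])).mean()
    if len(means) < 3:
        raise QCError(f"need >= 3 levels with quantities (got {len(means)})")
    res = stats.linregress(np.log2(means.index.to_numpy()), np.log2(means.to_numpy()))
    lo, hi = float(means.index.min()), float(means.index.max())
    return LinearFit(float(res.slope), float(res.intercept), float(res.rvalue**2), (lo, hi), len(means))


def qpcr_precision(quantities: pd.DataFrame, design: PanelDesign) -> pd.DataFrame:
    """CV% of efficiency-corrected quantities per (assay, abundance level).

    * ``cv_pct`` — 100 * SD/mean of Q over all determined replicates.
    * ``between_run_pct`` — CV of per-run mean Q.
    * ``within_run_pct`` — CV over replicates within a run, averaged across
      runs.

    Levels with fewer than two determined replicates are reported absent
    (NaN) rather than imputed — heavy-dropout levels are covered by the
    positive-reaction fraction instead.
    """
    _require_columns(quantities, ["assay_id", "sample", "run", "quantity"])
    q = quantities.copy()
    q["level"] = [
        design.level_of(a, s) for a, s in zip(q["assay_id"], q["sample"])
    ]
    q = q[np.isfinite(q["quantity"].to_numpy(dtype=float))]
    rows = []
    for (aid, level), grp in q.groupby(["assay_id", "level"]):
        x = grp["quantity"].to_numpy(dtype=float)
        cv = _cv(x)
        run_means = grp.groupby("run")["quantity"].mean().to_numpy()
        between = _cv(run_means)
        within_vals = [
            _cv(g["quantity"].to_numpy(dtype=float)) for _, g in grp.groupby("run")
        ]
        within_vals = [w for w in within_vals if not math.isnan(w)]
        within = float(np.mean(within_vals)) if within_vals else math.nan
        rows.append(
            {
                "assay_id": aid,
                "level": level,
                "n": x.size,
                "cv_pct": cv,
                "between_run_pct": between,
                "within_run_pct": within,
            }
        )
    return pd.DataFrame(rows).sort_values(["assay_id", "level"]).reset_index(drop=True)


def _cv(x: np.ndarray) -> float:
    if x.size < 2 or x.mean() == 0:
        return math.nan
    return float(100.0 * x.std(ddof=1) / x.mean())


def panel_fold_changes(
    cts: pd.DataFrame,
    efficiency: float | dict[str, float],
    sample_A: str = "A",
    sample_B: str = "B",
) -> pd.DataFrame:
    """Per-assay fold changes between two condition panels from Ct data.

    Within each run, ``ΔCt = mean Ct(B) - mean Ct(A)`` per assay (pairwise
    comparison of panel means on the same plate) and the run's fold change
    is ``(1+E)^(-ΔCt)``.  Runs lacking determined Cts on either side are
    skipped for that assay.  Returns columns
    ``assay_id, run, log2_fc, observed_fc``.
    """
    _require_columns(cts, ["assay_id", "sample", "run", "ct", "determined"])
    det = cts[cts["determined"].astype(bool)]
    rows = []
    for (aid, run), grp in det.groupby(["assay_id", "run"]):
        ca = grp.loc[grp["sample"] == sample_A, "ct"]
        cb = grp.loc[grp["sample"] == sample_B, "ct"]
        if ca.empty or cb.empty:
            continue
        if isinstance(efficiency, dict):
            if aid not in efficiency:
                raise QCError(f"no efficiency for assay {aid!r}")
            e = float(efficiency[aid])
        else:
            e = float(efficiency)
        lfc = -(cb.mean() - ca.mean()) * math.log2(1.0 + e)
        rows.append({"assay_id": aid, "run": run, "log2_fc": lfc, "observed_fc": 2.0**lfc})
    if not rows:
        raise QCError("no run has determined Cts for both panels")
    return pd.DataFrame(rows)


class QpcrQC:
    """Platform-QC model for a spike-in RT-qPCR experiment.

    Parameters
    ----------
    cts : DataFrame
        Long-format Ct table (``assay_id, sample, run, replicate, ct,
        determined``).
    design : PanelDesign
        Dosing design of the samples measured.
    efficiency : float or mapping assay -> float
        PCR efficiencies used for the correction (estimate them separately
        with :func:`efficiency_from_dilution`).
    reference_level : float
        Calibrator abundance for ΔCt referencing (default 1e6 copies/ng).
    detection_threshold : float
        Minimum positive-reaction fraction for a level to count as detected
        when deriving the platform LOD level (default 0.5).
    """

    def __init__(
        self,
        cts: pd.DataFrame,
        design: PanelDesign,
        efficiency: float | dict[str, float] = 0.9,
        reference_level: float = 1e6,
        detection_threshold: float = 0.5,
        linear_range: tuple[float, float] | None = None,
    ) -> None:
        _require_columns(cts, CT_COLUMNS)
        self.cts = cts
        self.design = design
        self.efficiency = efficiency
        self.reference_level = float(reference_level)
        self.detection_threshold = float(detection_threshold)
        self.linear_range = linear_range

    def fit(self) -> "QpcrQCResults":
        """Run the full qPCR-side QC analysis."""
        cts = self.cts.copy()
        cts["level"] = [
            self.design.level_of(a, s) for a, s in zip(cts["assay_id"], cts["sample"])
        ]
        pos_rows = [
            {"level": float(level), "positive_fraction": positive_fraction(grp), "n": len(grp)}
            for level, grp in cts.groupby("level")
        ]
        positives = pd.DataFrame(pos_rows).sort_values("level").reset_index(drop=True)

        dct = delta_ct(self.cts, self.design, self.reference_level)
        q = relative_quantity(dct, self.efficiency)
        q["level"] = [
            self.design.level_of(a, s) for a, s in zip(q["assay_id"], q["sample"])
        ]
        if self.linear_range is not None:
            lo, hi = self.linear_range
        else:
            # default linear window: from the called LOD level upwards
            pos = positives[positives["level"] > 0]
            ok = pos[pos["positive_fraction"] >= self.detection_threshold]
            lo = float(ok["level"].min()) if not ok.empty else 0.0
            hi = math.inf
        fits: dict[str, LinearFit] = {}
        for aid, grp in q.groupby("assay_id"):
            grp = grp[(grp["level"] >= max(lo, np.nextafter(0, 1))) & (grp["level"] <= hi)]
            try:
                fits[str(aid)] = qpcr_linear_fit(grp["level"], grp["quantity"])
            except QCError:
                pass
        precision = qpcr_precision(q, self.design)
        return QpcrQCResults(
            model=self, positives=positives, quantities=q, linear_fits=fits, precision=precision
        )


@dataclass
class QpcrQCResults:
    """Fitted qPCR-side QC metrics (dropout, linearity, precision)."""

    model: QpcrQC
    positives: pd.DataFrame
    quantities: pd.DataFrame
    linear_fits: dict[str, LinearFit]
    precision: pd.DataFrame

    def lod_level(self) -> float:
        """Lowest nonzero abundance whose positive fraction reaches the threshold."""
        pos = self.positives[self.positives["level"] > 0]
        ok = pos[pos["positive_fraction"] >= self.model.detection_threshold]
        if ok.empty:
            return math.inf
        return float(ok["level"].min())

    def summary(self) -> str:
        """Human-readable QC report."""
        from statsmodels.iolib.table import SimpleTable

        lines = [
            "RT-qPCR spike-in QC",
            "=" * 52,
            f"Reactions: {len(self.model.cts)}   "
            f"LOD level (copies/ng): {self.lod_level():g}",
            "",
            str(
                SimpleTable(
                    [
                        [f"{lv:g}", f"{fr:.2f}", str(n)]
                        for lv, fr, n in self.positives.itertuples(index=False)
                    ],
                    headers=["copies/ng", "positive", "n"],
                    title="Positive-reaction fractions",
                )
            ),
            "",
            str(
                SimpleTable(
                    [
                        [a, f"{f.slope:.4f}", f"{f.r_squared:.4f}",
                         f"{f.range_used[0]:g}-{f.range_used[1]:g}"]
                        for a, f in sorted(self.linear_fits.items())
                    ],
                    headers=["assay", "slope", "R^2", "range"],
                    title="Linear fits (log2 mean Q vs log2 copies/ng)",
                )
            ),
        ]
        return "\n".join(lines)
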