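"""Fold-change accuracy and DEG classification against spike-in ground truth.

Fold changes between the "normal" (A) and "disease" (B) panels are computed
per microarray feature from pairwise array comparisons — by default arrays
are paired within each run by matching labelling index, giving 2 pairs x 3
runs = 6 comparisons under the canonical layout — and combined as the mean
of log2 ratios (geometric mean on the linear scale).  Features are then
classified with a volcano rule (|mean log2 FC| >= log2(cutoff) and Welch
two-sample p < 0.05, no multiple-testing correction) and scored against the
known spike ratios as a confusion matrix; a feature's truth label is DEG iff
its standard's expected fold change differs from 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .microarray import QCError

__all__ = [
    "ConfusionMatrix",
    "pairwise_fold_changes",
    "fc_accuracy",
    "feature_pvalues",
    "welch_pvalues",
    "volcano_classify",
    "confusion_vs_truth",
    "platform_concordance",
    "PanelComparison",
    "PanelComparisonResults",
]


def default_pairing(norm_A: pd.DataFrame, norm_B: pd.DataFrame) -> list[tuple[str, str]]:
    """Pair panel-A and panel-B arrays within each run by labelling order."""
    def slots(df: pd.DataFrame) -> dict:
        arr = df.drop_duplicates("array_id").sort_values(["run", "array_id"])
        out: dict = {}
        for run, grp in arr.groupby("run"):
            out[run] = list(grp["array_id"])
        return out

    a, b = slots(norm_A), slots(norm_B)
    if set(a) != set(b):
        raise QCError("panels A and B do not share runs; supply an explicit pairing")
    pairs = []
    for run in sorted(a):
        if len(a[run]) != len(b[run]):
            raise QCError(f"run {run!r}: unequal array counts between panels")
        pairs += list(zip(a[run], b[run]))
    return pairs


def pairwise_fold_changes(
    norm_A: pd.DataFrame,
    norm_B: pd.DataFrame,
    pairing: list[tuple[str, str]] | None = None,
    value: str = "log2_norm",
) -> pd.DataFrame:
    """Per-feature log2 fold changes (B vs A) over paired arrays.

    Each pair contributes ``log2_fc = value_B - value_A`` per feature.
    Under the default pairing, arrays are matched within runs; an explicit
    ``pairing`` list of ``(array_A, array_B)`` supports other designs, but
    cross-run pairs are rejected when run annotations are present.

    Returns columns ``feature_id, standard_id, pair, log2_fc, observed_fc``.
    """
    if pairing is None:
        pairing = default_pairing(norm_A, norm_B)
    else:
        runs_a = norm_A.drop_duplicates("array_id").set_index("array_id").get("run")
        runs_b = norm_B.drop_duplicates("array_id").set_index("array_id").get("run")
        if runs_a is not None and runs_b is not None:
            for pa, pb in pairing:
                if runs_a.get(pa) != runs_b.get(pb):
                    raise QCError(f"pair ({pa}, {pb}) crosses runs")
    wa = norm_A.pivot(index="feature_id", columns="array_id", values=value)
    wb = norm_B.pivot(index="feature_id", columns="array_id", values=value)
    if not wa.index.equals(wb.index):
        wb = wb.reindex(wa.index)
        if wb.isna().any().any():
            raise QCError("panels A and B do not share the feature set")
    std_map = (
        norm_A.drop_duplicates("feature_id").set_index("feature_id")["standard_id"]
        if "standard_id" in norm_A.columns
        else None
    )
    frames = []
    for k, (pa, pb) in enumerate(pairing, start=1):
        lfc = wb[pb] - wa[pa]
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": wa.index,
                    "pair": f"pair{k}",
                    "log2_fc": lfc.to_numpy(dtype=float),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if std_map is not None:
        out.insert(1, "standard_id", out["feature_id"].map(std_map))
    out["observed_fc"] = 2.0 ** out["log2_fc"]
    return out


def fc_accuracy(
    observed: pd.DataFrame,
    expected_fc: dict[str, float],
    tolerance: float = 0.10,
) -> pd.DataFrame:
    """Fraction of per-feature fold changes within a relative tolerance of truth.

    A feature's combined observed FC is the geometric mean over comparisons;
    it counts as accurate when ``|observed/expected - 1| <= tolerance``
    (boundary inclusive).  Returns per-standard columns
    ``standard_id, n_features, fraction_within``.
    """
    if "standard_id" not in observed.columns:
        raise QCError("fold-change table lacks standard_id annotations")
    missing = sorted(set(observed["standard_id"]) - set(expected_fc))
    if missing:
        raise QCError(f"expected fold change missing for standards: {missing}")
    per_feature = (
        observed.groupby(["standard_id", "feature_id"])["log2_fc"].mean().reset_index()
    )
    per_feature["observed_fc"] = 2.0 ** per_feature["log2_fc"]
    rows = []
    for sid, grp in per_feature.groupby("standard_id"):
        exp = expected_fc[sid]
        ok = np.abs(grp["observed_fc"].to_numpy() / exp - 1.0) <= tolerance + 1e-12
        rows.append(
            {"standard_id": sid, "n_features": len(grp), "fraction_within": float(ok.mean())}
        )
    return pd.DataFrame(rows).sort_values("standard_id").reset_index(drop=True)


def welch_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Welch t-test p-values, one per matrix row.

    ``a``/``b`` are features x replicates matrices.  Degenerate features
    (zero variance in both groups) get p = 1 when the group means are equal
    and p -> 0 when they differ — the limits of the test statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise QCError("need >= 2 replicates per group for a t-test")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    p = np.ones_like(ma)
    zero = se2 == 0
    p[zero & (ma != mb)] = 0.0
    ok = ~zero
    t = (ma[ok] - mb[ok]) / np.sqrt(se2[ok])
    df = se2[ok] ** 2 / (
        (va[ok] / na) ** 2 / (na - 1) + (vb[ok] / nb) ** 2 / (nb - 1)
    )
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    return p


def feature_pvalues(group_A: pd.DataFrame, group_B: pd.DataFrame) -> pd.Series:
    """Welch p-value per feature from two features-x-arrays log2 value frames."""
    if not group_A.index.equals(group_B.index):
        group_B = group_B.reindex(group_A.index)
    return pd.Series(
        welch_pvalues(group_A.to_numpy(), group_B.to_numpy()),
        index=group_A.index,
        name="p_value",
    )


def volcano_classify(
    mean_log2_fc: pd.Series | np.ndarray,
    p_values: pd.Series | np.ndarray,
    fc_cutoff: float,
    p_cutoff: float = 0.05,
) -> pd.Series | np.ndarray:
    """Volcano rule: DEG iff |mean log2 FC| >= log2(fc_cutoff) and p < p_cutoff.

    The fold-change boundary is inclusive (a feature exactly at the cutoff is
    called); the p boundary is exclusive (p exactly at the cutoff is not).
    """
    if fc_cutoff < 1:
        raise QCError(f"fc_cutoff must be >= 1 (got {fc_cutoff})")
    lfc = np.asarray(mean_log2_fc, dtype=float)
    p = np.asarray(p_values, dtype=float)
    call = (np.abs(lfc) >= math.log2(fc_cutoff)) & (p < p_cutoff)
    if isinstance(mean_log2_fc, pd.Series):
        return pd.Series(call, index=mean_log2_fc.index, name="deg")
    return call


@dataclass
class ConfusionMatrix:
    """DEG-call counts against ground truth, with per-standard error breakdown."""

    tp: int
    fp: int
    tn: int
    fn: int
    fp_by_standard: dict[str, int] = field(default_factory=dict)
    fn_by_standard: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else math.nan


def confusion_vs_truth(
    calls: pd.Series,
    standards: pd.Series,
    expected_fc: dict[str, float],
) -> ConfusionMatrix:
    """Score per-feature DEG calls against the spike ratios.

    ``calls`` is a boolean per-feature series, ``standards`` maps each
    feature to its standard, and the truth label is DEG iff the standard's
    expected fold change differs from 1.0.
    """
    missing = sorted(set(standards) - set(expected_fc))
    if missing:
        raise QCError(f"truth missing for standards: {missing}")
    truth = standards.map(lambda s: expected_fc[s] != 1.0)
    call = calls.astype(bool)
    tp = int((call & truth).sum())
    fp = int((call & ~truth).sum())
    tn = int((~call & ~truth).sum())
    fn = int((~call & truth).sum())
    fp_by = (
        standards[call & ~truth].value_counts().to_dict() if fp else {}
    )
    fn_by = (
        standards[~call & truth].value_counts().to_dict() if fn else {}
    )
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn, fp_by_standard=fp_by, fn_by_standard=fn_by)


def platform_concordance(
    fc_a: dict[str, float] | pd.Series, fc_b: dict[str, float] | pd.Series
) -> tuple[float, float]:
    """Cross-platform agreement of per-standard fold changes.

    Returns ``(slope, pearson_r)`` of an OLS fit of platform-B on platform-A
    log2 fold changes over the shared standards (>= 3 required).  Perfect
    agreement gives slope 1 and R 1.
    """
    sa, sb = pd.Series(fc_a, dtype=float), pd.Series(fc_b, dtype=float)
    shared = sorted(set(sa.index) & set(sb.index))
    if len(shared) < 3:
        raise QCError("need >= 3 shared standards for concordance")
    x = np.log2(sa[shared].to_numpy())
    y = np.log2(sb[shared].to_numpy())
    if x.std() == 0 or y.std() == 0:
        raise QCError("zero variance in fold changes; concordance undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue)


class PanelComparison:
    """Differential-expression benchmark between two condition panels.

    Built from normalised feature-level tables for the "normal" (A) and
    "disease" (B) panels plus the known spike ratios; ``fit()`` estimates
    per-feature fold changes, their accuracy, volcano DEG calls at each
    cutoff, and the resulting confusion matrices.
    """

    def __init__(
        self,
        norm_A: pd.DataFrame,
        norm_B: pd.DataFrame,
        expected_fc: dict[str, float],
        pairing: list[tuple[str, str]] | None = None,
        fc_cutoffs: tuple[float, ...] = (3.0, 2.0, 1.5, 1.1),
        p_cutoff: float = 0.05,
        tolerance: float = 0.10,
    ) -> None:
        self.norm_A = norm_A
        self.norm_B = norm_B
        self.expected_fc = dict(expected_fc)
        self.pairing = pairing
        self.fc_cutoffs = tuple(fc_cutoffs)
        self.p_cutoff = float(p_cutoff)
        self.tolerance = float(tolerance)

    def fit(self) -> "PanelComparisonResults":
        fc = pairwise_fold_changes(self.norm_A, self.norm_B, self.pairing)
        accuracy = fc_accuracy(fc, self.expected_fc, self.tolerance)
        mean_lfc = fc.groupby("feature_id")["log2_fc"].mean()
        wa = self.norm_A.pivot(index="feature_id", columns="array_id", values="log2_norm")
        wb = self.norm_B.pivot(index="feature_id", columns="array_id", values="log2_norm")
        pvals = feature_pvalues(wa, wb).reindex(mean_lfc.index)
        standards = (
            self.norm_A.drop_duplicates("feature_id")
            .set_index("feature_id")["standard_id"]
            .reindex(mean_lfc.index)
        )
        calls = {
            c: volcano_classify(mean_lfc, pvals, c, self.p_cutoff) for c in self.fc_cutoffs
        }
        confusions = {
            c: confusion_vs_truth(calls[c], standards, self.expected_fc)
            for c in self.fc_cutoffs
        }
        return PanelComparisonResults(
            model=self,
            fold_changes=fc,
            accuracy=accuracy,
            mean_log2_fc=mean_lfc,
            p_values=pvals,
            standards=standards,
            calls=calls,
            confusions=confusions,
        )


@dataclass
class PanelComparisonResults:
    """Fold-change estimates, volcano calls and truth-scored confusion."""

    model: PanelComparison
    fold_changes: pd.DataFrame
    accuracy: pd.DataFrame
    mean_log2_fc: pd.Series
    p_values: pd.Series
    standards: pd.Series
    calls: dict[float, pd.Series]
    confusions: dict[float, ConfusionMatrix]

    def per_standard_fc(self) -> pd.Series:
        """Geometric-mean observed fold change per standard (linear scale)."""
        lfc = self.fold_changes.groupby("standard_id")["log2_fc"].mean()
        return (2.0 ** lfc).rename("observed_fc")

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        exp = self.model.expected_fc
        obs = self.per_standard_fc()
        rows = [
            [s, f"{exp[s]:.2f}", f"{obs[s]:.3f}",
             f"{self.accuracy.set_index('standard_id').at[s, 'fraction_within']:.2f}"]
            for s in sorted(exp)
        ]
        conf_rows = [
            [f"{c:g}", str(m.tp), str(m.fp), str(m.tn), str(m.fn)]
            for c, m in sorted(self.confusions.items(), reverse=True)
        ]
        return "\n".join(
            [
                "Condition-panel fold-change benchmark",
                "=" * 52,
                str(
                    SimpleTable(
                        rows,
                        headers=["standard", "expected", "observed", "frac within tol"],
                        title=f"Fold changes (tolerance {self.model.tolerance:.0%})",
                    )
                ),
                "",
                str(
                    SimpleTable(
                        conf_rows,
                        headers=["fc cutoff", "TP", "FP", "TN", "FN"],
                        title=f"Volcano classification (p < {self.model.p_cutoff})",
                    )
                ),
            ]
        )

    def plot_volcano(self, fc_cutoff: float = 2.0, ax=None):
        """Volcano plot of mean log2 FC vs -log10 p with the cutoff lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = np.maximum(self.p_values.to_numpy(dtype=float), 1e-300)
        deg = self.calls[fc_cutoff].to_numpy()
        ax.scatter(self.mean_log2_fc[~deg], -np.log10(p[~deg]), s=8, c="grey", label="non-DEG")
        ax.scatter(self.mean_log2_fc[deg], -np.log10(p[deg]), s=8, c="crimson", label="DEG")
        for s in (-1, 1):
            ax.axvline(s * math.log2(fc_cutoff), ls="--", c="k", lw=0.8)
        ax.axhline(-math.log10(self.model.p_cutoff), ls="--", c="k", lw=0.8)
        ax.set_xlabel("mean log2 fold change (B/A)")
        ax.set_ylabel("-log10 p")
        ax.legend()
        return ax
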