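"""Calibration of software quality scores against empirical accuracy.

Different imputation tools report quality scores (Rsq_soft) on different
effective scales: at the same score, the accuracy actually achieved
(Rsq_emp) can differ markedly between tools.  Binning variants by
Rsq_soft and summarising the Rsq_emp distribution per bin yields a
calibration curve from which a *software-equivalent threshold* can be
read off: the lowest score cutoff above which every (well-populated) bin
achieves a target mean Rsq_emp.  Harmonising tools at their equivalent
thresholds — rather than at one nominal score — keeps a common empirical
accuracy floor across studies, e.g. for meta-GWAS.

Threshold filtering is then audited with a confusion account: false
positives are variants passing the score threshold whose Rsq_emp misses
the target (reported as % of passing variants); false negatives are
variants failing the score threshold that nevertheless achieve the target
(% of non-passing variants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _clean_pairs(stats: pd.DataFrame, value: str) -> tuple[np.ndarray, np.ndarray, int]:
    soft = stats["rsq_soft"].to_numpy(dtype=float)
    emp = stats[value].to_numpy(dtype=float)
    ok = ~np.isnan(soft) & ~np.isnan(emp)
    return soft[ok], emp[ok], int((~ok).sum())


@dataclass
class CalibrationCurve:
    """Binned Rsq_soft -> Rsq_emp summary.

    ``table`` has one row per score bin with boxplot statistics of the
    per-bin Rsq_emp distribution (median, quartiles, whiskers at the most
    extreme points within 1.5 IQR of the box) plus the per-bin mean.
    """

    table: pd.DataFrame
    bin_width: float
    n_total: int  # variants with both values present
    n_excluded: int  # variants dropped for a missing value
    value: str = "rsq_emp_ds"

    @property
    def bin_edges(self) -> np.ndarray:
        return np.append(self.table["bin_lo"].to_numpy(), self.table["bin_hi"].iloc[-1])


def build_curve(
    stats: pd.DataFrame, bin_width: float = 0.05, value: str = "rsq_emp_ds"
) -> CalibrationCurve:
    """Bin variants by Rsq_soft and summarise Rsq_emp per bin.

    Bins are ``[k*w, (k+1)*w)`` over [0, 1]; a score of exactly 1 falls in
    the last bin, and a ``bin_width`` that does not divide 1 truncates the
    last bin.  Variants with a non-estimable Rsq_emp are excluded and
    counted.
    """
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must be in (0, 1]")
    soft, emp, n_excluded = _clean_pairs(stats, value)
    if soft.size == 0:
        raise ValueError("no variants with both rsq_soft and rsq_emp present")

    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0 - 1e-12:
        edges = np.append(edges, 1.0)
    edges[-1] = 1.0
    n_bins = len(edges) - 1
    idx = np.clip(np.searchsorted(edges, soft, side="right") - 1, 0, n_bins - 1)

    rows = []
    for b in range(n_bins):
        v = emp[idx == b]
        s = soft[idx == b]
        if v.size:
            q25, med, q75 = np.percentile(v, [25, 50, 75])
            iqr = q75 - q25
            lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
            inside = v[(v >= lo_fence) & (v <= hi_fence)]
            rows.append(
                {
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "n": int(v.size),
                    "mean_rsq_emp": float(v.mean()),
                    "mean_rsq_soft": float(s.mean()),
                    "median": float(med),
                    "q25": float(q25),
                    "q75": float(q75),
                    "whisker_lo": float(inside.min()),
                    "whisker_hi": float(inside.max()),
                }
            )
        else:
            rows.append(
                {
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "n": 0,
                    "mean_rsq_emp": np.nan,
                    "mean_rsq_soft": np.nan,
                    "median": np.nan,
                    "q25": np.nan,
                    "q75": np.nan,
                    "whisker_lo": np.nan,
                    "whisker_hi": np.nan,
                }
            )
    return CalibrationCurve(
        table=pd.DataFrame(rows),
        bin_width=bin_width,
        n_total=int(soft.size),
        n_excluded=n_excluded,
        value=value,
    )


@dataclass
class ThresholdResult:
    """Equivalent-threshold determination from a calibration curve."""

    threshold: float | None  # lowest bin edge whose upper tail all meets target
    cumulative_threshold: float | None  # alternative: mean over all variants >= t meets target
    target: float
    min_bin_n: int
    n_eligible_bins: int
    diagnostics: str | None = None


def equivalent_threshold(
    curve: CalibrationCurve, target_rsq_emp: float = 0.8, min_bin_n: int = 50
) -> ThresholdResult:
    """Read the software-equivalent score threshold off a calibration curve.

    Scanning bins from the top of the score range downward, the threshold
    is the smallest bin lower edge such that every eligible bin (n >=
    ``min_bin_n``) at or above it has mean Rsq_emp >= ``target_rsq_emp``.
    Sparse bins are ignored by the scan: with few variants a bin mean is
    too noisy to anchor a filtering rule.

    A second, "cumulative" reading is reported alongside: the smallest
    bin edge t such that the mean Rsq_emp over *all* variants with score
    >= t meets the target.
    """
    tab = curve.table
    eligible = tab[tab["n"] >= max(min_bin_n, 1)]
    if eligible.empty:
        raise ValueError(f"no bins with n >= {min_bin_n}; cannot determine a threshold")

    threshold = None
    for _, row in eligible.sort_values("bin_lo", ascending=False).iterrows():
        if row["mean_rsq_emp"] >= target_rsq_emp:
            threshold = float(row["bin_lo"])
        else:
            break

    # cumulative alternative over all bins (weighted by n)
    t_all = tab[tab["n"] > 0].sort_values("bin_lo", ascending=False)
    csum = (t_all["mean_rsq_emp"] * t_all["n"]).cumsum()
    cn = t_all["n"].cumsum()
    cmean = csum / cn
    ok = t_all["bin_lo"][cmean >= target_rsq_emp]
    cumulative = float(ok.min()) if len(ok) else None

    diag = None
    if threshold is None:
        top = eligible.sort_values("bin_lo", ascending=False).iloc[0]
        diag = (
            f"highest eligible bin [{top['bin_lo']:.3g}, {top['bin_hi']:.3g}) has mean "
            f"Rsq_emp {top['mean_rsq_emp']:.3f} < target {target_rsq_emp}"
        )
    return ThresholdResult(
        threshold=threshold,
        cumulative_threshold=cumulative,
        target=target_rsq_emp,
        min_bin_n=min_bin_n,
        n_eligible_bins=int(len(eligible)),
    ) if diag is None else ThresholdResult(
        threshold=None,
        cumulative_threshold=cumulative,
        target=target_rsq_emp,
        min_bin_n=min_bin_n,
        n_eligible_bins=int(len(eligible)),
        diagnostics=diag,
    )


def threshold_confusion(
    stats: pd.DataFrame,
    threshold: float,
    target_rsq_emp: float = 0.8,
    value: str = "rsq_emp_ds",
    group: bool = False,
    common_split: float = 0.05,
) -> pd.DataFrame:
    """TP/FP/FN accounting of score-threshold filtering.

    A variant *passes* when rsq_soft >= threshold and *achieves* when
    Rsq_emp >= target (both inclusive).  TP = pass & achieve, FP = pass &
    not achieve (% of passing), FN = not pass & achieve (% of not
    passing).  With ``group=True``, rows are added per variant class
    (SNP/INDEL) crossed with the MAF split (common: MAF > ``common_split``).
    Undefined percentages (zero denominator) are NaN.
    """
    soft = stats["rsq_soft"].to_numpy(dtype=float)
    emp = stats[value].to_numpy(dtype=float)
    ok = ~np.isnan(soft) & ~np.isnan(emp)
    if not ok.any():
        raise ValueError("no variants with both rsq_soft and rsq_emp present")

    def account(label: str, mask: np.ndarray) -> dict:
        s, e = soft[mask & ok], emp[mask & ok]
        n = s.size
        passing = s >= threshold
        achieve = e >= target_rsq_emp
        n_pass = int(passing.sum())
        n_fail = n - n_pass
        n_tp = int((passing & achieve).sum())
        n_fp = n_pass - n_tp
        n_fn = int((~passing & achieve).sum())
        return {
            "group": label,
            "threshold": threshold,
            "target": target_rsq_emp,
            "n_variants": n,
            "n_pass": n_pass,
            "pct_pass": 100.0 * n_pass / n if n else np.nan,
            "n_tp": n_tp,
            "pct_tp_of_pass": 100.0 * n_tp / n_pass if n_pass else np.nan,
            "n_fp": n_fp,
            "pct_fp_of_pass": 100.0 * n_fp / n_pass if n_pass else np.nan,
            "n_fn": n_fn,
            "pct_fn_of_notpass": 100.0 * n_fn / n_fail if n_fail else np.nan,
        }

    everything = np.ones(len(stats), dtype=bool)
    rows = [account("ALL", everything)]
    if group:
        vclass = stats["vclass"].to_numpy(dtype=object)
        maf = stats["maf_ref"].to_numpy(dtype=float)
        for vc in ("SNP", "INDEL"):
            for glabel, gmask in (
                ("common", maf > common_split),
                ("less_common", maf <= common_split),
            ):
                rows.append(account(f"{vc}/{glabel}", (vclass == vc) & gmask))
    return pd.DataFrame(rows)


def before_after_filter_summary(
    stats: pd.DataFrame,
    threshold: float,
    group_by: str = "maf_bins",
    value: str = "rsq_emp_ds",
    window_bp: int = 1_000_000,
    maf_edges=None,
) -> pd.DataFrame:
    """Group means of Rsq_emp before and after score-threshold filtering.

    ``group_by`` is ``"maf_bins"`` or ``"windows"``; grouping reuses the
    summaries from :mod:`imputeqc.accuracy`.  Fully filtered groups appear
    with n=0 and no mean.
    """
    from .accuracy import DEFAULT_MAF_EDGES, maf_summary, window_summary

    passing = stats[stats["rsq_soft"] >= threshold]
    if group_by == "maf_bins":
        edges = DEFAULT_MAF_EDGES if maf_edges is None else maf_edges
        before, _ = maf_summary(stats, edges, value=value)
        after, _ = maf_summary(passing, edges, value=value) if len(passing) else (
            before.assign(n_variants=0, **{f"mean_{value}": np.nan}),
            None,
        )
        on = ["maf_lo", "maf_hi"]
    elif group_by == "windows":
        before = window_summary(stats, window_bp, value=value)
        after = window_summary(passing, window_bp, value=value)
        on = ["chrom", "window_start", "window_end"]
    else:
        raise ValueError(f"group_by must be 'maf_bins' or 'windows', got {group_by!r}")

    merged = before.merge(after, on=on, how="left", suffixes=("_before", "_after"))
    merged["n_variants_after"] = merged["n_variants_after"].fillna(0).astype(int)
    return merged.drop(
        columns=[c for c in merged.columns if c.startswith("sd_")], errors="ignore"
    )
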