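"""Per-variant empirical imputation accuracy statistics.

Empirical accuracy r is the Pearson correlation, across target samples,
between true alternate-allele counts (0/1/2) and imputed genotypes —
either best-guess GT (0/1/2) or dosage DS (continuous in [0, 2]).  Its
square Rsq_emp is the quantity the software scores try to estimate.

In GT mode r is estimable only when the variant segregates in both the
truth and the imputed best-guess calls (otherwise one vector has zero
variance); in DS mode the truth must segregate and the dosages must not be
constant.  Allele-level error rates decompose imputation errors into false
positives (reference alleles imputed as alternate) and false negatives
(alternate alleles imputed as reference):

    fp_alleles = sum_i max(gt_i - truth_i, 0)
    fn_alleles = sum_i max(truth_i - gt_i, 0)
    FPR = 100 * fp_alleles / sum_i (2 - truth_i)
    FNR = 100 * fn_alleles / sum_i truth_i
    AER = 100 * (fp_alleles + fn_alleles) / (2 * n_pairs)

so that FP + FN allele counts always sum to the total number of wrongly
imputed alleles.  Rates with a zero denominator are undefined (NaN with a
reason), never silently 0.  Missing genotypes on either side drop the
(variant, sample) pair from every statistic of that variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcf_io import MISSING, ImputedCallSet, TruthMatrix

logger = logging.getLogger(__name__)

#: Default MAF bin edges; includes the 0.025 and 0.05 cut points used for
#: the common / less-common split.
DEFAULT_MAF_EDGES = (0.0, 0.005, 0.01, 0.025, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class RResult:
    """Outcome of a per-variant correlation: value or reason it is absent."""

    r: float  # NaN when not estimable
    estimable: bool
    reason: str | None = None  # e.g. "zero_truth_variance"

    @property
    def rsq(self) -> float:
        return self.r * self.r if self.estimable else float("nan")


def _pairwise(truth_vec, imp_vec, missing_imp_nan: bool):
    t = np.asarray(truth_vec, dtype=np.float64)
    x = np.asarray(imp_vec, dtype=np.float64)
    if t.shape != x.shape:
        raise ValueError("truth and imputed vectors differ in length")
    mask = t != MISSING
    mask &= ~np.isnan(x) if missing_imp_nan else (x != MISSING)
    return t[mask], x[mask]


def empirical_r(truth_vec, imp_vec, mode: str = "gt") -> RResult:
    """Pearson correlation between truth (0/1/2) and imputed genotypes.

    ``mode="gt"`` treats the imputed vector as best-guess calls (integer,
    :data:`~imputeqc.vcf_io.MISSING` allowed); ``mode="ds"`` as dosages
    (NaN marks missing).  Non-estimable cases return the reason: fewer
    than 2 complete pairs, zero truth variance, or (GT mode) zero imputed
    variance.
    """
    if mode not in ("gt", "ds"):
        raise ValueError(f"mode must be 'gt' or 'ds', got {mode!r}")
    t, x = _pairwise(truth_vec, imp_vec, missing_imp_nan=(mode == "ds"))
    if t.size < 2:
        return RResult(float("nan"), False, "fewer_than_2_pairs")
    tc = t - t.mean()
    xc = x - x.mean()
    st, sx = float(tc @ tc), float(xc @ xc)
    if st == 0.0:
        return RResult(float("nan"), False, "zero_truth_variance")
    if sx == 0.0:
        return RResult(float("nan"), False, f"zero_imputed_variance_{mode}")
    return RResult(float(tc @ xc) / np.sqrt(st * sx), True)


@dataclass
class AllelicErrorRates:
    """Allele-level error decomposition for one variant."""

    fp_alleles: int
    fn_alleles: int
    fpr: float  # % of reference alleles imputed as alternate; NaN if no ref alleles
    fnr: float  # % of alternate alleles imputed as reference; NaN if no alt alleles
    aer: float  # % of all alleles wrongly imputed
    n_ref_alleles: int
    n_alt_alleles: int
    n_pairs: int


def allelic_error_rates(truth_vec, gt_vec) -> AllelicErrorRates:
    """FPR / FNR / AER for one variant from complete (truth, GT) pairs."""
    t, x = _pairwise(truth_vec, gt_vec, missing_imp_nan=False)
    n = t.size
    if n == 0:
        raise ValueError("no complete (truth, imputed) pairs")
    diff = x - t
    fp = int(np.maximum(diff, 0).sum())
    fn = int(np.maximum(-diff, 0).sum())
    n_alt = int(t.sum())
    n_ref = 2 * n - n_alt
    fpr = 100.0 * fp / n_ref if n_ref > 0 else float("nan")
    fnr = 100.0 * fn / n_alt if n_alt > 0 else float("nan")
    aer = 100.0 * (fp + fn) / (2.0 * n)
    return AllelicErrorRates(fp, fn, fpr, fnr, aer, n_ref, n_alt, n)


def concordance(truth_vec, gt_vec) -> float:
    """Percentage of complete pairs where the best-guess call equals truth."""
    t, x = _pairwise(truth_vec, gt_vec, missing_imp_nan=False)
    if t.size == 0:
        raise ValueError("no complete (truth, imputed) pairs")
    return 100.0 * float((t == x).mean())


def _segregating(counts_sum: np.ndarray, n_called: np.ndarray) -> np.ndarray:
    """At least one copy of each allele among the called genotypes."""
    return (counts_sum >= 1) & (counts_sum <= 2 * n_called - 1) & (n_called >= 1)


def compute_stats(truth: TruthMatrix, imputed: ImputedCallSet) -> pd.DataFrame:
    """Per-variant statistics table for an aligned truth/imputed pair.

    Vectorised over variants; missing cells are removed pairwise per
    variant.  Columns follow :data:`imputeqc.vcf_io.STATS_COLUMNS`.
    """
    if truth.samples != imputed.samples:
        raise ValueError("call sets are not sample-aligned; run match_variants first")
    if len(truth.keys) != len(imputed.keys):
        raise ValueError("call sets are not variant-aligned; run match_variants first")

    g = truth.g.astype(np.float64)
    gt = imputed.gt.astype(np.float64)
    ds = imputed.ds.astype(np.float64)

    t_ok = truth.g != MISSING
    gt_ok = t_ok & (imputed.gt != MISSING)
    ds_ok = t_ok & ~np.isnan(ds)

    def moments(x, y, mask):
        n = mask.sum(axis=1).astype(np.float64)
        sx = np.where(mask, x, 0.0).sum(axis=1)
        sy = np.where(mask, y, 0.0).sum(axis=1)
        sxx = np.where(mask, x * x, 0.0).sum(axis=1)
        syy = np.where(mask, y * y, 0.0).sum(axis=1)
        sxy = np.where(mask, x * y, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vx = sxx - sx * sx / n
            vy = syy - sy * sy / n
            cov = sxy - sx * sy / n
            r = cov / np.sqrt(vx * vy)
        return n, sx, vx, vy, r

    n_gt, s_t_gt, v_t_gt, v_i_gt, r_gt = moments(g, gt, gt_ok)
    n_ds, _, v_t_ds, v_i_ds, r_ds = moments(g, ds, ds_ok)

    tol = 1e-12
    est_gt = (n_gt >= 2) & (v_t_gt > tol) & (v_i_gt > tol)
    est_ds = (n_ds >= 2) & (v_t_ds > tol) & (v_i_ds > tol)
    r_gt = np.where(est_gt, r_gt, np.nan)
    r_ds = np.where(est_ds, r_ds, np.nan)

    # allele-level errors on GT-complete pairs
    diff = np.where(gt_ok, gt - g, 0.0)
    fp = np.maximum(diff, 0.0).sum(axis=1)
    fn = np.maximum(-diff, 0.0).sum(axis=1)
    n_alt = np.where(gt_ok, g, 0.0).sum(axis=1)
    n_ref = 2.0 * n_gt - n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        fpr = np.where(n_ref > 0, 100.0 * fp / n_ref, np.nan)
        fnr = np.where(n_alt > 0, 100.0 * fn / n_alt, np.nan)
        aer = np.where(n_gt > 0, 100.0 * (fp + fn) / (2.0 * n_gt), np.nan)
        conc = np.where(
            n_gt > 0, 100.0 * np.where(gt_ok, g == gt, False).sum(axis=1) / n_gt, np.nan
        )

    imp_sum = np.where(gt_ok, gt, 0.0).sum(axis=1)
    seg_truth = _segregating(n_alt, n_gt)
    seg_imp = _segregating(imp_sum, n_gt)

    return pd.DataFrame(
        {
            "chrom": [k.chrom for k in truth.keys],
            "pos": [k.pos for k in truth.keys],
            "ref": [k.ref for k in truth.keys],
            "alt": [k.alt for k in truth.keys],
            "vclass": [k.vclass for k in truth.keys],
            "region": truth.region,
            "maf_ref": truth.maf_ref,
            "rsq_soft": imputed.rsq_soft,
            "n_pairs": n_gt.astype(int),
            "r_gt": r_gt,
            "r_ds": r_ds,
            "rsq_emp_gt": r_gt * r_gt,
            "rsq_emp_ds": r_ds * r_ds,
            "concordance": conc,
            "fpr": fpr,
            "fnr": fnr,
            "aer": aer,
            "estimable_gt": est_gt,
            "estimable_ds": est_ds,
            "seg_truth": seg_truth,
            "seg_imp_gt": seg_imp,
        }
    )


def common_estimable_set(stats_tables: list[pd.DataFrame]) -> set[tuple]:
    """Variants with estimable GT-mode r in every table.

    Cross-software comparisons are restricted to this overlap so that a
    tool's tendency to impute rare variants as monomorphic does not bias
    its average accuracy upward.
    """
    if not stats_tables:
        raise ValueError("at least one stats table required")
    from .vcf_io import stats_keys

    sets = []
    for df in stats_tables:
        est = df["estimable_gt"].to_numpy(dtype=bool)
        keys = stats_keys(df)
        sets.append({k for k, ok in zip(keys, est) if ok})
    out = set.intersection(*sets)
    if not out:
        logger.warning("common estimable set is empty across %d tables", len(sets))
    return out


@dataclass
class SegregationErrors:
    """Segregation agreement between truth and imputed best-guess calls."""

    pct_seg_as_mono: float  # % of truth-segregating variants imputed monomorphic (NaN if none segregate)
    pct_mono_as_seg: float  # % of truth-monomorphic variants imputed segregating (NaN if none monomorphic)
    n_seg_truth: int
    n_seg_as_mono: int
    n_mono_truth: int
    n_mono_as_seg: int
    reason: str | None = None


def segregation_errors(truth: TruthMatrix, imputed_gt: np.ndarray) -> SegregationErrors:
    """Rates of segregating variants imputed as monomorphic and vice versa."""
    if imputed_gt.shape != truth.g.shape:
        raise ValueError("imputed GT matrix shape does not match truth")
    mask = (truth.g != MISSING) & (imputed_gt != MISSING)
    n_called = mask.sum(axis=1)
    t_sum = np.where(mask, truth.g, 0).sum(axis=1)
    i_sum = np.where(mask, imputed_gt, 0).sum(axis=1)
    seg_t = _segregating(t_sum, n_called)
    seg_i = _segregating(i_sum, n_called)

    n_seg = int(seg_t.sum())
    n_mono = int((~seg_t & (n_called > 0)).sum())
    n_seg_as_mono = int((seg_t & ~seg_i).sum())
    n_mono_as_seg = int((~seg_t & (n_called > 0) & seg_i).sum())
    reason = None
    if n_seg == 0:
        reason = "no_segregating_truth_variants"
    return SegregationErrors(
        pct_seg_as_mono=100.0 * n_seg_as_mono / n_seg if n_seg else float("nan"),
        pct_mono_as_seg=100.0 * n_mono_as_seg / n_mono if n_mono else float("nan"),
        n_seg_truth=n_seg,
        n_seg_as_mono=n_seg_as_mono,
        n_mono_truth=n_mono,
        n_mono_as_seg=n_mono_as_seg,
        reason=reason,
    )


def window_summary(
    stats: pd.DataFrame, window_bp: int = 1_000_000, value: str = "rsq_emp_ds"
) -> pd.DataFrame:
    """Mean accuracy in adjacent genomic windows, per chromosome.

    Windows are half-open ``[k*w, (k+1)*w)`` multiples of the window size
    starting at 0; every window up to the last occupied one is reported,
    empty ones with n=0 and no mean.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for chrom, grp in stats.groupby("chrom", sort=True):
        win = (grp["pos"] // window_bp).to_numpy()
        vals = grp[value].to_numpy(dtype=float)
        for k in range(int(win.max()) + 1 if len(win) else 0):
            in_w = vals[win == k]
            in_w = in_w[~np.isnan(in_w)]
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": k * window_bp,
                    "window_end": (k + 1) * window_bp,
                    "n_variants": int(in_w.size),
                    f"mean_{value}": float(in_w.mean()) if in_w.size else float("nan"),
                    f"sd_{value}": float(in_w.std(ddof=1)) if in_w.size > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def maf_summary(
    stats: pd.DataFrame,
    maf_edges=DEFAULT_MAF_EDGES,
    value: str = "rsq_emp_ds",
    common_split: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean accuracy binned by reference-population MAF.

    Variants fall into half-open bins ``(lower, upper]`` (the first bin
    additionally includes its lower edge so MAF exactly 0 is kept).  A
    second table splits variants into common (MAF > ``common_split``) and
    less-common (MAF <= ``common_split``) groups.
    """
    maf = stats["maf_ref"].to_numpy(dtype=float)
    if np.any((maf < 0) | (maf > 0.5)):
        raise ValueError("maf_ref outside [0, 0.5]")
    vals = stats[value].to_numpy(dtype=float)
    edges = np.asarray(maf_edges, dtype=float)

    idx = np.searchsorted(edges, maf, side="left") - 1  # (lower, upper]
    idx[maf <= edges[0]] = 0
    idx = np.clip(idx, 0, len(edges) - 2)

    rows = []
    for b in range(len(edges) - 1):
        v = vals[(idx == b)]
        v = v[~np.isnan(v)]
        rows.append(
            {
                "maf_lo": edges[b],
                "maf_hi": edges[b + 1],
                "n_variants": int(v.size),
                f"mean_{value}": float(v.mean()) if v.size else float("nan"),
                f"sd_{value}": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
            }
        )
    bins = pd.DataFrame(rows)

    groups = []
    for label, mask in (
        ("common", maf > common_split),
        ("less_common", maf <= common_split),
    ):
        v = vals[mask]
        v = v[~np.isnan(v)]
        groups.append(
            {
                "group": label,
                "n_variants": int(v.size),
                f"mean_{value}": float(v.mean()) if v.size else float("nan"),
            }
        )
    return bins, pd.DataFrame(groups)


def group_summary(stats: pd.DataFrame, value: str = "rsq_emp_ds") -> pd.DataFrame:
    """Mean accuracy by region x variant class (SNP/INDEL)."""
    rows = []
    for (region, vclass), grp in stats.groupby(["region", "vclass"], sort=True):
        v = grp[value].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        rows.append(
            {
                "region": region,
                "vclass": vclass,
                "n_variants": int(v.size),
                f"mean_{value}": float(v.mean()) if v.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)
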