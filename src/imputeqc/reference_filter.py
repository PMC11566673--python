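"""Reference-panel variant filters: MAC and heterozygosity-excess windows.

Collapsed segmental duplications cause short-read misalignment that
inflates heterozygous calls and creates false variants.  The window filter
scans each chromosome in 0.5 Mb windows and, wherever 2% or more of a
window's variants show observed heterozygosity above 0.55, removes every
variant in that window exceeding the heterozygosity cutoff.  A separate
minor-allele-count filter drops near-monomorphic variants (MAC below 4 by
default, "at least 4" being inclusive).

Heterozygosity here is *observed* heterozygosity — the fraction of
non-missing calls that are heterozygous — since the artefacts being
targeted manifest directly in the calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcf_io import MISSING, TruthMatrix


def variant_heterozygosity(g_vec) -> float:
    """Fraction of non-missing calls that are heterozygous."""
    g = np.asarray(g_vec)
    called = g != MISSING
    n = int(called.sum())
    if n == 0:
        raise ValueError("all genotypes missing; heterozygosity undefined")
    return float((g[called] == 1).sum()) / n


def heterozygosity_profile(g: np.ndarray) -> np.ndarray:
    """Observed heterozygosity per variant for a genotype matrix."""
    called = g != MISSING
    n = called.sum(axis=1)
    if np.any(n == 0):
        raise ValueError("some variants have all genotypes missing")
    return (g == 1).sum(axis=1) / n


def het_excess_filter(
    chrom: np.ndarray,
    pos: np.ndarray,
    het: np.ndarray,
    window_bp: int = 500_000,
    step_bp: int | None = None,
    flag_pct: float = 2.0,
    het_threshold: float = 0.55,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag excess-heterozygosity windows and mark their high-het variants.

    Windows of ``window_bp`` tile each chromosome from position 0 at
    ``step_bp`` intervals (default: step = window, i.e. adjacent tiling,
    which makes the filter idempotent).  A window is flagged when at least
    ``flag_pct`` percent of its variants have het > ``het_threshold``
    (strict); in flagged windows exactly those variants are removed.  With
    a smaller step the removal is the union over all flagged windows.

    Returns a boolean removal mask over variants and a per-window report.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    step = step_bp if step_bp is not None else window_bp
    if step <= 0:
        raise ValueError("step_bp must be positive")

    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    het = np.asarray(het, dtype=float)
    high = het > het_threshold

    removed = np.zeros(len(pos), dtype=bool)
    rows = []
    for c in pd.unique(chrom):
        on_c = np.flatnonzero(chrom == c)
        if on_c.size == 0:
            continue
        max_pos = int(pos[on_c].max())
        start = 0
        while start <= max_pos:
            end = start + window_bp
            in_w = on_c[(pos[on_c] >= start) & (pos[on_c] < end)]
            n = in_w.size
            n_high = int(high[in_w].sum())
            pct = 100.0 * n_high / n if n else 0.0
            flagged = n >= 1 and pct >= flag_pct
            if flagged:
                removed[in_w[high[in_w]]] = True
            rows.append(
                {
                    "chrom": c,
                    "window_start": start,
                    "window_end": end,
                    "n_variants": n,
                    "n_high_het": n_high,
                    "pct_high_het": pct,
                    "flagged": flagged,
                }
            )
            start += step
    return removed, pd.DataFrame(rows)


def mac_filter(g: np.ndarray, min_mac: int = 4) -> np.ndarray:
    """Boolean retention mask: minor allele count >= ``min_mac``.

    MAC is computed over non-missing calls as min(alt alleles, ref
    alleles); "at least" is inclusive, so a variant at exactly ``min_mac``
    is retained.
    """
    called = g != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    mac = np.minimum(alt, 2 * n_called - alt)
    return mac >= min_mac


@dataclass
class FilterReport:
    """Counts and artefacts from the reference filtering cascade."""

    n_input: int
    n_fail_mac: int
    n_fail_het: int
    n_retained: int
    window_report: pd.DataFrame
    removed_het: pd.DataFrame  # chrom,pos,ref,alt,het of het-excess removals


def filter_reference(
    truth: TruthMatrix,
    min_mac: int = 4,
    window_bp: int = 500_000,
    step_bp: int | None = None,
    flag_pct: float = 2.0,
    het_threshold: float = 0.55,
) -> tuple[TruthMatrix, FilterReport]:
    """Apply the reference filters in order: MAC, then het-excess windows.

    (Biallelic filtering already happened at VCF read time.)  The window
    percentages are computed on the MAC-passing variants.
    """
    keep_mac = mac_filter(truth.g, min_mac=min_mac)
    after_mac = truth.subset_variants(np.flatnonzero(keep_mac))

    het = heterozygosity_profile(after_mac.g)
    chroms = np.array([k.chrom for k in after_mac.keys], dtype=object)
    positions = np.array([k.pos for k in after_mac.keys], dtype=np.int64)
    removed, window_report = het_excess_filter(
        chroms, positions, het, window_bp, step_bp, flag_pct, het_threshold
    )

    removed_het = pd.DataFrame(
        {
            "chrom": chroms[removed],
            "pos": positions[removed],
            "ref": [after_mac.keys[i].ref for i in np.flatnonzero(removed)],
            "alt": [after_mac.keys[i].alt for i in np.flatnonzero(removed)],
            "het": het[removed],
        }
    )
    retained = after_mac.subset_variants(np.flatnonzero(~removed))
    report = FilterReport(
        n_input=truth.n_variants,
        n_fail_mac=int((~keep_mac).sum()),
        n_fail_het=int(removed.sum()),
        n_retained=retained.n_variants,
        window_report=window_report,
        removed_het=removed_het,
    )
    return retained, report
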