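"""Per-variant imputation quality scores in the style of the three tools.

Each imputation program reports a per-variant estimate of imputation
quality computed from its own posteriors, without access to the truth:

* Beagle's DR2 estimates the squared correlation between imputed and true
  genotypes, approximating the variance of the true genotypes via the
  expected squared dosage implied by the posteriors.
* MACH/Minimac's Rsq is the observed variance of haploid allele dosages
  relative to the binomial variance p(1-p) expected at the estimated
  allele frequency.
* IMPUTE's INFO score is the ratio of observed to complete statistical
  information about the population allele frequency.

All three are 1 for fully confident posteriors at a polymorphic variant
and 0 when imputation carries no information.  Conventions for degenerate
(monomorphic) denominators follow each tool's observable behaviour and are
counted when they fire.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Denominators at or below this are treated as zero.
ZERO_TOL = 1e-12


@dataclass
class PosteriorSet:
    """Genotype posteriors for one variant across N diploid samples.

    ``gp`` is (N, 3) with rows (p0, p1, p2) summing to 1.  Derived
    quantities: per-sample expected dosage ``d = p1 + 2 p2``, expected
    squared dosage ``e = p1 + 4 p2`` (so ``e - d**2`` is the posterior
    genotype variance), and the estimated alternate allele frequency
    ``p_hat = sum(d) / 2N``.
    """

    gp: np.ndarray

    def __post_init__(self) -> None:
        gp = np.asarray(self.gp, dtype=np.float64)
        if gp.ndim != 2 or gp.shape[1] != 3:
            raise ValueError(f"gp must be (N, 3), got {gp.shape}")
        sums = gp.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("posterior triples must sum to 1 within 1e-6")
        if np.any(gp < -1e-9):
            raise ValueError("posterior probabilities must be non-negative")
        self.gp = gp

    @property
    def n(self) -> int:
        return self.gp.shape[0]

    @property
    def d(self) -> np.ndarray:
        return self.gp[:, 1] + 2.0 * self.gp[:, 2]

    @property
    def e(self) -> np.ndarray:
        return self.gp[:, 1] + 4.0 * self.gp[:, 2]

    @property
    def p_hat(self) -> float:
        return float(self.d.sum() / (2.0 * self.n))


def _as_gp_batch(gp: np.ndarray) -> np.ndarray:
    gp = np.asarray(gp, dtype=np.float64)
    if gp.ndim == 2:
        gp = gp[None, :, :]
    if gp.ndim != 3 or gp.shape[-1] != 3:
        raise ValueError(f"expected (n_variants, N, 3) posteriors, got {gp.shape}")
    return gp


def beagle_dr2_batch(gp: np.ndarray) -> np.ndarray:
    """Vectorised Beagle-style DR2 over (n_variants, N, 3) posteriors."""
    gp = _as_gp_batch(gp)
    n = gp.shape[1]
    if n < 2:
        raise ValueError("DR2 requires at least 2 samples")
    d = gp[..., 1] + 2.0 * gp[..., 2]
    e = gp[..., 1] + 4.0 * gp[..., 2]
    sd = d.sum(axis=1)
    num = (d * d).sum(axis=1) - sd * sd / n
    den = e.sum(axis=1) - sd * sd / n
    out = np.where(den > ZERO_TOL, num / np.where(den > ZERO_TOL, den, 1.0), 0.0)
    return np.clip(out, 0.0, 1.0)


def beagle_dr2(ps: PosteriorSet | np.ndarray) -> float:
    """Beagle-style dosage R2 for one variant.

    DR2 = (sum d_i^2 - (sum d_i)^2/N) / (sum e_i - (sum d_i)^2/N), the
    variance of the imputed dosages over the posterior-implied variance of
    the true genotypes.  A non-positive denominator (monomorphic
    posteriors) yields 0.
    """
    gp = ps.gp if isinstance(ps, PosteriorSet) else PosteriorSet(np.asarray(ps)).gp
    return float(beagle_dr2_batch(gp[None])[0])


def mach_rsq_batch(haploid_dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised MACH-style Rsq over (n_variants, H) haploid dosages."""
    dh = np.asarray(haploid_dosages, dtype=np.float64)
    if dh.ndim == 1:
        dh = dh[None, :]
    h = dh.shape[1]
    if h < 2:
        raise ValueError("MACH Rsq requires at least 2 haploid dosages")
    p_hat = dh.mean(axis=1)
    den = p_hat * (1.0 - p_hat)
    msd = ((dh - p_hat[:, None]) ** 2).mean(axis=1)
    raw = np.where(den > ZERO_TOL, msd / np.where(den > ZERO_TOL, den, 1.0), 0.0)
    return raw, np.clip(raw, 0.0, 1.0)


def mach_rsq_diploid_batch(diploid_dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised diploid-dosage MACH Rsq: Var(d) / (2 p_hat (1 - p_hat))."""
    d = np.asarray(diploid_dosages, dtype=np.float64)
    if d.ndim == 1:
        d = d[None, :]
    n = d.shape[1]
    if n < 2:
        raise ValueError("MACH Rsq requires at least 2 samples")
    p_hat = d.mean(axis=1) / 2.0
    den = 2.0 * p_hat * (1.0 - p_hat)
    var = ((d - d.mean(axis=1, keepdims=True)) ** 2).mean(axis=1)
    raw = np.where(den > ZERO_TOL, var / np.where(den > ZERO_TOL, den, 1.0), 0.0)
    return raw, np.clip(raw, 0.0, 1.0)


def mach_rsq(
    haploid_dosages: np.ndarray | None = None, *, diploid_dosages: np.ndarray | None = None
) -> tuple[float, float]:
    """MACH/Minimac-style Rsq: dosage variance over the binomial variance.

    Haploid form: Rsq = mean_h (D_h - p_hat)^2 / (p_hat (1 - p_hat)) with
    p_hat the mean haploid dosage.  Diploid fallback (unphased dosages):
    Rsq = Var(d) / (2 p_hat (1 - p_hat)), the same ratio against the HWE
    variance of a diploid genotype — for independently paired haplotypes
    the two forms estimate the same quantity.  Can exceed 1 when dosages
    are overdispersed; both the raw and the [0, 1]-capped value are
    returned.
    """
    if (haploid_dosages is None) == (diploid_dosages is None):
        raise ValueError("provide exactly one of haploid_dosages or diploid_dosages")
    if diploid_dosages is not None:
        raw, capped = mach_rsq_diploid_batch(np.asarray(diploid_dosages, dtype=np.float64)[None, :])
    else:
        dh = np.asarray(haploid_dosages, dtype=np.float64)
        raw, capped = mach_rsq_batch(dh[None, :])
    return float(raw[0]), float(capped[0])


def impute_info_batch(gp: np.ndarray) -> np.ndarray:
    """Vectorised IMPUTE-style INFO over (n_variants, N, 3) posteriors."""
    gp = _as_gp_batch(gp)
    n = gp.shape[1]
    if n < 2:
        raise ValueError("INFO requires at least 2 samples")
    d = gp[..., 1] + 2.0 * gp[..., 2]
    e = gp[..., 1] + 4.0 * gp[..., 2]
    p_hat = d.sum(axis=1) / (2.0 * n)
    den = 2.0 * n * p_hat * (1.0 - p_hat)
    post_var = (e - d * d).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        info = 1.0 - post_var / den
    # monomorphic p_hat: fully confident posteriors carry complete
    # information (INFO 1), uncertain ones none (INFO 0)
    degenerate = post_var <= ZERO_TOL * n
    info = np.where(den > ZERO_TOL, info, np.where(degenerate, 1.0, 0.0))
    return np.clip(info, 0.0, 1.0)


def impute_info(ps: PosteriorSet | np.ndarray) -> float:
    """IMPUTE-style INFO score for one variant.

    INFO = 1 - sum_i(e_i - d_i^2) / (2N p_hat (1 - p_hat)): one minus the
    posterior genotype variance relative to the HWE variance at the
    estimated frequency.
    """
    gp = ps.gp if isinstance(ps, PosteriorSet) else PosteriorSet(np.asarray(ps)).gp
    return float(impute_info_batch(gp[None])[0])
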