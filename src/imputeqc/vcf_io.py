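"""VCF input/output, variant identity and chromosome-region classification.

Truth and imputed call sets are read from VCF 4.2 (plain or bgzipped) into
dense numpy-backed containers.  Variant identity is the exact normalized
tuple (chrom, pos, ref, alt) — no indel left-alignment is attempted, so
call sets produced on the same reference representation match exactly.

The X chromosome is split into the pseudo-autosomal region (PAR) and the
X-specific remainder (non-PAR) at a single configurable coordinate;
positions at or below the boundary are classified non-PAR, positions above
it PAR (the PAR lies at the distal end of the chromosome).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel for a missing genotype in integer matrices

AUTOSOME = "AUTOSOME"
NONPAR = "NONPAR"
PAR = "PAR"

#: Default PAR boundary on the bovine X chromosome (ARS-UCD1.2), bp.
DEFAULT_PAR_BOUNDARY = 133_300_518

#: Conventional per-variant quality INFO tags of the three imputation tools.
DIALECT_KEYS = {
    "beagle_dr2": "DR2",
    "minimac_r2": "R2",
    "impute_info": "INFO",
}

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class VcfFormatError(ValueError):
    """Raised when a VCF lacks a required field or has an unusable layout."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized biallelic variant identity.

    ``vclass`` is ``"SNP"`` when both alleles are single bases, otherwise
    ``"INDEL"``.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        ref, alt = self.ref.upper(), self.alt.upper()
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        if not _ALLELE_RE.match(ref) or not _ALLELE_RE.match(alt):
            raise ValueError(f"alleles must be non-empty A/C/G/T strings: {ref!r}>{alt!r}")
        if ref == alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")

    @property
    def vclass(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"


@dataclass
class RegionConfig:
    """Chromosome-region classification rules.

    Positions on an X-chromosome label at or below ``par_boundary`` are
    non-PAR, above it PAR; every other chromosome is autosomal.  With
    ``strict`` enabled, chromosome labels outside ``known_chroms`` raise.
    """

    par_boundary: int = DEFAULT_PAR_BOUNDARY
    x_chroms: tuple[str, ...] = ("X", "chrX")
    known_chroms: tuple[str, ...] | None = None
    strict: bool = False

    def classify(self, chrom: str, pos: int) -> str:
        if self.strict and self.known_chroms is not None and chrom not in self.known_chroms:
            raise ValueError(f"unknown chromosome label {chrom!r} in strict mode")
        if chrom in self.x_chroms:
            return NONPAR if pos <= self.par_boundary else PAR
        return AUTOSOME


@dataclass
class TruthMatrix:
    """Truth genotypes: per-variant x per-sample alternate-allele counts.

    ``g`` holds 0/1/2 with :data:`MISSING` for missing calls.  ``af_ref``
    is the alternate-allele frequency in the reference population (from
    which the folded ``maf_ref`` derives); ``mac_ref`` the minor allele
    count there.
    """

    keys: list[VariantKey]
    samples: list[str]
    g: np.ndarray  # (n_variants, n_samples) int16
    region: np.ndarray  # (n_variants,) str
    af_ref: np.ndarray  # (n_variants,) float
    mac_ref: np.ndarray  # (n_variants,) int
    extra: dict = field(default_factory=dict)  # optional per-variant annotation arrays

    @property
    def n_variants(self) -> int:
        return len(self.keys)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def maf_ref(self) -> np.ndarray:
        return np.minimum(self.af_ref, 1.0 - self.af_ref)

    def subset_variants(self, idx: np.ndarray) -> "TruthMatrix":
        return TruthMatrix(
            keys=[self.keys[i] for i in np.atleast_1d(idx)],
            samples=list(self.samples),
            g=self.g[idx],
            region=self.region[idx],
            af_ref=self.af_ref[idx],
            mac_ref=self.mac_ref[idx],
            extra={k: np.asarray(v)[idx] for k, v in self.extra.items()},
        )

    def subset_samples(self, idx: np.ndarray) -> "TruthMatrix":
        return replace(
            self, samples=[self.samples[i] for i in np.atleast_1d(idx)], g=self.g[:, idx]
        )


@dataclass
class ImputedCallSet:
    """Imputed genotypes: best-guess GT, dosage DS, optional posteriors GP.

    ``rsq_soft`` carries the per-variant software quality score read from
    the INFO field named by ``dialect`` (DR2 for Beagle, R2 for Minimac,
    INFO for IMPUTE), capped into [0, 1].
    """

    keys: list[VariantKey]
    samples: list[str]
    gt: np.ndarray  # (n_variants, n_samples) int16, MISSING allowed
    ds: np.ndarray  # (n_variants, n_samples) float64, NaN allowed
    gp: np.ndarray | None  # (n_variants, n_samples, 3) or None
    rsq_soft: np.ndarray  # (n_variants,) float64
    dialect: str = "custom"

    @property
    def n_variants(self) -> int:
        return len(self.keys)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_variants(self, idx: np.ndarray) -> "ImputedCallSet":
        return ImputedCallSet(
            keys=[self.keys[i] for i in np.atleast_1d(idx)],
            samples=list(self.samples),
            gt=self.gt[idx],
            ds=self.ds[idx],
            gp=None if self.gp is None else self.gp[idx],
            rsq_soft=self.rsq_soft[idx],
            dialect=self.dialect,
        )

    def subset_samples(self, idx: np.ndarray) -> "ImputedCallSet":
        idx = np.atleast_1d(idx)
        return ImputedCallSet(
            keys=list(self.keys),
            samples=[self.samples[i] for i in idx],
            gt=self.gt[:, idx],
            ds=self.ds[:, idx],
            gp=None if self.gp is None else self.gp[:, idx],
            rsq_soft=self.rsq_soft,
            dialect=self.dialect,
        )


@dataclass
class MatchReport:
    """Bookkeeping from aligning a truth and an imputed call set."""

    n_matched: int
    n_truth_only: int
    n_imputed_only: int
    n_allele_mismatch: int  # same chrom:pos present on both sides, alleles differ
    n_samples: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"matched={self.n_matched} truth_only={self.n_truth_only} "
            f"imputed_only={self.n_imputed_only} allele_mismatch={self.n_allele_mismatch} "
            f"samples={self.n_samples}"
        )


def _biallelic_key(variant, skip_counts: dict) -> VariantKey | None:
    """Build a VariantKey from a cyvcf2 record, or None if not usable."""
    alts = variant.ALT
    if len(alts) != 1:
        skip_counts["multiallelic"] += 1
        return None
    ref, alt = variant.REF.upper(), alts[0].upper()
    if not _ALLELE_RE.match(ref) or not _ALLELE_RE.match(alt) or ref == alt:
        skip_counts["non_acgt"] += 1
        return None
    return VariantKey(variant.CHROM, variant.POS, ref, alt)


def _open_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if len(vcf.samples) == 0:
        raise VcfFormatError(f"{path}: VCF has no sample columns (GT required)")
    return vcf


def read_truth_vcf(path, region_config: RegionConfig | None = None) -> TruthMatrix:
    """Read truth genotypes from a VCF with GT.

    Only biallelic A/C/G/T records are retained; skipped multi-allelic
    records are counted and logged.  Reference-population allele frequency
    is taken from INFO/AF and minor allele count from INFO/MAC when
    present, otherwise computed from the sample genotypes themselves.
    """
    region_config = region_config or RegionConfig()
    vcf = _open_vcf(path)
    samples = list(vcf.samples)
    keys: list[VariantKey] = []
    rows: list[np.ndarray] = []
    regions: list[str] = []
    afs: list[float] = []
    macs: list[int] = []
    skip_counts = {"multiallelic": 0, "non_acgt": 0}

    for variant in vcf:
        key = _biallelic_key(variant, skip_counts)
        if key is None:
            continue
        gt = variant.gt_types.astype(np.int16)  # 0/1/2, 3 = missing
        gt[gt == 3] = MISSING
        n_called = int((gt != MISSING).sum())
        if n_called == 0 and variant.format("GT") is None:
            raise VcfFormatError(f"{path}: record {key.chrom}:{key.pos} lacks GT")
        af = variant.INFO.get("AF")
        if af is None:
            alt_alleles = int(gt[gt != MISSING].sum())
            af = alt_alleles / (2 * n_called) if n_called else float("nan")
        else:
            af = float(af)
        mac = variant.INFO.get("MAC")
        if mac is None:
            alt_alleles = int(gt[gt != MISSING].sum())
            mac = min(alt_alleles, 2 * n_called - alt_alleles)
        keys.append(key)
        rows.append(gt)
        regions.append(region_config.classify(key.chrom, key.pos))
        afs.append(float(af))
        macs.append(int(mac))

    if skip_counts["multiallelic"]:
        logger.info("%s: skipped %d multi-allelic records", path, skip_counts["multiallelic"])
    if skip_counts["non_acgt"]:
        logger.info("%s: skipped %d non-ACGT records", path, skip_counts["non_acgt"])

    g = np.array(rows, dtype=np.int16) if rows else np.empty((0, len(samples)), np.int16)
    return TruthMatrix(
        keys=keys,
        samples=samples,
        g=g,
        region=np.array(regions, dtype=object),
        af_ref=np.array(afs, dtype=float),
        mac_ref=np.array(macs, dtype=int),
    )


def read_imputed_vcf(
    path, dialect: str = "beagle_dr2", quality_key: str | None = None
) -> ImputedCallSet:
    """Read an imputed call set: GT, DS (or GP), and the quality INFO field.

    ``dialect`` selects the INFO tag carrying the software quality score
    (DR2 / R2 / INFO); pass ``dialect="custom"`` with ``quality_key`` for
    anything else.  When DS is absent it is reconstructed from GP as
    p1 + 2*p2.  Dosages outside [0, 2] are clipped (warned); quality
    scores above 1 are capped at 1 (counted).
    """
    if quality_key is None:
        try:
            quality_key = DIALECT_KEYS[dialect]
        except KeyError:
            raise ValueError(
                f"dialect {dialect!r} needs an explicit quality_key "
                f"(known dialects: {sorted(DIALECT_KEYS)})"
            ) from None

    vcf = _open_vcf(path)
    samples = list(vcf.samples)
    keys: list[VariantKey] = []
    gts: list[np.ndarray] = []
    dss: list[np.ndarray] = []
    gps: list[np.ndarray] = []
    rsqs: list[float] = []
    skip_counts = {"multiallelic": 0, "non_acgt": 0}
    n_clipped = 0
    n_capped = 0
    has_gp = True

    for variant in vcf:
        key = _biallelic_key(variant, skip_counts)
        if key is None:
            continue
        gt = variant.gt_types.astype(np.int16)
        gt[gt == 3] = MISSING

        try:
            ds = variant.format("DS")
        except KeyError:  # tag absent from the header entirely
            ds = None
        try:
            gp = variant.format("GP")
        except KeyError:
            gp = None
        if ds is None and gp is None:
            raise VcfFormatError(
                f"{path}: record {key.chrom}:{key.pos} has neither DS nor GP"
            )
        if gp is not None:
            gp = np.asarray(gp, dtype=np.float64)
        else:
            has_gp = False
        if ds is not None:
            ds = np.asarray(ds, dtype=np.float64).reshape(-1)
        else:
            ds = gp[:, 1] + 2.0 * gp[:, 2]

        out_of_range = (ds < 0) | (ds > 2)
        if out_of_range.any():
            n_clipped += int(out_of_range.sum())
            ds = np.clip(ds, 0.0, 2.0)

        rsq = variant.INFO.get(quality_key)
        if rsq is None:
            raise VcfFormatError(
                f"{path}: record {key.chrom}:{key.pos} lacks INFO field "
                f"{quality_key!r} required by dialect {dialect!r}"
            )
        rsq = float(rsq)
        if rsq > 1.0:
            n_capped += 1
            rsq = 1.0
        rsq = max(rsq, 0.0)

        keys.append(key)
        gts.append(gt)
        dss.append(ds)
        if gp is not None:
            gps.append(gp)
        rsqs.append(rsq)

    if n_clipped:
        logger.warning("%s: clipped %d dosage values into [0, 2]", path, n_clipped)
    if n_capped:
        logger.info("%s: capped %d quality scores above 1", path, n_capped)
    if skip_counts["multiallelic"]:
        logger.info("%s: skipped %d multi-allelic records", path, skip_counts["multiallelic"])

    n = len(keys)
    return ImputedCallSet(
        keys=keys,
        samples=samples,
        gt=np.array(gts, dtype=np.int16) if n else np.empty((0, len(samples)), np.int16),
        ds=np.array(dss, dtype=np.float64) if n else np.empty((0, len(samples))),
        gp=np.array(gps, dtype=np.float64) if (n and has_gp and len(gps) == n) else None,
        rsq_soft=np.array(rsqs, dtype=np.float64),
        dialect=dialect,
    )


def match_variants(
    truth: TruthMatrix, imputed: ImputedCallSet
) -> tuple[TruthMatrix, ImputedCallSet, MatchReport]:
    """Align a truth and an imputed call set on exact variant identity.

    Variants match on (chrom, pos, ref, alt) after uppercase normalization;
    samples are intersected and both sets reordered identically (truth
    sample order is preserved).  Truth-only, imputed-only and
    same-position/different-allele counts are reported.
    """
    common_samples = [s for s in truth.samples if s in set(imputed.samples)]
    if not common_samples:
        raise ValueError("no overlapping samples between truth and imputed call sets")

    t_index = {(k.chrom, k.pos, k.ref, k.alt): i for i, k in enumerate(truth.keys)}
    i_index = {(k.chrom, k.pos, k.ref, k.alt): j for j, k in enumerate(imputed.keys)}
    shared = [k for k in t_index if k in i_index]
    if not shared:
        raise ValueError("no overlapping variants between truth and imputed call sets")

    t_pos = {(k[0], k[1]) for k in t_index}
    i_only = [k for k in i_index if k not in t_index]
    n_allele_mismatch = sum((k[0], k[1]) in t_pos for k in i_only)

    t_idx = np.array([t_index[k] for k in shared], dtype=int)
    i_idx = np.array([i_index[k] for k in shared], dtype=int)
    order = np.argsort(t_idx)  # keep truth file order
    t_idx, i_idx = t_idx[order], i_idx[order]

    t_smp = np.array([truth.samples.index(s) for s in common_samples], dtype=int)
    i_smp = np.array([imputed.samples.index(s) for s in common_samples], dtype=int)

    truth_aligned = truth.subset_variants(t_idx).subset_samples(t_smp)
    imputed_aligned = imputed.subset_variants(i_idx).subset_samples(i_smp)

    report = MatchReport(
        n_matched=len(shared),
        n_truth_only=len(t_index) - len(shared),
        n_imputed_only=len(i_index) - len(shared),
        n_allele_mismatch=n_allele_mismatch,
        n_samples=len(common_samples),
    )
    return truth_aligned, imputed_aligned, report


#: Fixed column order of the per-variant statistics table.
STATS_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "vclass",
    "region",
    "maf_ref",
    "rsq_soft",
    "n_pairs",
    "r_gt",
    "r_ds",
    "rsq_emp_gt",
    "rsq_emp_ds",
    "concordance",
    "fpr",
    "fnr",
    "aer",
    "estimable_gt",
    "estimable_ds",
    "seg_truth",
    "seg_imp_gt",
]

_FLOAT_COLS = [
    "maf_ref", "rsq_soft", "r_gt", "r_ds", "rsq_emp_gt", "rsq_emp_ds",
    "concordance", "fpr", "fnr", "aer",
]


def write_stats_table(stats: pd.DataFrame, path, manifest_id: str | None = None) -> None:
    """Write per-variant statistics as TSV, one row per variant.

    Non-estimable / undefined values are written as ``NA``; floats are
    rounded to 6 decimal places and round-trip losslessly at that
    precision through :func:`read_stats_table`.
    """
    df = stats.copy()
    missing = [c for c in STATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stats table lacks columns: {missing}")
    df = df[STATS_COLUMNS]
    with open(path, "w") as fh:
        if manifest_id is not None:
            fh.write(f"# manifest: {manifest_id}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def read_stats_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    for col in ("estimable_gt", "estimable_ds", "seg_truth", "seg_imp_gt"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def stats_keys(stats: pd.DataFrame) -> list[tuple]:
    """(chrom, pos, ref, alt) identity tuples of a stats table."""
    return list(zip(stats["chrom"].astype(str), stats["pos"], stats["ref"], stats["alt"]))
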