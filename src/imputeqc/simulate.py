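"""Synthetic truth/imputed genotype generator.

The generator emulates the statistical structure the evaluation pipeline
consumes — not the imputation HMMs themselves.  A reference haplotype
panel is drawn per variant from a configurable allele-frequency spectrum
(default: density proportional to 1/p, the neutral-theory site-frequency
shape, truncated so every variant has minor allele count >= 1 in the
panel); diploid target samples are formed by pairing panel haplotypes.
Variants are placed uniformly within declared chromosome spans carrying a
region class (autosome baseline, PAR-like high-error region, a localized
error hotspot mimicking a collapsed segmental duplication) and an error
multiplier; ~7% of variants are INDELs.

Imputation error follows a posterior-mixture observation model: for each
(variant, sample) a latent observation ``y`` equals the truth with
probability 1 - lambda_v and is otherwise drawn from the Hardy-Weinberg
genotype distribution at the reference allele frequency.  The emitted
posterior is the exact Bayes posterior of that observation,

    gp = (1 - lambda_v) * onehot(y) + lambda_v * HWE(p),

which makes the posteriors *calibrated*: conditional on gp, the truth is
distributed as gp.  The per-cell corruption rate lambda_v = lambda_base *
maf_term(maf) * region_multiplier rises at low MAF and in high-error
regions, reproducing the familiar difficulty gradients.  An alternative
pure allele-flip error model (each truth allele flips independently at
rate lambda_v) is available for allele-level error-rate checks.

Software-style quality scores are computed from the simulated posteriors
by the configured estimator (Beagle DR2 by default) and then optionally
miscalibrated with a power transform s -> s**gamma: gamma > 1 deflates
scores (Minimac-like), gamma < 1 inflates them (Beagle/IMPUTE-like at the
high end); ``score_model="oracle"`` instead copies the realised empirical
Rsq so calibration machinery can be tested against a perfect score.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import rsq
from .vcf_io import AUTOSOME, MISSING, NONPAR, PAR, ImputedCallSet, TruthMatrix, VariantKey

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RegionSpan:
    """A simulated chromosome span with a region class and error scaling."""

    chrom: str
    start: int  # bp, inclusive
    end: int  # bp, exclusive
    region_class: str  # AUTOSOME | NONPAR | PAR
    error_multiplier: float = 1.0
    label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def default_regions() -> tuple[RegionSpan, ...]:
    """Desk-scale study layout: autosome baseline, error hotspot,
    het-excess span, and an X split into non-PAR and PAR (PAR boundary at
    4 Mb in simulated coordinates)."""
    return (
        RegionSpan("1", 1, 8_000_000, AUTOSOME, 1.0, "autosome"),
        RegionSpan("1", 8_000_000, 10_000_000, AUTOSOME, 6.0, "hotspot"),
        RegionSpan("1", 10_000_000, 10_500_000, AUTOSOME, 1.0, "het_excess"),
        RegionSpan("X", 1, 4_000_000, NONPAR, 1.0, "nonpar"),
        RegionSpan("X", 4_000_000, 5_000_000, PAR, 4.0, "par"),
    )


#: PAR boundary consistent with :func:`default_regions` simulated coordinates.
SIM_PAR_BOUNDARY = 4_000_000


@dataclass
class SimulationConfig:
    """Parameters of one synthetic truth/imputed data set.

    The seed fully determines the output.  ``maf_spectrum`` is either
    ``("one_over_p",)`` or ``("beta", a, b)``.  ``error_model`` is
    ``"posterior_mixture"`` (default) or ``"allele_flip"``;
    ``score_model`` one of ``"dr2" | "mach" | "info" | "oracle"``.
    """

    seed: int = 0
    n_ref_hap: int = 400
    n_target: int = 70
    n_variants: int = 5000
    indel_fraction: float = 0.07
    maf_spectrum: tuple = ("one_over_p",)
    regions: tuple[RegionSpan, ...] = field(default_factory=default_regions)
    error_rate: float = 0.04  # base per-cell corruption intensity lambda
    maf_exponent: float = 0.25  # lambda scales with (0.5 / max(maf, floor))**exponent
    maf_floor: float = 0.01
    error_model: str = "posterior_mixture"
    score_model: str = "dr2"
    gamma: float = 1.0  # score miscalibration s -> s**gamma
    het_excess_rate: float = 0.0  # fraction of variants in "het_excess" spans made high-het

    def __post_init__(self) -> None:
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must be in [0, 1]")
        if self.error_model not in ("posterior_mixture", "allele_flip"):
            raise ValueError(f"unknown error_model {self.error_model!r}")
        if self.score_model not in ("dr2", "mach", "info", "oracle"):
            raise ValueError(f"unknown score_model {self.score_model!r}")
        spans = sorted(self.regions, key=lambda s: (s.chrom, s.start))
        for a, b in zip(spans, spans[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"overlapping region spans {a} and {b}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = [dataclasses.asdict(s) for s in self.regions]
        d["maf_spectrum"] = list(self.maf_spectrum)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "regions" in d:
            d["regions"] = tuple(RegionSpan(**r) for r in d["regions"])
        if "maf_spectrum" in d:
            d["maf_spectrum"] = tuple(d["maf_spectrum"])
        return cls(**d)


def _sample_maf(cfg: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    kind = cfg.maf_spectrum[0]
    if kind == "one_over_p":
        m_min = 1.0 / cfg.n_ref_hap
        u = rng.random(n)
        return m_min * (0.5 / m_min) ** u  # inverse CDF of density ~ 1/p on [m_min, 0.5]
    if kind == "beta":
        _, a, b = cfg.maf_spectrum
        p = rng.beta(a, b, size=n)
        return np.minimum(p, 1.0 - p)
    raise ValueError(f"unknown maf_spectrum {cfg.maf_spectrum!r}")


def _region_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Allocate variants to spans proportional to span length; draw sorted
    unique positions within each span."""
    spans = list(cfg.regions)
    lengths = np.array([s.length for s in spans], dtype=float)
    counts = np.floor(cfg.n_variants * lengths / lengths.sum()).astype(int)
    for i in range(cfg.n_variants - counts.sum()):
        counts[i % len(counts)] += 1
    chroms, positions, classes, mults, labels = [], [], [], [], []
    for span, k in zip(spans, counts):
        pos = np.sort(rng.choice(np.arange(span.start, span.end), size=k, replace=False))
        chroms.extend([span.chrom] * k)
        positions.extend(pos.tolist())
        classes.extend([span.region_class] * k)
        mults.extend([span.error_multiplier] * k)
        labels.extend([span.label] * k)
    order = np.lexsort((np.array(positions), np.array(chroms, dtype=object)))
    return (
        np.array(chroms, dtype=object)[order],
        np.array(positions, dtype=np.int64)[order],
        np.array(classes, dtype=object)[order],
        np.array(mults, dtype=float)[order],
        np.array(labels, dtype=object)[order],
    )


def _alleles(cfg: SimulationConfig, rng: np.random.Generator, n: int):
    is_indel = rng.random(n) < cfg.indel_fraction
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    refs = _BASES[ref_idx]
    alts = _BASES[(ref_idx + alt_shift) % 4]
    refs, alts = refs.astype(object), alts.astype(object)
    ins = rng.random(n) < 0.5
    extra = _BASES[rng.integers(0, 4, size=n)]
    for i in np.flatnonzero(is_indel):
        if ins[i]:
            alts[i] = str(refs[i]) + str(extra[i])  # insertion
        else:
            refs[i] = str(refs[i]) + str(extra[i])  # deletion
            alts[i] = str(refs[i])[0]
    return refs, alts


def simulate_truth(cfg: SimulationConfig) -> tuple[TruthMatrix, np.ndarray]:
    """Draw the reference haplotype panel and target truth genotypes.

    Returns the truth matrix and the (n_variants, n_ref_hap) panel of 0/1
    haplotype alleles.  Panel allele frequencies are conditioned on
    1 <= MAC <= H-1 so every variant is polymorphic in the reference.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms, positions, classes, mults, labels = _region_layout(cfg, rng)
    n = len(positions)

    # error in elevated spans is heterogeneous across sites: per-variant
    # multipliers are drawn uniformly between the baseline and the span
    # maximum, so even a poor region contains some well-imputed variants
    elevated = mults > 1.0
    mults = np.where(elevated, rng.uniform(1.0, mults, size=n), mults)

    maf = _sample_maf(cfg, rng, n)
    side = rng.random(n) < 0.5
    p_target = np.where(side, maf, 1.0 - maf)

    panel = (rng.random((n, cfg.n_ref_hap)) < p_target[:, None]).astype(np.int8)
    count = panel.sum(axis=1)
    # force polymorphism in the panel (MAC >= 1 on both sides)
    fix0 = np.flatnonzero(count == 0)
    panel[fix0, rng.integers(0, cfg.n_ref_hap, size=fix0.size)] = 1
    fixH = np.flatnonzero(count == cfg.n_ref_hap)
    panel[fixH, rng.integers(0, cfg.n_ref_hap, size=fixH.size)] = 0
    count = panel.sum(axis=1)
    af = count / cfg.n_ref_hap
    mac = np.minimum(count, cfg.n_ref_hap - count)

    # diploid targets: each sample is a fixed pair of panel haplotypes
    hap_idx = np.array(
        [rng.choice(cfg.n_ref_hap, size=2, replace=False) for _ in range(cfg.n_target)]
    )
    g = (panel[:, hap_idx[:, 0]] + panel[:, hap_idx[:, 1]]).astype(np.int16)

    refs, alts = _alleles(cfg, rng, n)
    keys = [
        VariantKey(str(c), int(p), str(r), str(a))
        for c, p, r, a in zip(chroms, positions, refs, alts)
    ]
    samples = [f"S{i:03d}" for i in range(cfg.n_target)]
    truth = TruthMatrix(
        keys=keys,
        samples=samples,
        g=g,
        region=classes,
        af_ref=af,
        mac_ref=mac.astype(int),
        extra={"span_label": labels, "error_multiplier": mults},
    )
    if cfg.het_excess_rate > 0:
        for span in cfg.regions:
            if span.label == "het_excess":
                truth = inject_het_excess(
                    truth,
                    (span.chrom, span.start, span.end),
                    cfg.het_excess_rate,
                    rng=rng,
                )
    return truth, panel


def _error_intensity(cfg: SimulationConfig, truth: TruthMatrix) -> np.ndarray:
    mults = truth.extra.get("error_multiplier", np.ones(truth.n_variants))
    maf = np.maximum(truth.maf_ref, cfg.maf_floor)
    lam = cfg.error_rate * (0.5 / maf) ** cfg.maf_exponent * mults
    if np.any((lam < 0) | (lam > 1)):
        raise ValueError(
            f"error intensity outside [0, 1] after multipliers (max {lam.max():.3f}); "
            "lower error_rate, maf_exponent or region multipliers"
        )
    return lam


def _hwe(p: np.ndarray) -> np.ndarray:
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)


def _rowwise_rsq_emp_ds(g: np.ndarray, ds: np.ndarray) -> np.ndarray:
    n = g.shape[1]
    gc = g - g.mean(axis=1, keepdims=True)
    dc = ds - ds.mean(axis=1, keepdims=True)
    vg = (gc * gc).sum(axis=1)
    vd = (dc * dc).sum(axis=1)
    cov = (gc * dc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = cov * cov / (vg * vd)
    return np.where((vg > 1e-12) & (vd > 1e-12), r2, np.nan)


def simulate_imputation(truth: TruthMatrix, cfg: SimulationConfig) -> ImputedCallSet:
    """Generate imputed posteriors, genotypes, dosages and quality scores.

    Uses an independent random stream (seed + 1, kept below 2**31) so the
    same truth can be re-imputed under different error settings.
    """
    rng = np.random.default_rng((cfg.seed + 1) % (2**31))
    n, s = truth.g.shape
    g = truth.g.astype(np.int16)
    lam = _error_intensity(cfg, truth)
    p = truth.af_ref

    if cfg.error_model == "allele_flip":
        eps = np.broadcast_to(lam[:, None], (n, s))
        down = rng.binomial(g, eps)
        up = rng.binomial(2 - g, eps)
        new_g = (g - down + up).astype(np.int16)
        gp = np.eye(3)[new_g]
        ds = new_g.astype(np.float64)
        gt = new_g
    else:
        hwe = _hwe(p)  # (n, 3)
        corrupt = rng.random((n, s)) < lam[:, None]
        draw = rng.random((n, s, 1))
        y_hwe = (draw > np.cumsum(hwe, axis=1)[:, None, :]).sum(axis=-1).astype(np.int16)
        y = np.where(corrupt, y_hwe, g)
        gp = (1.0 - lam)[:, None, None] * np.eye(3)[y] + lam[:, None, None] * hwe[:, None, :]
        ds = gp[..., 1] + 2.0 * gp[..., 2]
        gt = np.argmax(gp, axis=-1).astype(np.int16)  # first max -> lowest genotype on ties

    if cfg.score_model == "dr2":
        score = rsq.beagle_dr2_batch(gp)
    elif cfg.score_model == "info":
        score = rsq.impute_info_batch(gp)
    elif cfg.score_model == "mach":
        _, score = rsq.mach_rsq_diploid_batch(ds)
    else:  # oracle: the realised empirical accuracy itself
        score = np.nan_to_num(_rowwise_rsq_emp_ds(g.astype(float), ds), nan=0.0)

    score = np.clip(score, 0.0, 1.0) ** cfg.gamma

    return ImputedCallSet(
        keys=list(truth.keys),
        samples=list(truth.samples),
        gt=gt,
        ds=ds,
        gp=gp,
        rsq_soft=score,
        dialect="custom",
    )


def inject_het_excess(
    truth: TruthMatrix,
    span: tuple[str, int, int],
    excess_rate: float,
    rng: np.random.Generator | None = None,
) -> TruthMatrix:
    """Resample a fraction of a span's variants to observed het > 0.55.

    Selected variants get ceil(0.7 * n_samples) heterozygous calls (the
    rest homozygous), mimicking the inflated-heterozygosity signature of
    collapsed segmental duplications.
    """
    chrom, start, end = span
    rng = rng if rng is not None else np.random.default_rng(truth.n_variants)
    in_span = np.array(
        [k.chrom == chrom and start <= k.pos < end for k in truth.keys], dtype=bool
    )
    idx = np.flatnonzero(in_span)
    if idx.size == 0:
        raise ValueError(f"no variants in span {chrom}:{start}-{end}")
    n_pick = int(round(excess_rate * idx.size))
    if n_pick == 0:
        return truth
    picked = rng.choice(idx, size=n_pick, replace=False)
    n_s = truth.n_samples
    n_het = int(np.ceil(0.7 * n_s))
    g = truth.g.copy()
    for i in picked:
        order = rng.permutation(n_s)
        g[i, order[:n_het]] = 1
        g[i, order[n_het:]] = rng.choice([0, 2], size=n_s - n_het)
    return dataclasses.replace(truth, g=g)


# ---------------------------------------------------------------------------
# VCF output


def _format_gt(val: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}[int(val)]


def _vcf_header(samples, contigs, info_lines, format_lines) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=imputeqc-simulate"]
    for c, length in contigs:
        lines.append(f"##contig=<ID={c},length={length}>")
    lines.extend(info_lines)
    lines.extend(format_lines)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


def _contigs(keys) -> list[tuple[str, int]]:
    out: dict[str, int] = {}
    for k in keys:
        out[k.chrom] = max(out.get(k.chrom, 0), k.pos + 1000)
    return sorted(out.items())


def write_truth_vcf(truth: TruthMatrix, path) -> None:
    """Write a truth call set as plain-text VCF (GT; INFO AF, MAC)."""
    info = [
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Reference panel alternate allele frequency">',
        '##INFO=<ID=MAC,Number=A,Type=Integer,Description="Reference panel minor allele count">',
    ]
    fmt = ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    with open(path, "w") as fh:
        fh.write(_vcf_header(truth.samples, _contigs(truth.keys), info, fmt))
        for i, k in enumerate(truth.keys):
            cells = "\t".join(_format_gt(v) for v in truth.g[i])
            fh.write(
                f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t"
                f"AF={truth.af_ref[i]:.6f};MAC={int(truth.mac_ref[i])}\tGT\t{cells}\n"
            )


def write_imputed_vcf(imputed: ImputedCallSet, path, quality_key: str = "DR2") -> None:
    """Write an imputed call set as plain-text VCF (GT:DS:GP; quality INFO tag)."""
    info = [
        f'##INFO=<ID={quality_key},Number=1,Type=Float,'
        'Description="Estimated imputation quality (software-style Rsq)">'
    ]
    fmt = [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Best-guess genotype">',
        '##FORMAT=<ID=DS,Number=A,Type=Float,Description="Alternate allele dosage">',
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior probabilities">',
    ]
    has_gp = imputed.gp is not None
    with open(path, "w") as fh:
        fh.write(
            _vcf_header(imputed.samples, _contigs(imputed.keys), info, fmt if has_gp else fmt[:2])
        )
        for i, k in enumerate(imputed.keys):
            cells = []
            for j in range(imputed.n_samples):
                cell = f"{_format_gt(imputed.gt[i, j])}:{imputed.ds[i, j]:.6f}"
                if has_gp:
                    gp = imputed.gp[i, j]
                    cell += f":{gp[0]:.6f},{gp[1]:.6f},{gp[2]:.6f}"
                cells.append(cell)
            fh.write(
                f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t"
                f"{quality_key}={imputed.rsq_soft[i]:.6f}\t"
                f"{'GT:DS:GP' if has_gp else 'GT:DS'}\t" + "\t".join(cells) + "\n"
            )


def write_simulation(
    truth: TruthMatrix,
    imputed: ImputedCallSet,
    out_dir,
    cfg: SimulationConfig,
    quality_key: str = "DR2",
) -> dict:
    """Write truth VCF, imputed VCF and a JSON manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_path = out / "truth.vcf"
    imputed_path = out / "imputed.vcf"
    write_truth_vcf(truth, truth_path)
    write_imputed_vcf(imputed, imputed_path, quality_key=quality_key)
    digest = {
        p.name: hashlib.md5(p.read_bytes()).hexdigest() for p in (truth_path, imputed_path)
    }
    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "n_variants": truth.n_variants,
        "n_samples": truth.n_samples,
        "quality_key": quality_key,
        "files": digest,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
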