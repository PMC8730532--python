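"""Genotype containers, PLINK/dosage-table I/O, and quality control.

Dosages are stored samples x variants as float64 with ``np.nan`` marking
missing calls; non-missing entries are alt-allele counts in {0, 1, 2}.
QC applies the standard per-variant filters (folded MAF, call rate,
Hardy-Weinberg exact test) followed by a per-sample missingness filter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "QCReport",
    "read_genotypes",
    "write_plink",
    "write_dosage_table",
    "hwe_test",
    "hwe_test_chisq",
    "qc_filter",
]


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant; ``maf`` is the folded alt-allele frequency."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """N x M dosage matrix with sample IDs and variant metadata."""

    dosages: np.ndarray
    samples: list[str]
    variants: list[VariantRecord]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants array")
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError(f"{n} dosage rows but {len(self.samples)} sample IDs")
        if m != len(self.variants):
            raise ValueError(f"{m} dosage columns but {len(self.variants)} variants")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample IDs")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != m:
            raise ValueError("duplicate variant IDs")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing (NaN)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Observed alt-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Folded minor allele frequency per variant (always <= 0.5)."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def variant_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        d = self.dosages
        samples = self.samples
        variants = self.variants
        if variant_idx is not None:
            variant_idx = np.asarray(variant_idx)
            d = d[:, variant_idx]
            variants = [variants[i] for i in variant_idx]
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]
            samples = [samples[i] for i in sample_idx]
        return GenotypeMatrix(d.copy(), list(samples), list(variants))


@dataclass
class QCReport:
    """Per-filter removal counts; conserved so removed + retained = input."""

    n_variants_in: int
    n_samples_in: int
    thresholds: dict = field(default_factory=dict)
    variants_removed: dict = field(default_factory=dict)  # filter name -> count
    samples_removed: dict = field(default_factory=dict)
    n_variants_out: int = 0
    n_samples_out: int = 0

    def validate(self) -> None:
        if sum(self.variants_removed.values()) + self.n_variants_out != self.n_variants_in:
            raise AssertionError("variant counts not conserved")
        if sum(self.samples_removed.values()) + self.n_samples_out != self.n_samples_in:
            raise AssertionError("sample counts not conserved")

    def to_json(self, path=None) -> str:
        payload = {
            "input": {"variants": self.n_variants_in, "samples": self.n_samples_in},
            "thresholds": self.thresholds,
            "variants_removed": self.variants_removed,
            "samples_removed": self.samples_removed,
            "retained": {"variants": self.n_variants_out, "samples": self.n_samples_out},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [
            f"Input: {self.n_variants_in} variants, {self.n_samples_in} samples",
            "Variant filters:",
        ]
        for name, count in self.variants_removed.items():
            lines.append(f"  {name}: removed {count}")
        lines.append("Sample filters:")
        for name, count in self.samples_removed.items():
            lines.append(f"  {name}: removed {count}")
        lines.append(
            f"Retained: {self.n_variants_out} variants, {self.n_samples_out} samples"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# PLINK 1.9 binary triple and dosage-table I/O
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))  # SNP-major mode
# 2-bit codes -> alt (A1) allele dosage; 0b01 is the missing code
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_BED_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def _read_plink(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix.with_suffix('.bed')}: bad magic bytes (not SNP-major PLINK 1.9 .bed)")
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise ValueError(
            f"{prefix.with_suffix('.bed')}: size {len(raw)} does not match "
            f"{n} samples x {m} variants (expected {expected})"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
    # unpack 2-bit codes, low bits first within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts) & 0b11  # (m, bytes, 4)
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T  # samples x variants
    variants = [
        VariantRecord(id=r.id, chrom=str(r.chrom), pos=int(r.pos),
                      ref_allele=str(r.a2), alt_allele=str(r.a1))
        for r in bim.itertuples()
    ]
    g = GenotypeMatrix(np.ascontiguousarray(dosages), list(fam["iid"]), variants)
    return _with_observed_maf(g)


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write a SNP-major PLINK 1.9 .bed/.bim/.fam triple."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with prefix.with_suffix(".bim").open("w") as fh:
        for v in g.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.alt_allele}\t{v.ref_allele}\n")
    with prefix.with_suffix(".fam").open("w") as fh:
        for s in g.samples:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    n, m = g.dosages.shape
    codes = np.full((m, n), 0b01, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_BED_CODE.items():
        codes[g.dosages.T == dosage] = code
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    grouped = codes.reshape(m, -1, 4)
    packed = (
        grouped[:, :, 0]
        | (grouped[:, :, 1] << 2)
        | (grouped[:, :, 2] << 4)
        | (grouped[:, :, 3] << 6)
    ).astype(np.uint8)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())


def _read_dosage_table(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    variants = [
        VariantRecord(id=str(c), chrom="0", pos=j + 1, ref_allele="A", alt_allele="B")
        for j, c in enumerate(df.columns)
    ]
    g = GenotypeMatrix(df.to_numpy(dtype=float), [str(s) for s in df.index], variants)
    return _with_observed_maf(g)


def write_dosage_table(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.dosages, index=g.samples, columns=[v.id for v in g.variants])
    df.index.name = "sample"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def _with_observed_maf(g: GenotypeMatrix) -> GenotypeMatrix:
    maf = g.maf()
    g.variants = [replace(v, maf=float(f)) for v, f in zip(g.variants, maf)]
    return g


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Read genotypes from a PLINK triple (path = prefix) or a TSV dosage table.

    The dosage table has one row per sample, a header of variant IDs, and
    "NA" for missing calls.
    """
    path = Path(path)
    if format == "auto":
        format = "plink-bed" if path.with_suffix(".bed").exists() else "dosage-table"
    if format == "plink-bed":
        for ext in (".bed", ".bim", ".fam"):
            if not path.with_suffix(ext).exists():
                raise FileNotFoundError(f"missing PLINK companion file {path.with_suffix(ext)}")
        return _read_plink(path)
    if format == "dosage-table":
        if not path.exists():
            raise FileNotFoundError(str(path))
        return _read_dosage_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on the heterozygote count.

    The p-value sums the probabilities of all heterozygote configurations
    (conditional on allele counts) no more probable than the observed one.
    Monomorphic variants return 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotype call required")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0

    # P(het = h | allele counts) over the reachable lattice h = parity, parity+2, ...
    parity = n_minor % 2
    hets = np.arange(parity, n_minor + 1, 2)
    logp = np.empty_like(hets, dtype=float)
    for i, h in enumerate(hets):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        logp[i] = (
            h * math.log(2.0)
            + math.lgamma(n + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_minor + 1)
            - math.lgamma(hom_major + 1)
            + math.lgamma(n_minor + 1)
            + math.lgamma(2 * n - n_minor + 1)
            - math.lgamma(2 * n + 1)
        )
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[(hets == n_het).nonzero()[0][0]]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-9)].sum()))


def hwe_test_chisq(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Chi-square (1 df) Hardy-Weinberg test; kept as a faster approximation."""
    from scipy.stats import chi2

    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotype call required")
    p = (2 * n_hom_alt + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    stat = ((observed - expected) ** 2 / expected).sum()
    return float(chi2.sf(stat, df=1))


def _hwe_pvalues(g: GenotypeMatrix, use_chisq: bool = False) -> np.ndarray:
    test = hwe_test_chisq if use_chisq else hwe_test
    d = g.dosages
    out = np.empty(g.n_variants)
    for j in range(g.n_variants):
        col = d[:, j]
        col = col[~np.isnan(col)]
        out[j] = test(int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
    return out


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.001,
    variant_missing_max: float = 0.02,
    hwe_alpha: float = 1e-6,
    sample_missing_max: float = 0.05,
    het_outlier_sd: float | None = None,
    hwe_chisq: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply variant filters (MAF, call rate, HWE), then sample filters.

    Variants are removed when folded MAF <= ``maf_min``, missing fraction
    > ``variant_missing_max``, or exact-HWE p < ``hwe_alpha``; each removed
    variant is attributed to the first failing filter in that order. Samples
    with missing fraction >= ``sample_missing_max`` (computed on retained
    variants) are then removed. Optionally, samples whose heterozygosity
    rate deviates more than ``het_outlier_sd`` standard deviations from the
    mean are dropped (off by default).
    """
    if g.n_variants == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(
        n_variants_in=g.n_variants,
        n_samples_in=g.n_samples,
        thresholds={
            "maf_min": maf_min,
            "variant_missing_max": variant_missing_max,
            "hwe_alpha": hwe_alpha,
            "sample_missing_max": sample_missing_max,
            "het_outlier_sd": het_outlier_sd,
        },
    )

    maf = g.maf()
    fail_maf = ~(maf > maf_min)  # NaN-frequency (all-missing) variants also fail
    vmiss = g.variant_missing_rate()
    fail_miss = vmiss > variant_missing_max
    hwe_p = _hwe_pvalues(g, use_chisq=hwe_chisq)
    fail_hwe = hwe_p < hwe_alpha
    report.variants_removed["maf"] = int(fail_maf.sum())
    report.variants_removed["missingness"] = int((fail_miss & ~fail_maf).sum())
    report.variants_removed["hwe"] = int((fail_hwe & ~fail_maf & ~fail_miss).sum())
    keep_v = ~(fail_maf | fail_miss | fail_hwe)
    if not keep_v.any():
        raise ValueError("all variants removed by QC; review thresholds")
    g2 = g.subset(variant_idx=np.flatnonzero(keep_v))

    smiss = g2.sample_missing_rate()
    fail_sample = smiss >= sample_missing_max
    report.samples_removed["missingness"] = int(fail_sample.sum())
    keep_s = ~fail_sample
    if het_outlier_sd is not None:
        obs = ~np.isnan(g2.dosages)
        het = (g2.dosages == 1).sum(axis=1) / obs.sum(axis=1)
        mu, sd = het[keep_s].mean(), het[keep_s].std()
        fail_het = keep_s & (np.abs(het - mu) > het_outlier_sd * sd) if sd > 0 else np.zeros_like(keep_s)
        report.samples_removed["heterozygosity"] = int(fail_het.sum())
        keep_s = keep_s & ~fail_het
    else:
        report.samples_removed["heterozygosity"] = 0
    if not keep_s.any():
        raise ValueError("all samples removed by QC; review thresholds")
    out = g2.subset(sample_idx=np.flatnonzero(keep_s))
    out = _with_observed_maf(out)

    report.n_variants_out = out.n_variants
    report.n_samples_out = out.n_samples
    report.validate()
    return out, report
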