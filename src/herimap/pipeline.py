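"""End-to-end orchestration: QC -> GRM -> PCs -> voxelwise REML -> maps ->
region extraction per arm and fraction -> region-level REML -> summary.

The same GRM and covariates feed both the voxel-level scan and every
region-level re-estimation. All randomness lives in the synthetic
generator; the pipeline itself is deterministic, so identical inputs give
byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix, QCReport, qc_filter, read_genotypes
from .greml import HeritabilityResult, RemlOptions, fit_reml_batch, write_hsq_table
from .grm import GRM, CovariateMatrix, compute_grm, grm_pca, make_covariates
from .regions import (
    RegionQTMatrix,
    RegionSet,
    atlas_regions,
    connected_components,
    region_qts,
    select_voxels,
    smooth_pmap,
)
from .voxelmap import BrainMap, VoxelQTMatrix, devectorize, load_volumes, save_map, vectorize

__all__ = ["PipelineConfig", "PipelineResult", "SummaryTable", "run", "run_pipeline", "summarize"]

log = logging.getLogger(__name__)

_THRESHOLDS = (0.9, 0.8, 0.5, 0.2, 0.1)  # > for the first three, < for the last two


@dataclass
class PipelineConfig:
    genotypes: str | None = None
    genotype_format: str = "auto"
    volumes: list[str] = field(default_factory=list)
    covariates: str | None = None
    atlas: str | None = None
    out_dir: str | None = None
    maf_min: float = 0.001
    variant_missing_max: float = 0.02
    hwe_alpha: float = 1e-6
    sample_missing_max: float = 0.05
    alpha: float = 0.05
    smoothing_sigma: float = 0.5
    significant_fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 1.0)
    insignificant_fractions: tuple[float, ...] = (0.1, 0.2, 0.3)
    connectivity: int = 26
    min_region_voxels: int = 0
    n_pcs: int = 10
    covariate_names: tuple[str, ...] = ("age", "sex")
    reml: RemlOptions = field(default_factory=RemlOptions)
    seed: int = 0

    def __post_init__(self) -> None:
        for f in tuple(self.significant_fractions) + tuple(self.insignificant_fractions):
            if not 0 < f <= 1:
                raise ValueError(f"fraction {f} outside (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "reml" in raw and isinstance(raw["reml"], dict):
            raw["reml"] = RemlOptions(**raw["reml"])
        for key in ("significant_fractions", "insignificant_fractions", "covariate_names"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class ArmResult:
    arm: str
    fraction: float | None
    region_set: RegionSet | None
    region_qt: RegionQTMatrix | None
    results: list[HeritabilityResult]


@dataclass
class SummaryTable:
    """Per (arm, fraction) counts of regions above/below h2 thresholds."""

    table: pd.DataFrame

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"rows": self.table.to_dict(orient="records")},
            indent=2,
            sort_keys=True,
            allow_nan=False,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_markdown(self) -> str:
        """Count(percent) formatting in the style of published ROI tables."""
        lines = ["| arm | fraction | ROI_total | >90% | >80% | >50% | <20% | <10% |",
                 "|---|---|---|---|---|---|---|---|"]
        for _, r in self.table.iterrows():
            cells = [str(r["arm"]), str(r["fraction"]), str(int(r["roi_total"]))]
            for col in ("gt_0.9", "gt_0.8", "gt_0.5", "lt_0.2", "lt_0.1"):
                c = int(r[f"count_{col}"])
                p = 100.0 * r[f"prop_{col}"] if r["roi_total"] else 0.0
                cells.append(f"{c}({p:.1f}%)")
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines)


@dataclass
class PipelineResult:
    qc_report: QCReport
    grm: GRM
    covariates: CovariateMatrix
    vqt: VoxelQTMatrix
    voxel_results: list[HeritabilityResult]
    h2_map: BrainMap
    p_map: BrainMap
    p_map_smoothed: BrainMap
    arms: list[ArmResult]
    summary: SummaryTable
    grm_hash: str


def summarize(
    groups: dict[tuple[str, float | None], list[HeritabilityResult]],
    thresholds: tuple[float, ...] = _THRESHOLDS,
) -> SummaryTable:
    """Count regions with h2 above the high thresholds / below the low ones.

    ``thresholds`` lists high cutoffs first then low cutoffs; a value t
    counts regions with h2 > t when t >= 0.5 and h2 < t otherwise,
    mirroring standard ROI-heritability summary tables.
    """
    rows = []
    for (arm, fraction), results in sorted(
        groups.items(), key=lambda kv: (kv[0][0], -1.0 if kv[0][1] is None else kv[0][1])
    ):
        h2 = np.array([r.h2 for r in results if r.status == "ok"])
        total = len(h2)
        row = {
            "arm": arm,
            "fraction": "all" if fraction is None else fraction,
            "roi_total": total,
        }
        for t in thresholds:
            key = f"gt_{t}" if t >= 0.5 else f"lt_{t}"
            count = int((h2 > t).sum()) if t >= 0.5 else int((h2 < t).sum())
            row[f"count_{key}"] = count
            row[f"prop_{key}"] = (count / total) if total else 0.0
        rows.append(row)
    return SummaryTable(pd.DataFrame(rows))


def _extract_arm(
    arm: str,
    fraction: float,
    p_smooth: BrainMap,
    vqt: VoxelQTMatrix,
    covariates: CovariateMatrix,
    a: GRM,
    config: PipelineConfig,
) -> ArmResult:
    try:
        binary = select_voxels(p_smooth, vqt.index, alpha=config.alpha,
                               top_fraction=fraction, arm=arm)
    except ValueError as exc:
        log.warning("arm=%s fraction=%s: %s", arm, fraction, exc)
        return ArmResult(arm, fraction, None, None, [])
    rs = connected_components(binary, connectivity=config.connectivity)
    if config.min_region_voxels > 1:
        keep = [r for r in rs.region_ids if len(rs.voxels[r]) >= config.min_region_voxels]
        if len(keep) < rs.n_regions:
            lab = rs.labels.volume.copy()
            for rid in set(rs.region_ids) - set(keep):
                lab[lab == rid] = 0
            rs = RegionSet(
                labels=BrainMap(lab, semantics="label", background_fill=0.0),
                region_ids=keep,
                voxels={r: rs.voxels[r] for r in keep},
                provenance=rs.provenance,
            )
    rs.provenance.update(
        {"arm": arm, "top_fraction": fraction, "alpha": config.alpha,
         "smoothing_sigma": config.smoothing_sigma, "connectivity": config.connectivity}
    )
    if rs.n_regions == 0:
        return ArmResult(arm, fraction, rs, None, [])
    rqt = region_qts(rs, vqt)
    results = fit_reml_batch(rqt.values, covariates, a, config.reml)
    for res, rid in zip(results, rqt.region_ids):
        res.trait_id = f"{arm}_f{fraction}_region{rid}"
    return ArmResult(arm, fraction, rs, rqt, results)


def run_pipeline(
    g: GenotypeMatrix,
    volumes: np.ndarray,
    covariates_df: pd.DataFrame | None,
    config: PipelineConfig = PipelineConfig(),
    atlas: BrainMap | None = None,
    sample_ids: list[str] | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    ``volumes`` is (N, X, Y, Z) aligned with ``g.samples`` (or with
    ``sample_ids``); subjects dropped by genotype QC are dropped from the
    phenotypes and covariates as well.
    """
    sample_ids = list(g.samples) if sample_ids is None else list(sample_ids)
    if len(sample_ids) != volumes.shape[0]:
        raise ValueError("sample_ids do not match volume count")
    if covariates_df is not None and len(covariates_df) != len(sample_ids):
        raise ValueError("covariate rows do not match volume count")

    g_qc, report = qc_filter(
        g,
        maf_min=config.maf_min,
        variant_missing_max=config.variant_missing_max,
        hwe_alpha=config.hwe_alpha,
        sample_missing_max=config.sample_missing_max,
    )
    keep = [i for i, s in enumerate(sample_ids) if s in set(g_qc.samples)]
    order = {s: i for i, s in enumerate([sample_ids[i] for i in keep])}
    # reorder phenotype rows to the QC'd genotype sample order
    perm = [keep[order[s]] for s in g_qc.samples]
    volumes = volumes[perm]
    if covariates_df is not None:
        covariates_df = covariates_df.iloc[perm].reset_index(drop=True)
        covariates_df = covariates_df[list(config.covariate_names)]

    a = compute_grm(g_qc)
    grm_hash = hashlib.sha256(np.ascontiguousarray(a.values).tobytes()).hexdigest()
    _, pcs = grm_pca(a, k=config.n_pcs)
    covariates = make_covariates(covariates_df, pcs, n_samples=a.n_samples)

    vqt = vectorize(volumes, samples=g_qc.samples)
    log.info("voxelwise REML over %d voxels, N=%d", vqt.n_voxels, a.n_samples)
    voxel_results = fit_reml_batch(vqt, covariates, a, config.reml)

    h2 = np.array([r.h2 if r.status == "ok" else 0.0 for r in voxel_results])
    pvals = np.array([r.p_value if r.status == "ok" else 1.0 for r in voxel_results])
    h2_map = devectorize(h2, vqt.index, semantics="heritability")
    p_map = devectorize(pvals, vqt.index, semantics="p_value")
    p_smooth = smooth_pmap(p_map, sigma=config.smoothing_sigma)

    arms: list[ArmResult] = []
    for fraction in config.significant_fractions:
        arms.append(_extract_arm("significant", fraction, p_smooth, vqt, covariates, a, config))
    for fraction in config.insignificant_fractions:
        arms.append(_extract_arm("insignificant", fraction, p_smooth, vqt, covariates, a, config))
    if atlas is not None:
        rs, rqt = atlas_regions(atlas, vqt)
        results = fit_reml_batch(rqt.values, covariates, a, config.reml)
        for res, rid in zip(results, rqt.region_ids):
            res.trait_id = f"atlas_region{rid}"
        arms.append(ArmResult("atlas", None, rs, rqt, results))

    summary = summarize({(ar.arm, ar.fraction): ar.results for ar in arms})
    return PipelineResult(
        qc_report=report, grm=a, covariates=covariates, vqt=vqt,
        voxel_results=voxel_results, h2_map=h2_map, p_map=p_map,
        p_map_smoothed=p_smooth, arms=arms, summary=summary, grm_hash=grm_hash,
    )


def run(config: PipelineConfig) -> PipelineResult:
    """Load inputs from the paths in ``config``, run, persist outputs."""
    from .voxelmap import load_map

    if config.genotypes is None or not config.volumes:
        raise ValueError("config must provide genotype and volume paths")
    g = read_genotypes(config.genotypes, format=config.genotype_format)
    volumes, affine = load_volumes(config.volumes)
    covars = None
    if config.covariates is not None:
        covars = pd.read_csv(config.covariates, sep="\t", index_col=0)
    atlas = load_map(config.atlas, semantics="label") if config.atlas else None
    result = run_pipeline(g, volumes, covars, config=config, atlas=atlas)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.qc_report.to_json(out / "qc_report.json")
        save_map(result.h2_map, out / "h2_map.nii.gz", affine)
        save_map(result.p_map, out / "p_map.nii.gz", affine)
        save_map(result.p_map_smoothed, out / "p_map_smoothed.nii.gz", affine)
        write_hsq_table(result.voxel_results, out / "voxel_heritability.tsv")
        for ar in result.arms:
            tag = ar.arm if ar.fraction is None else f"{ar.arm}_f{ar.fraction}"
            if ar.region_set is not None:
                ar.region_set.export(out / f"regions_{tag}.nii.gz",
                                     out / f"regions_{tag}.json", affine)
            if ar.results:
                write_hsq_table(ar.results, out / f"region_heritability_{tag}.tsv")
        result.summary.to_json(out / "summary.json")
        (out / "summary.md").write_text(result.summary.to_markdown() + "\n")
    return result
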