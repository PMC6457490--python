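"""End-to-end pipeline runs: ChIP binding-region calling and expression DE.

The ChIP stages run in order: QC flag filter -> dye-orientation correction
-> scale normalization -> strain averaging -> enrichment calling ->
clustering -> gene annotation -> peak-shape classification. The expression
stages: QC flag filter -> orientation -> median centering -> scale
normalization -> per-gene averaging -> Rank Product -> DE selection ->
cluster counting. Every run writes a JSON manifest serializing all
parameters and the RNG seed, sufficient to re-run any stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binding import (
    BindingRegion,
    ClusterParams,
    EnrichedProbeSet,
    ShapeParams,
    annotate_regions,
    call_enriched_probes,
    classify_peak_shape,
    cluster_regions,
    probe_midpoint,
)
from .de import RankProductResult, count_in_cluster, gene_signals, rank_product_test, select_de
from .io import (
    GenomeAnnotation,
    SignalBundle,
    read_annotation,
    read_signal_table,
    write_de_table,
    write_regions_bed,
)
from .preprocess import (
    FilterReport,
    apply_flag_filter,
    median_center,
    orient_matrix,
    scale_normalize,
    strain_average,
)

DEFAULT_CLUSTER_RANGES = {
    "cda": ("SCO3210", "SCO3249"),
    "act": ("SCO5071", "SCO5092"),
}
DEFAULT_CLUSTER_EXCLUSIONS = {"SCO3226"}  # the deleted gene itself


@dataclass
class ChipResult:
    """Everything the ChIP pipeline computes for one timepoint."""

    timepoint: float
    regions: list[BindingRegion]
    enriched: EnrichedProbeSet
    filter_report: FilterReport
    probe_table: pd.DataFrame  # per-locus profile (Fig-style columns)
    scale_factors: np.ndarray


def _strain_columns(samples: pd.DataFrame, strain: str) -> np.ndarray:
    mask = (samples["strain"] == strain).to_numpy()
    cols = np.flatnonzero(mask)
    reps = samples["replicate"].to_numpy()[cols]
    return cols[np.argsort(reps)]  # pair replicates by index


def call_binding_regions(
    bundle: SignalBundle,
    annotation: GenomeAnnotation,
    timepoint: float,
    strains: tuple[str, str] = ("complemented", "deleted"),
    cluster_params: ClusterParams | None = None,
    shape_params: ShapeParams | None = None,
    promoter_window: int = 300,
    on_degenerate_scale: str = "unit",
) -> ChipResult:
    """Run the full ChIP calling chain for one timepoint.

    ``strains`` is (complemented_label, deleted_label). Scale normalization
    treats all-background arrays (zero median absolute value) as carrying
    no scale information (factor 1) rather than aborting.
    """
    cluster_params = cluster_params or ClusterParams()
    shape_params = shape_params or ShapeParams()
    comp_label, del_label = strains

    report = apply_flag_filter(bundle, timepoint, assay="chip")
    sub = bundle.subset_samples(
        (bundle.samples["timepoint"] == timepoint) & (bundle.samples["assay"] == "chip")
    )
    sub = sub.drop_probes(report.excluded_probe_ids)

    oriented = orient_matrix(sub)
    norm = scale_normalize(oriented, on_degenerate=on_degenerate_scale)

    comp_cols = _strain_columns(sub.samples, comp_label)
    del_cols = _strain_columns(sub.samples, del_label)
    if len(comp_cols) == 0 or len(del_cols) == 0:
        raise ValueError(f"strain labels {strains} not found at timepoint {timepoint}")

    probe_ids = sub.probes["probe_id"].to_numpy()
    enriched = call_enriched_probes(
        norm.values[:, comp_cols], norm.values[:, del_cols], probe_ids
    )

    positions = probe_midpoint(sub.probes["start"].to_numpy(), sub.probes["end"].to_numpy())
    probe_table = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": sub.probes["chrom"].to_numpy(),
            "position": positions,
            "start": sub.probes["start"].to_numpy(),
            "end": sub.probes["end"].to_numpy(),
            f"mean_{comp_label}": strain_average(norm.values, sub.samples, comp_label),
            f"mean_{del_label}": strain_average(norm.values, sub.samples, del_label),
            "fold_change": enriched.fold_change,
            "is_candidate": enriched.is_candidate,
            "is_enriched": enriched.is_enriched,
        }
    )

    enriched_df = probe_table.loc[probe_table["is_enriched"]].copy()
    regions = cluster_regions(enriched_df, cluster_params)
    regions = annotate_regions(regions, annotation, promoter_window=promoter_window)

    spacing = float(np.median(np.diff(positions))) if len(positions) > 1 else 1.0
    for region in regions:
        lo = region.start - cluster_params.max_gap
        hi = region.end + cluster_params.max_gap
        window = (positions >= lo) & (positions <= hi)
        classify_peak_shape(
            region,
            positions[window],
            enriched.fold_change[window],
            enriched.threshold,
            params=shape_params,
            probe_spacing=spacing,
        )
    return ChipResult(
        timepoint=timepoint,
        regions=regions,
        enriched=enriched,
        filter_report=report,
        probe_table=probe_table,
        scale_factors=norm.scale_factors,
    )


@dataclass
class ExpressionResult:
    """Everything the expression pipeline computes for one timepoint."""

    timepoint: float
    gene_matrix: pd.DataFrame
    rank_product: RankProductResult
    de: dict[str, list[str]]
    counts: pd.DataFrame  # (cluster, direction) -> count
    filter_report: FilterReport


def run_expression_timepoint(
    bundle: SignalBundle,
    annotation: GenomeAnnotation,
    timepoint: float,
    strains: tuple[str, str] = ("complemented", "deleted"),
    n_permutations: int = 1000,
    seed: int = 0,
    pfp_cutoff: float = 0.15,
    cluster_ranges: dict[str, tuple[str, str]] | None = None,
    cluster_exclusions: set[str] | None = None,
) -> ExpressionResult:
    """Run the expression chain for one timepoint and count DE genes per
    biosynthetic cluster range."""
    comp_label, del_label = strains
    cluster_ranges = cluster_ranges if cluster_ranges is not None else DEFAULT_CLUSTER_RANGES
    cluster_exclusions = (
        cluster_exclusions if cluster_exclusions is not None else set(DEFAULT_CLUSTER_EXCLUSIONS)
    )

    report = apply_flag_filter(bundle, timepoint, assay="expression")
    sub = bundle.subset_samples(
        (bundle.samples["timepoint"] == timepoint) & (bundle.samples["assay"] == "expression")
    )
    oriented = orient_matrix(sub)
    centered = median_center(oriented)
    norm = scale_normalize(centered, on_degenerate="unit")

    genes = gene_signals(norm.values, sub.probes, annotation, report)
    value_cols = [c for c in genes.columns if c != "n_probes"]
    comp_cols = [value_cols[i] for i in _strain_columns(sub.samples, comp_label)]
    del_cols = [value_cols[i] for i in _strain_columns(sub.samples, del_label)]

    result = rank_product_test(
        genes[comp_cols].to_numpy(),
        genes[del_cols].to_numpy(),
        n_permutations=n_permutations,
        seed=seed,
        gene_ids=genes.index.to_numpy(),
    )
    de = select_de(result, pfp_cutoff=pfp_cutoff)

    rows = []
    for name, rng_ids in cluster_ranges.items():
        for direction in ("up", "down"):
            rows.append(
                {
                    "timepoint": timepoint,
                    "cluster": name,
                    "direction": direction,
                    "count": count_in_cluster(de[direction], rng_ids, cluster_exclusions),
                }
            )
    counts = pd.DataFrame(rows, columns=["timepoint", "cluster", "direction", "count"])
    return ExpressionResult(
        timepoint=timepoint,
        gene_matrix=genes,
        rank_product=result,
        de=de,
        counts=counts,
        filter_report=report,
    )


# ---------------------------------------------------------------------------
# file-level orchestration


@dataclass
class RunConfig:
    """Serializable configuration for a file-level pipeline run."""

    signals: str
    samples: str
    annotation: str
    outdir: str
    timepoints: list[float] = field(default_factory=list)  # empty = all in sheet
    strains: tuple[str, str] = ("complemented", "deleted")
    max_gap: int = 1000
    min_probes: int = 2
    cluster_method: str = "gap"
    smooth_window: int = 3
    min_prominence_frac: float = 0.25
    promoter_window: int = 300
    n_permutations: int = 1000
    seed: int = 0
    pfp_cutoff: float = 0.15
    cluster_ranges: dict = field(default_factory=lambda: dict(DEFAULT_CLUSTER_RANGES))
    cluster_exclusions: list = field(default_factory=lambda: sorted(DEFAULT_CLUSTER_EXCLUSIONS))

    def validate_paths(self) -> None:
        for name in ("signals", "samples", "annotation"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")


def _write_manifest(config: RunConfig, stage: str, outputs: dict[str, str]) -> Path:
    outdir = Path(config.outdir)
    manifest = {
        "tool": "chipchip",
        "version": __version__,
        "stage": stage,
        "config": asdict(config),
        "outputs": outputs,
    }
    path = outdir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _tp_label(tp: float) -> str:
    return str(int(tp)) if float(tp).is_integer() else str(tp)


def run_chip_pipeline(config: RunConfig) -> dict[float, ChipResult]:
    """File-level ChIP run: per timepoint, write regions BED, probe report
    and per-locus profile TSV, plus a manifest."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = read_signal_table(config.signals, config.samples)
    annotation = read_annotation(config.annotation)
    cluster_params = ClusterParams(
        max_gap=config.max_gap, min_probes=config.min_probes, method=config.cluster_method
    )
    shape_params = ShapeParams(
        smooth_window=config.smooth_window, min_prominence_frac=config.min_prominence_frac
    )
    timepoints = config.timepoints or sorted(
        bundle.samples.loc[bundle.samples["assay"] == "chip", "timepoint"].unique()
    )
    results: dict[float, ChipResult] = {}
    outputs: dict[str, str] = {}
    for tp in timepoints:
        res = call_binding_regions(
            bundle,
            annotation,
            tp,
            strains=config.strains,
            cluster_params=cluster_params,
            shape_params=shape_params,
            promoter_window=config.promoter_window,
        )
        label = _tp_label(tp)
        bed = outdir / f"regions_t{label}.bed"
        write_regions_bed(res.regions, bed)
        probe_report = outdir / f"probes_t{label}.tsv"
        res.probe_table.to_csv(probe_report, sep="\t", index=False, float_format="%.6f")
        region_tsv = outdir / f"regions_t{label}.tsv"
        _regions_frame(res.regions).to_csv(region_tsv, sep="\t", index=False)
        outputs[f"regions_bed_t{label}"] = str(bed)
        outputs[f"probe_report_t{label}"] = str(probe_report)
        outputs[f"regions_tsv_t{label}"] = str(region_tsv)
        results[tp] = res
    _write_manifest(config, "chip", outputs)
    return results


def _regions_frame(regions: list[BindingRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_probes": r.n_probes,
                "max_fold_change": round(r.max_fold_change, 6),
                "shape": r.shape,
                "summits": ",".join(f"{s:g}" for s in r.summits),
                "overlapping_genes": ",".join(r.overlapping_genes),
                "location_class": r.location_class or "",
            }
        )
    cols = ["region_id", "chrom", "start", "end", "n_probes", "max_fold_change",
            "shape", "summits", "overlapping_genes", "location_class"]
    return pd.DataFrame(rows, columns=cols)


def run_expression_pipeline(config: RunConfig) -> dict[float, ExpressionResult]:
    """File-level expression run: per timepoint, write the per-gene matrix,
    DE table and cluster-count summary, plus a manifest."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = read_signal_table(config.signals, config.samples)
    annotation = read_annotation(config.annotation)
    timepoints = config.timepoints or sorted(
        bundle.samples.loc[bundle.samples["assay"] == "expression", "timepoint"].unique()
    )
    results: dict[float, ExpressionResult] = {}
    outputs: dict[str, str] = {}
    all_counts = []
    for tp in timepoints:
        res = run_expression_timepoint(
            bundle,
            annotation,
            tp,
            strains=config.strains,
            n_permutations=config.n_permutations,
            seed=config.seed,
            pfp_cutoff=config.pfp_cutoff,
            cluster_ranges={k: tuple(v) for k, v in config.cluster_ranges.items()},
            cluster_exclusions=set(config.cluster_exclusions),
        )
        label = _tp_label(tp)
        gene_tsv = outdir / f"genes_t{label}.tsv"
        res.gene_matrix.to_csv(gene_tsv, sep="\t", float_format="%.6f")
        de_tsv = outdir / f"de_t{label}.tsv"
        write_de_table(res.rank_product.table, de_tsv)
        outputs[f"gene_matrix_t{label}"] = str(gene_tsv)
        outputs[f"de_table_t{label}"] = str(de_tsv)
        all_counts.append(res.counts)
        results[tp] = res
    counts_tsv = outdir / "cluster_counts.tsv"
    pd.concat(all_counts, ignore_index=True).to_csv(counts_tsv, sep="\t", index=False)
    outputs["cluster_counts"] = str(counts_tsv)
    _write_manifest(config, "expression", outputs)
    return results
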