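"""Ground-truthed synthetic two-strain tiling-array datasets.

Emulates the study design the pipeline expects: a complemented strain
(regulator restored from a tagged construct) and a deletion strain, each
in two biological replicates labelled in opposite Cy-dye orientations,
sampled at three timepoints across growth (defaults 14, 18, 35 h), on a
fixed-step tiling array. ChIP samples carry log2(IP/mock) ratios with
Gaussian binding-site profiles spiked into the complemented strain only;
expression samples carry log2(cDNA/gDNA) ratios with per-gene differential
effects realized on all probes overlapping the gene.

The generator is the benchmark's ground truth: identical (config, truth,
seed) yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GenomeAnnotation,
    SignalBundle,
    write_annotation_gff3,
    write_sample_sheet,
    write_signal_table,
)

CHROM = "chr"
INTERGENIC_EXPRESSION = -2.0  # log2(cDNA/gDNA) background off genes


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults emulate the real experiment at desk scale: a 100 kb genome
    slice tiled at 80 bp with 60-mer probes (the full experiment used ~105K
    probes over an 8.7 Mb genome at comparable density), two strains x two
    dye-swapped replicates x three timepoints, log2-scale Gaussian noise
    with sd 0.3, and a small per-array dye bias.
    """

    genome_length: int = 100_000
    n_genes: int = 60
    probe_spacing: int = 80
    probe_length: int = 60
    strains: tuple[str, str] = ("complemented", "deleted")  # first = complemented
    replicates_per_strain: int = 2
    timepoints: tuple[float, ...] = (14.0, 18.0, 35.0)
    noise_sd: float = 0.3
    dye_bias: float = 0.1  # per-array offset drawn uniform in +/- this
    flag_rate: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")
        if self.genome_length < 10 * self.probe_spacing:
            raise ValueError("genome_length must be >= 10 x probe_spacing")
        if self.replicates_per_strain < 2:
            raise ValueError(
                "replicates_per_strain must be >= 2 (candidate rule needs paired replicates)"
            )
        if len(self.strains) != 2 or len(set(self.strains)) != 2:
            raise ValueError("exactly two distinct strain labels required")
        if self.noise_sd < 0 or self.dye_bias < 0:
            raise ValueError("noise_sd and dye_bias must be >= 0")
        if not (0 <= self.flag_rate <= 1):
            raise ValueError("flag_rate must be a probability")

    @property
    def complemented(self) -> str:
        return self.strains[0]

    @property
    def deleted(self) -> str:
        return self.strains[1]


@dataclass
class TrueRegion:
    """A spiked binding site: one Gaussian peak, or two for biphasic shapes.

    ``center`` is the first (major) peak center; biphasic regions add a
    second peak of relative height ``amplitude_ratio`` at
    ``center + peak_separation``.
    """

    center: int
    shape: str = "monophasic"
    amplitude: float = 2.0
    width: float = 120.0  # Gaussian sigma, bp
    peak_separation: float = 0.0
    amplitude_ratio: float = 0.5
    active_timepoints: tuple[float, ...] | None = None  # None = all

    def __post_init__(self) -> None:
        if self.shape not in ("monophasic", "biphasic"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.shape == "biphasic" and self.peak_separation <= 0:
            raise ValueError("biphasic regions require peak_separation > 0")
        if not (0 < self.amplitude_ratio <= 1):
            raise ValueError("amplitude_ratio must be in (0, 1]")

    def active_at(self, timepoint: float) -> bool:
        return self.active_timepoints is None or timepoint in self.active_timepoints

    @property
    def last_center(self) -> float:
        return self.center + (self.peak_separation if self.shape == "biphasic" else 0.0)


@dataclass
class TrueDE:
    """A spiked expression effect: positive log2_effect = higher in the
    complemented strain at the given timepoint."""

    gene_id: str
    timepoint: float
    log2_effect: float


def spike_profile(region: TrueRegion, probe_positions: np.ndarray) -> np.ndarray:
    """Evaluate a region's log2 enrichment profile at probe positions.

    Monophasic: ``A * exp(-(p - c)^2 / (2 w^2))``; biphasic adds a second
    Gaussian of height ``A * amplitude_ratio`` at ``c + peak_separation``.
    Nonnegative everywhere. Positions must be sorted ascending.
    """
    if region.width <= 0:
        raise ValueError("width must be > 0")
    p = np.asarray(probe_positions, dtype=float)
    if np.any(np.diff(p) < 0):
        raise ValueError("probe positions must be sorted ascending")
    out = region.amplitude * np.exp(-((p - region.center) ** 2) / (2 * region.width**2))
    if region.shape == "biphasic":
        c2 = region.center + region.peak_separation
        out = out + region.amplitude * region.amplitude_ratio * np.exp(
            -((p - c2) ** 2) / (2 * region.width**2)
        )
    return out


def make_probes(config: SimConfig) -> pd.DataFrame:
    """Fixed-step tiling layout: probes every ``probe_spacing`` bp."""
    starts = np.arange(1, config.genome_length - config.probe_length + 2, config.probe_spacing)
    return pd.DataFrame(
        {
            "probe_id": [f"probe_{i:05d}" for i in range(len(starts))],
            "chrom": CHROM,
            "start": starts.astype(int),
            "end": (starts + config.probe_length - 1).astype(int),
        }
    )


def make_annotation(config: SimConfig) -> GenomeAnnotation:
    """Deterministic gene layout with divergent pairs.

    Genes occupy ~70% of evenly spaced slots; strands alternate -, +, so
    every even/odd pair is divergent and shares its intergenic region
    (mirroring divergent promoter pairs in the source genome).
    """
    slot = config.genome_length // config.n_genes
    gene_len = max(int(round(0.7 * slot)), 1)
    margin = (slot - gene_len) // 2
    rows = []
    for i in range(config.n_genes):
        start = i * slot + margin + 1
        end = min(start + gene_len - 1, config.genome_length)
        rows.append(
            {
                "gene_id": f"SCO{1001 + i}",
                "chrom": CHROM,
                "start": start,
                "end": end,
                "strand": "-" if i % 2 == 0 else "+",
            }
        )
    return GenomeAnnotation(genes=pd.DataFrame(rows))


def default_truth_regions(config: SimConfig | None = None) -> list[TrueRegion]:
    """Twelve spiked regions (8 monophasic, 4 biphasic) spread over the genome.

    One center sits in the first divergent intergenic region and the rest
    fall inside or near genes, mirroring the promoter-proximal, divergent
    and gene-internal binding cases the caller must resolve.
    """
    config = config or SimConfig()
    lo, hi = int(0.05 * config.genome_length), int(0.92 * config.genome_length)
    centers = np.linspace(lo, hi, 12).astype(int)
    # first center on the first divergent intergenic midpoint
    ann = make_annotation(config)
    if len(ann) >= 2:
        g0, g1 = ann.genes.iloc[0], ann.genes.iloc[1]
        centers[0] = int((g0.end + g1.start) / 2)
    regions = []
    for i, c in enumerate(centers):
        if i % 3 == 2 and sum(1 for r in regions if r.shape == "biphasic") < 4:
            regions.append(
                TrueRegion(center=int(c), shape="biphasic", amplitude=2.0,
                           width=120.0, peak_separation=600.0, amplitude_ratio=0.5)
            )
        else:
            regions.append(TrueRegion(center=int(c), shape="monophasic", amplitude=2.0, width=120.0))
    return regions


def default_truth_de(
    config: SimConfig | None = None,
    n_de: int = 6,
    effect: float = 1.5,
    timepoint: float | None = None,
) -> list[TrueDE]:
    """Evenly spread DE genes, alternating up/down in the complemented strain."""
    config = config or SimConfig()
    ann = make_annotation(config)
    tps = config.timepoints
    idx = np.linspace(0, len(ann) - 1, n_de).astype(int)
    out = []
    for j, i in enumerate(idx):
        gid = ann.genes["gene_id"].iloc[int(i)]
        tp = timepoint if timepoint is not None else tps[j % len(tps)]
        out.append(TrueDE(gene_id=gid, timepoint=tp, log2_effect=effect if j % 2 == 0 else -effect))
    return out


def _dye_for_rep(rep: int) -> str:
    """Opposite Cy-dye orientations for paired replicates."""
    return "Cy5" if rep % 2 == 1 else "Cy3"


def simulate_dataset(
    config: SimConfig,
    truth_regions: list[TrueRegion] | None = None,
    truth_de: list[TrueDE] | None = None,
) -> tuple[SignalBundle, SignalBundle, GenomeAnnotation, dict]:
    """Generate paired ChIP and expression bundles with known ground truth.

    Returns (chip_bundle, expression_bundle, annotation, truth) where
    ``truth`` holds the region and DE truth tables as DataFrames.
    """
    truth_regions = truth_regions if truth_regions is not None else []
    truth_de = truth_de if truth_de is not None else []

    probes = make_probes(config)
    annotation = make_annotation(config)
    positions = ((probes["start"] + probes["end"]) / 2.0).to_numpy()
    n_probes = len(probes)

    for r in truth_regions:
        if not (1 <= r.center <= config.genome_length and 1 <= r.last_center <= config.genome_length):
            raise ValueError(
                f"truth region at center {r.center} extends outside genome [1, {config.genome_length}]"
            )
    known_genes = set(annotation.genes["gene_id"])
    for d in truth_de:
        if d.gene_id not in known_genes:
            raise ValueError(f"truth DE gene {d.gene_id!r} not in generated annotation")
        if d.timepoint not in config.timepoints:
            raise ValueError(f"truth DE timepoint {d.timepoint} not in config timepoints")

    rng = np.random.default_rng(config.rng_seed)

    # per-gene baseline expression (biological structure, not noise)
    baselines = rng.normal(0.0, 1.0, size=len(annotation))
    gene_by_id = dict(zip(annotation.genes["gene_id"], range(len(annotation))))

    # probe -> overlapping gene indices (fixed layout, computed directly)
    gene_starts = annotation.genes["start"].to_numpy()
    gene_ends = annotation.genes["end"].to_numpy()
    probe_genes: list[np.ndarray] = []
    for ps, pe in zip(probes["start"], probes["end"]):
        hit = np.flatnonzero((gene_starts <= pe) & (gene_ends >= ps))
        probe_genes.append(hit)

    effects: dict[tuple[float, int], float] = {}
    for d in truth_de:
        effects[(d.timepoint, gene_by_id[d.gene_id])] = d.log2_effect

    def build_bundle(assay: str) -> SignalBundle:
        sample_rows = []
        cols_raw = []
        cols_flags = []
        for tp in config.timepoints:
            spike = np.zeros(n_probes)
            if assay == "chip":
                for r in truth_regions:
                    if r.active_at(tp):
                        spike = spike + spike_profile(r, positions)
            expr_base = None
            if assay == "expression":
                expr_base = np.full(n_probes, INTERGENIC_EXPRESSION)
                for i, hit in enumerate(probe_genes):
                    if len(hit):
                        expr_base[i] = float(np.mean(baselines[hit]))
            for strain in config.strains:
                for rep in range(1, config.replicates_per_strain + 1):
                    if assay == "chip":
                        oriented = np.zeros(n_probes)
                        if strain == config.complemented:
                            oriented = oriented + spike
                    else:
                        oriented = expr_base.copy()
                        if strain == config.complemented:
                            for i, hit in enumerate(probe_genes):
                                if len(hit):
                                    eff = [effects.get((tp, g), 0.0) for g in hit]
                                    oriented[i] += float(np.mean(eff))
                    if config.noise_sd > 0:
                        oriented = oriented + rng.normal(0.0, config.noise_sd, size=n_probes)
                    dye = _dye_for_rep(rep)
                    raw = oriented if dye == "Cy5" else -oriented
                    if config.dye_bias > 0:
                        raw = raw + rng.uniform(-config.dye_bias, config.dye_bias)
                    if config.flag_rate > 0:
                        fl = rng.random((n_probes, 2)) < config.flag_rate
                    else:
                        fl = np.zeros((n_probes, 2), dtype=bool)
                    tp_label = int(tp) if float(tp).is_integer() else tp
                    sample_rows.append(
                        {
                            "sample_id": f"{assay}_{strain}_t{tp_label}_r{rep}",
                            "strain": strain,
                            "timepoint": tp,
                            "replicate": rep,
                            "assay": assay,
                            "ip_dye": dye,
                        }
                    )
                    cols_raw.append(raw)
                    cols_flags.append(fl)
        return SignalBundle(
            probes=probes.copy(),
            samples=pd.DataFrame(sample_rows),
            raw_log2=np.column_stack(cols_raw),
            flags=np.stack(cols_flags, axis=1),
        )

    chip = build_bundle("chip")
    expr = build_bundle("expression")

    truth = {
        "regions": truth_regions_frame(truth_regions),
        "de": truth_de_frame(truth_de),
    }
    return chip, expr, annotation, truth


def truth_regions_frame(truth_regions: list[TrueRegion]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(truth_regions, 1):
        rows.append(
            {
                "region_id": f"truth_{i:03d}",
                "chrom": CHROM,
                "center": r.center,
                "shape": r.shape,
                "amplitude": r.amplitude,
                "width": r.width,
                "peak_separation": r.peak_separation if r.shape == "biphasic" else 0.0,
                "amplitude_ratio": r.amplitude_ratio if r.shape == "biphasic" else 1.0,
                "active_timepoints": (
                    "all" if r.active_timepoints is None
                    else ",".join(str(t) for t in r.active_timepoints)
                ),
                "span_start": int(r.center - 2 * r.width),
                "span_end": int(r.last_center + 2 * r.width),
            }
        )
    cols = ["region_id", "chrom", "center", "shape", "amplitude", "width",
            "peak_separation", "amplitude_ratio", "active_timepoints",
            "span_start", "span_end"]
    return pd.DataFrame(rows, columns=cols)


def truth_de_frame(truth_de: list[TrueDE]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": d.gene_id, "timepoint": d.timepoint, "log2_effect": d.log2_effect}
         for d in truth_de],
        columns=["gene_id", "timepoint", "log2_effect"],
    )


def write_truth(truth: dict, outdir: str | Path) -> None:
    """Write region truth as BED (0-based half-open) + TSV, and DE truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions = truth["regions"]
    regions.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)
    with open(outdir / "truth_regions.bed", "w") as fh:
        for r in regions.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{max(r.span_start - 1, 0)}\t{r.span_end}\t"
                f"{r.region_id}:{r.shape}\t0\t.\n"
            )
    truth["de"].to_csv(outdir / "truth_de.tsv", sep="\t", index=False)


def write_simulated_dataset(
    config: SimConfig,
    outdir: str | Path,
    truth_regions: list[TrueRegion] | None = None,
    truth_de: list[TrueDE] | None = None,
) -> dict[str, Path]:
    """Generate and write a full dataset (signals, sheets, GFF3, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chip, expr, annotation, truth = simulate_dataset(config, truth_regions, truth_de)
    paths = {
        "chip_signals": outdir / "chip_signals.tsv",
        "chip_samples": outdir / "chip_samples.tsv",
        "expression_signals": outdir / "expression_signals.tsv",
        "expression_samples": outdir / "expression_samples.tsv",
        "annotation": outdir / "genes.gff3",
    }
    write_signal_table(chip, paths["chip_signals"])
    write_sample_sheet(chip.samples, paths["chip_samples"])
    write_signal_table(expr, paths["expression_signals"])
    write_sample_sheet(expr.samples, paths["expression_samples"])
    write_annotation_gff3(annotation, paths["annotation"])
    write_truth(truth, outdir)
    paths["truth_regions_tsv"] = outdir / "truth_regions.tsv"
    paths["truth_regions_bed"] = outdir / "truth_regions.bed"
    paths["truth_de"] = outdir / "truth_de.tsv"
    return paths
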