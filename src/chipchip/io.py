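"""Readers and writers for the probe-signal dialect, annotation and results.

Internal coordinates are 1-based inclusive throughout (GFF3/GenBank
convention of the source genome); BED output is 0-based half-open and the
conversion happens only here.

The probe-signal table is a TSV with header columns ``probe_id``, ``chrom``,
``start``, ``end`` followed, for every sample declared in a sidecar sample
sheet, by three columns: ``<sample_id>`` (raw log2(Cy5/Cy3) value),
``<sample_id>.flag_cy3`` and ``<sample_id>.flag_cy5`` (0/1 QC flags, any
nonzero integer is truthy). The sample sheet is a TSV with columns
``sample_id``, ``strain``, ``timepoint``, ``replicate``, ``assay``,
``ip_dye``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end"]
SHEET_COLUMNS = ["sample_id", "strain", "timepoint", "replicate", "assay", "ip_dye"]
DYES = ("Cy3", "Cy5")
ASSAYS = ("chip", "expression")

_FLOAT_FMT = "%.6f"


class FormatError(ValueError):
    """Malformed input file; readers reject rather than silently repair."""


@dataclass
class SignalBundle:
    """Probe x sample matrix of raw log2(Cy5/Cy3) values with QC flags.

    ``raw_log2`` has shape (n_probes, n_samples); ``flags`` has shape
    (n_probes, n_samples, 2) with channel order (Cy3, Cy5).
    """

    probes: pd.DataFrame
    samples: pd.DataFrame
    raw_log2: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        self.probes = self.probes.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        validate_probes(self.probes)
        validate_samples(self.samples)
        n_p, n_s = len(self.probes), len(self.samples)
        if self.raw_log2.shape != (n_p, n_s):
            raise FormatError(
                f"raw_log2 shape {self.raw_log2.shape} does not match "
                f"{n_p} probes x {n_s} samples"
            )
        if self.flags.shape != (n_p, n_s, 2):
            raise FormatError(
                f"flags shape {self.flags.shape} must be ({n_p}, {n_s}, 2)"
            )
        self.flags = self.flags.astype(bool)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        idx = self.samples.index[self.samples["sample_id"] == sample_id]
        if len(idx) != 1:
            raise KeyError(f"sample {sample_id!r} not found")
        return int(idx[0])

    def subset_samples(self, mask: Sequence[bool] | pd.Series) -> "SignalBundle":
        mask = np.asarray(mask, dtype=bool)
        return SignalBundle(
            probes=self.probes.copy(),
            samples=self.samples.loc[mask].copy(),
            raw_log2=self.raw_log2[:, mask].copy(),
            flags=self.flags[:, mask, :].copy(),
        )

    def drop_probes(self, probe_ids: Iterable[str]) -> "SignalBundle":
        drop = set(probe_ids)
        keep = ~self.probes["probe_id"].isin(drop).to_numpy()
        return SignalBundle(
            probes=self.probes.loc[keep].copy(),
            samples=self.samples.copy(),
            raw_log2=self.raw_log2[keep, :].copy(),
            flags=self.flags[keep, :, :].copy(),
        )


@dataclass
class GenomeAnnotation:
    """Gene models with 1-based inclusive coordinates on one chromosome."""

    genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand"]
        )
    )

    def __post_init__(self) -> None:
        g = self.genes.reset_index(drop=True)
        if len(g):
            if g["gene_id"].duplicated().any():
                dups = g.loc[g["gene_id"].duplicated(), "gene_id"].tolist()
                raise FormatError(f"duplicate gene_id(s): {dups}")
            bad = g.loc[g["start"] > g["end"], "gene_id"].tolist()
            if bad:
                raise FormatError(f"gene(s) with start > end: {bad}")
            unknown = set(g["strand"]) - {"+", "-"}
            if unknown:
                raise FormatError(f"unknown strand value(s): {sorted(unknown)}")
            g = g.sort_values("start", kind="stable").reset_index(drop=True)
        self.genes = g

    def __len__(self) -> int:
        return len(self.genes)


def validate_probes(probes: pd.DataFrame) -> None:
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise FormatError(f"probe table missing column(s): {missing}")
    if probes["probe_id"].duplicated().any():
        dups = probes.loc[probes["probe_id"].duplicated(), "probe_id"].tolist()
        raise FormatError(f"duplicate probe_id(s): {dups}")
    bad = probes.loc[probes["start"] > probes["end"], "probe_id"].tolist()
    if bad:
        raise FormatError(f"probe(s) with start > end: {bad}")


def validate_samples(samples: pd.DataFrame) -> None:
    missing = [c for c in SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"sample sheet missing column(s): {missing}")
    if samples["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample sheet")
    key = samples[["strain", "timepoint", "replicate", "assay"]]
    if key.duplicated().any():
        raise FormatError("duplicate (strain, timepoint, replicate, assay) in sample sheet")
    bad_dye = set(samples["ip_dye"]) - set(DYES)
    if bad_dye:
        raise FormatError(f"unknown dye label(s): {sorted(bad_dye)}; expected {DYES}")
    bad_assay = set(samples["assay"]) - set(ASSAYS)
    if bad_assay:
        raise FormatError(f"unknown assay label(s): {sorted(bad_assay)}")


def _flag_cols(sample_id: str) -> tuple[str, str]:
    return f"{sample_id}.flag_cy3", f"{sample_id}.flag_cy5"


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "strain": str})
    validate_samples(sheet)
    return sheet


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_signal_table(path: str | Path, sample_sheet: str | Path | pd.DataFrame) -> SignalBundle:
    """Read the probe-signal TSV against its sample sheet.

    Raises :class:`FormatError` naming the offending row or column on any
    malformation (missing column, duplicate probe_id, non-numeric value).
    """
    if isinstance(sample_sheet, (str, Path)):
        samples = read_sample_sheet(sample_sheet)
    else:
        samples = sample_sheet.copy()
        validate_samples(samples)

    table = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = [c for c in PROBE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")

    sample_ids = samples["sample_id"].tolist()
    for sid in sample_ids:
        for col in (sid, *_flag_cols(sid)):
            if col not in table.columns:
                raise FormatError(
                    f"{path}: sample sheet references column {col!r} absent from table"
                )

    probes = table[PROBE_COLUMNS].copy()
    validate_probes(probes)

    values = np.empty((len(table), len(sample_ids)), dtype=float)
    flags = np.empty((len(table), len(sample_ids), 2), dtype=bool)
    for j, sid in enumerate(sample_ids):
        col = pd.to_numeric(table[sid], errors="coerce")
        bad = col.isna() & table[sid].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {table[sid].iloc[row]!r} "
                f"in column {sid!r}, row {row + 2}"
            )
        values[:, j] = col.to_numpy()
        c3, c5 = _flag_cols(sid)
        for k, fc in enumerate((c3, c5)):
            fcol = pd.to_numeric(table[fc], errors="coerce")
            if fcol.isna().any():
                row = int(np.flatnonzero(fcol.isna().to_numpy())[0])
                raise FormatError(
                    f"{path}: non-numeric flag in column {fc!r}, row {row + 2}"
                )
            flags[:, j, k] = fcol.to_numpy() != 0

    return SignalBundle(probes=probes, samples=samples, raw_log2=values, flags=flags)


def write_signal_table(bundle: SignalBundle, path: str | Path) -> None:
    """Write the canonical probe-signal TSV (values to 6 decimal places)."""
    out = bundle.probes[PROBE_COLUMNS].copy()
    for j, sid in enumerate(bundle.samples["sample_id"]):
        out[sid] = [_FLOAT_FMT % v if np.isfinite(v) else "nan" for v in bundle.raw_log2[:, j]]
        c3, c5 = _flag_cols(sid)
        out[c3] = bundle.flags[:, j, 0].astype(int)
        out[c5] = bundle.flags[:, j, 1].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation

_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise FormatError(f"malformed GFF3 attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Read gene models from GFF3 (``gene`` features) or a 5-column TSV.

    GFF3 coordinates are 1-based inclusive per the standard and are kept
    exactly. The TSV dialect has columns gene_id, chrom, start, end, strand
    with a header. An empty annotation parses to an empty gene list.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
                rec = dict(zip(_GFF_COLS, parts))
                if rec["type"] != "gene":
                    continue
                attrs = _parse_gff_attributes(rec["attributes"])
                gene_id = attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Name")
                if gene_id is None:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID attribute")
                try:
                    start, end = int(rec["start"]), int(rec["end"])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
                rows.append(
                    {"gene_id": gene_id, "chrom": rec["seqid"], "start": start,
                     "end": end, "strand": rec["strand"]}
                )
        genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    else:
        genes = pd.read_csv(
            path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str}
        )
        missing = [c for c in ["gene_id", "chrom", "start", "end", "strand"] if c not in genes.columns]
        if missing:
            raise FormatError(f"{path}: annotation TSV missing column(s) {missing}")
    return GenomeAnnotation(genes=genes)


def write_annotation_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in annotation.genes.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\tchipchip\tgene\t{rec.start}\t{rec.end}\t.\t{rec.strand}\t.\t"
                f"ID={rec.gene_id}\n"
            )


def write_annotation_tsv(annotation: GenomeAnnotation, path: str | Path) -> None:
    annotation.genes.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# regions / DE output

def bed_score(max_fold_change: float) -> int:
    """Scale a log2 fold change to the 0-1000 BED score range (x100, clipped)."""
    if not np.isfinite(max_fold_change):
        return 0
    return int(np.clip(round(100 * max_fold_change), 0, 1000))


def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """Write binding regions as BED6, 0-based half-open, sorted by chromStart."""
    recs = sorted(regions, key=lambda r: (r.chrom, r.start - 1, r.end))
    with open(path, "w") as fh:
        for r in recs:
            name = f"{r.region_id}:{r.shape}"
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{bed_score(r.max_fold_change)}\t.\n"
            )


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 back into 1-based inclusive internal coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected >=6 BED columns")
            chrom, cstart, cend, name, score, strand = parts[:6]
            rows.append(
                {"chrom": chrom, "start": int(cstart) + 1, "end": int(cend),
                 "name": name, "score": int(score), "strand": strand}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_de_table(result: pd.DataFrame, path: str | Path) -> None:
    """Write per-gene, per-direction Rank Product results as TSV."""
    cols = ["gene_id", "direction", "RP", "rank", "pfp"]
    out = result[cols].copy()
    out["RP"] = out["RP"].map(lambda v: _FLOAT_FMT % v)
    out["pfp"] = out["pfp"].map(lambda v: _FLOAT_FMT % v)
    out.to_csv(path, sep="\t", index=False)
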