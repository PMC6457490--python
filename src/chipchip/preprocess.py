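"""Probe QC filtering, dye-orientation correction and normalization.

The two-color design hybridizes the IP (ChIP) or cDNA (expression) channel
against a mock-IP or genomic-DNA reference, with biological replicates
labelled in opposite Cy-dye orientations. All stages here operate on log2
ratios.

Stage order differs by assay: ChIP matrices are scale-normalized only;
expression matrices are median-centered within each array first, then
scale-normalized across arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DYES, SignalBundle

REASON_BOTH_STRAINS = "both_strains"
REASON_MORE_THAN_TWO = "more_than_two"


@dataclass
class FilterReport:
    """Probes excluded by the QC flag rule, with the reason per probe.

    Reasons: ``both_strains`` (flagged in >=1 sample of each strain) or
    ``more_than_two`` (flagged in more than two samples of the timepoint).
    ``both_strains`` takes precedence when both apply.
    """

    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def excluded_probe_ids(self) -> set[str]:
        return set(self.reasons)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.reasons.items()), columns=["probe_id", "reason"]
        )


def apply_flag_filter(bundle: SignalBundle, timepoint: float, assay: str | None = None) -> FilterReport:
    """Apply the per-timepoint QC exclusion rule.

    A sample counts as flagged for a probe iff *both* channels are flagged.
    A probe is excluded iff it is flagged in at least one sample of each
    strain, or in more than two samples at the timepoint.
    """
    samples = bundle.samples
    mask = samples["timepoint"] == timepoint
    if assay is not None:
        mask &= samples["assay"] == assay
    if not mask.any():
        raise ValueError(f"timepoint {timepoint!r} absent from bundle")
    cols = np.flatnonzero(mask.to_numpy())
    strains = samples["strain"].to_numpy()[cols]
    uniq_strains = pd.unique(strains)

    # sample flagged iff both channels flagged
    flagged = bundle.flags[:, cols, 0] & bundle.flags[:, cols, 1]  # probes x k

    n_flagged = flagged.sum(axis=1)
    per_strain_any = np.column_stack(
        [flagged[:, strains == s].any(axis=1) for s in uniq_strains]
    )
    both_strains = per_strain_any.all(axis=1) & (len(uniq_strains) >= 2)
    more_than_two = n_flagged > 2

    reasons: dict[str, str] = {}
    probe_ids = bundle.probes["probe_id"].to_numpy()
    for i in np.flatnonzero(both_strains | more_than_two):
        reasons[probe_ids[i]] = (
            REASON_BOTH_STRAINS if both_strains[i] else REASON_MORE_THAN_TWO
        )
    return FilterReport(reasons=reasons)


def orient_ratio(raw_log2: float | np.ndarray, ip_dye: str):
    """Orient a raw log2(Cy5/Cy3) ratio so positive means IP/cDNA-enriched.

    ``ip_dye`` names the dye carrying the IP (ChIP) or cDNA (expression)
    channel; when it is Cy3 the raw ratio is sign-flipped.
    """
    if ip_dye == "Cy5":
        return raw_log2
    if ip_dye == "Cy3":
        return -np.asarray(raw_log2) if isinstance(raw_log2, np.ndarray) else -raw_log2
    raise ValueError(f"unknown dye label {ip_dye!r}; expected one of {DYES}")


def orient_matrix(bundle: SignalBundle) -> np.ndarray:
    """Orientation-correct every sample column of a bundle's raw matrix."""
    out = bundle.raw_log2.astype(float).copy()
    for j, dye in enumerate(bundle.samples["ip_dye"]):
        out[:, j] = orient_ratio(out[:, j], dye)
    return out


@dataclass
class NormalizedMatrix:
    """Scale-normalized oriented log2 matrix with per-array diagnostics."""

    values: np.ndarray
    scale_factors: np.ndarray
    medians: np.ndarray  # per-array median(|x|) before scaling


def scale_normalize(matrix: np.ndarray, on_degenerate: str = "error") -> NormalizedMatrix:
    """Equalize the median absolute log2 value across arrays.

    For each array (column) ``a``, ``m_a = median(|x_a|)`` over non-missing
    values; every array is rescaled by ``g / m_a`` where ``g`` is the
    geometric mean of the ``m_a``, so that after scaling all arrays share
    median absolute value ``g``.

    ``on_degenerate`` controls arrays with ``m_a == 0`` (no scale
    information): "error" rejects them; "unit" assigns them scale factor 1
    and excludes them from the geometric mean.
    """
    if on_degenerate not in ("error", "unit"):
        raise ValueError(f"on_degenerate must be 'error' or 'unit', got {on_degenerate!r}")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 1:
        raise ValueError("need a 2-D matrix with at least one array (column)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        m = np.nanmedian(np.abs(matrix), axis=0)
    degenerate = ~np.isfinite(m) | (m == 0)
    if degenerate.any() and on_degenerate == "error":
        bad = np.flatnonzero(degenerate).tolist()
        raise ValueError(f"degenerate array(s) with zero median absolute value: columns {bad}")
    good = ~degenerate
    if good.any():
        g = float(np.exp(np.mean(np.log(m[good]))))
    else:
        g = 1.0
    factors = np.ones_like(m)
    factors[good] = g / m[good]
    return NormalizedMatrix(values=matrix * factors, scale_factors=factors, medians=m)


def median_center(matrix: np.ndarray) -> np.ndarray:
    """Subtract each array's median ("global median within array")."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("empty matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(matrix, axis=0)
    if not np.isfinite(med).all():
        raise ValueError("array with no finite values cannot be median-centered")
    return matrix - med


def strain_average(
    values: np.ndarray, samples: pd.DataFrame, strain: str, timepoint: float | None = None
) -> np.ndarray:
    """Per-probe arithmetic mean over a strain's replicates.

    Replicates must already be orientation-corrected and normalized. A probe
    missing in one replicate averages over the remaining ones; missing in
    all replicates propagates as NaN.
    """
    mask = samples["strain"] == strain
    if timepoint is not None:
        mask &= samples["timepoint"] == timepoint
    cols = np.flatnonzero(mask.to_numpy())
    if len(cols) == 0:
        raise ValueError(f"no replicates for strain {strain!r}"
                         + (f" at timepoint {timepoint!r}" if timepoint is not None else ""))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        return np.nanmean(values[:, cols], axis=1)
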