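"""Missing-value imputation, replicate collapsing and feature normalization.

Each peak is ultimately represented as a mean-centered unit vector over the
samples (one element per sample, replicates averaged first), together with a
replicate-noise estimate on that normalized scale.  The noise estimate is
the pooled variance of the duplicate pairs, (rep1 - rep2)^2 / 2 averaged
over samples, multiplied by the squared normalization factor so that it is
commensurate with the unit-vector elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFeatureError, ImputationError
from .io_tables import PeakRecord, PeakTable, SampleDesign

#: floor applied to noise variances when used as inverse weights
NOISE_FLOOR = 1e-12


@dataclass(frozen=True)
class NormalizedFeature:
    """A peak's mean-centered unit vector over samples plus its noise.

    ``scale`` is the factor applied to the centered replicate means to reach
    unit norm (1/||centered||); ``noise_var`` is the pooled duplicate-pair
    variance rescaled by ``scale**2``.
    """

    peak_id: tuple[str, str, str, str]
    vector: np.ndarray
    scale: float
    noise_var: float

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", vec)
        assert abs(float(vec.sum())) < 1e-9 * max(1.0, vec.size)
        assert abs(float(np.linalg.norm(vec)) - 1.0) < 1e-9
        if not (self.noise_var >= 0):
            raise ValueError(f"negative noise_var {self.noise_var}")


# ---------------------------------------------------------------------------
# imputation


def _table_matrix(table: PeakTable) -> np.ndarray:
    """Peaks x replicate-columns matrix (column order = design order)."""
    design = table.design
    n_cols = 2 * len(design.sample_ids)
    mat = np.empty((len(table.peaks), n_cols))
    for i, peak in enumerate(table.peaks):
        for j, sid in enumerate(design.sample_ids):
            r1, r2 = peak.intensities[sid]
            mat[i, 2 * j] = r1
            mat[i, 2 * j + 1] = r2
    return mat


def impute_missing(table: PeakTable, k: int = 10) -> PeakTable:
    """Fill missing replicate cells by k-nearest-neighbor over peaks.

    For a missing cell (peak *i*, replicate column *c*): candidate donor
    peaks are those observed in *c*; distance to each candidate is the
    Euclidean distance over the replicate columns where both peaks are
    observed; the imputed value is the mean of the *k* nearest candidates'
    values in *c* (ties broken by ascending distance, then ascending mass,
    then label).  ``k`` is capped at the number of available candidates.
    Non-missing cells are returned untouched.
    """
    if k < 1:
        raise ImputationError(f"k must be >= 1, got {k}")
    mat = _table_matrix(table)
    if not np.isnan(mat).any():
        return table
    observed = ~np.isnan(mat)
    all_missing = np.where(~observed.any(axis=1))[0]
    if all_missing.size:
        labels = [table.peaks[i].display_label for i in all_missing]
        raise ImputationError(f"peaks with no observed values: {labels}")

    filled = mat.copy()
    masses = np.array([p.mass_da for p in table.peaks])
    labels = [p.mass_label for p in table.peaks]
    for i in range(mat.shape[0]):
        missing_cols = np.where(~observed[i])[0]
        if missing_cols.size == 0:
            continue
        for c in missing_cols:
            candidates = []
            for j in range(mat.shape[0]):
                if j == i or not observed[j, c]:
                    continue
                joint = observed[i] & observed[j]
                if not joint.any():
                    continue
                diff = mat[i, joint] - mat[j, joint]
                dist = float(np.sqrt(np.sum(diff * diff)))
                candidates.append((dist, masses[j], labels[j], mat[j, c]))
            if not candidates:
                raise ImputationError(
                    f"no donor peaks for cell ({table.peaks[i].display_label}, column {c})"
                )
            candidates.sort(key=lambda t: (t[0], t[1], t[2]))
            top = candidates[: min(k, len(candidates))]
            filled[i, c] = float(np.mean([t[3] for t in top]))

    design = table.design
    peaks = []
    for i, peak in enumerate(table.peaks):
        intens = {}
        for j, sid in enumerate(design.sample_ids):
            intens[sid] = (float(filled[i, 2 * j]), float(filled[i, 2 * j + 1]))
        peaks.append(
            PeakRecord(
                fraction=peak.fraction,
                surface=peak.surface,
                energy=peak.energy,
                mass_label=peak.mass_label,
                mass_da=peak.mass_da,
                intensities=intens,
            )
        )
    return PeakTable(peaks, design)


# ---------------------------------------------------------------------------
# replicate collapsing and normalization


def replicate_means(record: PeakRecord, design: SampleDesign) -> np.ndarray:
    """Per-sample arithmetic mean of the duplicate pair (design sample order)."""
    out = np.empty(len(design.sample_ids))
    for j, sid in enumerate(design.sample_ids):
        r1, r2 = record.intensities[sid]
        out[j] = 0.5 * (r1 + r2)
    return out


def normalize_feature(record: PeakRecord, design: SampleDesign) -> NormalizedFeature:
    """Build the mean-centered unit vector and its replicate-noise estimate.

    Raises :class:`DegenerateFeatureError` when the replicate-mean vector is
    constant (zero centering norm); callers exclude such peaks from
    clustering with a warning.
    """
    means = replicate_means(record, design)
    if np.isnan(means).any():
        raise ImputationError(
            f"peak {record.display_label} still has missing values; impute first"
        )
    centered = means - means.mean()
    norm = float(np.linalg.norm(centered))
    if norm <= 0 or not math.isfinite(norm):
        raise DegenerateFeatureError(
            f"peak {record.display_label} has a constant intensity vector"
        )
    scale = 1.0 / norm
    pair_sq = np.empty(len(design.sample_ids))
    for j, sid in enumerate(design.sample_ids):
        r1, r2 = record.intensities[sid]
        pair_sq[j] = (r1 - r2) ** 2 / 2.0
    noise_var = scale**2 * float(pair_sq.mean())
    return NormalizedFeature(
        peak_id=record.peak_id,
        vector=centered * scale,
        scale=scale,
        noise_var=noise_var,
    )
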