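"""Ratio CV test, cluster formation and noise-weighted centroids.

Two candidate peaks are declared technical aliases when the per-sample
ratio of their intensities is nearly constant: the coefficient of variation
(CV) of the ratios across samples falls strictly below a user threshold.
Passing pairs from the four search steps form the edges of a graph whose
connected components (size >= 2) are the technical clusters.

Each cluster is replaced by a centroid: a weighted average of the members'
mean-centered unit vectors, re-centered and re-normalized.  Member weights
are inversely proportional to each member's total variance about the
cluster — its replicate-measurement noise plus its squared distance from
the centroid — so a member that merely rides along (e.g. one whose sample
identities were scrambled) contributes almost nothing even when its
replicate noise is small.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .alias_search import (
    DEFAULT_MAX_MULTIPLE,
    CandidatePair,
    MassWindowTable,
    applicable_steps,
    generate_candidates,
)
from .errors import DegenerateClusterError, DegenerateFeatureError, NotTestableError
from .io_tables import PeakTable, SampleDesign
from .preprocess import NOISE_FLOOR, NormalizedFeature, normalize_feature, replicate_means

logger = logging.getLogger(__name__)

#: samples whose denominator is below this fraction of the max are excluded
_DENOM_EPS = 1e-9
#: the CV is +inf (pair untestable in practice) beyond this excluded fraction
_MAX_EXCLUDED_FRAC = 0.2
#: lack-of-fit refinement passes: the first cleans the provisional centroid
#: of ill-fitting members, the second measures misfit against the cleaned
#: centroid; further passes would progressively concentrate weight on the
#: single best-fitting member, which is not the intent
_CENTROID_PASSES = 2


def _cv_of_ratios(numer: np.ndarray, denom: np.ndarray) -> float:
    """CV of per-sample ratios numer/denom with small-denominator exclusion."""
    numer = np.asarray(numer, dtype=float)
    denom = np.asarray(denom, dtype=float)
    usable = denom >= _DENOM_EPS * float(np.max(denom, initial=0.0))
    n_usable = int(usable.sum())
    if n_usable < 3:
        raise NotTestableError(f"only {n_usable} usable samples")
    if n_usable < (1.0 - _MAX_EXCLUDED_FRAC) * denom.size:
        return math.inf
    ratios = numer[usable] / denom[usable]
    mean = float(ratios.mean())
    if mean <= 0:
        return math.inf
    sd = float(ratios.std(ddof=1))
    return sd / mean


def ratio_cv(
    intensities_a: np.ndarray,
    intensities_b: np.ndarray,
    mass_a: Optional[float] = None,
    mass_b: Optional[float] = None,
) -> float:
    """Coefficient of variation of the per-sample intensity ratio of a pair.

    The ratio is oriented so the denominator is the vector with the larger
    grand mean (on a tie, the lower-mass peak when masses are given,
    otherwise the second vector): this keeps the denominator away from
    zero.  Samples whose denominator is ~0 are excluded; the CV is +inf if
    more than 20% of samples were excluded or the mean ratio is <= 0.
    Raises :class:`NotTestableError` below 3 usable samples.
    """
    a = np.asarray(intensities_a, dtype=float)
    b = np.asarray(intensities_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("intensity vectors must cover the same samples")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if mean_a > mean_b:
        numer, denom = b, a
    elif mean_b > mean_a:
        numer, denom = a, b
    else:  # tie: denominator is the lower-mass peak
        if mass_a is not None and mass_b is not None and mass_a < mass_b:
            numer, denom = b, a
        else:
            numer, denom = a, b
    return _cv_of_ratios(numer, denom)


def test_pair(pair: CandidatePair, table: PeakTable, threshold: float) -> bool:
    """Whether a candidate pair passes the ratio CV test (strict inequality)."""
    design = table.design
    rec_a = table.get(pair.peak_a)
    rec_b = table.get(pair.peak_b)
    try:
        cv = ratio_cv(
            replicate_means(rec_a, design),
            replicate_means(rec_b, design),
            rec_a.mass_da,
            rec_b.mass_da,
        )
    except NotTestableError:
        return False
    return cv < threshold


# ---------------------------------------------------------------------------
# centroids


def compute_centroid(
    members: Sequence[NormalizedFeature],
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-weighted centroid of >= 2 normalized features, plus the weights.

    A provisional centroid is formed with weights proportional to
    1/noise_var (floored); two refinement passes then set
    ``w_i ∝ 1 / (noise_var_i + ||v_i - c||^2)`` — inverse total variance
    about the cluster — re-mean-centering and rescaling the centroid to
    unit norm each pass.  For mutually proportional members the
    lack-of-fit term vanishes and the weights reduce exactly to
    normalized 1/noise_var.
    """
    if len(members) < 2:
        raise DegenerateClusterError("a cluster needs >= 2 members")
    vectors = np.stack([m.vector for m in members])
    noise = np.maximum([m.noise_var for m in members], NOISE_FLOOR)

    def _combine(weights: np.ndarray) -> np.ndarray:
        c = weights @ vectors
        c = c - c.mean()
        norm = float(np.linalg.norm(c))
        if norm <= 1e-12 or not math.isfinite(norm):
            raise DegenerateClusterError("weighted member sum has zero norm")
        return c / norm

    weights = (1.0 / noise) / np.sum(1.0 / noise)
    centroid = _combine(weights)
    for _ in range(_CENTROID_PASSES):
        lack_of_fit = np.sum((vectors - centroid) ** 2, axis=1)
        weights = 1.0 / (noise + lack_of_fit)
        weights = weights / weights.sum()
        centroid = _combine(weights)
    return centroid, weights


@dataclass
class Cluster:
    """A technical cluster: members, weights, centroid and noise bookkeeping."""

    cluster_id: str
    members: list[tuple[str, str, str, str]]
    weights: np.ndarray
    centroid: np.ndarray
    member_noise: np.ndarray
    group_cvs: Optional[Mapping[tuple, Mapping[str, float]]] = None

    def __post_init__(self) -> None:
        assert len(self.members) >= 2
        assert abs(float(np.sum(self.weights)) - 1.0) < 1e-9
        assert np.all(np.asarray(self.weights) > 0)


def group_variance_report(
    cluster: Cluster, table: PeakTable, design: SampleDesign
) -> dict[tuple, dict[str, float]]:
    """Informational per-member, per-group ratio CVs against the anchor member.

    Each member is compared (ratio CV) with the cluster's highest-weight
    member, restricted to each group's samples.  Groups with fewer than 3
    samples yield NaN.  Never used for clustering itself.
    """
    anchor_idx = int(np.argmax(cluster.weights))
    anchor = table.get(cluster.members[anchor_idx])
    anchor_means = replicate_means(anchor, design)
    sample_pos = {sid: i for i, sid in enumerate(design.sample_ids)}
    out: dict[tuple, dict[str, float]] = {}
    for member_id in cluster.members:
        rec = table.get(member_id)
        means = replicate_means(rec, design)
        per_group: dict[str, float] = {}
        for g in design.group_labels:
            idx = [sample_pos[s] for s in design.samples_in_group(g)]
            if len(idx) < 3:
                per_group[g] = math.nan
                continue
            try:
                per_group[g] = ratio_cv(
                    means[idx], anchor_means[idx], rec.mass_da, anchor.mass_da
                )
            except NotTestableError:
                per_group[g] = math.nan
        out[member_id] = per_group
    return out


# ---------------------------------------------------------------------------
# clustering driver


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


@dataclass
class ClusteringResult:
    """Clusters plus the peaks (and degenerate peaks) left unclustered."""

    clusters: list[Cluster]
    unclustered: list[tuple[str, str, str, str]]
    features: dict[tuple, NormalizedFeature]
    degenerate: list[tuple[str, str, str, str]]
    passing_pairs: list[CandidatePair]
    steps_run: list[int]
    steps_skipped: list[int]

    @property
    def n_clustered_peaks(self) -> int:
        return sum(len(c.members) for c in self.clusters)

    @property
    def n_features_out(self) -> int:
        """Features after clustering: centroids plus unclustered peaks."""
        return len(self.clusters) + len(self.unclustered)

    def output_features(self):
        """(feature_id, vector) pairs: cluster centroids then unclustered peaks."""
        for cluster in self.clusters:
            yield cluster.cluster_id, cluster.centroid
        for pid in self.unclustered:
            yield "_".join(pid), self.features[pid].vector


def run_clustering(
    table: PeakTable,
    threshold: float,
    windows: Optional[MassWindowTable] = None,
    max_multiple: int = DEFAULT_MAX_MULTIPLE,
) -> ClusteringResult:
    """Run the four-step alias search plus CV test and form clusters.

    Candidates from every applicable step are CV-tested; passing pairs are
    edges and clusters are the connected components of size >= 2
    (single linkage).  The table must be imputation-complete.  Clusters are
    ordered by smallest member mass and labelled ``cluster_001`` onward;
    members are ordered by (mass, fraction, surface, energy).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    windows = windows or MassWindowTable()
    design = table.design

    features: dict[tuple, NormalizedFeature] = {}
    degenerate: list[tuple] = []
    for peak in table.peaks:
        try:
            features[peak.peak_id] = normalize_feature(peak, design)
        except DegenerateFeatureError:
            logger.warning(
                "peak %s has a constant vector; excluded from clustering",
                peak.display_label,
            )
            degenerate.append(peak.peak_id)

    applicable = applicable_steps(table)
    steps_run = [s for s in (1, 2, 3, 4) if applicable[s]]
    steps_skipped = [s for s in (1, 2, 3, 4) if not applicable[s]]

    passing: list[CandidatePair] = []
    for step in steps_run:
        for pair in generate_candidates(table, step, windows, max_multiple):
            if pair.peak_a in features and pair.peak_b in features:
                if test_pair(pair, table, threshold):
                    passing.append(pair)

    index = {p.peak_id: i for i, p in enumerate(table.peaks)}
    uf = _UnionFind(len(table.peaks))
    for pair in passing:
        uf.union(index[pair.peak_a], index[pair.peak_b])
    components: dict[int, list] = {}
    for peak in table.peaks:
        if peak.peak_id in features:
            components.setdefault(uf.find(index[peak.peak_id]), []).append(peak)

    raw_clusters = [c for c in components.values() if len(c) >= 2]
    raw_clusters.sort(key=lambda c: min(p.mass_da for p in c))
    width = max(3, len(str(len(raw_clusters))))

    clusters: list[Cluster] = []
    clustered_ids: set[tuple] = set()
    rank = 0
    for group in raw_clusters:
        group.sort(key=lambda p: (p.mass_da, p.fraction, p.surface, p.energy))
        member_feats = [features[p.peak_id] for p in group]
        try:
            centroid, weights = compute_centroid(member_feats)
        except DegenerateClusterError:
            logger.warning(
                "cluster of %s dissolved: degenerate centroid",
                [p.display_label for p in group],
            )
            continue
        rank += 1
        cluster = Cluster(
            cluster_id=f"cluster_{rank:0{width}d}",
            members=[p.peak_id for p in group],
            weights=weights,
            centroid=centroid,
            member_noise=np.array([f.noise_var for f in member_feats]),
        )
        if design.groups is not None:
            cluster.group_cvs = group_variance_report(cluster, table, design)
        clusters.append(cluster)
        clustered_ids.update(cluster.members)

    unclustered = [
        p.peak_id
        for p in table.peaks
        if p.peak_id in features and p.peak_id not in clustered_ids
    ]
    return ClusteringResult(
        clusters=clusters,
        unclustered=unclustered,
        features=features,
        degenerate=degenerate,
        passing_pairs=passing,
        steps_run=steps_run,
        steps_skipped=steps_skipped,
    )
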