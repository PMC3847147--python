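"""Reading, validating and writing SELDI peak tables and sample designs.

A peak table is a delimited text file (tab or comma separated, auto-detected
from the header line) whose rows are detected peaks.  The first four columns
carry the acquisition condition and the vendor mass label — ``fraction``,
``energy``, ``surface`` and ``mass`` — followed by one intensity column per
replicate spectrum.  Samples are measured in duplicate; the mapping from
intensity columns to samples, replicate slots and (optional) comparison
groups lives in a separate design file with columns
``column_name, sample_id, replicate_index[, group]``.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, MassLabelError, TableFormatError

logger = logging.getLogger(__name__)

#: column names (canonical order) of the four annotation columns
ANNOTATION_COLUMNS = ("fraction", "energy", "surface", "mass")

_VENDOR_LABEL_RE = re.compile(r"^C(\d+)_*$")


def parse_mass_label(label: str) -> float:
    """Convert a vendor-style mass label to a mass in Daltons.

    The vendor's export writes peak identifiers such as
    ``Fx4_CM10_high_C066628_``: the final underscore-delimited token is a
    ``C`` followed by zero-padded digits holding the apparent m/z in whole
    Daltons (trailing underscores are padding).  Plain numeric labels pass
    through unchanged.

    >>> parse_mass_label("C066628_")
    66628.0
    >>> parse_mass_label("5000")
    5000.0
    """
    text = str(label).strip()
    if not text:
        raise MassLabelError("empty mass label")
    # plain number (vendor sometimes exports bare m/z)
    try:
        value = float(text)
    except ValueError:
        pass
    else:
        if value <= 0 or not math.isfinite(value):
            raise MassLabelError(f"non-positive mass label: {label!r}")
        return value
    # vendor token: last underscore-delimited 'C' + digits chunk
    token = text.rstrip("_").split("_")[-1] + "_" * (len(text) - len(text.rstrip("_")))
    match = _VENDOR_LABEL_RE.match(token)
    if match is None:
        raise MassLabelError(f"cannot parse mass from label: {label!r}")
    value = float(int(match.group(1)))
    if value <= 0:
        raise MassLabelError(f"non-positive mass in label: {label!r}")
    return value


def format_mass_label(mass_da: float) -> str:
    """Render a mass as a vendor-style 8-character label (``C066628_``)."""
    digits = "0" + str(int(round(mass_da)))
    return ("C" + digits).ljust(8, "_")


@dataclass(frozen=True)
class PeakRecord:
    """One detected peak: its acquisition condition, mass and intensities.

    ``intensities`` maps sample id -> (rep1, rep2); missing replicate values
    are ``nan`` (never silently zero).
    """

    fraction: str
    surface: str
    energy: str
    mass_label: str
    mass_da: float
    intensities: Mapping[str, tuple[float, float]]

    @property
    def peak_id(self) -> tuple[str, str, str, str]:
        return (self.fraction, self.surface, self.energy, self.mass_label)

    @property
    def display_label(self) -> str:
        return f"{self.fraction}_{self.surface}_{self.energy}_{self.mass_label}"

    def __post_init__(self) -> None:
        if not (self.mass_da > 0):
            raise TableFormatError(
                f"peak {self.mass_label!r} has non-positive mass {self.mass_da}"
            )


@dataclass(frozen=True)
class SampleDesign:
    """Sample identifiers, duplicate-column pairing and optional groups."""

    sample_ids: tuple[str, ...]
    replicate_columns: Mapping[str, tuple[str, str]]
    groups: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.sample_ids) < 3:
            raise DesignError(f"need >= 3 samples, got {len(self.sample_ids)}")
        if set(self.sample_ids) != set(self.replicate_columns):
            raise DesignError("sample_ids and replicate_columns disagree")
        seen: set[str] = set()
        for sid in self.sample_ids:
            pair = self.replicate_columns[sid]
            if len(pair) != 2 or pair[0] == pair[1]:
                raise DesignError(f"sample {sid!r} needs two distinct replicate columns")
            for col in pair:
                if col in seen:
                    raise DesignError(f"column {col!r} assigned to more than one sample")
                seen.add(col)
        if self.groups is not None:
            if set(self.groups) != set(self.sample_ids):
                raise DesignError("group labels must cover exactly the design samples")
            counts: dict[str, int] = {}
            for g in self.groups.values():
                counts[g] = counts.get(g, 0) + 1
            if len(counts) < 2 or any(n < 2 for n in counts.values()):
                raise DesignError("need >= 2 groups each with >= 2 samples")

    @property
    def group_labels(self) -> tuple[str, ...]:
        if self.groups is None:
            return ()
        return tuple(sorted(set(self.groups.values())))

    def samples_in_group(self, group: str) -> tuple[str, ...]:
        if self.groups is None:
            raise DesignError("design has no groups")
        return tuple(s for s in self.sample_ids if self.groups[s] == group)

    @property
    def intensity_columns(self) -> tuple[str, ...]:
        cols: list[str] = []
        for sid in self.sample_ids:
            cols.extend(self.replicate_columns[sid])
        return tuple(cols)


@dataclass
class PeakTable:
    """An ordered collection of peaks plus the sample design."""

    peaks: list[PeakRecord]
    design: SampleDesign
    _index: dict[tuple, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for i, peak in enumerate(self.peaks):
            if peak.peak_id in self._index:
                raise TableFormatError(f"duplicate peak identity: {peak.peak_id}")
            self._index[peak.peak_id] = i
            missing = set(self.design.sample_ids) - set(peak.intensities)
            if missing:
                raise TableFormatError(
                    f"peak {peak.display_label} lacks samples {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def get(self, peak_id: tuple) -> PeakRecord:
        return self.peaks[self._index[peak_id]]

    def index_of(self, peak_id: tuple) -> int:
        return self._index[peak_id]

    def replace(self, peak_id: tuple, record: PeakRecord) -> "PeakTable":
        """Return a new table with one peak replaced (identity preserved)."""
        peaks = list(self.peaks)
        peaks[self._index[peak_id]] = record
        return PeakTable(peaks, self.design)


# ---------------------------------------------------------------------------
# reading


def _sniff_separator(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_design(path) -> SampleDesign:
    """Read a sample design file (column_name, sample_id, replicate_index[, group])."""
    with open(path, "r", encoding="utf-8") as fh:
        sep = _sniff_separator(fh.readline())
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"column_name", "sample_id", "replicate_index"}
    if not required.issubset(df.columns):
        raise DesignError(f"design file must have columns {sorted(required)}")
    sample_ids: list[str] = []
    reps: dict[str, dict[int, str]] = {}
    groups: dict[str, str] = {}
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        if sid not in reps:
            reps[sid] = {}
            sample_ids.append(sid)
        idx = int(row.replicate_index)
        if idx not in (1, 2):
            raise DesignError(f"replicate_index must be 1 or 2, got {idx}")
        if idx in reps[sid]:
            raise DesignError(f"duplicate replicate {idx} for sample {sid!r}")
        reps[sid][idx] = str(row.column_name)
        if "group" in df.columns and not pd.isna(getattr(row, "group")):
            groups[sid] = str(row.group)
    incomplete = [s for s, r in reps.items() if set(r) != {1, 2}]
    if incomplete:
        raise DesignError(f"samples without a full duplicate pair: {incomplete}")
    return SampleDesign(
        sample_ids=tuple(sample_ids),
        replicate_columns={s: (r[1], r[2]) for s, r in reps.items()},
        groups=groups if groups else None,
    )


def _parse_cell(value, column: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    text = str(value).strip()
    if text == "" or text.upper() in ("NA", "NAN"):
        return math.nan
    try:
        x = float(text)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric intensity {value!r} in column {column!r}") from exc
    if x < 0:
        logger.warning("negative intensity %g in column %s clamped to 0", x, column)
        x = 0.0
    return x


def read_peak_table(path, design_path) -> PeakTable:
    """Read and validate a delimited peak table against its design file."""
    design = read_design(design_path)
    with open(path, "r", encoding="utf-8") as fh:
        sep = _sniff_separator(fh.readline())
    df = pd.read_csv(path, sep=sep, dtype={c: str for c in ANNOTATION_COLUMNS})
    header = list(df.columns)
    if set(ANNOTATION_COLUMNS).issubset(header):
        anno = {name: name for name in ANNOTATION_COLUMNS}
    else:
        # positional fallback: paper fixes the order fraction, energy, surface, mass
        if len(header) < 4:
            raise TableFormatError("peak table needs >= 4 columns")
        anno = dict(zip(ANNOTATION_COLUMNS, header[:4]))
        df = df.rename(columns={v: k for k, v in anno.items()})
        header = list(df.columns)
    intensity_cols = [c for c in header if c not in ANNOTATION_COLUMNS]
    expected = set(design.intensity_columns)
    unknown = [c for c in intensity_cols if c not in expected]
    if unknown:
        raise TableFormatError(f"columns not in design: {unknown}")
    absent = [c for c in design.intensity_columns if c not in intensity_cols]
    if absent:
        raise TableFormatError(f"design columns missing from table: {absent}")

    peaks: list[PeakRecord] = []
    for _, row in df.iterrows():
        label = str(row["mass"])
        mass = parse_mass_label(label)
        intens = {}
        for sid in design.sample_ids:
            c1, c2 = design.replicate_columns[sid]
            intens[sid] = (_parse_cell(row[c1], c1), _parse_cell(row[c2], c2))
        peaks.append(
            PeakRecord(
                fraction=str(row["fraction"]),
                surface=str(row["surface"]),
                energy=str(row["energy"]),
                mass_label=label,
                mass_da=mass,
                intensities=intens,
            )
        )
    return PeakTable(peaks, design)


# ---------------------------------------------------------------------------
# writing


def write_peak_table(table: PeakTable, path, sep: str = "\t") -> None:
    """Write a peak table in the same dialect ``read_peak_table`` accepts."""
    design = table.design
    rows = []
    for peak in table.peaks:
        row: dict[str, object] = {
            "fraction": peak.fraction,
            "energy": peak.energy,
            "surface": peak.surface,
            "mass": peak.mass_label,
        }
        for sid in design.sample_ids:
            c1, c2 = design.replicate_columns[sid]
            r1, r2 = peak.intensities[sid]
            row[c1] = "" if math.isnan(r1) else repr(float(r1))
            row[c2] = "" if math.isnan(r2) else repr(float(r2))
        rows.append(row)
    cols = list(ANNOTATION_COLUMNS) + list(design.intensity_columns)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def write_design(design: SampleDesign, path, sep: str = "\t") -> None:
    rows = []
    for sid in design.sample_ids:
        for idx, col in enumerate(design.replicate_columns[sid], start=1):
            row = {"column_name": col, "sample_id": sid, "replicate_index": idx}
            if design.groups is not None:
                row["group"] = design.groups[sid]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_cluster_report(clusters: Sequence, design: SampleDesign, path, sep: str = "\t") -> None:
    """Write the cluster membership report: one row per cluster member.

    Columns: cluster_id, member, fraction, surface, energy, mass_da, weight,
    replicate_variance, then one informational per-group ratio-CV column per
    sample group.  Member weights within a cluster sum to 1.
    """
    group_labels = design.group_labels
    rows = []
    for cluster in clusters:
        for member_id, weight, noise in zip(
            cluster.members, cluster.weights, cluster.member_noise
        ):
            frac, surf, energy, label = member_id
            row: dict[str, object] = {
                "cluster_id": cluster.cluster_id,
                "member": "_".join(member_id),
                "fraction": frac,
                "surface": surf,
                "energy": energy,
                "mass_da": parse_mass_label(label),
                "weight": weight,
                "replicate_variance": noise,
            }
            for g in group_labels:
                value = None
                if cluster.group_cvs is not None:
                    value = cluster.group_cvs.get(member_id, {}).get(g)
                row[f"cv_group_{g}"] = "" if value is None or math.isnan(value) else value
            rows.append(row)
    cols = [
        "cluster_id",
        "member",
        "fraction",
        "surface",
        "energy",
        "mass_da",
        "weight",
        "replicate_variance",
    ] + [f"cv_group_{g}" for g in group_labels]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def write_centroid_table(
    features: Iterable[tuple[str, np.ndarray]],
    design: SampleDesign,
    path,
    sep: str = "\t",
) -> None:
    """Write a feature-by-sample table of mean-centered unit vectors.

    ``features`` yields (feature_id, vector) pairs with one vector element
    per design sample; used both for the pre-clustering normalized table and
    for the post-clustering centroid table.
    """
    ids, vectors = [], []
    for fid, vec in features:
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(design.sample_ids),):
            raise TableFormatError(
                f"feature {fid!r} vector length {vec.shape} != {len(design.sample_ids)} samples"
            )
        ids.append(fid)
        vectors.append(vec)
    df = pd.DataFrame(
        np.asarray(vectors) if vectors else np.empty((0, len(design.sample_ids))),
        columns=list(design.sample_ids),
    )
    df.insert(0, "feature_id", ids)
    df.to_csv(path, sep=sep, index=False)


def read_centroid_table(path) -> pd.DataFrame:
    """Read a centroid table back as a DataFrame indexed by feature_id."""
    with open(path, "r", encoding="utf-8") as fh:
        sep = _sniff_separator(fh.readline())
    df = pd.read_csv(path, sep=sep)
    if "feature_id" not in df.columns:
        raise TableFormatError("centroid table lacks a feature_id column")
    return df.set_index("feature_id")
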