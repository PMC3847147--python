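"""Synthetic SELDI peak tables with planted technical aliases.

The generator emulates the shape of a vendor peak-table export from a
duplicate-measurement protein-profiling study: peaks detected under
condition combinations of chromatographic fraction, array surface and
laser energy, with two replicate intensity columns per sample.  Protein
abundances are log-normal across samples (multiplicative biology),
planted aliases are the parent's per-sample abundance times a condition
attenuation factor times multiplicative noise, and replicates scatter
multiplicatively around the sample value.  A ground-truth map of the
planted parent/alias pairs is returned alongside the table.

Also provided are the sample-identity randomization utilities used to
probe the clustering: permuting a peak's duplicate pairs across samples
(optionally within groups) destroys its correlation with every other
peak while preserving replicate pairing and per-peak value multisets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alias_search import MassWindowTable
from .errors import ConfigError
from .io_tables import PeakRecord, PeakTable, SampleDesign, format_mass_label

#: (multiple, condition shift) planting: multiple >= 2 places the alias at
#: parent_mass / multiple; multiple == 1 places it at the parent mass and
#: requires a non-empty condition shift (same-mass alias in another
#: spectrum set).
AliasPlanting = tuple[int, Mapping[str, str]]


def _lognorm_sigma(cv: float) -> float:
    """Log-scale sigma of a log-normal with the given coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv * cv))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror a duplicate-measurement discovery study: 45 samples in
    two groups, three laser energies on one surface (unfractionated), 5%
    multiplicative alias noise and 5% replicate noise.
    """

    n_samples: int = 45
    n_groups: int = 2
    n_proteins: int = 40
    fractions: tuple[str, ...] = ("Fx0",)
    surfaces: tuple[str, ...] = ("CM10",)
    energies: tuple[str, ...] = ("low", "med", "high")
    alias_spec: Optional[Sequence[Sequence[AliasPlanting]]] = None
    abundance_mu_range: tuple[float, float] = (math.log(1.0), math.log(50.0))
    abundance_sigma: float = 1.0
    group_effect: float = 1.5
    frac_affected: float = 0.2
    alias_noise_cv: float = 0.05
    replicate_noise_cv: float = 0.05
    missing_rate: float = 0.0
    mass_range: tuple[float, float] = (7_000.0, 160_000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ConfigError("need >= 3 samples")
        if self.n_groups < 1 or self.n_samples < 2 * self.n_groups:
            raise ConfigError("each group needs >= 2 samples")
        if self.n_proteins < 1:
            raise ConfigError("need >= 1 protein")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.frac_affected <= 1.0):
            raise ConfigError("frac_affected must be in [0, 1]")
        for name in ("alias_noise_cv", "replicate_noise_cv", "abundance_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.group_effect <= 0:
            raise ConfigError("group_effect must be > 0")


@dataclass(frozen=True)
class PlantedAlias:
    """Ground truth: the alias peak is the same protein as the parent peak."""

    parent_id: tuple[str, str, str, str]
    alias_id: tuple[str, str, str, str]
    multiple: int


def default_alias_spec(config: SimulationConfig) -> list[list[AliasPlanting]]:
    """A deterministic mixed planting plan.

    Every other protein gets a z = 2 alias in its home condition; every
    fourth additionally appears at the same mass under the next laser
    energy (when several energies exist); every eighth also gets a z = 3
    alias.  Remaining proteins stay singletons.
    """
    spec: list[list[AliasPlanting]] = []
    for i in range(config.n_proteins):
        plantings: list[AliasPlanting] = []
        if i % 2 == 0:
            plantings.append((2, {}))
        if i % 4 == 0 and len(config.energies) > 1:
            plantings.append((1, {"energy": None}))  # placeholder: next energy
        if i % 8 == 0:
            plantings.append((3, {}))
        spec.append(plantings)
    return spec


def _resolve_shift(
    home: tuple[str, str, str], shift: Mapping[str, Optional[str]], config: SimulationConfig
) -> tuple[str, str, str]:
    frac, surf, energy = home
    axes = {"fraction": (frac, config.fractions), "surface": (surf, config.surfaces), "energy": (energy, config.energies)}
    out = {}
    for axis, (current, choices) in axes.items():
        target = shift.get(axis, current) if axis in shift else current
        if target is None:  # "next" along the axis
            target = choices[(choices.index(current) + 1) % len(choices)]
        elif target not in choices:
            raise ConfigError(f"unknown {axis} {target!r} in alias shift")
        out[axis] = target
    return out["fraction"], out["surface"], out["energy"]


def generate_table(config: SimulationConfig) -> tuple[PeakTable, list[PlantedAlias]]:
    """Generate a synthetic peak table plus its ground-truth alias map."""
    rng = np.random.default_rng(config.seed)
    windows = MassWindowTable()

    sample_ids = tuple(f"S{i + 1:02d}" for i in range(config.n_samples))
    groups = (
        {sid: f"g{(i % config.n_groups) + 1}" for i, sid in enumerate(sample_ids)}
        if config.n_groups >= 2
        else None
    )
    design = SampleDesign(
        sample_ids=sample_ids,
        replicate_columns={s: (f"{s}_r1", f"{s}_r2") for s in sample_ids},
        groups=groups,
    )

    spec = config.alias_spec if config.alias_spec is not None else default_alias_spec(config)
    if len(spec) != config.n_proteins:
        raise ConfigError("alias_spec must list plantings for every protein")

    conditions = list(itertools.product(config.fractions, config.surfaces, config.energies))
    n_affected = int(round(config.frac_affected * config.n_proteins))
    sig_alias = _lognorm_sigma(config.alias_noise_cv)
    sig_rep = _lognorm_sigma(config.replicate_noise_cv)

    lo, hi = config.mass_range
    if lo < windows.min_mass:
        raise ConfigError(f"mass_range starts below the window table ({windows.min_mass})")

    peaks: list[PeakRecord] = []
    truth: list[PlantedAlias] = []
    used_labels: set[tuple[tuple[str, str, str], str]] = set()

    def _add_peak(condition, mass, values) -> tuple[str, str, str, str]:
        # values: per-sample intensity; replicates scatter multiplicatively
        mass = float(mass)
        label = format_mass_label(mass)
        while (condition, label) in used_labels:
            mass += 1.0
            label = format_mass_label(mass)
        used_labels.add((condition, label))
        reps = values[:, None] * np.exp(
            rng.normal(0.0, sig_rep, size=(config.n_samples, 2))
        ) if sig_rep > 0 else np.repeat(values[:, None], 2, axis=1)
        intens = {sid: (float(reps[i, 0]), float(reps[i, 1])) for i, sid in enumerate(sample_ids)}
        frac, surf, energy = condition
        peaks.append(
            PeakRecord(
                fraction=frac, surface=surf, energy=energy,
                mass_label=label, mass_da=mass, intensities=intens,
            )
        )
        return (frac, surf, energy, label)

    for p in range(config.n_proteins):
        home = conditions[p % len(conditions)]
        mass = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        mu = rng.uniform(*config.abundance_mu_range)
        abundance = np.exp(mu + config.abundance_sigma * rng.normal(size=config.n_samples))
        if groups is not None and p < n_affected:
            in_g2 = np.array([groups[s] == "g2" for s in sample_ids])
            abundance = np.where(in_g2, abundance * config.group_effect, abundance)
        parent_id = _add_peak(home, mass, abundance)

        for multiple, shift in spec[p]:
            if multiple < 1:
                raise ConfigError(f"alias multiple must be >= 1, got {multiple}")
            if multiple == 1 and not shift:
                raise ConfigError("a same-mass alias needs a condition shift")
            alias_mass = mass / multiple
            if alias_mass < windows.min_mass:
                raise ConfigError(
                    f"planted alias mass {alias_mass:.0f} below the window table range"
                )
            # jitter within 30% of the search half-window so the pair stays findable
            half = 0.5 * windows.window_pct(alias_mass) * alias_mass
            alias_mass += rng.uniform(-0.3, 0.3) * half
            condition = _resolve_shift(home, shift, config)
            attenuation = rng.uniform(0.2, 0.9)
            noise = (
                np.exp(rng.normal(0.0, sig_alias, size=config.n_samples))
                if sig_alias > 0
                else np.ones(config.n_samples)
            )
            alias_id = _add_peak(condition, alias_mass, abundance * attenuation * noise)
            truth.append(PlantedAlias(parent_id, alias_id, multiple))

    table = PeakTable(peaks, design)
    if config.missing_rate > 0:
        table = _drop_cells(table, config.missing_rate, rng)
    return table, truth


def _drop_cells(table: PeakTable, rate: float, rng: np.random.Generator) -> PeakTable:
    """Set replicate cells to NaN at the given rate (never a whole peak)."""
    design = table.design
    peaks = []
    for peak in table.peaks:
        mask = rng.random((len(design.sample_ids), 2)) < rate
        if mask.all():
            mask[0, 0] = False
        intens = {}
        for i, sid in enumerate(design.sample_ids):
            r1, r2 = peak.intensities[sid]
            intens[sid] = (
                math.nan if mask[i, 0] else r1,
                math.nan if mask[i, 1] else r2,
            )
        peaks.append(
            PeakRecord(
                fraction=peak.fraction, surface=peak.surface, energy=peak.energy,
                mass_label=peak.mass_label, mass_da=peak.mass_da, intensities=intens,
            )
        )
    return PeakTable(peaks, design)


def write_truth(truth: Sequence[PlantedAlias], path, sep: str = "\t") -> None:
    rows = [
        {
            "parent": "_".join(t.parent_id),
            "alias": "_".join(t.alias_id),
            "multiple": t.multiple,
        }
        for t in truth
    ]
    pd.DataFrame(rows, columns=["parent", "alias", "multiple"]).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# sample-identity randomization


def _peak_rng(seed: int, peak_index: int) -> np.random.Generator:
    """Per-peak generator derived from (master seed, peak index)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(peak_index)]))


def _permute_record(
    record: PeakRecord, design: SampleDesign, within_groups: bool, rng: np.random.Generator
) -> PeakRecord:
    sample_ids = list(design.sample_ids)
    perm = np.arange(len(sample_ids))
    if within_groups:
        if design.groups is None:
            raise ConfigError("within-group randomization needs a grouped design")
        for g in design.group_labels:
            idx = [i for i, s in enumerate(sample_ids) if design.groups[s] == g]
            perm[idx] = np.asarray(idx)[rng.permutation(len(idx))]
    else:
        perm = rng.permutation(len(sample_ids))
    intens = {
        sample_ids[i]: record.intensities[sample_ids[perm[i]]]
        for i in range(len(sample_ids))
    }
    return PeakRecord(
        fraction=record.fraction, surface=record.surface, energy=record.energy,
        mass_label=record.mass_label, mass_da=record.mass_da, intensities=intens,
    )


def randomize_peak(
    table: PeakTable, peak_id: tuple, within_groups: bool = False, seed: int = 0
) -> PeakTable:
    """Permute one peak's duplicate pairs across samples; all else untouched.

    Replicate pairs travel together, so the multiset of (rep1, rep2) pairs
    is preserved.  The permutation for peak *i* depends only on
    (seed, i), so single-peak and all-peak randomization agree.
    """
    idx = table.index_of(peak_id)
    record = table.peaks[idx]
    new_record = _permute_record(record, table.design, within_groups, _peak_rng(seed, idx))
    return table.replace(peak_id, new_record)


def randomize_all_peaks(
    table: PeakTable, within_groups: bool = False, seed: int = 0
) -> PeakTable:
    """Independently permute every peak's pairs across samples."""
    peaks = [
        _permute_record(peak, table.design, within_groups, _peak_rng(seed, i))
        for i, peak in enumerate(table.peaks)
    ]
    return PeakTable(peaks, table.design)
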