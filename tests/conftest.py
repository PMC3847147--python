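import math

import numpy as np
import pytest

from aliasclust.io_tables import PeakRecord, PeakTable, SampleDesign


def make_design(n_samples=3, groups=None):
    sids = tuple(f"S{i + 1:02d}" for i in range(n_samples))
    return SampleDesign(
        sample_ids=sids,
        replicate_columns={s: (f"{s}_r1", f"{s}_r2") for s in sids},
        groups={s: groups[i] for i, s in enumerate(sids)} if groups else None,
    )


def make_record(mass, means, design, pair_delta=0.0, fraction="Fx0",
                surface="CM10", energy="high", label=None):
    """Peak whose replicate pair straddles each mean by +/- pair_delta/2."""
    if label is None:
        label = f"C{int(round(mass)):07d}_"
    deltas = np.broadcast_to(np.asarray(pair_delta, dtype=float), (len(means),))
    intens = {
        sid: (m - d / 2.0, m + d / 2.0)
        for sid, m, d in zip(design.sample_ids, means, deltas)
    }
    return PeakRecord(
        fraction=fraction, surface=surface, energy=energy,
        mass_label=label, mass_da=float(mass), intensities=intens,
    )


@pytest.fixture
def design3():
    return make_design(3)


@pytest.fixture
def tiny_table(design3):
    """Four peaks, one condition: an exact 66k/33k alias pair + 2 bystanders."""
    parent = make_record(66000, [1.0, 2.0, 3.0], design3, pair_delta=0.2)
    alias = make_record(33000, [2.0, 4.0, 6.0], design3, pair_delta=0.8)
    lone1 = make_record(7000, [5.0, 1.0, 2.0], design3, pair_delta=0.1)
    lone2 = make_record(15100, [1.0, 9.0, 4.0], design3, pair_delta=0.1)
    return PeakTable([parent, alias, lone1, lone2], design3)


def planted_pairs(truth):
    return {frozenset((t.parent_id, t.alias_id)) for t in truth}


def recovered_pairs(result):
    got = set()
    for c in result.clusters:
        for i in range(len(c.members)):
            for j in range(i + 1, len(c.members)):
                got.add(frozenset((c.members[i], c.members[j])))
    return got


def protein_root_map(truth):
    """peak_id -> parent protein id for every planted peak."""
    root = {}
    for t in truth:
        root.setdefault(t.parent_id, t.parent_id)
        root[t.alias_id] = t.parent_id
    return root
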