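import numpy as np
import pytest

from ppiconserve.core import InteractionRecord, SnapshotSet, canonical_pair


def make_snapshot(name, triples):
    """Snapshot from (accA, accB, taxid) triples."""
    return SnapshotSet(
        name,
        (
            InteractionRecord(pair=canonical_pair(a, b), taxid=t, source_db=name)
            for a, b, t in triples
        ),
    )


@pytest.fixture
def snapshot_factory():
    return make_snapshot


def random_snapshot_family(rng, n_snaps=None, n_keys=None):
    """A family of snapshots drawn from a small random key universe."""
    n_snaps = n_snaps or int(rng.integers(2, 7))
    n_keys = n_keys or int(rng.integers(5, 300))
    accs = [f"P{i:05d}" for i in range(int(rng.integers(5, 40)))]
    taxids = [9606, 10090, 4932]
    # cap the draw by the universe capacity (pairs incl. self-pairs x taxids)
    capacity = (len(accs) * (len(accs) - 1) // 2 + len(accs)) * len(taxids)
    n_keys = min(n_keys, capacity // 2)
    universe = set()
    while len(universe) < n_keys:
        a, b = rng.choice(len(accs), size=2)
        universe.add(
            (canonical_pair(accs[int(a)], accs[int(b)]), taxids[int(rng.integers(3))])
        )
    universe = sorted(universe)
    snaps = []
    for i in range(n_snaps):
        size = int(rng.integers(1, len(universe) + 1))
        idx = rng.choice(len(universe), size=size, replace=False)
        snaps.append(
            SnapshotSet(
                f"db{i}",
                (
                    InteractionRecord(pair=universe[j][0], taxid=universe[j][1],
                                      source_db=f"db{i}")
                    for j in sorted(idx)
                ),
            )
        )
    return snaps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
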