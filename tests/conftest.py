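import numpy as np
import pandas as pd
import pytest

from neurointeract.tables_io import SpectralCountTable, load_table1_fixture

BAIT_CONDITIONS = ["Cter", "Nter"]
CONTROL_CONDITIONS = ["Beads", "MAR", "RAM"]


def make_table(counts_by_protein, lengths, conditions=None, replicates=3):
    """Build a SpectralCountTable from {symbol: {condition: [reps...]}}."""
    conditions = conditions or BAIT_CONDITIONS + CONTROL_CONDITIONS
    cols = pd.MultiIndex.from_tuples(
        [(c, r + 1) for c in conditions for r in range(replicates)],
        names=["condition", "replicate"],
    )
    rows, accs, syms, lens = [], [], [], []
    for i, (sym, conds) in enumerate(counts_by_protein.items()):
        row = []
        for c in conditions:
            reps = conds.get(c, [0] * replicates)
            row.extend(reps)
        rows.append(row)
        accs.append(f"P{i:03d}")
        syms.append(sym)
        lens.append(lengths[sym])
    return SpectralCountTable(
        counts=pd.DataFrame(rows, index=accs, columns=cols),
        meta=pd.DataFrame({"symbol": syms, "length_aa": lens}, index=accs),
    )


def random_table(rng, n_proteins, conditions=None, replicates=3, max_count=12):
    """A random small count table for oracle-equivalence checks."""
    conditions = conditions or BAIT_CONDITIONS + CONTROL_CONDITIONS
    counts = {}
    lengths = {}
    for i in range(n_proteins):
        sym = f"R{i:03d}"
        counts[sym] = {
            c: list(rng.integers(0, max_count + 1, size=replicates))
            for c in conditions
        }
        lengths[sym] = int(rng.integers(50, 2000))
    return make_table(counts, lengths, conditions, replicates)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_partners(table1):
    return [a for a in table1 if not a.is_bait]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240313)
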