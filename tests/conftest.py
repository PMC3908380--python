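"""Shared fixtures: hand-built toy experiments with known-by-construction values."""

import pytest

from ppirank.datamodel import CONTROL_GROUP, PurificationTable, Run

BAITS = ["A", "B", "C", "D"]

TOY_LENGTHS = {
    "PX": 300,    # rescue case: SCs (3, 21, 0) in bait A, absent from controls
    "PONE": 200,  # all-singleton: (1, 1, 1) in bait A
    "PU": 150,    # unique to bait A, (8, 8, 8)
    "PALL": 400,  # SC 5 in every replicate of every bait group
    "PCTL": 250,  # detected only in controls
    "PEQ": 100,   # SC 2 in bait A replicates and in every control
    "PLOW": 500,  # (5,5,5) in A,B,C and (3,3,3) in D: low cross-bait variation
    "PSING": 350, # single detection (0, 7, 0) in bait A
}


def build_toy_table() -> PurificationTable:
    """Four bait groups x three replicates, six clean controls."""
    runs = []
    for bait in BAITS:
        for i in (1, 2, 3):
            runs.append(Run(f"{bait}{i}", bait, False, bait, ""))
    for i in range(1, 7):
        runs.append(Run(f"ctrl{i}", CONTROL_GROUP, True))

    counts = {}
    counts[("A1", "PX")] = 3
    counts[("A2", "PX")] = 21
    for r in ("A1", "A2", "A3"):
        counts[(r, "PONE")] = 1
        counts[(r, "PU")] = 8
        counts[(r, "PEQ")] = 2
    for bait in BAITS:
        for i in (1, 2, 3):
            counts[(f"{bait}{i}", "PALL")] = 5
    for bait in ("A", "B", "C"):
        for i in (1, 2, 3):
            counts[(f"{bait}{i}", "PLOW")] = 5
    for i in (1, 2, 3):
        counts[(f"D{i}", "PLOW")] = 3
    counts[("A2", "PSING")] = 7
    for i in range(1, 7):
        counts[(f"ctrl{i}", "PCTL")] = 4
        counts[(f"ctrl{i}", "PEQ")] = 2
    return PurificationTable(runs, counts, TOY_LENGTHS)


@pytest.fixture
def toy_table() -> PurificationTable:
    return build_toy_table()


@pytest.fixture(scope="session")
def default_simulation():
    """One default synthetic experiment, shared across tests (read-only)."""
    from ppirank.simulate import SimulationConfig, simulate_experiment

    return simulate_experiment(SimulationConfig(seed=20))


BIOGRID_TAB = (
    "#BioGRID Interaction ID\tOfficial Symbol Interactor A\t"
    "Official Symbol Interactor B\tExperimental System\tExperimental System Type\n"
    "1\tInR\tchico\tAffinity Capture-MS\tphysical\n"
    "2\tgig\tTSC1\tReconstituted Complex\tphysical\n"
    "3\tfoxo\tsima\tSynthetic Lethality\tgenetic\n"
    "4\tchico\tInR\tTwo-hybrid\tphysical\n"
)


@pytest.fixture
def biogrid_file(tmp_path):
    path = tmp_path / "biogrid.tab.txt"
    path.write_text(BIOGRID_TAB, encoding="utf-8")
    return str(path)
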