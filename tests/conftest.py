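"""Shared fixtures: tiny handcrafted peak-list tables and simulated
two-state experiments, all generated in-process."""

from __future__ import annotations

import io

import numpy as np
import pytest
from hypothesis import settings

from hdxstat.peaklist import build_dataset, parse_peaklist_table
from hdxstat.simulate import simulate_dataset, two_state_spec

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

HEADER = "peptide_id\tstate\tcharge\ttime_s\treplicate\tmz\tintensity"


def table(rows: list[tuple]) -> io.StringIO:
    """Render (peptide_id, state, charge, time_s, replicate, mz, intensity)
    tuples as a canonical TSV stream; None time_s becomes an empty field."""
    lines = [HEADER]
    for row in rows:
        lines.append("\t".join("" if v is None else str(v) for v in row))
    return io.StringIO("\n".join(lines) + "\n")


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def two_peptide_rows():
    """Two peptides x two states x two timepoints x two replicates, with
    nondeut/fulldeut references for each peptide."""
    rows = []
    for pid, base in (("pepA", 500.0), ("pepB", 640.0)):
        for state, shift in (("apo", 0.3), ("ligand", 0.5)):
            for t in (600, 3600):
                for rep in (1, 2):
                    for k in range(3):
                        rows.append(
                            (pid, state, 1, t, rep,
                             base + shift + 0.01 * rep + k * 1.0033, 100 * (3 - k))
                        )
        for state, shift in (("nondeut", 0.0), ("fulldeut", 2.0)):
            for k in range(3):
                rows.append((pid, state, 1, None, 1, base + shift + k * 1.0033, 100 * (3 - k)))
    return rows


@pytest.fixture
def two_peptide_dataset(two_peptide_rows):
    lists = parse_peaklist_table(table(two_peptide_rows))
    return build_dataset(lists, "apo", "ligand")


@pytest.fixture
def null_simulation():
    """Single-peptide exact-null experiment (identical kinetics in both
    states) under the default study conditions."""
    return simulate_dataset(two_state_spec(seed=421, rate_ratio=1.0))


@pytest.fixture
def shifted_simulation():
    """Single-peptide experiment where the bound state exchanges 30% faster."""
    return simulate_dataset(two_state_spec(seed=422, rate_ratio=1.3))
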