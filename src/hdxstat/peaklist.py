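"""Peak-list I/O and dataset assembly.

The canonical on-disk format is UTF-8 delimited text (tab by default), one
row per observed isotopic peak, with the exact header::

    peptide_id  state  charge  time_s  replicate  mz  intensity

``state`` is a free label for a comparison state (e.g. ``apo`` or a ligand
name) or one of the reserved reference labels ``nondeut`` / ``fulldeut``.
Reference rows leave ``time_s`` empty; comparison rows must carry it.
Lines starting with ``#`` are comments. A missing ``replicate`` column
defaults every row to replicate 1.

This module groups rows into :class:`PeakList` objects and assembles a
validated two-state :class:`ExchangeDataset`, and reads/writes the results
and uptake tables produced downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyDatasetError,
    FormatError,
    PairingError,
    ValidationError,
)

logger = logging.getLogger(__name__)

NONDEUT = "nondeut"
FULLDEUT = "fulldeut"
#: State labels reserved for the exchange references anchoring percent-D.
REFERENCE_STATES = frozenset({NONDEUT, FULLDEUT})

PEAKLIST_COLUMNS = ("peptide_id", "state", "charge", "time_s", "replicate", "mz", "intensity")

RESULTS_COLUMNS = (
    "peptide_id",
    "method",
    "response",
    "estimate",
    "ci_low",
    "ci_high",
    "p_value",
    "adjusted_p",
    "df",
    "n",
)

UPTAKE_COLUMNS = ("peptide_id", "state", "time_s", "replicate", "centroid_mz", "deuteration_pct")


@dataclass(frozen=True)
class Peak:
    """A single isotopic peak: m/z in Thomson, intensity in arbitrary units."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (self.mz > 0):
            raise ValidationError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValidationError(f"peak intensity must be non-negative, got {self.intensity}")


@dataclass(frozen=True)
class PeakList:
    """One peptide ion's isotopic cluster at one state/time/replicate.

    Invariants enforced on construction: at least one peak with positive
    intensity; peaks sorted by nondecreasing m/z; reference states carry no
    exchange time while comparison states must.
    """

    peptide_id: str
    state: str
    charge: int
    time_s: float | None
    replicate: int
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValidationError(f"{self.peptide_id}: charge must be a positive integer")
        if self.replicate < 1:
            raise ValidationError(f"{self.peptide_id}: replicate must be a positive integer")
        if not self.peaks:
            raise ValidationError(f"{self.peptide_id}: peak list is empty")
        if not any(p.intensity > 0 for p in self.peaks):
            raise ValidationError(f"{self.peptide_id}: all peaks have zero intensity")
        mzs = [p.mz for p in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            raise ValidationError(f"{self.peptide_id}: peaks are not sorted by m/z")
        if self.state in REFERENCE_STATES:
            if self.time_s is not None:
                raise ValidationError(
                    f"{self.peptide_id}: reference state {self.state!r} must not carry time_s"
                )
        else:
            if self.time_s is None:
                raise ValidationError(
                    f"{self.peptide_id}: comparison state {self.state!r} requires time_s"
                )
            if self.time_s < 0:
                raise ValidationError(f"{self.peptide_id}: time_s must be >= 0")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)


@dataclass
class PeptideRecord:
    """All peak lists for one peptide: per-state observations plus any
    measured exchange references, sharing a single charge state."""

    peptide_id: str
    charge: int
    observations: dict[str, list[PeakList]] = field(default_factory=dict)
    references: dict[str, PeakList] = field(default_factory=dict)

    def timepoints(self, state: str) -> list[float]:
        return sorted({pl.time_s for pl in self.observations.get(state, [])})


@dataclass
class ExchangeDataset:
    """A validated two-state exchange experiment ready for analysis.

    Every retained peptide is present in both comparison states, on one
    charge state, with identical timepoint sets across states.
    """

    state_a: str
    state_b: str
    peptides: dict[str, PeptideRecord]

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.peptides)


def parse_peaklist_table(source: IO[str] | str, *, sep: str = "\t") -> list[PeakList]:
    """Parse a canonical peak-list table into a list of :class:`PeakList`.

    Parameters
    ----------
    source
        Path or open text stream.
    sep
        Field delimiter; tab by default, ``","`` accepted for CSV input.

    Returns
    -------
    One ``PeakList`` per distinct ``(peptide_id, state, charge, time_s,
    replicate)`` group, peaks sorted by m/z. Every input row lands in
    exactly one group (peak conservation).
    """
    try:
        df = pd.read_csv(
            source, sep=sep, comment="#", dtype={"peptide_id": str, "state": str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError("peak-list table is empty") from exc

    columns = list(df.columns)
    required = [c for c in PEAKLIST_COLUMNS if c != "replicate"]
    missing = [c for c in required if c not in columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    unknown = [c for c in columns if c not in PEAKLIST_COLUMNS]
    if unknown:
        raise FormatError(f"unknown column(s): {', '.join(unknown)}")
    if "replicate" not in columns:
        df = df.assign(replicate=1)

    # Row numbers as in the file (1-based, header = row 1), for diagnostics.
    df = df.assign(_row=df.index + 2)

    bad_mz = df[~(df["mz"] > 0)]
    if len(bad_mz):
        raise ValidationError(f"nonpositive mz at row {int(bad_mz['_row'].iloc[0])}")
    bad_int = df[df["intensity"] < 0]
    if len(bad_int):
        raise ValidationError(f"negative intensity at row {int(bad_int['_row'].iloc[0])}")

    group_cols = ["peptide_id", "state", "charge", "time_s", "replicate"]
    dup = df.duplicated(subset=group_cols + ["mz"], keep=False)
    if dup.any():
        raise ValidationError(
            f"duplicate (group, mz) rows, first at row {int(df.loc[dup, '_row'].iloc[0])}"
        )

    lists: list[PeakList] = []
    for (pid, state, charge, time_s, rep), grp in df.groupby(group_cols, dropna=False, sort=True):
        grp = grp.sort_values("mz")
        peaks = tuple(Peak(mz=float(m), intensity=float(i)) for m, i in zip(grp["mz"], grp["intensity"]))
        t = None if (isinstance(time_s, float) and math.isnan(time_s)) else float(time_s)
        lists.append(
            PeakList(
                peptide_id=str(pid),
                state=str(state),
                charge=int(charge),
                time_s=t,
                replicate=int(rep),
                peaks=peaks,
            )
        )
    return lists


def write_peaklist_table(lists: Iterable[PeakList], sink: IO[str] | str, *, sep: str = "\t") -> None:
    """Write peak lists in the canonical dialect (inverse of the parser)."""
    rows = []
    for pl in lists:
        for p in pl.peaks:
            rows.append(
                {
                    "peptide_id": pl.peptide_id,
                    "state": pl.state,
                    "charge": pl.charge,
                    "time_s": pl.time_s,
                    "replicate": pl.replicate,
                    "mz": p.mz,
                    "intensity": p.intensity,
                }
            )
    # full round-trip precision: closely spaced jittered peaks must never
    # collapse into duplicate rows through formatting
    pd.DataFrame(rows, columns=list(PEAKLIST_COLUMNS)).to_csv(sink, sep=sep, index=False)


def build_dataset(
    lists: Sequence[PeakList],
    state_a: str,
    state_b: str,
    *,
    policy: str = "intersection",
) -> ExchangeDataset:
    """Assemble a two-state :class:`ExchangeDataset` from parsed peak lists.

    Peptides missing either comparison state are dropped with a warning.
    Under the default ``"intersection"`` policy, timepoints not shared by
    both states are dropped; under ``"strict"`` a timepoint mismatch raises
    :class:`~hdxstat.exceptions.PairingError`. Idempotent: re-assembling an
    already assembled dataset changes nothing.
    """
    if policy not in ("intersection", "strict"):
        raise ValueError(f"unknown pairing policy {policy!r}")
    if not lists:
        raise EmptyDatasetError("no peak lists supplied")
    if state_a == state_b:
        raise ValueError("state_a and state_b must be distinct")
    present = {pl.state for pl in lists}
    for s in (state_a, state_b):
        if s not in present:
            raise EmptyDatasetError(f"state {s!r} does not occur in the data")

    by_pid: dict[str, list[PeakList]] = {}
    for pl in lists:
        by_pid.setdefault(pl.peptide_id, []).append(pl)

    peptides: dict[str, PeptideRecord] = {}
    for pid, pls in sorted(by_pid.items()):
        charges = {pl.charge for pl in pls if pl.state in (state_a, state_b)}
        if len(charges) > 1:
            raise ValidationError(
                f"peptide {pid!r}: mixed charge states {sorted(charges)} among compared records"
            )
        rec = PeptideRecord(peptide_id=pid, charge=next(iter(charges)) if charges else pls[0].charge)
        for pl in pls:
            if pl.state in REFERENCE_STATES:
                rec.references[pl.state] = pl
            elif pl.state in (state_a, state_b):
                rec.observations.setdefault(pl.state, []).append(pl)
        if state_a not in rec.observations or state_b not in rec.observations:
            logger.warning("peptide %r lacks one of the comparison states; dropped", pid)
            continue

        times_a = set(rec.timepoints(state_a))
        times_b = set(rec.timepoints(state_b))
        if times_a != times_b:
            if policy == "strict":
                raise PairingError(
                    f"peptide {pid!r}: timepoint mismatch {sorted(times_a)} vs {sorted(times_b)}"
                )
            shared = times_a & times_b
            logger.warning(
                "peptide %r: keeping %d shared timepoint(s), dropping unshared", pid, len(shared)
            )
            if not shared:
                continue
            for s in (state_a, state_b):
                rec.observations[s] = [pl for pl in rec.observations[s] if pl.time_s in shared]
        for s in (state_a, state_b):
            rec.observations[s].sort(key=lambda pl: (pl.time_s, pl.replicate))
        peptides[pid] = rec

    if not peptides:
        raise EmptyDatasetError("no peptide is present in both comparison states")
    return ExchangeDataset(state_a=state_a, state_b=state_b, peptides=peptides)


def dataset_peaklists(dataset: ExchangeDataset) -> list[PeakList]:
    """Flatten a dataset back to its peak lists (references included)."""
    out: list[PeakList] = []
    for rec in dataset.peptides.values():
        for pls in rec.observations.values():
            out.extend(pls)
        out.extend(rec.references.values())
    return out


def write_results_table(results: Sequence, sink: IO[str] | str) -> None:
    """Write differential results as TSV, one row per (peptide, method).

    Numbers are serialized with at least six significant digits so a
    write-parse round trip reproduces them to serialization precision.
    """
    if not results:
        raise ValueError("no results to write")
    rows = [
        {
            "peptide_id": r.peptide_id,
            "method": r.method,
            "response": r.response,
            "estimate": r.estimate,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "adjusted_p": r.adjusted_p,
            "df": r.df,
            "n": r.n,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=list(RESULTS_COLUMNS)).to_csv(
        sink, sep="\t", index=False, float_format="%.8g"
    )


def read_results_table(source: IO[str] | str) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"results table missing column(s): {', '.join(missing)}")
    return df


def write_uptake_table(observations: Sequence, sink: IO[str] | str) -> None:
    """Write uptake observations as TSV; a missing percent-D is an empty
    field, never zero."""
    if not observations:
        raise ValueError("no observations to write")
    rows = [
        {
            "peptide_id": o.peptide_id,
            "state": o.state,
            "time_s": o.time_s,
            "replicate": o.replicate,
            "centroid_mz": o.centroid_mz,
            "deuteration_pct": o.deuteration_pct,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=list(UPTAKE_COLUMNS)).to_csv(
        sink, sep="\t", index=False, float_format="%.10g"
    )


def read_uptake_table(source: IO[str] | str) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in UPTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"uptake table missing column(s): {', '.join(missing)}")
    return df


def read_peptide_map(source: IO[str] | str) -> pd.DataFrame:
    """Read the optional per-peptide metadata table.

    Required columns: ``peptide_id``, ``residue_start``, ``residue_end``;
    optional ``n_exchangeable`` (used for the theoretical fully-deuterated
    anchor when no fulldeut control was measured).
    """
    df = pd.read_csv(source, sep="\t", dtype={"peptide_id": str})
    for c in ("peptide_id", "residue_start", "residue_end"):
        if c not in df.columns:
            raise FormatError(f"peptide map missing column: {c}")
    bad = df[df["residue_start"] > df["residue_end"]]
    if len(bad):
        raise ValidationError(
            f"peptide map: residue_start > residue_end for {bad['peptide_id'].iloc[0]!r}"
        )
    return df


def n_exchangeable_map(peptide_map: pd.DataFrame | None) -> Mapping[str, int]:
    """Extract a peptide_id -> n_exchangeable mapping from a peptide map."""
    if peptide_map is None or "n_exchangeable" not in peptide_map.columns:
        return {}
    sub = peptide_map.dropna(subset=["n_exchangeable"])
    return {str(p): int(n) for p, n in zip(sub["peptide_id"], sub["n_exchangeable"])}
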