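"""Centroid and percent-deuteration computation.

The centroid of an isotopic cluster is its intensity-weighted mean m/z.
Percent deuterium incorporation anchors the partially deuterated centroid
between a nondeuterated control (0 %) and a fully deuterated control
(100 %):

    %D = 100 * (m/z_P - m/z_N) / (m/z_F - m/z_N)

When no fully deuterated control was measured, a theoretical anchor is
synthesized from the number of exchangeable backbone amides, scaled by the
back-exchange recovery fraction and the deuterium content of the labeling
buffer (defaults 0.70 and 0.80, user-definable). A measured control already
embodies back-exchange, so no further correction is applied to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .exceptions import DegenerateClusterError, MissingReferenceError, ValidationError
from .peaklist import FULLDEUT, NONDEUT, ExchangeDataset, PeakList, PeptideRecord

logger = logging.getLogger(__name__)

#: Mass difference between deuterium and protium, in Da.
DEUTERIUM_MASS_SHIFT = 1.00628
#: Nominal 13C-12C isotopic spacing, in Da.
C13_SPACING = 1.0033


@dataclass(frozen=True)
class CorrectionSettings:
    """Back-exchange correction factors for the theoretical 100 % anchor.

    Attributes
    ----------
    recovery
        Fraction of incorporated deuterium surviving workup (back-exchange
        recovery), in (0, 1].
    buffer_d
        Deuterium content of the labeling buffer, in (0, 1].
    apply_correction
        If False, both factors are treated as 1 (no correction).
    """

    recovery: float = 0.70
    buffer_d: float = 0.80
    apply_correction: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.recovery <= 1):
            raise ValidationError(f"recovery must be in (0, 1], got {self.recovery}")
        if not (0 < self.buffer_d <= 1):
            raise ValidationError(f"buffer_d must be in (0, 1], got {self.buffer_d}")

    @property
    def effective_factor(self) -> float:
        return self.recovery * self.buffer_d if self.apply_correction else 1.0


@dataclass(frozen=True)
class ReferencePair:
    """Exchange anchors for one peptide/charge: nondeuterated and fully
    deuterated centroids, the latter measured or theoretical."""

    peptide_id: str
    charge: int
    mz_N: float
    mz_F: float
    mz_F_source: str  # "measured" | "theoretical"

    def __post_init__(self) -> None:
        if not (self.mz_F > self.mz_N):
            raise ValidationError(
                f"{self.peptide_id}: fully deuterated centroid ({self.mz_F}) must exceed "
                f"nondeuterated centroid ({self.mz_N})"
            )


@dataclass(frozen=True)
class UptakeObservation:
    """One centroid (and optionally percent-D) at one state/time/replicate;
    the response value fed to the differential statistics."""

    peptide_id: str
    state: str
    time_s: float
    replicate: int
    centroid_mz: float
    charge: int = 0  # 0 = unknown (e.g. re-read from an uptake table)
    deuteration_pct: float | None = None


def compute_centroid(cluster: PeakList) -> float:
    """Intensity-weighted mean m/z of an isotopic cluster.

    Raises :class:`DegenerateClusterError` if the total intensity is zero.
    The result always lies within the cluster's m/z range.
    """
    intensity = cluster.intensity_array
    total = intensity.sum()
    if total <= 0:
        raise DegenerateClusterError(f"{cluster.peptide_id}: cluster has zero total intensity")
    return float(np.dot(cluster.mz_array, intensity) / total)


def theoretical_full_mz(
    mz_N: float,
    n_exchangeable: int,
    charge: int,
    settings: CorrectionSettings = CorrectionSettings(),
) -> float:
    """Theoretical fully-deuterated centroid from the nondeuterated one.

    The maximal mass shift is ``n_exchangeable * 1.00628`` Da, scaled by
    ``recovery * buffer_d`` and divided by the charge to land on the m/z
    scale.
    """
    if n_exchangeable < 1:
        raise ValueError(f"n_exchangeable must be >= 1, got {n_exchangeable}")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    shift = n_exchangeable * DEUTERIUM_MASS_SHIFT * settings.effective_factor / charge
    return mz_N + shift


def deuteration_level(centroid_P: float, refs: ReferencePair) -> float:
    """Percent deuterium incorporation of a partially deuterated centroid.

    Values slightly outside [0, 100] (measurement noise) are returned
    unclamped so downstream statistics stay unbiased; excursions beyond
    five points are logged.
    """
    span = refs.mz_F - refs.mz_N
    if span == 0:
        raise DegenerateClusterError(f"{refs.peptide_id}: mz_F equals mz_N, percent-D undefined")
    pct = 100.0 * (centroid_P - refs.mz_N) / span
    if pct < -5.0 or pct > 105.0:
        logger.warning("%s: percent-D %.2f far outside [0, 100]", refs.peptide_id, pct)
    return pct


def reference_pair_for(
    record: PeptideRecord,
    corrections: CorrectionSettings = CorrectionSettings(),
    n_exchangeable: int | None = None,
) -> ReferencePair:
    """Build the exchange anchors for one peptide.

    Uses the measured ``nondeut``/``fulldeut`` controls when present; falls
    back to a theoretical fully-deuterated anchor if ``n_exchangeable`` is
    known. Raises :class:`MissingReferenceError` otherwise.
    """
    nondeut = record.references.get(NONDEUT)
    if nondeut is None:
        raise MissingReferenceError(f"{record.peptide_id}: no nondeuterated reference")
    mz_N = compute_centroid(nondeut)
    fulldeut = record.references.get(FULLDEUT)
    if fulldeut is not None:
        return ReferencePair(
            peptide_id=record.peptide_id,
            charge=record.charge,
            mz_N=mz_N,
            mz_F=compute_centroid(fulldeut),
            mz_F_source="measured",
        )
    if n_exchangeable is None:
        raise MissingReferenceError(
            f"{record.peptide_id}: no fully deuterated reference and no n_exchangeable "
            "to synthesize a theoretical one"
        )
    return ReferencePair(
        peptide_id=record.peptide_id,
        charge=record.charge,
        mz_N=mz_N,
        mz_F=theoretical_full_mz(mz_N, n_exchangeable, record.charge, corrections),
        mz_F_source="theoretical",
    )


def build_uptake_series(
    dataset: ExchangeDataset,
    response: str = "percentD",
    min_time_s: float = 0.0,
    corrections: CorrectionSettings = CorrectionSettings(),
    n_exchangeable: Mapping[str, int] | None = None,
) -> dict[str, list[UptakeObservation]]:
    """Compute per-peptide uptake observations for both comparison states.

    Parameters
    ----------
    response
        ``"mz"`` keeps centroids only; ``"percentD"`` also computes percent
        deuteration, which requires exchange references for every peptide.
    min_time_s
        Observations earlier than this are excluded (very early timepoints
        show too little exchange to be informative; ten minutes = 600 s is
        the conventional cutoff).
    n_exchangeable
        Optional per-peptide amide counts enabling the theoretical
        fully-deuterated anchor.

    Returns
    -------
    Mapping peptide_id -> observations (both states), each carrying the
    centroid and, for ``percentD``, the deuteration percentage. Timepoint
    sets remain identical across the two states because the filter is a
    pure threshold on a shared time axis.
    """
    if response not in ("mz", "percentD"):
        raise ValueError(f"unknown response {response!r}")
    n_exchangeable = n_exchangeable or {}
    series: dict[str, list[UptakeObservation]] = {}
    for pid, rec in dataset.peptides.items():
        refs: ReferencePair | None = None
        if response == "percentD":
            refs = reference_pair_for(rec, corrections, n_exchangeable.get(pid))
        obs: list[UptakeObservation] = []
        for state in (dataset.state_a, dataset.state_b):
            for pl in rec.observations[state]:
                if pl.time_s < min_time_s:
                    continue
                centroid = compute_centroid(pl)
                pct = deuteration_level(centroid, refs) if refs is not None else None
                obs.append(
                    UptakeObservation(
                        peptide_id=pid,
                        state=state,
                        time_s=pl.time_s,
                        replicate=pl.replicate,
                        centroid_mz=centroid,
                        charge=rec.charge,
                        deuteration_pct=pct,
                    )
                )
        series[pid] = obs
    return series


def response_value(obs: UptakeObservation, response: str) -> float:
    """The scalar analyzed for one observation: centroid m/z or percent-D."""
    if response == "mz":
        return obs.centroid_mz
    if response == "percentD":
        if obs.deuteration_pct is None:
            raise MissingReferenceError(f"{obs.peptide_id}: observation lacks percent-D")
        return obs.deuteration_pct
    raise ValueError(f"unknown response {response!r}")
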