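"""Uptake-curve plots and export tables for external tools.

Each peptide gets one figure — exchange time on the x axis, centroid m/z or
percent-D on the y axis, the two states overlaid in different colors, with
per-timepoint replicate means and the raw replicate scatter — plus a
sidecar plot-data TSV holding exactly the numbers drawn, so plot content is
verifiable without image comparison. A separate exporter writes per-residue
annotations (estimate, p-values) that structure viewers can map onto a 3D
model.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .diffstats import DifferentialResult, format_pvalue
from .exceptions import ValidationError
from .uptake import UptakeObservation

logger = logging.getLogger(__name__)

STATE_COLORS = ("#1f77b4", "#d62728")

ANNOTATION_COLUMNS = ("residue_start", "residue_end", "peptide_id", "estimate", "p_value", "adjusted_p")


def sanitize_filename(name: str) -> str:
    """Collapse anything outside [A-Za-z0-9._-] so peptide ids are safe
    path components."""
    cleaned = re.sub(r"[^A-Za-z0-9._-]+", "_", name).strip("_")
    return cleaned or "peptide"


def _unique_path(outdir: Path, stem: str, suffix: str) -> Path:
    candidate = outdir / f"{stem}{suffix}"
    k = 1
    while candidate.exists():
        candidate = outdir / f"{stem}_{k}{suffix}"
        k += 1
    return candidate


def export_plots(
    series: Mapping[str, Sequence[UptakeObservation]],
    results: Sequence[DifferentialResult],
    outdir: str | Path,
    response: str = "percentD",
) -> list[Path]:
    """Write one uptake-curve image (plus plot-data sidecar TSV) per peptide.

    The title carries the peptide id and, when available, the regression or
    paired-t estimate and p-value. Returns the image paths.
    """
    if not series:
        raise ValueError("no uptake series to plot")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_peptide: dict[str, list[DifferentialResult]] = {}
    for r in results:
        by_peptide.setdefault(r.peptide_id, []).append(r)

    ylabel = "deuterium incorporation (%)" if response == "percentD" else "centroid m/z (Th)"
    paths: list[Path] = []
    for pid, obs in series.items():
        if not obs:
            continue
        df = pd.DataFrame(
            {
                "state": [o.state for o in obs],
                "time_s": [o.time_s for o in obs],
                "replicate": [o.replicate for o in obs],
                "value": [
                    o.deuteration_pct if response == "percentD" else o.centroid_mz for o in obs
                ],
            }
        ).sort_values(["state", "time_s", "replicate"])

        fig, ax = plt.subplots(figsize=(5, 3.5))
        for color, (state, grp) in zip(STATE_COLORS, df.groupby("state", sort=True)):
            means = grp.groupby("time_s")["value"].mean()
            ax.plot(means.index, means.values, "-o", color=color, label=state, ms=4)
            ax.scatter(grp["time_s"], grp["value"], color=color, alpha=0.35, s=10)
        title = pid
        for r in by_peptide.get(pid, []):
            title += f"\n{r.method}: est={r.estimate:.3g}, p={format_pvalue(r.p_value)}"
            break
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("exchange time (s)")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=8)
        fig.tight_layout()

        stem = sanitize_filename(pid)
        img = _unique_path(outdir, stem, ".png")
        fig.savefig(img, dpi=120)
        plt.close(fig)
        df.to_csv(img.with_suffix(".plotdata.tsv"), sep="\t", index=False, float_format="%.10g")
        paths.append(img)
    return paths


def export_structure_annotation(
    results: Sequence[DifferentialResult],
    peptide_map: pd.DataFrame,
    sink,
) -> int:
    """Write a per-residue-range annotation table for structure coloring.

    ``peptide_map`` needs columns peptide_id, residue_start, residue_end.
    Peptides absent from the map are skipped with a log line; overlapping
    ranges pass through unmerged. Returns the number of rows written.
    """
    ranges: dict[str, tuple[int, int]] = {}
    for row in peptide_map.itertuples(index=False):
        start, end = int(row.residue_start), int(row.residue_end)
        if start < 1 or end < start:
            raise ValidationError(
                f"malformed residue range [{start}, {end}] for {row.peptide_id!r}"
            )
        ranges[str(row.peptide_id)] = (start, end)

    rows = []
    for r in results:
        if r.peptide_id not in ranges:
            logger.warning("peptide %r has no residue mapping; skipped", r.peptide_id)
            continue
        start, end = ranges[r.peptide_id]
        rows.append(
            {
                "residue_start": start,
                "residue_end": end,
                "peptide_id": r.peptide_id,
                "estimate": r.estimate,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
            }
        )
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        sink, sep="\t", index=False, float_format="%.8g"
    )
    return len(rows)
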