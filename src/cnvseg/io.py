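"""Plain-text interchange formats used between pipeline stages.

* probe tables: one TSV row per probe (probe_id, chrom, pos, grid_x,
  grid_y, test_intensity, ref_intensity), 1-based positions, header
  required; preprocessing stages append ``log2ratio_<stage>`` columns;
* segment tables: BED-like TSV (0-based half-open starts on disk);
* call tables: BED-like TSV with sample id and class columns;
* truth regions: BED with class in column 4 and log2 shift in column 5.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calling import CNVCall
from .segment import Segment
from .simulate import ChannelIntensities, ProbeLayout, TruthRegion

__all__ = [
    "write_probe_table",
    "read_probe_table",
    "write_truth_bed",
    "read_truth_bed",
    "write_segments",
    "read_segments",
    "write_calls",
    "read_calls",
]

_PROBE_COLS = ["probe_id", "chrom", "pos", "grid_x", "grid_y",
               "test_intensity", "ref_intensity"]


def write_probe_table(
    path,
    layout: ProbeLayout,
    intensities: ChannelIntensities,
    log2_tracks: dict[str, np.ndarray] | None = None,
) -> None:
    df = layout.probes.copy()
    df["test_intensity"] = intensities.test
    df["ref_intensity"] = intensities.ref
    for stage, values in (log2_tracks or {}).items():
        df[f"log2ratio_{stage}"] = values
    df.to_csv(path, sep="\t", index=False)


def read_probe_table(path) -> tuple[ProbeLayout, ChannelIntensities, pd.DataFrame]:
    """Returns (layout, intensities, full frame incl. any log2ratio columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _PROBE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {missing}")
    layout = ProbeLayout(df[_PROBE_COLS[:5]].copy())
    intens = ChannelIntensities(
        test=df["test_intensity"].to_numpy(dtype=float),
        ref=df["ref_intensity"].to_numpy(dtype=float),
    )
    return layout, intens, df


def write_truth_bed(path, regions) -> None:
    """Truth regions as BED: 0-based half-open, class col 4, shift col 5."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.cnv_class}\t{r.log2_shift}\n")


def read_truth_bed(path) -> list[TruthRegion]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, cls, shift = line.split("\t")[:5]
            out.append(
                TruthRegion(chrom, int(start) + 1, int(end), cls, float(shift))
            )
    return out


_SEG_COLS = ["chrom", "start", "end", "mean_log2", "n_probes", "sse",
             "first_probe_index", "last_probe_index"]


def write_segments(path, segments: list[Segment]) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "start": s.start_bp - 1,
            "end": s.end_bp,
            "mean_log2": s.mean_log2,
            "n_probes": s.n_probes,
            "sse": s.sse,
            "first_probe_index": s.first_probe_index,
            "last_probe_index": s.last_probe_index,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        Segment(
            chrom=row.chrom,
            first_probe_index=int(row.first_probe_index),
            last_probe_index=int(row.last_probe_index),
            start_bp=int(row.start) + 1,
            end_bp=int(row.end),
            n_probes=int(row.n_probes),
            mean_log2=float(row.mean_log2),
            sse=float(row.sse),
        )
        for row in df.itertuples()
    ]


_CALL_COLS = ["chrom", "start", "end", "sample_id", "cnv_class", "mean_log2",
              "n_probes", "sse", "first_probe_index", "last_probe_index"]


def write_calls(path, calls: list[CNVCall]) -> None:
    rows = [
        {
            "chrom": c.chrom,
            "start": c.start_bp - 1,
            "end": c.end_bp,
            "sample_id": c.sample_id,
            "cnv_class": c.cnv_class,
            "mean_log2": c.mean_log2,
            "n_probes": c.n_probes,
            "sse": c.sse,
            "first_probe_index": c.first_probe_index,
            "last_probe_index": c.last_probe_index,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=_CALL_COLS).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[CNVCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    return [
        CNVCall(
            chrom=row.chrom,
            first_probe_index=int(row.first_probe_index),
            last_probe_index=int(row.last_probe_index),
            start_bp=int(row.start) + 1,
            end_bp=int(row.end),
            n_probes=int(row.n_probes),
            mean_log2=float(row.mean_log2),
            sse=float(row.sse),
            cnv_class=row.cnv_class,
            sample_id=row.sample_id,
        )
        for row in df.itertuples()
    ]
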