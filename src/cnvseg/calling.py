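"""Retention filtering and five-way classification of segments.

The calling rules operate on segment mean log2 ratios with inclusive
thresholds:

* mean >= 1.0            -> amplification
* 0.25 <= mean < 1.0     -> gain
* -0.25 < mean < 0.25    -> unchanged
* -1.0 < mean <= -0.25   -> loss
* mean <= -1.0           -> deletion

and a segment is retained as a call only if it spans at least 5
consecutive probes and |mean| >= 0.25.  Amplifications satisfy the gain
criterion and deletions the loss criterion (class nesting), which the
recurrence analysis relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .segment import Segment

__all__ = [
    "CNVCall",
    "classify_segment",
    "retain_segments",
    "call_sample",
    "AMPLIFICATION_THRESHOLD",
    "GAIN_THRESHOLD",
    "MIN_PROBES",
]

GAIN_THRESHOLD = 0.25
AMPLIFICATION_THRESHOLD = 1.0
MIN_PROBES = 5


@dataclass(frozen=True)
class CNVCall(Segment):
    cnv_class: str = "unchanged"
    sample_id: str = ""


def classify_segment(
    mean_log2: float,
    gain_threshold: float = GAIN_THRESHOLD,
    amp_threshold: float = AMPLIFICATION_THRESHOLD,
) -> str:
    """Five-way class of a segment mean; all boundaries inclusive."""
    if not math.isfinite(mean_log2):
        raise ValueError(f"non-finite segment mean: {mean_log2}")
    if mean_log2 >= amp_threshold:
        return "amplification"
    if mean_log2 >= gain_threshold:
        return "gain"
    if mean_log2 <= -amp_threshold:
        return "deletion"
    if mean_log2 <= -gain_threshold:
        return "loss"
    return "unchanged"


def retain_segments(
    segments: list[Segment],
    min_probes: int = MIN_PROBES,
    min_abs_mean: float = GAIN_THRESHOLD,
) -> list[Segment]:
    """Keep segments with n_probes >= min_probes and |mean| >= min_abs_mean."""
    return [
        s
        for s in segments
        if s.n_probes >= min_probes and abs(s.mean_log2) >= min_abs_mean
    ]


def call_sample(
    segments: list[Segment],
    sample_id: str,
    min_probes: int = MIN_PROBES,
    min_abs_mean: float = GAIN_THRESHOLD,
    amp_threshold: float = AMPLIFICATION_THRESHOLD,
    gain_threshold: float = GAIN_THRESHOLD,
) -> list[CNVCall]:
    """Retention then classification; unchanged segments are never emitted.

    The retention bound (``min_abs_mean``) and the gain/loss classification
    boundary (``gain_threshold``) default to the same 0.25 but are separate
    knobs: loosening retention must not relabel sub-threshold segments.
    """
    calls = []
    for seg in retain_segments(segments, min_probes, min_abs_mean):
        cls = classify_segment(seg.mean_log2, gain_threshold, amp_threshold)
        if cls == "unchanged":
            continue
        calls.append(
            CNVCall(
                chrom=seg.chrom,
                first_probe_index=seg.first_probe_index,
                last_probe_index=seg.last_probe_index,
                start_bp=seg.start_bp,
                end_bp=seg.end_bp,
                n_probes=seg.n_probes,
                mean_log2=seg.mean_log2,
                sse=seg.sse,
                cnv_class=cls,
                sample_id=sample_id,
            )
        )
    return calls
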