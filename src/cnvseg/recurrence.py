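"""Cohort recurrence: minimal common regions and frequency tables.

Across a cohort, the union of all call breakpoints partitions the covered
genomic footprint of each chromosome into atomic intervals over which
per-sample carriage is constant — minimal common regions.  Each atomic
interval carries per-class counts of distinct samples whose calls cover
it, with class nesting applied (an amplification also counts as a gain, a
deletion also as a loss).  Adjacent atomic intervals with identical count
vectors are merged.

Two summary tables mirror the cohort reports this pipeline feeds:
regions whose gain or loss frequency reaches 50% of cases, and regions
whose amplification or deletion frequency reaches 20% of cases.  Both
thresholds are compared inclusively (the published tables themselves list
rows at exactly the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .calling import CNVCall

__all__ = [
    "FrequencyRegion",
    "minimal_common_regions",
    "recurrent_regions",
    "class_frequency_table",
]

_COUNT_CLASSES = ("amplification", "gain", "loss", "deletion")

#: With nesting an amplification call covers both counters, etc.
_NESTED = {
    "amplification": ("amplification", "gain"),
    "gain": ("gain",),
    "loss": ("loss",),
    "deletion": ("deletion", "loss"),
}


@dataclass(frozen=True)
class FrequencyRegion:
    chrom: str
    start_bp: int
    end_bp: int
    n_samples_total: int
    count_by_class: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("inverted region coordinates")
        if self.count_by_class.get("gain", 0) < self.count_by_class.get(
            "amplification", 0
        ) or self.count_by_class.get("loss", 0) < self.count_by_class.get(
            "deletion", 0
        ):
            raise ValueError("class nesting violated in counts")

    def frequency(self, cnv_class: str) -> float:
        return self.count_by_class.get(cnv_class, 0) / self.n_samples_total

    @property
    def frequency_by_class(self) -> dict:
        return {c: self.frequency(c) for c in _COUNT_CLASSES}


def minimal_common_regions(
    calls: list[CNVCall],
    n_samples: int | None = None,
) -> list[FrequencyRegion]:
    """Atomic regions of constant per-class carriage across the cohort.

    ``n_samples`` defaults to the number of distinct sample ids present in
    ``calls``; pass it explicitly when some cohort samples contributed no
    calls (they still belong in the frequency denominator).
    """
    sample_ids = sorted({c.sample_id for c in calls})
    if n_samples is None:
        n_samples = len(sample_ids)
    if n_samples < 1:
        raise ValueError("cohort must contain at least one sample")
    for c in calls:
        if c.start_bp > c.end_bp:
            raise ValueError(
                f"inverted call coordinates {c.chrom}:{c.start_bp}-{c.end_bp}"
            )

    out: list[FrequencyRegion] = []
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)

    for chrom in sorted(by_chrom):
        cs = by_chrom[chrom]
        # candidate atomic boundaries: every call start, and every call
        # end + 1 (1-based inclusive arithmetic)
        bounds = sorted({c.start_bp for c in cs} | {c.end_bp + 1 for c in cs})
        atoms = []
        for lo, hi in zip(bounds, bounds[1:]):
            covering = [c for c in cs if c.start_bp <= lo and c.end_bp >= hi - 1]
            if not covering:
                continue
            counts = {k: set() for k in _COUNT_CLASSES}
            for c in covering:
                for cls in _NESTED[c.cnv_class]:
                    counts[cls].add(c.sample_id)
            atoms.append((lo, hi - 1, {k: len(v) for k, v in counts.items()}))

        # merge adjacent atoms with identical count vectors
        merged: list[list] = []
        for lo, hi, counts in atoms:
            if merged and merged[-1][1] + 1 == lo and merged[-1][2] == counts:
                merged[-1][1] = hi
            else:
                merged.append([lo, hi, counts])
        out.extend(
            FrequencyRegion(chrom, lo, hi, n_samples, counts)
            for lo, hi, counts in merged
        )
    return out


def recurrent_regions(
    regions: list[FrequencyRegion],
    classes: tuple[str, ...] = ("gain", "loss"),
    threshold: float = 0.50,
) -> list[FrequencyRegion]:
    """Regions whose best frequency over ``classes`` reaches ``threshold``.

    The comparison is inclusive (frequency >= threshold).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    return [
        r
        for r in regions
        if max(r.frequency(c) for c in classes) >= threshold
    ]


def class_frequency_table(
    regions: list[FrequencyRegion],
    cnv_class: str,
    threshold: float = 0.20,
    feature_map: dict | None = None,
) -> pd.DataFrame:
    """Table of regions with frequency_by_class[cnv_class] >= threshold.

    Columns mirror the published region tables: chrom, start, end,
    frequency (%), and mapped feature names if a region -> names mapping is
    supplied.  Sorted by chromosome then position.
    """
    if cnv_class not in _COUNT_CLASSES:
        raise ValueError(f"unknown cnv class {cnv_class!r}")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    rows = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start_bp)):
        if r.frequency(cnv_class) < threshold:
            continue
        names = feature_map.get((r.chrom, r.start_bp, r.end_bp), []) if feature_map else []
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start_bp,
                "end": r.end_bp,
                "frequency_pct": 100.0 * r.frequency(cnv_class),
                "genes": ", ".join(names),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "frequency_pct", "genes"])
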