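"""Feature annotation: BED/GFF readers, interval overlap, Circos tracks.

Internally everything is 1-based inclusive (the convention genomic region
tables print); BED's 0-based half-open coordinates are converted at the
file boundary.  A feature maps to a region iff their closed intervals
share at least one base pair; strand is ignored.  Chromosome names are
normalized so "chr12" and "12" refer to the same sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "FeatureRecord",
    "read_features",
    "overlap_features",
    "write_circos_tracks",
    "read_circos_track",
    "normalize_chrom",
    "CIRCOS_COLORS",
]

#: Track colors of the four call classes on the genomic map.
CIRCOS_COLORS = {
    "gain": "orange",
    "loss": "purple",
    "amplification": "red",
    "deletion": "green",
}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' so both naming dialects compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class FeatureRecord:
    """A gene or miRNA with 1-based inclusive coordinates."""

    name: str
    feature_type: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"inverted feature {self.name}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r} for {self.name}")


def _gff_attribute(attrs: str, keys=("Name", "ID", "gene", "gene_id")) -> str | None:
    for part in attrs.replace("; ", ";").split(";"):
        part = part.strip()
        for key in keys:
            if part.startswith(key + "=") or part.startswith(key + " "):
                return part[len(key) + 1 :].strip().strip('"')
    return None


def read_features(
    path, fmt: str | None = None, feature_type: str = "gene"
) -> list[FeatureRecord]:
    """Parse a BED or GFF file into FeatureRecords.

    ``fmt`` is inferred from the extension when omitted.  BED is 0-based
    half-open on disk; GFF is 1-based inclusive.  Malformed lines are
    reported with their line numbers.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix == ".bed":
            fmt = "BED"
        elif suffix in (".gff", ".gff3", ".gtf"):
            fmt = "GFF"
        else:
            raise ValueError(f"cannot infer format from {path.name!r}")
    fmt = fmt.upper()
    if fmt not in ("BED", "GFF"):
        raise ValueError(f"unknown format {fmt!r}")

    records: list[FeatureRecord] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    if len(fields) < 4:
                        raise ValueError("fewer than 4 BED columns")
                    chrom, start, end, name = fields[:4]
                    strand = fields[5] if len(fields) > 5 else "."
                    rec = FeatureRecord(
                        name=name,
                        feature_type=feature_type,
                        chrom=normalize_chrom(chrom),
                        start_bp=int(start) + 1,
                        end_bp=int(end),
                        strand=strand if strand in "+-" else ".",
                    )
                else:
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 GFF columns")
                    chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
                    name = _gff_attribute(attrs)
                    if name is None:
                        raise ValueError("no Name/ID/gene attribute")
                    rec = FeatureRecord(
                        name=name,
                        feature_type=feature_type,
                        chrom=normalize_chrom(chrom),
                        start_bp=int(start),
                        end_bp=int(end),
                        strand=strand if strand in "+-" else ".",
                    )
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            records.append(rec)
    if errors:
        raise ValueError(
            f"{path.name}: {len(errors)} malformed line(s): " + "; ".join(errors[:5])
        )
    return records


def overlap_features(regions, features: list[FeatureRecord]) -> dict:
    """Map each region to the features overlapping it by >= 1 bp.

    ``regions`` is any iterable of objects with chrom / start_bp / end_bp
    attributes (FrequencyRegion, CNVCall, ...).  The result maps
    (chrom, start_bp, end_bp) to feature names sorted by position.
    Feature chromosomes absent from the regions trigger a warning only.
    """
    regions = list(regions)
    region_chroms = {normalize_chrom(r.chrom) for r in regions}
    by_chrom: dict[str, list[FeatureRecord]] = {}
    for f in features:
        c = normalize_chrom(f.chrom)
        if c not in region_chroms:
            continue
        by_chrom.setdefault(c, []).append(f)
    orphan = {normalize_chrom(f.chrom) for f in features} - region_chroms
    if orphan:
        warnings.warn(
            f"features on chromosome(s) {sorted(orphan)} have no matching "
            "region chromosome",
            RuntimeWarning,
        )
    mapping: dict = {}
    for r in regions:
        c = normalize_chrom(r.chrom)
        hits = [
            f
            for f in by_chrom.get(c, [])
            if f.start_bp <= r.end_bp and f.end_bp >= r.start_bp
        ]
        hits.sort(key=lambda f: (f.start_bp, f.end_bp, f.name))
        mapping[(r.chrom, r.start_bp, r.end_bp)] = [f.name for f in hits]
    return mapping


def write_circos_tracks(calls, out_dir) -> dict[str, Path]:
    """One Circos data file per call class, colored as on the genomic map.

    Record format is the plain-text Circos convention
    ``chrom start end color=<class color>``; ordering is deterministic
    (chromosome, start, end).  Returns the class -> path mapping; classes
    with no calls still get a header-only file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cls, color in CIRCOS_COLORS.items():
        path = out_dir / f"{cls}.txt"
        rows = sorted(
            (c for c in calls if c.cnv_class == cls),
            key=lambda c: (c.chrom, c.start_bp, c.end_bp),
        )
        with open(path, "w") as fh:
            fh.write(f"# cnvseg circos track: class={cls} color={color}\n")
            for c in rows:
                fh.write(f"{c.chrom} {c.start_bp} {c.end_bp} color={color}\n")
        paths[cls] = path
    return paths


def read_circos_track(path) -> list[tuple[str, int, int]]:
    """Parse a track file written by :func:`write_circos_tracks`."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, *_ = line.split()
            out.append((chrom, int(start), int(end)))
    return out
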