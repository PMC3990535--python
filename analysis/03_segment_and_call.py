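"""Segment each normalized array and emit CNV calls.

Per chromosome, the exact least-squares dynamic program partitions the
log2-ratio series; segments with >= 5 probes and |mean log2| >= 0.25
become calls, classified as amplification (>= 1.0), gain, loss or
deletion (<= -1.0).  Per-sample segment/call tables and the combined
cohort call table land under scratch/sim/.
"""

import argparse
from collections import Counter
from pathlib import Path

from cnvseg import calling, io
from cnvseg.preprocess import Log2RatioTrack
from cnvseg.segment import segment_sample

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", type=Path, default=ROOT / "scratch" / "sim")
    args = ap.parse_args()

    tables = sorted(args.sim_dir.glob("S*.norm.tsv"))
    if not tables:
        raise SystemExit("no normalized tables found; run 02_preprocess.py first")
    all_calls = []
    for path in tables:
        sid = path.stem.split(".")[0]
        layout, _, df = io.read_probe_table(path)
        col = [c for c in df.columns if c.startswith("log2ratio_")][-1]
        track = Log2RatioTrack(df[col].to_numpy(dtype=float),
                               col.removeprefix("log2ratio_"))
        segs = segment_sample(track, layout)
        calls = calling.call_sample(segs, sid)
        io.write_segments(path.with_name(f"{sid}.segments.tsv"), segs)
        io.write_calls(path.with_name(f"{sid}.calls.tsv"), calls)
        all_calls.extend(calls)
        counts = Counter(c.cnv_class for c in calls)
        print(f"{sid}: {len(segs)} segments, {len(calls)} calls "
              f"({dict(sorted(counts.items()))})")

    combined = args.sim_dir / "cohort.calls.tsv"
    io.write_calls(combined, all_calls)
    print(f"cohort: {len(all_calls)} calls from {len(tables)} samples -> {combined}")


if __name__ == "__main__":
    main()
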