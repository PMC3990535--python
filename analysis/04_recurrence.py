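"""Cohort recurrence: minimal common regions and the two frequency tables.

The union of all call breakpoints partitions the covered genome into
minimal common regions with per-class sample counts (amplifications also
count as gains, deletions as losses).  Regions altered in >= 50% of
cases make the gain/loss recurrence table; >= 20% makes the
amplification/deletion table.  Tables land under results/.
"""

import argparse
from pathlib import Path

from cnvseg import io, recurrence

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim-dir", type=Path, default=ROOT / "scratch" / "sim")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results")
    ap.add_argument("--n-samples", type=int, default=20)
    args = ap.parse_args()

    calls = io.read_calls(args.sim_dir / "cohort.calls.tsv")
    regions = recurrence.minimal_common_regions(calls, n_samples=args.n_samples)
    print(f"{len(regions)} minimal common regions from {len(calls)} calls")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    gainloss = recurrence.recurrent_regions(regions, classes=("gain", "loss"),
                                            threshold=0.50)
    for cls in ("gain", "loss"):
        t = recurrence.class_frequency_table(gainloss, cls, threshold=0.50)
        t.to_csv(args.out_dir / f"recurrent_{cls}.tsv", sep="\t", index=False)
        print(f"recurrent {cls} regions (>=50%): {len(t)}")
        for _, row in t.iterrows():
            print(f"  chr{row.chrom}:{row.start}-{row.end}  "
                  f"{row.frequency_pct:.0f}%")
    for cls in ("amplification", "deletion"):
        t = recurrence.class_frequency_table(regions, cls, threshold=0.20)
        t.to_csv(args.out_dir / f"frequent_{cls}.tsv", sep="\t", index=False)
        print(f"frequent {cls} regions (>=20%): {len(t)}")
        for _, row in t.iterrows():
            print(f"  chr{row.chrom}:{row.start}-{row.end}  "
                  f"{row.frequency_pct:.0f}%")


if __name__ == "__main__":
    main()
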