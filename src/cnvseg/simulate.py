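"""Synthetic two-channel aCGH data with known copy-number ground truth.

Everything downstream of the scanner is testable against data produced
here: a NimbleGen-style tiling layout (one probe every ~2509 bp), implanted
copy-number regions expressed as mean log2-ratio shifts, two-channel
intensities with spatial gradients, dye bias and per-probe noise, cohorts
carrying recurrent regions with configurable penetrance, and triplicate
qPCR Ct tables with a known fold change.

The diploid baseline is log2 ratio 0.  CNV classes are encoded purely as
mean-shift magnitude (the calling rules operate on mean log2 ratios, never
on integer copy number).  Default shifts are +/-0.4 for gain/loss and
+/-1.3 for amplification/deletion, comfortably clearing the 0.25 and 1.0
calling thresholds while remaining configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeLayout",
    "TruthRegion",
    "TruthSet",
    "ChannelIntensities",
    "RecurrentRegionSpec",
    "CohortTruth",
    "DEFAULT_SPACING_BP",
    "DEFAULT_CLASS_SHIFTS",
    "CNV_CLASSES",
    "make_layout",
    "implant_truth",
    "simulate_channels",
    "simulate_cohort",
    "simulate_qpcr",
]

#: Median inter-probe spacing of the emulated 720K tiling platform.
DEFAULT_SPACING_BP = 2509

CNV_CLASSES = ("amplification", "gain", "loss", "deletion")

#: Expected mean log2-ratio offset per class; signs are part of the contract.
DEFAULT_CLASS_SHIFTS = {
    "gain": 0.4,
    "loss": -0.4,
    "amplification": 1.3,
    "deletion": -1.3,
}


@dataclass(frozen=True)
class ProbeLayout:
    """Ordered probes with genomic coordinates and array grid positions.

    ``probes`` is a DataFrame with columns probe_id, chrom, pos (1-based bp),
    grid_x, grid_y.  Positions are strictly increasing within a chromosome
    and (grid_x, grid_y) pairs are unique across the array.
    """

    probes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.probes
        required = ["probe_id", "chrom", "pos", "grid_x", "grid_y"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        for chrom, grp in df.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if df.duplicated(subset=["grid_x", "grid_y"]).any():
            raise ValueError("duplicate (grid_x, grid_y) assignments")

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.probes["chrom"]))

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Row indices (layout order) of the probes on ``chrom``."""
        return np.flatnonzero((self.probes["chrom"] == chrom).to_numpy())


@dataclass(frozen=True)
class TruthRegion:
    """A ground-truth CNV: 1-based inclusive interval plus its class and shift."""

    chrom: str
    start: int
    end: int
    cnv_class: str
    log2_shift: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"inverted region {self.chrom}:{self.start}-{self.end}")
        if self.cnv_class not in CNV_CLASSES:
            raise ValueError(f"unknown cnv class {self.cnv_class!r}")
        positive = self.cnv_class in ("gain", "amplification")
        if (self.log2_shift > 0) != positive or self.log2_shift == 0:
            raise ValueError(
                f"log2_shift sign inconsistent with class {self.cnv_class}: "
                f"{self.log2_shift}"
            )


@dataclass(frozen=True)
class TruthSet:
    """Per-probe expected log2 shift plus the regions that produced it."""

    regions: tuple[TruthRegion, ...]
    shift: np.ndarray  # aligned with the layout

    @property
    def shifted_probe_count(self) -> int:
        return int(np.count_nonzero(self.shift))


@dataclass(frozen=True)
class ChannelIntensities:
    """Strictly positive test/reference intensities aligned with a layout."""

    test: np.ndarray
    ref: np.ndarray

    def __post_init__(self) -> None:
        if self.test.shape != self.ref.shape:
            raise ValueError("channel length mismatch")
        if np.any(self.test <= 0) or np.any(self.ref <= 0):
            raise ValueError("intensities must be strictly positive")

    def __len__(self) -> int:
        return len(self.test)


@dataclass(frozen=True)
class RecurrentRegionSpec:
    """A cohort-level recurrent region carried with probability ``penetrance``."""

    region: TruthRegion
    penetrance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError(f"penetrance {self.penetrance} outside [0, 1]")


@dataclass
class CohortTruth:
    sample_ids: list[str]
    regions_by_sample: dict[str, list[TruthRegion]]
    recurrent_spec: list[RecurrentRegionSpec]
    carriage: dict[int, list[str]] = field(default_factory=dict)
    """Maps recurrent-spec index -> sample ids that realized the region."""

    def carriage_fraction(self, spec_index: int) -> float:
        return len(self.carriage.get(spec_index, [])) / len(self.sample_ids)


def make_layout(
    n_chrom: int,
    chrom_length_bp: int,
    spacing_bp: int = DEFAULT_SPACING_BP,
    grid_dims: tuple[int, int] | None = None,
    seed: int = 0,
    chrom_names: list[str] | None = None,
) -> ProbeLayout:
    """Evenly spaced probes per chromosome, scattered over the array grid.

    Each chromosome receives ``floor(chrom_length_bp / spacing_bp)`` probes at
    positions spacing, 2*spacing, ...  Probes are assigned to grid cells by a
    seeded random permutation, so spatial artifacts are independent of
    genomic position — exactly the situation spatial correction assumes.
    """
    if spacing_bp <= 0:
        raise ValueError("spacing must be positive")
    if n_chrom < 1:
        raise ValueError("need at least one chromosome")
    per_chrom = chrom_length_bp // spacing_bp
    if per_chrom < 1:
        raise ValueError("chromosome shorter than probe spacing")
    total = n_chrom * per_chrom
    if grid_dims is None:
        side = int(np.ceil(np.sqrt(total)))
        grid_dims = (side, side)
    rows, cols = grid_dims
    if rows * cols < total:
        raise ValueError(
            f"grid {rows}x{cols} cannot hold {total} probes (capacity {rows * cols})"
        )
    if chrom_names is None:
        chrom_names = [str(i + 1) for i in range(n_chrom)]
    elif len(chrom_names) != n_chrom:
        raise ValueError("chrom_names length mismatch")

    rng = np.random.default_rng(seed)
    cells = rng.permutation(rows * cols)[:total]
    grid_x, grid_y = cells % cols, cells // cols

    chrom = np.repeat(chrom_names, per_chrom)
    pos = np.tile((np.arange(per_chrom) + 1) * spacing_bp, n_chrom)
    probe_id = [f"P{c}_{p:09d}" for c, p in zip(chrom, pos)]
    df = pd.DataFrame(
        {
            "probe_id": probe_id,
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "grid_x": grid_x.astype(np.int64),
            "grid_y": grid_y.astype(np.int64),
        }
    )
    return ProbeLayout(df)


def _as_truth_regions(regions, shifts=None) -> list[TruthRegion]:
    shifts = dict(DEFAULT_CLASS_SHIFTS, **(shifts or {}))
    out = []
    for r in regions:
        if isinstance(r, TruthRegion):
            out.append(r)
        else:
            chrom, start, end, cls = r[:4]
            shift = r[4] if len(r) > 4 else shifts[cls]
            out.append(TruthRegion(str(chrom), int(start), int(end), cls, float(shift)))
    return out


def implant_truth(
    layout: ProbeLayout,
    regions,
    class_shifts: dict[str, float] | None = None,
) -> TruthSet:
    """Turn region tuples into a per-probe expected log2-shift track.

    ``regions`` is a list of TruthRegion or (chrom, start, end, cnv_class
    [, log2_shift]) tuples.  Regions must be pairwise non-overlapping and lie
    within the layout's chromosome bounds.
    """
    truth = _as_truth_regions(regions, class_shifts)
    by_chrom: dict[str, list[TruthRegion]] = {}
    for r in truth:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping truth regions on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
        if chrom in layout.chroms:
            cmax = int(layout.probes.loc[layout.probes["chrom"] == chrom, "pos"].max())
            for r in rs:
                if r.start < 1 or r.start > cmax:
                    raise ValueError(
                        f"region {chrom}:{r.start}-{r.end} outside probe span"
                    )

    shift = np.zeros(len(layout))
    chroms = layout.probes["chrom"].to_numpy()
    pos = layout.probes["pos"].to_numpy()
    for r in truth:
        mask = (chroms == r.chrom) & (pos >= r.start) & (pos <= r.end)
        shift[mask] = r.log2_shift
    return TruthSet(regions=tuple(truth), shift=shift)


def simulate_channels(
    layout: ProbeLayout,
    truth: TruthSet | None = None,
    baseline_intensity: float = 1000.0,
    noise_sd: float = 0.15,
    gradient: tuple[float, float] = (0.0, 0.0),
    dye_bias: float = 0.0,
    seed: int = 0,
) -> ChannelIntensities:
    """Two-channel intensities whose log2 ratio is shift + gradient + bias + noise.

    The noise draw is split symmetrically across channels
    (ref = B*2^(-e/2), test = B*2^(signal + e/2)) so both stay positive by
    construction and the ratio carries exactly Normal(0, noise_sd) noise.
    """
    if baseline_intensity <= 0:
        raise ValueError("baseline intensity must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n = len(layout)
    shift = truth.shift if truth is not None else np.zeros(n)
    if len(shift) != n:
        raise ValueError("truth/layout length mismatch")
    gx, gy = gradient
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    signal = (
        shift
        + gx * layout.probes["grid_x"].to_numpy()
        + gy * layout.probes["grid_y"].to_numpy()
        + dye_bias
    )
    ref = baseline_intensity * np.exp2(-e / 2.0)
    test = baseline_intensity * np.exp2(signal + e / 2.0)
    return ChannelIntensities(test=test, ref=ref)


def _place_private_regions(
    layout: ProbeLayout,
    occupied: list[TruthRegion],
    n_regions: int,
    probe_span: tuple[int, int],
    class_shifts: dict[str, float],
    rng: np.random.Generator,
) -> list[TruthRegion]:
    """Uniformly place private CNVs that avoid already-occupied intervals."""
    spacing_pos = {
        c: layout.probes.loc[layout.probes["chrom"] == c, "pos"].to_numpy()
        for c in layout.chroms
    }
    placed: list[TruthRegion] = []
    classes = ("gain", "loss", "amplification", "deletion")
    weights = (0.4, 0.4, 0.1, 0.1)
    attempts = 0
    while len(placed) < n_regions and attempts < 200 * max(n_regions, 1):
        attempts += 1
        chrom = rng.choice(layout.chroms)
        pos = spacing_pos[chrom]
        span = int(rng.integers(probe_span[0], probe_span[1] + 1))
        if span >= len(pos):
            continue
        i0 = int(rng.integers(0, len(pos) - span))
        start, end = int(pos[i0]), int(pos[i0 + span - 1])
        clash = any(
            r.chrom == chrom and not (end < r.start or start > r.end)
            for r in occupied + placed
        )
        if clash:
            continue
        cls = str(rng.choice(classes, p=weights))
        placed.append(TruthRegion(chrom, start, end, cls, class_shifts[cls]))
    return placed


def simulate_cohort(
    layout: ProbeLayout,
    recurrent_spec: list[RecurrentRegionSpec],
    n_samples: int = 20,
    private_cnv_rate: float = 2.0,
    private_probe_span: tuple[int, int] = (25, 75),
    baseline_intensity: float = 1000.0,
    noise_sd: float = 0.15,
    gradient: tuple[float, float] = (0.0, 0.0),
    dye_bias: float = 0.0,
    class_shifts: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[dict[str, ChannelIntensities], CohortTruth]:
    """A cohort of arrays sharing recurrent regions with Bernoulli penetrance.

    Each sample independently carries every recurrent region with its
    penetrance; on top of that a Poisson(``private_cnv_rate``) number of
    private CNVs per sample are placed uniformly, never overlapping each
    other or the recurrent regions.  The default cohort size of 20 mirrors
    the tumor series the analysis design is aimed at.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    shifts = dict(DEFAULT_CLASS_SHIFTS, **(class_shifts or {}))
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    recurrent_regions = [s.region for s in recurrent_spec]

    intensities: dict[str, ChannelIntensities] = {}
    regions_by_sample: dict[str, list[TruthRegion]] = {}
    carriage: dict[int, list[str]] = {i: [] for i in range(len(recurrent_spec))}

    for sid in sample_ids:
        regions: list[TruthRegion] = []
        for i, spec in enumerate(recurrent_spec):
            if rng.random() < spec.penetrance:
                regions.append(spec.region)
                carriage[i].append(sid)
        n_private = rng.poisson(private_cnv_rate) if private_cnv_rate > 0 else 0
        regions += _place_private_regions(
            layout, recurrent_regions + regions, n_private,
            private_probe_span, shifts, rng,
        )
        truth = implant_truth(layout, regions, shifts)
        sample_seed = int(rng.integers(0, 2**31 - 1))
        intensities[sid] = simulate_channels(
            layout, truth,
            baseline_intensity=baseline_intensity,
            noise_sd=noise_sd, gradient=gradient, dye_bias=dye_bias,
            seed=sample_seed,
        )
        regions_by_sample[sid] = regions

    cohort = CohortTruth(
        sample_ids=sample_ids,
        regions_by_sample=regions_by_sample,
        recurrent_spec=list(recurrent_spec),
        carriage=carriage,
    )
    return intensities, cohort


def simulate_qpcr(
    fold: float,
    control_mean_expression: float = 1.0,
    ct_sd: float = 0.3,
    n_tumor: int = 26,
    n_control: int = 14,
    gene: str = "GENE",
    reference_ct: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Triplicate Ct table whose group expression ratio is ``fold``.

    Group ΔCt means are set to -log2(expression); with ``ct_sd`` = 0 the
    realized fold equals the requested fold exactly (the generative inverse
    of the 2^-ΔCt readout).  Replicate noise of sd ``ct_sd`` cycles is added
    independently to target and reference wells.  Group sizes default to the
    26-tumor / 14-control comparison of the validation experiment.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if control_mean_expression <= 0:
        raise ValueError("control_mean_expression must be positive")
    if ct_sd < 0:
        raise ValueError("ct_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    groups = [("tumor", n_tumor, fold * control_mean_expression),
              ("control", n_control, control_mean_expression)]
    idx = 0
    for group, n, expression in groups:
        delta_ct = -np.log2(expression)
        for _ in range(n):
            idx += 1
            tgt = reference_ct + delta_ct + rng.normal(0.0, ct_sd, 3)
            ref = reference_ct + rng.normal(0.0, ct_sd, 3)
            tgt = np.clip(tgt, 1e-6, 44.999999)
            ref = np.clip(ref, 1e-6, 44.999999)
            rows.append(
                {
                    "sample_id": f"{group[0].upper()}{idx:02d}",
                    "group": group,
                    "gene": gene,
                    "ct_rep1": tgt[0], "ct_rep2": tgt[1], "ct_rep3": tgt[2],
                    "ref_ct_rep1": ref[0], "ref_ct_rep2": ref[1],
                    "ref_ct_rep3": ref[2],
                }
            )
    return pd.DataFrame(rows)
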