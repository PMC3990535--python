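"""End-to-end driver: simulate -> preprocess -> segment -> call -> recur.

Configuration is a single YAML document with one block per stage; unknown
keys are rejected and the defaults are the analysis thresholds the
calling rules define (|mean log2| >= 0.25, 5 probes, amplification at
1.0, recurrence at 50% gain/loss and 20% amplification/deletion,
significance at p < 0.05).  Every stage writes its output before the
next starts, and the machine-readable summary records per-stage counts,
all effective parameters, the seed and a config hash, so a rerun with
the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from copy import deepcopy
from pathlib import Path

import yaml

from . import calling, io, recurrence
from .annotation import write_circos_tracks
from .evaluation import demo_layout, demo_recurrent_spec
from .preprocess import preprocess_sample
from .qpcr import analyze_qpcr_table
from .segment import segment_sample
from .simulate import simulate_cohort, simulate_qpcr

__all__ = ["PipelineConfig", "DEFAULT_CONFIG", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_samples": 20,
        "probes_per_chrom": 600,
        "noise_sd": 0.15,
        "private_cnv_rate": 2.0,
        "gradient": [0.0, 0.0],
        "dye_bias": 0.0,
        "baseline_intensity": 1000.0,
    },
    "preprocess": {
        "order": "spatial-first",
        "span": 0.3,
        "degree": 2,
        "n_anchors": 14,
        "spatial": True,
    },
    "segment": {"penalty": "auto", "kmax": 25},
    "call": {"min_probes": 5, "min_abs_mean": 0.25, "amp_threshold": 1.0},
    "recurrence": {"threshold_gainloss": 0.5, "threshold_ampdel": 0.2},
    "qpcr": {
        "enabled": True,
        "folds": {"GLI1": 6.61, "GEFT": 3.92},
        "ct_sd": 0.3,
        "n_tumor": 26,
        "n_control": 14,
    },
}


class PipelineConfig:
    """Validated stage parameters; unknown keys are rejected."""

    def __init__(self, overrides: dict | None = None) -> None:
        cfg = deepcopy(DEFAULT_CONFIG)
        self._merge(cfg, overrides or {}, path="")
        self._validate(cfg)
        self.data = cfg

    @staticmethod
    def _merge(base: dict, overrides: dict, path: str) -> None:
        for key, value in overrides.items():
            if key not in base:
                raise ValueError(f"unknown config key {path + key!r}")
            if isinstance(base[key], dict) and key != "folds":
                if not isinstance(value, dict):
                    raise ValueError(f"config block {path + key!r} must be a mapping")
                PipelineConfig._merge(base[key], value, path + key + ".")
            else:
                base[key] = value

    @staticmethod
    def _validate(cfg: dict) -> None:
        rec = cfg["recurrence"]
        for key in ("threshold_gainloss", "threshold_ampdel"):
            if not 0 < rec[key] <= 1:
                raise ValueError(f"recurrence.{key} must lie in (0, 1]")
        if cfg["call"]["min_probes"] < 1:
            raise ValueError("call.min_probes must be >= 1")
        if cfg["call"]["min_abs_mean"] < 0:
            raise ValueError("call.min_abs_mean must be >= 0")
        if cfg["preprocess"]["order"] not in ("spatial-first", "qspline-first"):
            raise ValueError("preprocess.order must be spatial-first or qspline-first")
        if cfg["simulate"]["noise_sd"] < 0:
            raise ValueError("simulate.noise_sd must be >= 0")
        pen = cfg["segment"]["penalty"]
        if pen != "auto" and (not isinstance(pen, (int, float)) or pen < 0):
            raise ValueError("segment.penalty must be 'auto' or a non-negative number")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        return cls(overrides)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages on a simulated demo cohort; returns the summary.

    Stage outputs land under ``out_dir``: per-sample probe tables and
    truth BEDs, normalized tracks, segments, calls, the two recurrence
    tables, Circos track files, qPCR results and ``summary.json``.
    """
    cfg = config.data
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cnvseg")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    summary: dict = {
        "config_hash": config.config_hash,
        "seed": cfg["seed"],
        "parameters": cfg,
        "stages": {},
    }
    try:
        sim = cfg["simulate"]
        layout = demo_layout(seed=cfg["seed"], probes_per_chrom=sim["probes_per_chrom"])
        spec = demo_recurrent_spec(layout)
        stage = "simulate"
        intensities, truth = simulate_cohort(
            layout, spec,
            n_samples=sim["n_samples"],
            private_cnv_rate=sim["private_cnv_rate"],
            baseline_intensity=sim["baseline_intensity"],
            noise_sd=sim["noise_sd"],
            gradient=tuple(sim["gradient"]),
            dye_bias=sim["dye_bias"],
            seed=cfg["seed"],
        )
        sim_dir = out / "sim"
        sim_dir.mkdir(exist_ok=True)
        for sid, intens in intensities.items():
            io.write_probe_table(sim_dir / f"{sid}.probes.tsv", layout, intens)
            io.write_truth_bed(sim_dir / f"{sid}.truth.bed", truth.regions_by_sample[sid])
        logger.info("simulated %d samples x %d probes", len(intensities), len(layout))
        summary["stages"]["simulate"] = {
            "n_samples": len(intensities),
            "n_probes": len(layout),
            "recurrent_regions": len(spec),
        }

        stage = "preprocess"
        pp = cfg["preprocess"]
        tracks = {}
        for sid, intens in intensities.items():
            track = preprocess_sample(
                intens, layout,
                order=pp["order"], span=pp["span"], degree=pp["degree"],
                n_anchors=pp["n_anchors"], spatial=pp["spatial"],
            )
            tracks[sid] = track
            io.write_probe_table(
                out / "sim" / f"{sid}.norm.tsv", layout, intens,
                log2_tracks={track.stage: track.values},
            )
        summary["stages"]["preprocess"] = {"order": pp["order"], "n_samples": len(tracks)}

        stage = "segment"
        seg_cfg = cfg["segment"]
        penalty = None if seg_cfg["penalty"] == "auto" else float(seg_cfg["penalty"])
        segments_by_sample = {}
        for sid, track in tracks.items():
            segs = segment_sample(track, layout, penalty=penalty, kmax=seg_cfg["kmax"])
            segments_by_sample[sid] = segs
            io.write_segments(out / "sim" / f"{sid}.segments.tsv", segs)
            logger.info("sample %s: %d segments", sid, len(segs))
        summary["stages"]["segment"] = {
            "total_segments": sum(len(v) for v in segments_by_sample.values())
        }

        stage = "call"
        call_cfg = cfg["call"]
        all_calls = []
        for sid, segs in segments_by_sample.items():
            calls = calling.call_sample(
                segs, sid,
                min_probes=call_cfg["min_probes"],
                min_abs_mean=call_cfg["min_abs_mean"],
                amp_threshold=call_cfg["amp_threshold"],
            )
            all_calls.extend(calls)
        io.write_calls(out / "calls.tsv", all_calls)
        summary["stages"]["call"] = {"total_calls": len(all_calls)}

        stage = "recurrence"
        rec_cfg = cfg["recurrence"]
        regions = recurrence.minimal_common_regions(
            all_calls, n_samples=sim["n_samples"]
        )
        gainloss = recurrence.recurrent_regions(
            regions, classes=("gain", "loss"), threshold=rec_cfg["threshold_gainloss"]
        )
        tables_dir = out / "tables"
        tables_dir.mkdir(exist_ok=True)
        for cls in ("gain", "loss"):
            recurrence.class_frequency_table(
                gainloss, cls, threshold=rec_cfg["threshold_gainloss"]
            ).to_csv(tables_dir / f"recurrent_{cls}.tsv", sep="\t", index=False)
        for cls in ("amplification", "deletion"):
            recurrence.class_frequency_table(
                regions, cls, threshold=rec_cfg["threshold_ampdel"]
            ).to_csv(tables_dir / f"frequent_{cls}.tsv", sep="\t", index=False)
        summary["stages"]["recurrence"] = {
            "minimal_common_regions": len(regions),
            "recurrent_gain_loss": len(gainloss),
        }

        stage = "annotate"
        write_circos_tracks(all_calls, out / "circos")
        summary["stages"]["annotate"] = {"circos_tracks": 4}

        stage = "qpcr"
        qcfg = cfg["qpcr"]
        if qcfg["enabled"]:
            qpcr_rows = []
            for i, (gene, fold) in enumerate(sorted(qcfg["folds"].items())):
                table = simulate_qpcr(
                    fold=float(fold), ct_sd=qcfg["ct_sd"],
                    n_tumor=qcfg["n_tumor"], n_control=qcfg["n_control"],
                    gene=gene, seed=cfg["seed"] + i + 1,
                )
                (res,) = analyze_qpcr_table(table, genes=[gene])
                qpcr_rows.append(
                    {
                        "gene": gene,
                        "fold_change": round(res.fold_change, 6),
                        "t_statistic": round(res.t_statistic, 6),
                        "p_value": round(res.p_value, 6),
                    }
                )
            summary["stages"]["qpcr"] = {"genes": qpcr_rows}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
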