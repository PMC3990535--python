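"""Relative quantification of qPCR data: delta-Ct, 2^-dCt, group fold change.

Per sample, triplicate Ct values of the target gene and the reference
(housekeeping) gene are averaged, the difference dCt = Ct_target -
Ct_reference is formed, and the relative expression level is 2^-dCt.
Group comparison follows the validation design: fold change is the ratio
of group mean expressions (tumor over control) and significance comes
from an independent-samples t-test on the expression values (Welch by
default, pooled-variance optionally), declared at p < 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneResult",
    "aggregate_replicates",
    "delta_ct",
    "expression_level",
    "group_fold",
    "group_compare",
    "analyze_qpcr_table",
]

_REP_COLS = ["ct_rep1", "ct_rep2", "ct_rep3"]
_REF_COLS = ["ref_ct_rep1", "ref_ct_rep2", "ref_ct_rep3"]


@dataclass(frozen=True)
class GeneResult:
    """Per-gene outcome of the relative-quantification analysis."""

    gene: str
    fold_change: float
    tumor_mean: float
    control_mean: float
    tumor_sem: float
    control_sem: float
    t_statistic: float
    p_value: float
    per_sample: pd.DataFrame

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def aggregate_replicates(cts) -> float:
    """Arithmetic mean of the finite replicate Ct values.

    Missing (NaN) replicates are dropped with a warning; all-missing input
    is an error.
    """
    cts = np.asarray(cts, dtype=float)
    finite = cts[np.isfinite(cts)]
    if finite.size == 0:
        raise ValueError("no finite replicate Ct values")
    if finite.size < cts.size:
        warnings.warn(
            f"{cts.size - finite.size} missing replicate(s) dropped", RuntimeWarning
        )
    return float(finite.mean())


def delta_ct(target_ct: float, reference_ct: float) -> float:
    """dCt = Ct(target) - Ct(reference); larger dCt means lower expression."""
    if not (math.isfinite(target_ct) and math.isfinite(reference_ct)):
        raise ValueError("Ct values must be finite")
    return target_ct - reference_ct


def expression_level(dct: float) -> float:
    """Relative expression 2^-dCt."""
    if not math.isfinite(dct):
        raise ValueError("delta Ct must be finite")
    return float(2.0 ** (-dct))


def group_fold(tumor_expressions, control_expressions):
    """Fold change = mean(tumor) / mean(control), with group means and SEMs."""
    t = np.asarray(tumor_expressions, dtype=float)
    c = np.asarray(control_expressions, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    if c.mean() == 0:
        raise ValueError("control mean expression is zero")

    def sem(x):
        return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0

    fold = float(t.mean() / c.mean())
    return fold, (float(t.mean()), float(c.mean())), (sem(t), sem(c))


def group_compare(
    tumor_expressions, control_expressions, equal_var: bool = False
):
    """Two-sided independent-samples t-test on expression values.

    Welch's correction by default; set ``equal_var`` for the classic
    pooled-variance test.
    """
    t = np.asarray(tumor_expressions, dtype=float)
    c = np.asarray(control_expressions, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    res = stats.ttest_ind(t, c, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def analyze_qpcr_table(
    table: pd.DataFrame,
    genes: list[str] | None = None,
    equal_var: bool = False,
    test_scale: str = "expression",
) -> list[GeneResult]:
    """Full relative-quantification analysis of a triplicate Ct table.

    Expected columns: sample_id, group (tumor/control), gene,
    ct_rep1..3, ref_ct_rep1..3.  ``test_scale`` selects whether the group
    test runs on 2^-dCt expression values (default, matching the
    validation design) or directly on dCt.
    """
    if test_scale not in ("expression", "delta_ct"):
        raise ValueError(f"unknown test scale {test_scale!r}")
    missing = [c for c in ["sample_id", "group", "gene", *_REP_COLS, *_REF_COLS]
               if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if genes is None:
        genes = list(dict.fromkeys(table["gene"]))

    results = []
    for gene in genes:
        sub = table[table["gene"] == gene]
        if sub.empty:
            raise ValueError(f"no rows for gene {gene!r}")
        rows = []
        for _, row in sub.iterrows():
            tgt = aggregate_replicates(row[_REP_COLS].to_numpy(dtype=float))
            ref = aggregate_replicates(row[_REF_COLS].to_numpy(dtype=float))
            dct = delta_ct(tgt, ref)
            rows.append(
                {
                    "sample_id": row["sample_id"],
                    "group": row["group"],
                    "delta_ct": dct,
                    "expression": expression_level(dct),
                }
            )
        per_sample = pd.DataFrame(rows)
        tumor = per_sample.loc[per_sample["group"] == "tumor"]
        control = per_sample.loc[per_sample["group"] == "control"]
        if tumor.empty or control.empty:
            raise ValueError(f"gene {gene!r}: need both tumor and control samples")
        fold, (tm, cm), (tsem, csem) = group_fold(
            tumor["expression"], control["expression"]
        )
        col = "expression" if test_scale == "expression" else "delta_ct"
        tstat, p = group_compare(tumor[col], control[col], equal_var=equal_var)
        results.append(
            GeneResult(
                gene=gene,
                fold_change=fold,
                tumor_mean=tm,
                control_mean=cm,
                tumor_sem=tsem,
                control_sem=csem,
                t_statistic=tstat,
                p_value=p,
                per_sample=per_sample,
            )
        )
    return results
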