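"""Interpretation of methylation-specific PCR (MSP) runs.

Per sample the pipeline applies, in order:

1. **Validity gate** — the reaction is valid only when the reference gene
   ACTB amplified with Ct ≤ 36 (enough intact human DNA in the well).
2. **Per-gene calls** — a target gene (SDC2, TFPI2) is methylation positive
   when its Ct is numeric and ≤ 38; NO_AMP is negative.
3. **Combined call** — the dual-marker OR rule: positive if any target gene
   is positive.
4. **Relative methylation level** — ML = 2^−ΔΔCt with
   ΔΔCt = (Ct_target − Ct_ACTB)_sample − (Ct_target − Ct_ACTB)_calibrator,
   the calibrator being the fully methylated positive-control plasmid mix.
   A NO_AMP target has ML = 0 (no detectable methylated template).

For ROC analysis two scalar scores per sample are also produced: the
combined Ct score (min target Ct, NO_AMP coerced to the 45-cycle run length
— the only place that coercion happens) and the combined ML score (max
target ML).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CtTable,
    MAX_CYCLES,
    NO_AMP,
    REFERENCE_GENE,
    TARGET_GENES,
    ValidationError,
    is_no_amp,
)

__all__ = [
    "CallConfig",
    "CallResult",
    "validity",
    "gene_positive",
    "methylation_level",
    "call_sample",
    "call_cohort",
    "write_call_report",
]


@dataclass(frozen=True)
class CallConfig:
    """Fixed MSP decision thresholds.

    ct_cutoff_target : Ct at or below which a target gene is positive (38).
    ct_cutoff_actb   : maximum reference-gene Ct for a valid reaction (36).
    no_amp_ct_for_scoring : Ct substituted for NO_AMP when building the
        combined ROC score (the 45-cycle run length).
    ml_for_no_amp    : ML assigned to a NO_AMP target (0).
    """

    ct_cutoff_target: float = 38.0
    ct_cutoff_actb: float = 36.0
    no_amp_ct_for_scoring: float = MAX_CYCLES
    ml_for_no_amp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ct_cutoff_target", "ct_cutoff_actb", "no_amp_ct_for_scoring"):
            v = getattr(self, name)
            if not (0.0 < v <= MAX_CYCLES):
                raise ValidationError(f"{name}={v} outside (0, {MAX_CYCLES}]")


@dataclass
class CallResult:
    """Per-sample MSP interpretation.

    For an invalid sample (ACTB gate failed) ``gene_calls``,
    ``combined_call`` and the scores are absent (None).
    """

    sample_id: str
    valid: bool
    gene_calls: dict[str, bool] | None = None
    combined_call: bool | None = None
    ml: dict[str, float] = field(default_factory=dict)
    combined_score_ct: float | None = None
    combined_score_ml: float | None = None


def validity(ct_actb: object, config: CallConfig = CallConfig()) -> bool:
    """Reaction validity: ACTB amplified with Ct ≤ the 36-cycle gate."""
    if is_no_amp(ct_actb):
        return False
    return float(ct_actb) <= config.ct_cutoff_actb  # type: ignore[arg-type]


def gene_positive(ct: object, config: CallConfig = CallConfig()) -> bool:
    """Target-gene methylation call: positive iff Ct numeric and ≤ 38."""
    if is_no_amp(ct):
        return False
    return float(ct) <= config.ct_cutoff_target  # type: ignore[arg-type]


def methylation_level(
    ct_target: object,
    ct_actb: float,
    calib_target: float,
    calib_actb: float,
    config: CallConfig = CallConfig(),
) -> float:
    """Relative methylation level ML = 2^−ΔΔCt against the calibrator.

    ΔΔCt = (Ct_target − Ct_ACTB)_sample − (Ct_target − Ct_ACTB)_calibrator.
    A NO_AMP target returns ``config.ml_for_no_amp`` without computing.
    """
    if is_no_amp(ct_target):
        return config.ml_for_no_amp
    for name, v in (("ct_actb", ct_actb), ("calib_target", calib_target),
                    ("calib_actb", calib_actb)):
        if is_no_amp(v):
            raise ValidationError(f"methylation_level: {name} is NO_AMP/missing")
    ddct = (float(ct_target) - float(ct_actb)) - (float(calib_target) - float(calib_actb))  # type: ignore[arg-type]
    return float(2.0 ** (-ddct))


def call_sample(
    sample_id: str,
    cts: Mapping[str, object],
    calibrator: Mapping[str, float],
    config: CallConfig = CallConfig(),
    target_genes: Sequence[str] = TARGET_GENES,
) -> CallResult:
    """Full interpretation of one sample's wells.

    ``cts`` maps gene → Ct or NO_AMP and must contain the reference gene and
    at least one target gene.
    """
    if REFERENCE_GENE not in cts:
        raise ValidationError(f"sample {sample_id!r}: missing {REFERENCE_GENE} row")
    targets = [g for g in target_genes if g in cts]
    if not targets:
        raise ValidationError(f"sample {sample_id!r}: no target-gene rows")
    ct_actb = cts[REFERENCE_GENE]
    if not validity(ct_actb, config):
        return CallResult(sample_id=sample_id, valid=False)
    gene_calls = {g: gene_positive(cts[g], config) for g in targets}
    ml = {
        g: methylation_level(cts[g], float(ct_actb), calibrator[g],  # type: ignore[arg-type]
                             calibrator[REFERENCE_GENE], config)
        for g in targets
    }
    score_ct = min(
        config.no_amp_ct_for_scoring if is_no_amp(cts[g]) else float(cts[g])  # type: ignore[arg-type]
        for g in targets
    )
    return CallResult(
        sample_id=sample_id,
        valid=True,
        gene_calls=gene_calls,
        combined_call=any(gene_calls.values()),
        ml=ml,
        combined_score_ct=score_ct,
        combined_score_ml=max(ml.values()),
    )


def call_cohort(
    table: CtTable,
    config: CallConfig = CallConfig(),
    target_genes: Sequence[str] = TARGET_GENES,
) -> pd.DataFrame:
    """Call every sample of a Ct table; one row per sample.

    Columns: valid, ct_<gene>, call_<gene>, ml_<gene> per target gene plus
    ct_ACTB, call_combined, score_ct, score_ml.  Invalid samples keep their
    raw Cts but have NA calls/scores.
    """
    rows = []
    for sid in table.sample_ids:
        cts = table.sample_cts(sid)
        res = call_sample(sid, cts, table.calibrator, config, target_genes)
        row: dict[str, object] = {"sample_id": sid, "valid": res.valid}
        for g in target_genes:
            if g in cts:
                row[f"ct_{g}"] = np.nan if is_no_amp(cts[g]) else float(cts[g])  # type: ignore[arg-type]
        row[f"ct_{REFERENCE_GENE}"] = (
            np.nan if is_no_amp(cts[REFERENCE_GENE]) else float(cts[REFERENCE_GENE])  # type: ignore[arg-type]
        )
        if res.valid:
            for g, c in res.gene_calls.items():  # type: ignore[union-attr]
                row[f"call_{g}"] = c
            for g, m in res.ml.items():
                row[f"ml_{g}"] = m
            row["call_combined"] = res.combined_call
            row["score_ct"] = res.combined_score_ct
            row["score_ml"] = res.combined_score_ml
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    for col in df.columns:
        if col.startswith("call_"):
            df[col] = df[col].astype("boolean")
    return df


def write_call_report(report: pd.DataFrame, path: str | Path) -> None:
    report.reset_index().to_csv(path, index=False, na_rep="NA")
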