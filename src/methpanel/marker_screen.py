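"""Discovery of a complementary methylation marker from β-value cohorts.

The screen works at CpG-island level: a gene's methylation level in a sample
is the arithmetic mean β over the island's probes, a sample is methylation
*positive* for the gene when that level exceeds 0.2 (strictly), and
*hypomethylated* when the level is at or below 0.2.  Starting from an anchor
gene (SDC2 here), the screen

1. selects the anchor-hypomethylated samples (the anchor's false negatives),
2. scores every other island by the fraction of those samples in which it is
   methylation positive (the *complement rate*), and
3. ranks islands by complement rate, the top hit being the best candidate
   second marker.

Subsite breakdown tables (positive / negative / total / rate % per tumor
location) mirror the published contingency layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    BetaMatrix,
    Location,
    ProbeAnnotation,
    SampleRecord,
    ValidationError,
    records_to_frame,
)

logger = logging.getLogger("methpanel")

__all__ = [
    "BETA_THRESHOLD",
    "round_half_up",
    "island_beta",
    "beta_call",
    "beta_calls",
    "select_hypomethylated",
    "joint_positive",
    "complement_screen",
    "ScreenResult",
    "subsite_rate_table",
]

#: Island-level β threshold separating the unmethylated peak (≤ 0.2) from the
#: methylated peak (> 0.2) of the bimodal 450k β distribution.
BETA_THRESHOLD = 0.2


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at ``decimals`` places (table convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def island_beta(matrix: BetaMatrix, probe_ids: Sequence[str]) -> pd.Series:
    """Per-sample island methylation level: mean β over the island's probes.

    Missing probe values are excluded from the mean; a sample with every
    probe missing gets a missing level (NaN) and a warning.
    """
    if len(probe_ids) == 0:
        raise ValidationError("island_beta: empty probe list")
    missing = [p for p in probe_ids if p not in matrix.values.index]
    if missing:
        raise ValidationError(f"island_beta: probes not in matrix: {missing[:5]}")
    sub = matrix.values.loc[list(probe_ids)]
    levels = sub.mean(axis=0, skipna=True)
    all_missing = sub.isna().all(axis=0)
    if all_missing.any():
        logger.warning(
            "island level missing for %d sample(s) (all probes NA): %s",
            int(all_missing.sum()),
            list(levels.index[all_missing])[:5],
        )
    levels.name = "island_beta"
    return levels


def beta_call(level: float, threshold: float = BETA_THRESHOLD) -> bool | None:
    """Methylation call at a β level: positive iff level > threshold (strict).

    A missing level yields a missing call (None).
    """
    if level is None or (isinstance(level, float) and np.isnan(level)):
        return None
    if not 0.0 <= level <= 1.0:
        raise ValidationError(f"beta level {level} outside [0,1]")
    return bool(level > threshold)


def beta_calls(levels: pd.Series, threshold: float = BETA_THRESHOLD) -> pd.Series:
    """Vectorized :func:`beta_call`: nullable-boolean Series per sample."""
    out = pd.Series(pd.array(levels > threshold, dtype="boolean"), index=levels.index)
    out[levels.isna()] = pd.NA
    return out


def select_hypomethylated(
    anchor_levels: pd.Series, threshold: float = BETA_THRESHOLD
) -> set[str]:
    """Samples whose anchor island level is ≤ threshold (anchor-negative)."""
    keep = anchor_levels.notna() & (anchor_levels <= threshold)
    return set(anchor_levels.index[keep])


def joint_positive(call_a: bool | None, call_b: bool | None) -> bool | None:
    """Combine two marker calls by logical OR (dual-marker rule).

    Missing propagates conservatively: one missing call plus one positive is
    positive; one missing plus one negative stays missing.
    """
    if call_a is None and call_b is None:
        return None
    if call_a is None:
        return True if call_b else None
    if call_b is None:
        return True if call_a else None
    return bool(call_a or call_b)


@dataclass
class ScreenResult:
    """Outcome of the genome-wide complement screen.

    ``ranking``: one row per island, sorted by ``complement_rate`` descending
    (ties broken by gene name ascending), with columns gene, island_id,
    n_hypo, n_scored, n_positive, complement_rate (percent).
    ``calls``: island × hypo-sample nullable-boolean call matrix, kept so
    subsite breakdowns can be derived without recomputation.
    """

    ranking: pd.DataFrame
    calls: pd.DataFrame
    threshold: float = BETA_THRESHOLD

    @property
    def top_gene(self) -> str:
        return str(self.ranking.iloc[0]["gene"])

    def location_table(
        self,
        island_id: str,
        records: Iterable[SampleRecord],
        decimals: int = 2,
    ) -> pd.DataFrame:
        """Per-location positive/negative/total/rate table for one island."""
        calls = self.calls.loc[island_id]
        return subsite_rate_table(calls, records, decimals=decimals)


def complement_screen(
    matrix: BetaMatrix,
    annotation: ProbeAnnotation,
    hypo_samples: set[str],
    threshold: float = BETA_THRESHOLD,
    per_probe: bool = False,
) -> ScreenResult:
    """Rank islands by methylation-positive rate within anchor-negative samples.

    For every island in the annotation, ``complement_rate`` is
    ``100 * (#hypo samples with island level > threshold) /
    (#hypo samples with a non-missing level)``.

    With ``per_probe=True`` each probe is screened as its own one-probe
    island (not the standard island-level procedure; exposed for
    exploration).
    """
    if not hypo_samples:
        raise ValidationError("complement_screen: empty hypomethylated sample set")
    missing = hypo_samples - set(matrix.sample_ids)
    if missing:
        raise ValidationError(f"hypo samples not in matrix: {sorted(missing)[:5]}")
    cols = [s for s in matrix.sample_ids if s in hypo_samples]

    if per_probe:
        islands = {
            p: (g, [p])
            for p, g in zip(annotation.table["probe_id"], annotation.table["gene"])
        }
    else:
        islands = annotation.islands()

    rows = []
    call_rows = {}
    for island_id, (gene, probes) in islands.items():
        levels = island_beta(matrix, probes)[cols]
        calls = beta_calls(levels, threshold)
        n_scored = int(levels.notna().sum())
        n_pos = int((calls == True).sum())  # noqa: E712 - nullable boolean
        rate = 100.0 * n_pos / n_scored if n_scored else float("nan")
        rows.append(
            {
                "gene": gene,
                "island_id": island_id,
                "n_hypo": len(cols),
                "n_scored": n_scored,
                "n_positive": n_pos,
                "complement_rate": rate,
            }
        )
        call_rows[island_id] = calls
    ranking = pd.DataFrame(rows).sort_values(
        ["complement_rate", "gene"], ascending=[False, True], kind="mergesort"
    )
    ranking.insert(0, "rank", np.arange(1, len(ranking) + 1))
    calls_df = pd.DataFrame(call_rows).T
    calls_df.index.name = "island_id"
    return ScreenResult(ranking=ranking.reset_index(drop=True), calls=calls_df,
                        threshold=threshold)


def subsite_rate_table(
    calls: pd.Series | Mapping[str, bool | None],
    records: Iterable[SampleRecord],
    by: str = "location",
    decimals: int = 2,
) -> pd.DataFrame:
    """Positive / negative / total counts and positivity rate per subsite.

    ``calls`` maps sample_id → positive/negative (missing calls are dropped
    from the denominators).  Rates are ``100 * positive / total`` rounded
    half-up to ``decimals``; a ``Total`` row aggregates all strata, and the
    per-stratum counts partition it exactly.
    """
    calls = pd.Series(dict(calls)) if not isinstance(calls, pd.Series) else calls
    meta = records_to_frame(records)
    common = [s for s in calls.index if s in meta.index and calls[s] is not pd.NA
              and calls[s] is not None]
    if not common:
        raise ValidationError("subsite_rate_table: no scored samples with metadata")
    sub = pd.DataFrame(
        {"positive": calls[common].astype(bool), by: meta.loc[common, by]}
    )
    grouped = sub.groupby(by, sort=True)["positive"].agg(
        positive="sum", total="count"
    )
    grouped["negative"] = grouped["total"] - grouped["positive"]
    total_row = pd.DataFrame(
        {
            "positive": [int(sub["positive"].sum())],
            "total": [len(sub)],
            "negative": [int((~sub["positive"]).sum())],
        },
        index=pd.Index(["Total"], name=by),
    )
    table = pd.concat([grouped, total_row])
    table["rate"] = [
        round_half_up(100.0 * p / t, decimals) for p, t in zip(table["positive"], table["total"])
    ]
    return table[["positive", "negative", "total", "rate"]].astype(
        {"positive": int, "negative": int, "total": int}
    )
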