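"""Domain types and plain-text readers/writers for methylation-panel data.

The pipeline works on three kinds of tables:

* **β-value matrices** — Illumina 450k-style exports, probes in rows and
  samples in columns, every non-missing entry a methylated fraction in
  ``[0, 1]``.
* **Ct tables** — long-format methylation-specific PCR (MSP) results, one row
  per (sample, gene) with a threshold cycle or the no-amplification state,
  plus positive/negative control wells.
* **Sample metadata** — diagnostic group (CRC / adenoma / normal), tumor
  location and cohort tag per sample.

All readers validate on load and raise :class:`ValidationError` with the
offending row/column named.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methpanel")

__all__ = [
    "ValidationError",
    "Group",
    "Location",
    "LOCATION_ALIASES",
    "normalize_location",
    "TARGET_GENES",
    "REFERENCE_GENE",
    "GENES",
    "MAX_CYCLES",
    "NO_AMP",
    "is_no_amp",
    "SDC2_ISLAND_PROBES",
    "ProbeAnnotation",
    "BetaMatrix",
    "SampleRecord",
    "CtMeasurement",
    "CtTable",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_sample_metadata",
    "write_sample_metadata",
    "records_to_frame",
    "read_ct_table",
    "write_ct_table",
]


class ValidationError(ValueError):
    """Raised when an input file or object violates a data-model invariant."""


# --------------------------------------------------------------------------
# Controlled vocabularies
# --------------------------------------------------------------------------

class Group(str, enum.Enum):
    """Diagnostic group of a sample."""

    CRC = "CRC"
    adenoma = "adenoma"
    normal = "normal"


class Location(str, enum.Enum):
    """Colorectal subsite vocabulary (anatomical strata of the tumor)."""

    left_colon = "left_colon"
    right_colon = "right_colon"
    sigmoid_colon = "sigmoid_colon"
    rectum = "rectum"
    rectosigmoid_junction = "rectosigmoid_junction"
    descending_colon = "descending_colon"
    ascending_colon = "ascending_colon"
    transverse_colon = "transverse_colon"
    splenic_flexure = "splenic_flexure"
    hepatic_flexure = "hepatic_flexure"
    colon_NOS = "colon_NOS"
    rectum_NOS = "rectum_NOS"
    other = "other"
    unknown = "unknown"


#: Default alias table mapping free-text location strings (as they appear in
#: clinical exports) onto the controlled vocabulary.  Keys are matched after
#: ``strip().casefold()``; it is config-extensible via ``normalize_location``.
LOCATION_ALIASES: dict[str, Location] = {
    "left colon": Location.left_colon,
    "right colon": Location.right_colon,
    "sigmoid colon": Location.sigmoid_colon,
    "rectum": Location.rectum,
    "rectal": Location.rectum,
    "rectosigmoid junction": Location.rectosigmoid_junction,
    "descending colon": Location.descending_colon,
    "ascending colon": Location.ascending_colon,
    "transverse colon": Location.transverse_colon,
    "splenic flexure of the colon": Location.splenic_flexure,
    "splenic flexure": Location.splenic_flexure,
    "hepatic flexure of the colon": Location.hepatic_flexure,
    "hepatic flexure": Location.hepatic_flexure,
    "colon, nos": Location.colon_NOS,
    "rectum, nos": Location.rectum_NOS,
    "unknown": Location.unknown,
    "other": Location.other,
    "connective, subcutaneous, and other soft tissues of the abdomen": Location.other,
}
# enum value names map to themselves
LOCATION_ALIASES.update({loc.value.casefold(): loc for loc in Location})


def normalize_location(
    raw: str, aliases: Mapping[str, Location] | None = None
) -> Location:
    """Map a free-text location string onto the controlled vocabulary.

    Unmapped strings fall back to :attr:`Location.other` with a logged
    warning, so that the mapping is total.
    """
    table = LOCATION_ALIASES if aliases is None else {**LOCATION_ALIASES, **aliases}
    key = raw.strip().casefold()
    if key in table:
        return table[key]
    logger.warning("unmapped tumor location %r -> 'other'", raw)
    return Location.other


#: Genes assayed by the MSP panel: two methylation targets and the reference.
TARGET_GENES: tuple[str, ...] = ("SDC2", "TFPI2")
REFERENCE_GENE = "ACTB"
GENES: tuple[str, ...] = TARGET_GENES + (REFERENCE_GENE,)

#: MSP run length in cycles; Ct values beyond this are impossible.
MAX_CYCLES = 45.0


class _NoAmp:
    """Singleton marker for 'no amplification within the run'.

    Distinct from a numeric Ct: it is never silently coerced to a cycle
    number at the data layer (coercion to ``MAX_CYCLES`` happens only when
    building ROC scores, see :mod:`methpanel.msp_calls`).
    """

    _instance = None
    __slots__ = ()

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_AMP"


NO_AMP = _NoAmp()


def is_no_amp(ct: object) -> bool:
    """True for the NO_AMP sentinel, None, or NaN (file-level encodings)."""
    if ct is NO_AMP or ct is None:
        return True
    return isinstance(ct, float) and np.isnan(ct)


#: The 12 array probes of the SDC2 promoter CpG island used for island-level
#: methylation scoring.
SDC2_ISLAND_PROBES: tuple[str, ...] = (
    "cg13096260",
    "cg18719750",
    "cg24732574",
    "cg08979737",
    "cg25070637",
    "cg14538332",
    "cg16935295",
    "cg04261408",
    "cg14625631",
    "cg10292139",
    "cg16673702",
    "cg07146119",
)


# --------------------------------------------------------------------------
# Probe annotation
# --------------------------------------------------------------------------

@dataclass
class ProbeAnnotation:
    """Probe → gene / CpG-island mapping.

    ``table`` has columns ``probe_id``, ``gene``, ``island_id``; probe ids are
    unique and every island has at least one probe.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "gene", "island_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        dup = self.table["probe_id"][self.table["probe_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate probe_id in annotation: {dup.iloc[0]!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])

    def islands(self) -> dict[str, tuple[str, list[str]]]:
        """Return ``island_id -> (gene, [probe_ids])``."""
        out: dict[str, tuple[str, list[str]]] = {}
        for island_id, sub in self.table.groupby("island_id", sort=True):
            genes = sub["gene"].unique()
            out[str(island_id)] = (str(genes[0]), list(sub["probe_id"]))
        return out

    def probes_for_gene(self, gene: str) -> list[str]:
        sel = self.table.loc[self.table["gene"] == gene, "probe_id"]
        if sel.empty:
            raise ValidationError(f"gene {gene!r} not in annotation")
        return list(sel)


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, dtype=str)
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Beta matrix
# --------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Probe × sample matrix of methylated fractions (β values).

    ``values`` is a DataFrame indexed by probe id with one column per sample;
    missing β are NaN, all non-missing entries lie in ``[0, 1]``.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample_id: {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValidationError(
                f"beta value {vals[i, j]} outside [0,1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_beta_matrix(path: str | Path, sep: str | None = None) -> BetaMatrix:
    """Read a delimited β matrix: first column probe_id, one column per sample.

    Missing β may be encoded as empty fields or ``NA``.
    """
    path = Path(path)
    sep = sep or _sep_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    if df.index.name is None or df.columns.size == 0:
        raise ValidationError(f"malformed beta-matrix header in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric beta value in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    matrix.values.to_csv(path, sep=sep or _sep_for(path), index_label="probe_id", na_rep="NA")


# --------------------------------------------------------------------------
# Sample metadata
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    """Identity and clinical annotation of one sample."""

    sample_id: str
    group: Group
    location: Location = Location.unknown
    cohort: str = ""


def read_sample_metadata(
    path: str | Path, aliases: Mapping[str, Location] | None = None
) -> list[SampleRecord]:
    """Read sample metadata CSV with columns sample_id, group, location, cohort.

    Location strings are mapped through the alias table (unmapped → ``other``
    with a warning); an unknown diagnostic group is an error.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise ValidationError(f"metadata missing columns: {sorted(required - set(df.columns))}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample_id in metadata: {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        try:
            group = Group(row.group.strip())
        except ValueError:
            raise ValidationError(
                f"unknown group {row.group!r} for sample {row.sample_id!r}; "
                f"expected one of {[g.value for g in Group]}"
            ) from None
        raw_loc = getattr(row, "location", "") or "unknown"
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                group=group,
                location=normalize_location(raw_loc, aliases),
                cohort=str(getattr(row, "cohort", "") or ""),
            )
        )
    return records


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Tabular view of sample records, indexed by sample_id."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group": [r.group.value for r in records],
            "location": [r.location.value for r in records],
            "cohort": [r.cohort for r in records],
        }
    )
    return df.set_index("sample_id")


def write_sample_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    records_to_frame(records).reset_index().to_csv(path, index=False)


# --------------------------------------------------------------------------
# Ct tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CtMeasurement:
    """One MSP well: sample, gene, and threshold cycle (or NO_AMP)."""

    sample_id: str
    gene: str
    ct: float | _NoAmp

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValidationError(f"unknown gene {self.gene!r}; expected one of {GENES}")
        if not is_no_amp(self.ct):
            ct = float(self.ct)  # type: ignore[arg-type]
            if not (0.0 < ct <= MAX_CYCLES):
                raise ValidationError(
                    f"Ct {ct} for ({self.sample_id}, {self.gene}) outside (0, {MAX_CYCLES}]"
                )


#: Reserved sample ids flagging control wells in Ct files.
POSITIVE_CONTROL_ID = "POS_CTRL"
NEGATIVE_CONTROL_ID = "NEG_CTRL"


@dataclass
class CtTable:
    """Per-sample MSP Ct measurements plus the control wells.

    ``measurements``: DataFrame with columns ``sample_id``, ``gene``, ``ct``
    (float; NaN encodes NO_AMP).  ``calibrator`` maps each assayed gene to the
    positive-control Ct (finite for every gene — the calibrator anchors the
    2^−ΔΔCt computation).  ``negative_control`` maps gene → Ct or NO_AMP.
    """

    measurements: pd.DataFrame
    calibrator: dict[str, float]
    negative_control: dict[str, float | _NoAmp] = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"sample_id", "gene", "ct"}
        if not req <= set(self.measurements.columns):
            raise ValidationError(
                f"Ct table missing columns: {sorted(req - set(self.measurements.columns))}"
            )
        dup = self.measurements.duplicated(subset=["sample_id", "gene"])
        if dup.any():
            row = self.measurements[dup].iloc[0]
            raise ValidationError(
                f"duplicate (sample_id, gene) pair: ({row.sample_id!r}, {row.gene!r})"
            )
        genes_present = set(self.measurements["gene"].unique()) | {REFERENCE_GENE}
        for gene in sorted(genes_present):
            ct = self.calibrator.get(gene)
            if ct is None or is_no_amp(ct) or not np.isfinite(ct):
                raise ValidationError(f"calibrator incomplete: no finite Ct for {gene!r}")
        ct = self.measurements["ct"]
        bad = ct.notna() & ((ct <= 0) | (ct > MAX_CYCLES))
        if bad.any():
            row = self.measurements[bad].iloc[0]
            raise ValidationError(
                f"Ct {row.ct} for ({row.sample_id!r}, {row.gene!r}) outside (0, {MAX_CYCLES}]"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.measurements["sample_id"]))

    def sample_cts(self, sample_id: str) -> dict[str, float | _NoAmp]:
        """Ct per gene for one sample, with NaN decoded back to NO_AMP."""
        sub = self.measurements[self.measurements["sample_id"] == sample_id]
        return {
            g: (NO_AMP if np.isnan(c) else float(c))
            for g, c in zip(sub["gene"], sub["ct"])
        }


#: Ct-file tokens accepted for the no-amplification state.  "Undetermined" is
#: the instrument-export dialect and is normalized to NO_AMP on read.
_NO_AMP_TOKENS = {"NO_AMP", "UNDETERMINED"}


def _parse_ct_token(token: str, where: str) -> float:
    token = token.strip()
    if token.upper() in _NO_AMP_TOKENS:
        return float("nan")
    try:
        return float(token)
    except ValueError:
        raise ValidationError(f"unparseable Ct {token!r} at {where}") from None


def read_ct_table(path: str | Path) -> CtTable:
    """Read a long-format Ct CSV (columns sample_id, gene, ct).

    Control wells are flagged by the reserved sample ids ``POS_CTRL`` and
    ``NEG_CTRL``; the positive control supplies the ΔΔCt calibrator and must
    have a finite Ct for every assayed gene.
    """
    df = pd.read_csv(path, dtype=str)
    req = {"sample_id", "gene", "ct"}
    if not req <= set(df.columns):
        raise ValidationError(f"Ct table missing columns: {sorted(req - set(df.columns))}")
    df["ct"] = [
        _parse_ct_token(tok, f"row {i + 2} of {path}")
        for i, tok in enumerate(df["ct"].astype(str))
    ]
    is_pos = df["sample_id"] == POSITIVE_CONTROL_ID
    is_neg = df["sample_id"] == NEGATIVE_CONTROL_ID
    calibrator = {g: float(c) for g, c in zip(df.loc[is_pos, "gene"], df.loc[is_pos, "ct"])}
    negative = {
        g: (NO_AMP if np.isnan(c) else float(c))
        for g, c in zip(df.loc[is_neg, "gene"], df.loc[is_neg, "ct"])
    }
    body = df[~(is_pos | is_neg)].reset_index(drop=True)
    return CtTable(measurements=body, calibrator=calibrator, negative_control=negative)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    rows = table.measurements.copy()
    rows["ct"] = [("NO_AMP" if np.isnan(c) else format(c, "g")) for c in rows["ct"]]
    extra = [
        {"sample_id": POSITIVE_CONTROL_ID, "gene": g, "ct": format(c, "g")}
        for g, c in sorted(table.calibrator.items())
    ] + [
        {"sample_id": NEGATIVE_CONTROL_ID, "gene": g,
         "ct": "NO_AMP" if is_no_amp(c) else format(float(c), "g")}  # type: ignore[arg-type]
        for g, c in sorted(table.negative_control.items())
    ]
    out = pd.concat([rows, pd.DataFrame(extra)], ignore_index=True)
    out.to_csv(path, index=False)
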