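"""Cohort containers, TSV readers/writers, and RT-qPCR Ct normalization.

The substrate of every downstream statistic is a miRNA-by-sample matrix of
log2 relative expression, derived from raw quantification-cycle (Ct) values
by normalizing each sample against the median Ct of its synthetic spike-in
controls.  Lower Ct means higher abundance, so expression is defined as
``spike_median(sample) - ct(mirna, sample)``: a per-sample additive
technical shift (pipetting, RT efficiency) cancels exactly, and one log2
unit equals one PCR cycle, i.e. a two-fold abundance difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CT_MIN",
    "CT_MAX",
    "UNKNOWN",
    "HISTOLOGY_LEVELS",
    "MOLECULAR_LEVELS",
    "CTNNB1_LEVELS",
    "GRADE_LEVELS",
    "ANNOTATION_COLUMNS",
    "FormatError",
    "ValidationError",
    "ContrastError",
    "RawCtMatrix",
    "MirnaExpressionMatrix",
    "GroupContrast",
    "read_ct_matrix",
    "write_ct_matrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotations",
    "write_annotations",
    "validate_annotations",
    "annotation_levels",
    "normalize_ct",
    "make_contrast",
]

CT_MIN = 0.0
CT_MAX = 45.0
UNKNOWN = "unknown"

HISTOLOGY_LEVELS = ("endometrioid", "serous", "clear_cell", "dedifferentiated")
MOLECULAR_LEVELS = ("MMRd", "POLE", "p53wt", "p53abn")
CTNNB1_LEVELS = ("mutated", "wildtype")
GRADE_LEVELS = ("G1", "G2", "G3")

ANNOTATION_COLUMNS = ("sample_id", "histology", "grade", "molecular", "ctnnb1")

#: levels a one-vs-rest contrast may target, per annotation variable
CONTRAST_VARIABLES = {
    "histology": HISTOLOGY_LEVELS,
    "molecular": MOLECULAR_LEVELS,
    "ctnnb1": CTNNB1_LEVELS,
}


class FormatError(ValueError):
    """Malformed input file (duplicate ids, non-numeric cells, bad header)."""


class ValidationError(ValueError):
    """Structurally parseable input violating a domain invariant."""


class ContrastError(ValueError):
    """A one-vs-rest contrast that cannot support a two-sample test."""


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class RawCtMatrix:
    """Raw Ct values for miRNA assays and spike-in controls across samples.

    Missing Ct (no amplification within the run) is stored as NaN.  Values
    must lie in [0, 45] cycles, the physical range of a qPCR run.
    """

    assay_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    ct: np.ndarray
    spike_in_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay_ids", tuple(self.assay_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(
            self, "ct", np.asarray(self.ct, dtype=float).reshape(len(self.assay_ids), -1)
        )
        object.__setattr__(self, "spike_in_ids", frozenset(self.spike_in_ids))
        _check_unique(list(self.assay_ids), "assay id")
        _check_unique(list(self.sample_ids), "sample id")
        if self.ct.shape != (len(self.assay_ids), len(self.sample_ids)):
            raise ValidationError(
                f"ct matrix shape {self.ct.shape} does not match "
                f"{len(self.assay_ids)} assays x {len(self.sample_ids)} samples"
            )
        unknown_spikes = self.spike_in_ids - set(self.assay_ids)
        if unknown_spikes:
            raise ValidationError(f"spike-in ids not among assays: {sorted(unknown_spikes)}")
        bad = np.argwhere(~np.isnan(self.ct) & ((self.ct < CT_MIN) | (self.ct > CT_MAX)))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"Ct value {self.ct[i, j]:g} outside [{CT_MIN:g}, {CT_MAX:g}] at "
                f"assay {self.assay_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def mirna_ids(self) -> tuple[str, ...]:
        return tuple(a for a in self.assay_ids if a not in self.spike_in_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ct, index=list(self.assay_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class MirnaExpressionMatrix:
    """Log2 relative expression, miRNAs x samples; finite everywhere."""

    mirna_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    expr: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mirna_ids", tuple(self.mirna_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(
            self,
            "expr",
            np.asarray(self.expr, dtype=float).reshape(len(self.mirna_ids), -1),
        )
        _check_unique(list(self.mirna_ids), "miRNA id")
        _check_unique(list(self.sample_ids), "sample id")
        if self.expr.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression shape {self.expr.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.expr)):
            i, j = np.argwhere(~np.isfinite(self.expr))[0]
            raise ValidationError(
                f"non-finite expression at miRNA {self.mirna_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    def row(self, mirna_id: str) -> np.ndarray:
        try:
            i = self.mirna_ids.index(mirna_id)
        except ValueError:
            raise KeyError(f"miRNA {mirna_id!r} not in matrix") from None
        return self.expr[i]

    def sample_index(self, sample_ids) -> np.ndarray:
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expr, index=list(self.mirna_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class GroupContrast:
    """One-vs-rest contrast: a target group against all other labelled samples."""

    name: str
    positive_ids: tuple[str, ...]
    negative_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive_ids", tuple(self.positive_ids))
        object.__setattr__(self, "negative_ids", tuple(self.negative_ids))
        overlap = set(self.positive_ids) & set(self.negative_ids)
        if overlap:
            raise ContrastError(f"samples in both groups of {self.name!r}: {sorted(overlap)}")
        if not self.positive_ids or not self.negative_ids:
            raise ContrastError(f"contrast {self.name!r} has an empty group")

    @property
    def n_positive(self) -> int:
        return len(self.positive_ids)

    @property
    def n_negative(self) -> int:
        return len(self.negative_ids)

    def indices(self, expr: MirnaExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of (positives, negatives) within ``expr``."""
        return expr.sample_index(self.positive_ids), expr.sample_index(self.negative_ids)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_assay_tsv(path: str | Path, value_name: str) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expected an assay_id column plus >=1 sample column")
    _check_unique(header[1:], "sample id in header")  # pandas would mangle duplicates
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = header
    ids = df.iloc[:, 0].tolist()
    _check_unique(ids, "assay id")
    values = np.full((len(ids), len(header) - 1), np.nan)
    for j, col in enumerate(header[1:]):
        raw = df[col].str.strip()
        missing = ((raw == "") | (raw.str.upper() == "NA")).to_numpy()
        cells = raw.to_numpy()
        try:
            # numpy's parser is correctly rounded, so writes round-trip exactly
            values[~missing, j] = cells[~missing].astype(np.float64)
        except ValueError:
            for i in np.flatnonzero(~missing):
                try:
                    float(cells[i])
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric {value_name} {cells[i]!r} at assay "
                        f"{ids[i]!r}, sample {col!r}"
                    ) from None
    out = pd.DataFrame(values, index=ids, columns=header[1:])
    out.index.name = header[0]
    return out


def read_ct_matrix(path: str | Path, spike_in_prefix: str = "SPIKE_") -> RawCtMatrix:
    """Read a Ct TSV (rows = assays, columns = samples; missing = empty/NA).

    Rows whose assay id starts with ``spike_in_prefix`` are flagged as
    synthetic spike-in controls.
    """
    df = _read_assay_tsv(path, "Ct")
    spikes = frozenset(a for a in df.index if a.startswith(spike_in_prefix))
    return RawCtMatrix(tuple(df.index), tuple(df.columns), df.to_numpy(), spikes)


def write_ct_matrix(raw: RawCtMatrix, path: str | Path) -> None:
    df = raw.to_frame()
    df.index.name = "assay_id"
    # 17 significant digits round-trip IEEE doubles bit-exactly
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_expression_matrix(path: str | Path) -> MirnaExpressionMatrix:
    df = _read_assay_tsv(path, "expression")
    if df.isna().to_numpy().any():
        raise ValidationError(f"{path}: expression matrix contains missing values")
    return MirnaExpressionMatrix(tuple(df.index), tuple(df.columns), df.to_numpy())


def write_expression_matrix(expr: MirnaExpressionMatrix, path: str | Path) -> None:
    df = expr.to_frame()
    df.index.name = "assay_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a sample annotation table.

    Required columns: sample_id, histology, grade, molecular, ctnnb1.
    Grade applies to endometrioid tumors only; molecular subtype and CTNNB1
    status may be ``unknown`` (not every sample was subtyped or sequenced).
    """
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    ann = ann.loc[:, list(ANNOTATION_COLUMNS)].astype(str).copy()
    ann["grade"] = ann["grade"].replace({"": UNKNOWN, "nan": UNKNOWN, "NA": UNKNOWN})
    _check_unique(ann["sample_id"].tolist(), "sample id")
    for col, levels in (
        ("histology", HISTOLOGY_LEVELS),
        ("molecular", MOLECULAR_LEVELS + (UNKNOWN,)),
        ("ctnnb1", CTNNB1_LEVELS + (UNKNOWN,)),
        ("grade", GRADE_LEVELS + (UNKNOWN,)),
    ):
        bad = ~ann[col].isin(levels)
        if bad.any():
            val = ann.loc[bad, col].iloc[0]
            raise ValidationError(f"invalid {col} value {val!r}")
    graded_nonendo = (ann["grade"] != UNKNOWN) & (ann["histology"] != "endometrioid")
    if graded_nonendo.any():
        sid = ann.loc[graded_nonendo, "sample_id"].iloc[0]
        raise ValidationError(f"grade given for non-endometrioid sample {sid!r}")
    return ann.reset_index(drop=True)


def read_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return validate_annotations(ann)


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    validate_annotations(ann).to_csv(path, sep="\t", index=False)


def annotation_levels(variable: str) -> tuple[str, ...]:
    """Known levels of a contrastable annotation variable."""
    try:
        return CONTRAST_VARIABLES[variable]
    except KeyError:
        raise ValueError(
            f"unknown variable {variable!r}; expected one of {sorted(CONTRAST_VARIABLES)}"
        ) from None


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_ct(
    raw: RawCtMatrix,
    detection_limit: float = 38.0,
    max_missing_frac: float = 0.2,
) -> MirnaExpressionMatrix:
    """Convert raw Ct to spike-in-normalized log2 relative expression.

    Per sample the technical factor is the median Ct of the spike-in
    controls; ``expression = spike_median - ct``.  A Ct at or above
    ``detection_limit`` (or missing) counts as undetected.  miRNAs
    undetected in more than ``max_missing_frac`` of samples are dropped;
    remaining undetected entries are imputed at that miRNA's minimum
    observed expression minus one cycle (a conservative floor just below
    the weakest detection).
    """
    if not raw.spike_in_ids:
        raise ValidationError("no spike-in assays present; cannot normalize")
    spike_rows = [i for i, a in enumerate(raw.assay_ids) if a in raw.spike_in_ids]
    mirna_rows = [i for i, a in enumerate(raw.assay_ids) if a not in raw.spike_in_ids]
    spike_ct = raw.ct[spike_rows]
    n_usable = np.sum(~np.isnan(spike_ct), axis=0)
    if np.any(n_usable == 0):
        j = int(np.flatnonzero(n_usable == 0)[0])
        raise ValidationError(f"sample {raw.sample_ids[j]!r} has no usable spike-in Ct")
    with np.errstate(invalid="ignore"):
        spike_median = np.nanmedian(spike_ct, axis=0)

    ct = raw.ct[mirna_rows]
    undetected = np.isnan(ct) | (ct >= detection_limit)
    expr = spike_median[None, :] - ct

    keep = undetected.mean(axis=1) <= max_missing_frac
    # a fully undetected miRNA has no observed value to impute from
    keep &= ~undetected.all(axis=1)
    expr, undetected = expr[keep], undetected[keep]
    mirna_ids = tuple(raw.assay_ids[mirna_rows[i]] for i in np.flatnonzero(keep))

    masked = np.where(undetected, np.nan, expr)
    floor = np.nanmin(masked, axis=1) - 1.0
    expr = np.where(undetected, floor[:, None], expr)
    return MirnaExpressionMatrix(mirna_ids, raw.sample_ids, expr)


def make_contrast(
    ann: pd.DataFrame,
    variable: str,
    level: str,
    samples: list[str] | None = None,
) -> GroupContrast:
    """Build the one-vs-rest contrast for ``level`` of ``variable``.

    Samples whose value of ``variable`` is unknown are excluded from both
    sides rather than pooled into the control group.
    """
    levels = annotation_levels(variable)
    if level not in levels:
        raise ValueError(f"{level!r} is not a level of {variable!r}; expected one of {levels}")
    ann = validate_annotations(ann)
    if samples is not None:
        ann = ann[ann["sample_id"].isin(set(samples))]
    known = ann[ann[variable] != UNKNOWN]
    pos = known.loc[known[variable] == level, "sample_id"].tolist()
    neg = known.loc[known[variable] != level, "sample_id"].tolist()
    if len(pos) < 2 or len(neg) < 2:
        raise ContrastError(
            f"contrast {variable}={level} needs >=2 samples per side "
            f"(got {len(pos)} vs {len(neg)})"
        )
    return GroupContrast(f"{variable}={level}", tuple(pos), tuple(neg))
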