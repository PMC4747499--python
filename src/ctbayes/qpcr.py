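"""Ct-matrix data model, I/O, detection filtering and comparative-Ct quantification.

Ct values live on a log2-like cycle scale: lower Ct means more template.
Undetected wells (reported by the instrument as a sentinel token, typically
``"Undetermined"``) are represented internally as ``NaN`` and are treated as
missing throughout — never imputed with a ceiling cycle.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, InputError

logger = logging.getLogger(__name__)

#: Default token used by TaqMan-style exports for wells below the limit of detection.
UNDETECTED = "Undetermined"

ROLES = ("target", "housekeeping", "reference-candidate")
AGE_GROUPS = ("child", "adult")
STATUSES = ("CD", "control")
CATEGORIES = ("CD-locus", "Th17", "both", "none")

SAMPLE_COLUMNS = ("sample_id", "age_years", "age_group", "status")
ASSAY_COLUMNS = ("assay_id", "gene", "role", "category")


@dataclass(frozen=True)
class CtMatrix:
    """Samples x assays matrix of threshold cycles with undetected wells as NaN.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with assay ids as columns. Cells are
        positive floats (cycles) or NaN for undetected wells.
    """

    values: pd.DataFrame

    def __post_init__(self):
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate assay ids: {dups}")
        vals = self.values.to_numpy(dtype=float, copy=False)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise FormatError("Ct values must be strictly positive")
        object.__setattr__(self, "values", self.values.astype(float))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected wells."""
        return self.values.notna()

    def detection_counts(self) -> pd.Series:
        """Number of samples in which each assay was detected."""
        return self.values.notna().sum(axis=0)

    def __eq__(self, other) -> bool:  # value semantics, NaN-aware
        if not isinstance(other, CtMatrix):
            return NotImplemented
        a, b = self.values, other.values
        if not (a.index.equals(b.index) and a.columns.equals(b.columns)):
            return False
        return bool(((a == b) | (a.isna() & b.isna())).all().all())


def read_ct_table(path, sentinel: str = UNDETECTED) -> CtMatrix:
    """Read a wide Ct CSV (first column = sample id, header = assay ids).

    Cells equal to *sentinel* are parsed as undetected. Raises
    :class:`FormatError` on duplicate ids or cells that are neither numeric
    nor the sentinel (the error names the offending row and column).
    """
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    assay_ids = header[1:]
    seen = [a for a in assay_ids if assay_ids.count(a) > 1]
    if seen:
        raise FormatError(f"duplicate assay column(s) in {path}: {sorted(set(seen))}")

    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    raw.columns = assay_ids  # undo any pandas dedup mangling (none by now)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample row(s) in {path}: {dups}")

    parsed = raw.mask(raw.eq(sentinel) | raw.eq(""))
    coerced = parsed.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & parsed.notna()
    if bad.any().any():
        row, col = next(
            (r, c) for r in bad.index for c in bad.columns if bad.at[r, c]
        )
        raise FormatError(
            f"cell at sample {row!r}, assay {col!r} is neither numeric nor "
            f"{sentinel!r}: {raw.at[row, col]!r}"
        )
    # astype(float) is correctly rounded; pandas' fast to_numeric parser is not
    numeric = parsed.astype(float)
    numeric.index.name = "sample_id"
    return CtMatrix(numeric)


def write_ct_table(ct: CtMatrix, path, sentinel: str = UNDETECTED) -> None:
    """Write a CtMatrix back to wide CSV, rendering NaN as the sentinel."""
    out = ct.values.copy()
    out.index.name = "sample_id"
    # %.17g round-trips doubles exactly; pandas' default 16 digits does not
    out.to_csv(path, na_rep=sentinel, float_format="%.17g")


def read_sample_table(path) -> pd.DataFrame:
    """Read and validate the sample sheet (sample_id, age_years, age_group, status)."""
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet {path} missing column(s): {missing}")
    df = df.set_index("sample_id")
    return validate_sample_table(df)


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    if samples.index.duplicated().any():
        raise FormatError("duplicate sample ids in sample table")
    if samples[["age_group", "status"]].isna().any().any():
        raise FormatError("age_group and status must be non-missing")
    bad_group = set(samples["age_group"]) - set(AGE_GROUPS)
    if bad_group:
        raise FormatError(f"unknown age_group value(s): {sorted(bad_group)}")
    bad_status = set(samples["status"]) - set(STATUSES)
    if bad_status:
        raise FormatError(f"unknown status value(s): {sorted(bad_status)}")
    if (samples["age_years"] <= 0).any():
        raise FormatError("age_years must be positive")
    return samples


def read_assay_table(path) -> pd.DataFrame:
    """Read and validate the assay sheet (assay_id, gene, role, category)."""
    df = pd.read_csv(path)
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"assay sheet {path} missing column(s): {missing}")
    df = df.set_index("assay_id")
    return validate_assay_table(df)


def validate_assay_table(assays: pd.DataFrame) -> pd.DataFrame:
    if assays.index.duplicated().any():
        raise FormatError("duplicate assay ids in assay table")
    bad_role = set(assays["role"]) - set(ROLES)
    if bad_role:
        raise FormatError(f"unknown role value(s): {sorted(bad_role)}")
    return assays


@dataclass(frozen=True)
class DetectionPartition:
    """Disjoint split of target/reference-candidate assays by detection status."""

    all_undetected: tuple[str, ...]
    majority_undetected: tuple[str, ...]
    analyzable: tuple[str, ...]

    def __post_init__(self):
        sets = (
            set(self.all_undetected),
            set(self.majority_undetected),
            set(self.analyzable),
        )
        total = sum(len(s) for s in sets)
        if len(set.union(*sets)) != total:
            raise ValueError("partition lists must be disjoint")


def partition_by_detection(
    ct: CtMatrix,
    assays: pd.DataFrame,
    majority_fraction: float = 0.5,
) -> DetectionPartition:
    """Split non-housekeeping assays by how often they were detected.

    An assay detected in zero samples goes to ``all_undetected``; one detected
    in fewer than ``majority_fraction`` of all samples (strict) goes to
    ``majority_undetected``; the rest are ``analyzable``. Housekeeping assays
    are not partitioned.
    """
    if ct.n_samples == 0 or ct.n_assays == 0:
        raise InputError("empty Ct matrix")
    if not (0 < majority_fraction <= 1):
        raise InputError(f"majority_fraction must be in (0, 1], got {majority_fraction}")

    eligible = [
        a
        for a in ct.assay_ids
        if a in assays.index and assays.at[a, "role"] in ("target", "reference-candidate")
    ]
    counts = ct.detection_counts()
    n = ct.n_samples
    all_un, majority, analyzable = [], [], []
    for a in eligible:
        k = int(counts[a])
        if k == 0:
            all_un.append(a)
        elif k < majority_fraction * n:
            majority.append(a)
        else:
            analyzable.append(a)
    return DetectionPartition(tuple(all_un), tuple(majority), tuple(analyzable))


def delta_ct(
    ct: CtMatrix,
    reference_assays: Sequence[str],
    targets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Normalize target Ct against the arithmetic mean of the reference assays.

    Returns a samples x targets DataFrame of dCt values
    (``Ct_target - mean(Ct_reference)``), missing wherever the target or any
    reference assay is undetected in that sample. Lower dCt means higher
    relative expression.
    """
    if not reference_assays:
        raise ConfigurationError("reference assay list must be non-empty")
    absent = [r for r in reference_assays if r not in ct.values.columns]
    if absent:
        raise ConfigurationError(f"reference assay(s) absent from Ct matrix: {absent}")
    if targets is None:
        targets = [a for a in ct.assay_ids if a not in set(reference_assays)]
    ref = ct.values[list(reference_assays)]
    ref_mean = ref.mean(axis=1)
    ref_mean[ref.isna().any(axis=1)] = np.nan  # any undetected reference voids the sample
    expr = ct.values[list(targets)].sub(ref_mean, axis=0)
    return expr


def relative_expression(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    calibrator: Mapping[str, str] | None = None,
    match_age_group: bool = True,
) -> pd.DataFrame:
    """Comparative-Ct fold changes, ``2**-ddCt``, against a calibrator group.

    By default the calibrator is the control group matched on ``age_group``:
    each sample's ddCt subtracts the mean dCt of controls in its own age
    stratum. Pass an explicit ``calibrator`` selector (e.g.
    ``{"status": "control"}``) to use one global calibrator; set
    ``match_age_group=False`` to disable stratum matching for explicit
    selectors too.

    Genes whose calibrator group has no detected value get NaN (flagged, not
    dropped) and a warning is logged.
    """
    if calibrator is None:
        calibrator = {"status": "control"}
    mask = pd.Series(True, index=samples.index)
    for col, val in calibrator.items():
        mask &= samples[col] == val

    ddct = pd.DataFrame(index=expr.index, columns=expr.columns, dtype=float)
    if match_age_group:
        strata = samples.loc[expr.index, "age_group"]
        for stratum in strata.unique():
            in_stratum = strata == stratum
            calib = mask & (samples["age_group"] == stratum)
            calib_ids = samples.index[calib].intersection(expr.index)
            means = expr.loc[calib_ids].mean(axis=0)
            ddct.loc[in_stratum.index[in_stratum]] = (
                expr.loc[in_stratum.index[in_stratum]] - means
            )
            empty = means.index[means.isna()]
            if len(empty):
                logger.warning(
                    "calibrator group empty for %d gene(s) in stratum %s: %s",
                    len(empty), stratum, list(empty[:5]),
                )
    else:
        calib_ids = samples.index[mask].intersection(expr.index)
        means = expr.loc[calib_ids].mean(axis=0)
        ddct = expr - means
        empty = means.index[means.isna()]
        if len(empty):
            logger.warning("calibrator group empty for %d gene(s)", len(empty))
    return np.power(2.0, -ddct)
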