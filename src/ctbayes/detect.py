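"""Inference on detection frequencies and the age-correlation screen.

Genes discarded from the expression analysis because they were rarely
detected can still carry signal in *whether* they were detected: a 2x2 table
of detected/undetected wells by case status is tested with Fisher's exact
test, one-sided in the direction of greater detection in cases by default
(the printed study values reconcile with the one-sided tail; see tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .qpcr import CtMatrix


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 detection counts: rows (CD, control), columns (detected, undetected)."""

    cd_detected: int
    cd_undetected: int
    ctrl_detected: int
    ctrl_undetected: int

    def __post_init__(self):
        if min(self.cd_detected, self.cd_undetected,
               self.ctrl_detected, self.ctrl_undetected) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [
                [self.cd_detected, self.cd_undetected],
                [self.ctrl_detected, self.ctrl_undetected],
            ]
        )

    @property
    def n_cd(self) -> int:
        return self.cd_detected + self.cd_undetected

    @property
    def n_ctrl(self) -> int:
        return self.ctrl_detected + self.ctrl_undetected


def detection_counts(
    ct: CtMatrix,
    samples: pd.DataFrame,
    assay: str,
    stratum: str | None = None,
) -> ContingencyTable:
    """Count detected/undetected wells for one assay by CD/control status.

    ``stratum`` restricts to one ``age_group`` ("child"/"adult"); ``None``
    uses all samples.
    """
    if assay not in ct.values.columns:
        raise InputError(f"assay {assay!r} absent from Ct matrix")
    meta = samples.loc[ct.sample_ids]
    keep = pd.Series(True, index=meta.index)
    if stratum is not None:
        keep &= meta["age_group"] == stratum
    cd = keep & (meta["status"] == "CD")
    ctrl = keep & (meta["status"] == "control")
    if cd.sum() == 0 or ctrl.sum() == 0:
        raise InputError(
            f"stratum {stratum!r} needs >= 1 CD and >= 1 control sample"
        )
    det = ct.values[assay].notna()
    return ContingencyTable(
        cd_detected=int((det & cd).sum()),
        cd_undetected=int((~det & cd).sum()),
        ctrl_detected=int((det & ctrl).sum()),
        ctrl_undetected=int((~det & ctrl).sum()),
    )


def fisher_one_sided(table: ContingencyTable | np.ndarray) -> float:
    """One-sided Fisher exact p-value for greater detection in the CD row.

    Exact hypergeometric tail probability of tables at least as extreme as
    observed in the direction of more detected CD wells, at fixed margins.
    Full precision is returned; display rounds to 2 decimals.
    """
    arr = table.table if isinstance(table, ContingencyTable) else np.asarray(table)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    return float(stats.fisher_exact(arr, alternative="greater").pvalue)


def fisher_two_sided(table: ContingencyTable | np.ndarray) -> float:
    arr = table.table if isinstance(table, ContingencyTable) else np.asarray(table)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


def detection_tests(
    ct: CtMatrix,
    samples: pd.DataFrame,
    assays: list[str],
    strata: tuple[str, ...] = ("child", "adult"),
    two_sided: bool = False,
) -> pd.DataFrame:
    """Fisher detection tests for several assays across age strata."""
    test = fisher_two_sided if two_sided else fisher_one_sided
    rows = []
    for assay in assays:
        for stratum in strata:
            tab = detection_counts(ct, samples, assay, stratum)
            rows.append(
                {
                    "assay_id": assay,
                    "stratum": stratum,
                    "cd_detected": tab.cd_detected,
                    "cd_undetected": tab.cd_undetected,
                    "ctrl_detected": tab.ctrl_detected,
                    "ctrl_undetected": tab.ctrl_undetected,
                    "p_value": test(tab),
                }
            )
    return pd.DataFrame(rows)


def age_correlation(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    min_n: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of each gene's dCt with age in years.

    Genes with fewer than ``min_n`` detected samples or constant dCt are
    flagged (``undefined``) with NaN statistics instead of being dropped.
    """
    ages = samples.loc[expr.index, "age_years"]
    rows = []
    for gene in expr.columns:
        vals = expr[gene].dropna()
        n = len(vals)
        if n < min_n or vals.nunique() <= 1:
            rows.append({"gene": gene, "n": n, "rho": np.nan,
                         "p_value": np.nan, "undefined": True})
            continue
        rho, p = stats.spearmanr(vals, ages.loc[vals.index])
        rows.append({"gene": gene, "n": n, "rho": float(rho),
                     "p_value": float(p), "undefined": False})
    return pd.DataFrame(rows).set_index("gene")
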