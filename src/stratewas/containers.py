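"""In-memory containers shared across the pipeline.

A :class:`BetaMatrix` couples a probes x samples matrix of methylation beta
values (fractions in [0, 1]) with per-probe genomic annotation (chromosome,
1-based position, nearest gene).  Sample metadata travels separately as a
plain :class:`pandas.DataFrame` sample sheet with the columns listed in
:data:`SAMPLE_SHEET_COLUMNS`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError

#: Cell types whose estimated proportions appear in a sample sheet.
CELL_TYPES = ["Mono", "Gran", "NK", "CD4T", "CD8T", "B"]

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "cohort",
    "status",
    "sex",
    "age",
    "smoking_score",
    *CELL_TYPES,
    "batch",
]

SEX_CHROMS = {"X", "Y", "chrX", "chrY"}


@dataclass
class BetaMatrix:
    """Methylation beta values with probe annotation.

    Parameters
    ----------
    values
        probes x samples DataFrame; index = probe ids, columns = sample ids,
        entries in [0, 1].
    annot
        DataFrame indexed by probe id with columns ``chrom`` (label),
        ``pos`` (1-based bp) and ``gene``.
    """

    values: pd.DataFrame
    annot: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate probe ids: {list(dups[:5])}")
        missing = self.values.index.difference(self.annot.index)
        if len(missing):
            raise InputError(
                "probes missing from annotation: " + ", ".join(map(str, missing[:5]))
            )
        vals = self.values.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise InputError("beta values must lie in [0, 1]")
        # keep annotation aligned and ordered with the value matrix
        self.annot = self.annot.loc[self.values.index]

    # -- convenience accessors -------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def autosomal(self) -> "BetaMatrix":
        """Return a view restricted to non-sex-chromosome probes."""
        keep = ~self.annot["chrom"].astype(str).isin(SEX_CHROMS)
        return BetaMatrix(self.values.loc[keep.to_numpy()], self.annot.loc[keep.to_numpy()])

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.values[list(sample_ids)], self.annot)

    def sorted_by_position(self) -> "BetaMatrix":
        order = self.annot.sort_values(["chrom", "pos"], kind="mergesort").index
        return BetaMatrix(self.values.loc[order], self.annot.loc[order])


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check mandatory sample-sheet columns and invariants; return the sheet."""
    missing = [c for c in ("sample_id", "status", "sex") if c not in sheet.columns]
    if missing:
        raise InputError(f"sample sheet missing columns: {missing}")
    if sheet["status"].isna().any() or sheet["sex"].isna().any():
        raise InputError("status/sex must be non-missing for every sample")
    bad_status = set(sheet["status"].unique()) - {"case", "control"}
    if bad_status:
        raise InputError(f"unknown status labels: {sorted(bad_status)}")
    bad_sex = set(sheet["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise InputError(f"unknown sex labels: {sorted(bad_sex)}")
    if all(ct in sheet.columns for ct in CELL_TYPES):
        props = sheet[CELL_TYPES].to_numpy(float)
        if (props < -1e-9).any() or np.abs(props.sum(axis=1) - 1).max() > 1e-6:
            raise InputError("cell proportions must be >= 0 and sum to 1 per sample")
    return sheet
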