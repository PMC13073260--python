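"""Feature-by-sample abundance container shared by all omics layers.

A three-group design (control / disease model / treated) is assumed
throughout: every sample carries one of those group labels, and the
matrix holds log2-scale abundances unless explicitly flagged raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUPS = ("control", "model", "treated")
LAYERS = ("transcript", "protein", "metabolite")


@dataclass
class OmicsMatrix:
    """Feature x sample abundance table with group labels.

    Parameters
    ----------
    values
        DataFrame, rows are features, columns are samples. Log2 scale
        unless ``log2_scale`` is False (raw counts/intensities).
    groups
        Series mapping each sample id to one of ``GROUPS``.
    layer
        One of ``LAYERS``.
    log2_scale
        Whether ``values`` is already on log2 scale.
    """

    values: pd.DataFrame
    groups: pd.Series
    layer: str
    log2_scale: bool = True

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifiers: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = sorted(set(self.groups.loc[list(self.values.columns)]) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown group labels {bad}; expected subset of {GROUPS}")
        if self.values.isna().any().any():
            raise ValueError(
                "matrix contains missing values; impute or drop explicitly before use"
            )
        self.groups = self.groups.loc[list(self.values.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def restrict_groups(self, keep: tuple[str, ...]) -> "OmicsMatrix":
        cols = [s for s in self.values.columns if self.groups[s] in keep]
        return replace(self, values=self.values[cols], groups=self.groups.loc[cols])

    def to_log2(self) -> "OmicsMatrix":
        """Return a log2(x + 1)-transformed copy; identity if already log2."""
        if self.log2_scale:
            return self
        if (self.values.values < 0).any():
            raise ValueError("raw matrix has negative entries; cannot log2(x+1)")
        return replace(self, values=np.log2(self.values + 1.0), log2_scale=True)

    # --- TSV round trip -------------------------------------------------
    def write_tsv(self, matrix_path, samples_path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(matrix_path, sep="\t")
        sheet = pd.DataFrame(
            {"sample_id": list(self.groups.index), "group": list(self.groups.values)}
        )
        sheet.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, matrix_path, samples_path, layer: str, log2_scale: bool = True
    ) -> "OmicsMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
        if not {"sample_id", "group"} <= set(sheet.columns):
            raise ValueError("sample sheet must have columns sample_id, group")
        groups = pd.Series(
            sheet["group"].values, index=sheet["sample_id"].values, name="group"
        )
        return cls(values=values, groups=groups, layer=layer, log2_scale=log2_scale)
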