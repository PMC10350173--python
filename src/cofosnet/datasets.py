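"""Region x subject c-Fos count tables and their delimited-text formats.

The pipeline's root input is a table of c-Fos-positive cell counts per
brain region (rows, Allen-atlas-style acronyms) and per subject (columns),
paired with a subject metadata table carrying the behavioural phenotype
(AGG = attacks the intruder, NON = does not), sex, and virus group
(e.g. mCherry / hM4Di for chemogenetic cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SUBJECT_COLUMNS = ("subject_id", "phenotype", "sex", "virus_group")


@dataclass
class CountMatrix:
    """c-Fos counts (regions x subjects) plus subject metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by region acronym with one column per subject id;
        entries are non-negative integers (cell counts).
    subjects
        DataFrame with columns ``subject_id, phenotype, sex, virus_group``,
        one row per subject, in the same order as the count columns.
    """

    counts: pd.DataFrame
    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate region acronyms in count matrix")
        missing = [c for c in SUBJECT_COLUMNS if c not in self.subjects.columns]
        if missing:
            raise ValueError(f"subject table missing columns: {missing}")
        if self.subjects["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids")
        if list(self.counts.columns) != list(self.subjects["subject_id"]):
            raise ValueError("count columns and subject table disagree")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integer-valued")
        self.counts = self.counts.astype(np.int64)
        self.subjects = self.subjects.reset_index(drop=True)

    @property
    def region_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[1]

    def subject_ids_where(self, field: str, level: str) -> list[str]:
        """Subject ids whose metadata ``field`` equals ``level``."""
        if field not in self.subjects.columns:
            raise KeyError(f"unknown subject field {field!r}")
        mask = self.subjects[field].astype(str) == str(level)
        return list(self.subjects.loc[mask, "subject_id"])

    def subset_subjects(self, subject_ids: list[str]) -> "CountMatrix":
        """Restrict to the given subjects, preserving their order."""
        unknown = [s for s in subject_ids if s not in self.counts.columns]
        if unknown:
            raise KeyError(f"unknown subjects: {unknown}")
        sub = self.subjects.set_index("subject_id").loc[subject_ids].reset_index()
        return CountMatrix(self.counts[subject_ids].copy(), sub)

    def to_files(self, counts_path, subjects_path) -> None:
        """Write the tab-delimited count and metadata tables."""
        out = self.counts.copy()
        out.index.name = "region"
        out.to_csv(counts_path, sep="\t")
        self.subjects.to_csv(subjects_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, counts_path, subjects_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        subjects = pd.read_csv(subjects_path, sep="\t", dtype=str)
        return cls(counts, subjects)


def concat_subjects(*matrices: CountMatrix) -> CountMatrix:
    """Column-concatenate cohorts measured over the same regions.

    Lets a study combine groups simulated (or measured) under different
    conditions — e.g. a module whose co-activation exists in one phenotype
    but not the other — into a single analysis matrix.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two cohorts")
    first = matrices[0]
    for m in matrices[1:]:
        if m.region_ids != first.region_ids:
            raise ValueError("cohorts must share the same regions in order")
    counts = pd.concat([m.counts for m in matrices], axis=1)
    subjects = pd.concat([m.subjects for m in matrices], ignore_index=True)
    return CountMatrix(counts, subjects)
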