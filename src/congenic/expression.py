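"""Expression-matrix container: log2 values, detection calls, sample metadata.

The container is the contract between upstream normalization (out of scope;
values arrive RMA-normalized and log2-transformed) and the differential
analysis.  It couples three aligned tables:

* ``values`` — probe sets x samples, finite log2 expression;
* ``detection`` — optional boolean present/absent calls, same shape;
* ``samples`` — one row per sample with ``animal_id``, ``group``, ``region``.

Groups name the allele carried in the introgressed interval rather than the
strain, because the same analysis is run on both reciprocal experiments: in
the iP-vs-P.NP experiment the background strain carries the iP allele, while
in the NP.P-vs-iNP experiment the congenic strain does.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "REGIONS",
    "GROUP_IP",
    "GROUP_INP",
    "GROUPS",
    "COMBINED",
    "SampleMeta",
    "ExpressionMatrix",
]

#: The five dissected brain regions of the mesolimbic/mesocortical system.
REGIONS = (
    "nucleus_accumbens",
    "amygdala",
    "frontal_cortex",
    "hippocampus",
    "caudate_putamen",
)

GROUP_IP = "iP-allele-carrier"
GROUP_INP = "iNP-allele-carrier"
GROUPS = (GROUP_IP, GROUP_INP)

#: Pseudo-region label for the per-animal cross-region average.
COMBINED = "combined"

_SAMPLE_COLUMNS = ["sample_id", "animal_id", "group", "region"]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    animal_id: str
    group: str
    region: str


class ExpressionMatrix:
    """Log2 expression over samples, with optional detection calls.

    Parameters
    ----------
    values
        DataFrame, probe sets (index) x samples (columns), finite log2 values.
    samples
        Sample sheet with columns ``sample_id``, ``animal_id``, ``group``,
        ``region`` covering exactly the columns of ``values``.
    detection
        Optional boolean DataFrame with the same index/columns as ``values``
        (True = reliably detected / "present").
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: pd.DataFrame,
        detection: Optional[pd.DataFrame] = None,
    ):
        samples = samples.copy()
        if "sample_id" in samples.columns:
            samples = samples.set_index("sample_id")
        missing = [c for c in ("animal_id", "group", "region") if c not in samples.columns]
        if missing:
            raise ValidationError(f"sample sheet missing column(s) {missing}")
        if not np.isfinite(values.to_numpy(dtype=float)).all():
            raise ValidationError("expression values must all be finite")
        if set(values.columns) != set(samples.index):
            extra = sorted(set(values.columns) - set(samples.index))
            miss = sorted(set(samples.index) - set(values.columns))
            raise ValidationError(
                f"sample sheet / matrix mismatch: matrix-only={extra}, sheet-only={miss}"
            )
        samples = samples.loc[values.columns]
        samples.index.name = "sample_id"
        bad_groups = sorted(set(samples["group"]) - set(GROUPS))
        if bad_groups:
            raise ValidationError(f"unknown group label(s) {bad_groups}; expected {GROUPS}")
        dup = samples.reset_index().duplicated(subset=["animal_id", "region"])
        if dup.any():
            pairs = samples.reset_index().loc[dup, ["animal_id", "region"]].to_records(index=False)
            raise ValidationError(f"duplicate (animal, region) pairs: {list(pairs)}")
        ngroups = samples.groupby("animal_id")["group"].nunique()
        split = ngroups[ngroups > 1].index.tolist()
        if split:
            raise ValidationError(f"animal(s) assigned to more than one group: {split}")
        if values.index.duplicated().any():
            raise ValidationError("duplicate probe_set_id in expression matrix")
        if detection is not None:
            if not (detection.shape == values.shape
                    and detection.index.equals(values.index)
                    and detection.columns.equals(values.columns)):
                detection = detection.reindex(index=values.index, columns=values.columns)
                if detection.isna().any().any():
                    raise ValidationError(
                        "detection matrix does not cover the expression matrix"
                    )
            detection = detection.astype(bool)
        self.values = values.astype(float)
        self.samples = samples
        self.detection = detection

    # ------------------------------------------------------------------
    @property
    def probe_set_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def regions(self) -> list[str]:
        return sorted(self.samples["region"].unique())

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_sizes(self) -> dict[str, int]:
        animals = self.samples.drop_duplicates("animal_id")
        return animals["group"].value_counts().to_dict()

    def subset_region(self, region: str) -> "ExpressionMatrix":
        keep = self.samples.index[self.samples["region"] == region]
        if len(keep) == 0:
            raise ValidationError(f"no samples in region {region!r}")
        det = None if self.detection is None else self.detection[keep]
        return ExpressionMatrix(self.values[keep], self.samples.loc[keep], det)

    def subset_probe_sets(self, probe_set_ids) -> "ExpressionMatrix":
        ids = list(probe_set_ids)
        det = None if self.detection is None else self.detection.loc[ids]
        return ExpressionMatrix(self.values.loc[ids], self.samples, det)

    # ------------------------------------------------------------------
    @classmethod
    def from_tsv(cls, values_path, samples_path, detection_path=None) -> "ExpressionMatrix":
        """Load from the package's tab-separated dialect.

        Expression file: first column ``probe_set_id``, remaining columns the
        sample ids.  Sample sheet: ``sample_id  animal_id  group  region``.
        Detection matrix: same layout as the expression file with ``P``
        (present) / ``A`` (absent; ``M`` marginal counts as absent).
        """
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        if values.index.name != "probe_set_id":
            raise FormatError(
                f"{values_path}: first column must be 'probe_set_id', got {values.index.name!r}"
            )
        sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
        missing = [c for c in _SAMPLE_COLUMNS if c not in sheet.columns]
        if missing:
            raise FormatError(f"{samples_path}: missing sample-sheet column(s) {missing}")
        detection = None
        if detection_path is not None:
            calls = pd.read_csv(detection_path, sep="\t", index_col=0)
            detection = calls == "P"
        return cls(values, sheet, detection)

    def to_tsv(self, values_path, samples_path, detection_path=None) -> None:
        out = self.values.copy()
        out.index.name = "probe_set_id"
        out.to_csv(values_path, sep="\t", float_format="%.6g")
        self.samples.reset_index().rename(columns={"index": "sample_id"}).to_csv(
            samples_path, sep="\t", index=False
        )
        if detection_path is not None:
            if self.detection is None:
                raise ValidationError("no detection calls to write")
            calls = self.detection.replace({True: "P", False: "A"})
            calls.index.name = "probe_set_id"
            calls.to_csv(detection_path, sep="\t")

    def __repr__(self) -> str:
        det = "with" if self.detection is not None else "without"
        return (
            f"<ExpressionMatrix {self.values.shape[0]} probe sets x "
            f"{self.values.shape[1]} samples, {det} detection calls>"
        )
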