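"""Probe-level screen for SNP-driven hybridization artifacts.

A sequence variant under a single 25-mer probe can depress hybridization in
one strain and mimic a cis expression difference for the whole probe set.
Such an artifact leaves a signature: one probe's between-group difference
deviates from the probe set's overall differential expression, which the
remaining probes share.

The screen works on animal-averaged, background-corrected log2 probe
intensities.  Per probe p: d_p = mean(iP-allele carriers) - mean(iNP-allele
carriers).  Per probe set, the overall differential expression is the median
of its probes' d_p (median centering, so the statistic being screened cannot
drag its own reference), the residual e_p = d_p - median, and the robust z
is e_p over the MAD-based scale 1.4826 * median(|e|).  A probe is flagged
iff |z| > k (default 3) AND |e_p| >= min_effect (default 0.5 log2); the
absolute floor stops trivially small deviations being flagged in probe sets
with near-zero scatter.

Probe sets with fewer than 4 probes cannot support a meaningful robust scale
and are emitted unflagged (``flagged`` left missing) with a logged warning.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .expression import COMBINED, GROUP_INP, GROUP_IP, ExpressionMatrix

__all__ = [
    "ProbeLevelMatrix",
    "average_probe_levels",
    "probe_screen",
    "probe_profile_table",
    "ProbeSNPScreen",
    "ProbeScreenResults",
]

logger = logging.getLogger(__name__)

MIN_PROBES = 4
MAD_SCALE = 1.4826  # consistency constant for normal data

SCREEN_COLUMNS = ["probe_set_id", "probe_id", "d_p", "center_D", "residual_e", "robust_z", "flagged"]


class ProbeLevelMatrix:
    """Background-corrected log2 intensities of individual probes.

    Parameters
    ----------
    values
        DataFrame, probes (index = probe_id) x samples.
    probe_sets
        Series mapping probe_id -> probe_set_id (every probe to exactly one
        probe set).
    samples
        Sample sheet as for :class:`~congenic.expression.ExpressionMatrix`.
    """

    def __init__(self, values: pd.DataFrame, probe_sets: pd.Series, samples: pd.DataFrame):
        if values.index.duplicated().any():
            raise ValidationError("duplicate probe_id in probe-level matrix")
        probe_sets = probe_sets.reindex(values.index)
        if probe_sets.isna().any():
            missing = probe_sets.index[probe_sets.isna()].tolist()[:5]
            raise ValidationError(f"probe(s) without probe_set_id, e.g. {missing}")
        # reuse the expression-matrix validation of values/sheet alignment
        self._em = ExpressionMatrix(values, samples)
        self.values = self._em.values
        self.samples = self._em.samples
        self.probe_sets = probe_sets.rename("probe_set_id")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @classmethod
    def from_tsv(cls, values_path, samples_path) -> "ProbeLevelMatrix":
        """Read the tab-separated dialect ``probe_id  probe_set_id  <samples...>``."""
        df = pd.read_csv(values_path, sep="\t")
        if list(df.columns[:2]) != ["probe_id", "probe_set_id"]:
            raise FormatError(
                f"{values_path}: first two columns must be probe_id, probe_set_id"
            )
        df = df.set_index("probe_id")
        probe_sets = df.pop("probe_set_id").astype(str)
        sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
        return cls(df, probe_sets, sheet)

    def to_tsv(self, values_path, samples_path=None) -> None:
        out = self.values.copy()
        out.insert(0, "probe_set_id", self.probe_sets)
        out.index.name = "probe_id"
        out.to_csv(values_path, sep="\t", float_format="%.6g")
        if samples_path is not None:
            self.samples.reset_index().to_csv(samples_path, sep="\t", index=False)

    def __repr__(self) -> str:
        return (
            f"<ProbeLevelMatrix {self.values.shape[0]} probes in "
            f"{self.probe_sets.nunique()} probe sets x {self.values.shape[1]} samples>"
        )


def average_probe_levels(m: ProbeLevelMatrix) -> ProbeLevelMatrix:
    """Average probe intensities within animal across regions.

    Identical to the probe-set-level region averaging: one pseudo-sample per
    animal, arithmetic mean over the configured regions on the log2 scale.
    """
    from .diffexpr import average_regions  # shared region-averaging logic

    avg = average_regions(m._em)
    return ProbeLevelMatrix(avg.values, m.probe_sets, avg.samples)


def probe_screen(
    m: ProbeLevelMatrix,
    k: float = 3.0,
    min_effect: float = 0.5,
    center: str = "median",
) -> pd.DataFrame:
    """Screen every probe for deviation from its probe set's group difference.

    Returns a DataFrame with columns ``probe_set_id, probe_id, d_p, center_D,
    residual_e, robust_z, flagged`` (``flagged`` is nullable boolean: missing
    for probes of sets too small to screen).

    ``center`` selects how the probe-set-level differential expression is
    ascertained: ``median`` (default, robust to the outlier being sought) or
    ``mean``.
    """
    if center not in ("median", "mean"):
        raise ValidationError(f"center must be 'median' or 'mean', got {center!r}")
    a_cols = m.samples.index[m.samples["group"] == GROUP_IP]
    b_cols = m.samples.index[m.samples["group"] == GROUP_INP]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValidationError(
            f"both groups need >= 2 animals; got {len(a_cols)} and {len(b_cols)}"
        )
    d_p = m.values[a_cols].mean(axis=1) - m.values[b_cols].mean(axis=1)
    frames = []
    skipped = 0
    for ps, probe_idx in d_p.groupby(m.probe_sets).groups.items():
        d = d_p.loc[probe_idx].to_numpy()
        if len(d) < MIN_PROBES:
            skipped += 1
            frames.append(pd.DataFrame({
                "probe_set_id": ps, "probe_id": list(probe_idx), "d_p": d,
                "center_D": np.nan, "residual_e": np.nan, "robust_z": np.nan,
                "flagged": pd.array([pd.NA] * len(d), dtype="boolean"),
            }))
            continue
        center_val = float(np.median(d)) if center == "median" else float(np.mean(d))
        e = d - center_val
        scale = MAD_SCALE * float(np.median(np.abs(e)))
        if scale == 0:
            z = np.zeros_like(e)
            z[e != 0] = np.sign(e[e != 0]) * np.inf
        else:
            z = e / scale
        flagged = (np.abs(z) > k) & (np.abs(e) >= min_effect)
        frames.append(pd.DataFrame({
            "probe_set_id": ps, "probe_id": list(probe_idx), "d_p": d,
            "center_D": center_val, "residual_e": e, "robust_z": z,
            "flagged": pd.array(flagged, dtype="boolean"),
        }))
    if skipped:
        logger.warning(
            "%d probe set(s) with < %d probes skipped by the screen", skipped, MIN_PROBES
        )
    if not frames:
        return pd.DataFrame(columns=SCREEN_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SCREEN_COLUMNS]


def probe_profile_table(results: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-probe residual profile for plotting or reporting.

    One row per probe: ``probe_set_id, probe_index`` (0-based within the probe
    set, input order), ``residual_e, flagged``.
    """
    if results.empty:
        return pd.DataFrame(columns=["probe_set_id", "probe_index", "residual_e", "flagged"])
    out = results.copy()
    out["probe_index"] = out.groupby("probe_set_id").cumcount()
    return out[["probe_set_id", "probe_index", "residual_e", "flagged"]].reset_index(drop=True)


class ProbeSNPScreen:
    """Model wrapper for the probe-level SNP artifact screen.

    Averages the probe-level matrix across regions (unless it already holds
    one pseudo-sample per animal) and screens every probe set.
    """

    def __init__(self, matrix: ProbeLevelMatrix, k: float = 3.0,
                 min_effect: float = 0.5, center: str = "median"):
        self.matrix = matrix
        self.k = k
        self.min_effect = min_effect
        self.center = center

    def fit(self) -> "ProbeScreenResults":
        m = self.matrix
        regions = set(m.samples["region"].unique())
        if regions != {COMBINED}:
            m = average_probe_levels(m)
        table = probe_screen(m, self.k, self.min_effect, self.center)
        return ProbeScreenResults(self, table)


class ProbeScreenResults:
    """Results of :meth:`ProbeSNPScreen.fit`."""

    def __init__(self, model: ProbeSNPScreen, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"].fillna(False).astype(bool)].reset_index(drop=True)

    def flagged_counts(self) -> pd.Series:
        """Flagged-probe count per probe set (probe sets with >= 1 flag)."""
        f = self.flagged
        return f.groupby("probe_set_id")["probe_id"].count() if not f.empty else pd.Series(dtype=int)

    def profile_table(self) -> pd.DataFrame:
        return probe_profile_table(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        n_sets = self.table["probe_set_id"].nunique() if not self.table.empty else 0
        n_flag = int(self.table["flagged"].fillna(False).sum()) if not self.table.empty else 0
        n_sets_flag = self.flagged["probe_set_id"].nunique() if n_flag else 0
        return "\n".join([
            f"Probe-level SNP screen (|z| > {self.model.k:g}, |residual| >= "
            f"{self.model.min_effect:g} log2, {self.model.center} centering)",
            f"  probe sets screened: {n_sets}",
            f"  probes flagged:      {n_flag} in {n_sets_flag} probe set(s)",
        ])

    def __repr__(self) -> str:
        return f"<ProbeScreenResults: {len(self.table)} probes>"
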