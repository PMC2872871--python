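"""Cross-experiment concordance of the two reciprocal congenic comparisons.

The two experiments measure the same allele contrast from opposite strain
backgrounds: experiment A compares the iP background against the P.NP
congenic (which carries the iNP interval), experiment B compares the NP.P
congenic (carrying the iP interval) against the iNP background.  Both ratios
are oriented iP-allele-carrier over iNP-allele-carrier, so a genuine cis
effect must appear with the same sign in both.

A probe set is a strong candidate when at least one context (a brain region,
or the cross-region average) shows it significant in *both* experiments at a
relaxed per-test level (raw p <= alpha, default 0.05) with consistent
direction there.  Because the experiments are independent, false positives
introduced by the relaxation are unlikely to replicate: under the null the
per-context selection probability is at most alpha^2.

Agreement between the selected candidates is summarized by the same-direction
count and by the squared Pearson correlation of the two log2 ratio vectors.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .diffexpr import to_log2
from .errors import ValidationError
from .expression import COMBINED, REGIONS

__all__ = [
    "EXPERIMENT_A",
    "EXPERIMENT_B",
    "orient_ratio",
    "select_concordant",
    "direction_agreement",
    "log_ratio_correlation",
    "combined_direction_discordance",
    "load_table3",
    "load_table2",
    "ReciprocalConcordance",
    "ConcordanceResults",
]

#: Experiment labels: A = iP vs P.NP (8v8 animals), B = NP.P vs iNP (6v6).
EXPERIMENT_A = "A"
EXPERIMENT_B = "B"

#: Numerator group of each experiment's published ratio, already the
#: iP-allele carrier in both (iP strain in A, NP.P congenic in B).
_IP_CARRIER_NUMERATOR = {EXPERIMENT_A: "iP", EXPERIMENT_B: "NP.P"}
_ALL_NUMERATORS = {
    EXPERIMENT_A: ("iP", "P.NP"),
    EXPERIMENT_B: ("NP.P", "iNP"),
}


def _flip_signed(s: float) -> float:
    """Signed-ratio inversion (r -> 1/r in the signed convention)."""
    if abs(s) == 1.0:
        return 1.0
    return -s


def orient_ratio(experiment: str, numerator_group: str, ratio: float) -> float:
    """Orient a signed ratio to the common iP-over-iNP-allele convention.

    *numerator_group* names the strain whose expression sat in the numerator
    when *ratio* was computed.  If that strain carries the iP interval allele
    the ratio is returned unchanged; otherwise it is inverted (signed-ratio
    inversion s -> -s).
    """
    if experiment not in _ALL_NUMERATORS:
        raise ValidationError(f"unknown experiment {experiment!r}; expected 'A' or 'B'")
    if numerator_group not in _ALL_NUMERATORS[experiment]:
        raise ValidationError(
            f"unknown numerator {numerator_group!r} for experiment {experiment}; "
            f"expected one of {_ALL_NUMERATORS[experiment]}"
        )
    if abs(ratio) < 1:
        raise ValidationError(f"|signed ratio| must be >= 1, got {ratio}")
    if numerator_group == _IP_CARRIER_NUMERATOR[experiment]:
        return float(ratio)
    return float(_flip_signed(ratio))


# ----------------------------------------------------------------------
# Pair-level statistics
# ----------------------------------------------------------------------

def _signs(ratios: np.ndarray) -> np.ndarray:
    """Direction of each signed ratio: sign of its log2 (0 for |r| == 1)."""
    return np.sign(np.sign(ratios) * np.log2(np.abs(ratios)))


def _complete(pairs: pd.DataFrame) -> pd.DataFrame:
    return pairs.dropna(subset=["ratio_a", "ratio_b"])


def direction_agreement(pairs: pd.DataFrame) -> tuple[int, int]:
    """(n_same_sign, n_total) over complete ratio pairs.

    Pairs with a missing ratio, or with a ratio of exactly +/-1 (zero log2
    difference, direction undefined), are excluded from n_total.
    """
    sub = _complete(pairs)
    sa = _signs(sub["ratio_a"].to_numpy(dtype=float))
    sb = _signs(sub["ratio_b"].to_numpy(dtype=float))
    defined = (sa != 0) & (sb != 0)
    n_total = int(defined.sum())
    n_same = int((sa[defined] == sb[defined]).sum())
    return n_same, n_total


def log_ratio_correlation(pairs: pd.DataFrame) -> float:
    """Squared Pearson correlation of the two log2-ratio vectors.

    Equivalently the OLS coefficient of determination of either axis on the
    other; symmetric in the two experiments.  Requires >= 3 complete pairs
    and non-zero variance on both axes.
    """
    sub = _complete(pairs)
    if len(sub) < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {len(sub)}")
    x = to_log2(sub["ratio_a"].to_numpy(dtype=float))
    y = to_log2(sub["ratio_b"].to_numpy(dtype=float))
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance on one axis; correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def combined_direction_discordance(pairs: pd.DataFrame) -> int:
    """Number of combined-context pairs whose ratios disagree in sign."""
    sub = pairs[pairs["context"] == COMBINED] if "context" in pairs.columns else pairs
    n_same, n_total = direction_agreement(sub)
    return n_total - n_same


# ----------------------------------------------------------------------
# Dual-significance selection
# ----------------------------------------------------------------------

def select_concordant(pairs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the dual-significance / direction-consistency filter.

    *pairs* is a tidy table with one row per (probe set, context) carrying
    ``probe_set_id, context, ratio_a, ratio_b`` and either raw p-values
    (``p_a, p_b``) or pre-marked significance flags (``sig_a, sig_b``).

    A context qualifies iff both experiments are significant there (p <= alpha
    in each, or both flags set) *and* the two ratios share a defined sign in
    that same context.  A probe set is selected iff at least one context
    qualifies.

    Returns one row per probe set: ``probe_set_id, qualifying_contexts``
    (list), ``selected`` (bool).
    """
    has_p = {"p_a", "p_b"}.issubset(pairs.columns)
    has_sig = {"sig_a", "sig_b"}.issubset(pairs.columns)
    if not (has_p or has_sig):
        raise ValidationError("pairs need either (p_a, p_b) or (sig_a, sig_b)")
    df = pairs.copy()
    if has_p and df[["p_a", "p_b"]].notna().all(axis=None):
        both_sig = (df["p_a"] <= alpha) & (df["p_b"] <= alpha)
    elif has_p and has_sig:
        # mixed fixtures: prefer p where present, fall back to flags
        both_sig = np.where(
            df["p_a"].notna() & df["p_b"].notna(),
            (df["p_a"] <= alpha) & (df["p_b"] <= alpha),
            df["sig_a"].fillna(False).astype(bool) & df["sig_b"].fillna(False).astype(bool),
        )
    elif has_p:
        both_sig = (df["p_a"] <= alpha) & (df["p_b"] <= alpha)
    else:
        both_sig = df["sig_a"].astype(bool) & df["sig_b"].astype(bool)
    complete = df["ratio_a"].notna() & df["ratio_b"].notna()
    sa = np.where(complete, _signs(df["ratio_a"].fillna(1.0).to_numpy(dtype=float)), 0)
    sb = np.where(complete, _signs(df["ratio_b"].fillna(1.0).to_numpy(dtype=float)), 0)
    qualifies = np.asarray(both_sig, dtype=bool) & (sa == sb) & (sa != 0)
    df = df.assign(_q=qualifies)
    records = []
    for pid, sub in df.groupby("probe_set_id", sort=False):
        ctxs = sub.loc[sub["_q"], "context"].tolist()
        records.append(
            {"probe_set_id": pid, "qualifying_contexts": ctxs, "selected": bool(ctxs)}
        )
    return pd.DataFrame(records, columns=["probe_set_id", "qualifying_contexts", "selected"])


# ----------------------------------------------------------------------
# Packaged fixtures (transcriptions of the published candidate tables)
# ----------------------------------------------------------------------

_CONTEXTS = list(REGIONS) + [COMBINED]


def _data_path(name: str):
    return resources.files("congenic.data").joinpath(name)


def load_table3(tidy: bool = True) -> pd.DataFrame:
    """The packaged 74-probe-set reciprocal-comparison candidate table.

    Per context (five regions + combined): the oriented signed ratios of both
    experiments and the published per-context dual-significance marks.
    ``tidy=True`` (default) melts to one row per (probe set, context) with
    columns ``probe_set_id, symbol, context, ratio_a, ratio_b, sig_a, sig_b``;
    ratios absent in the source ("ND") become NaN.
    """
    with resources.as_file(_data_path("table3_ratios.tsv")) as path:
        wide = pd.read_csv(path, sep="\t", na_values=["ND"])
    if not tidy:
        return wide
    rows = []
    for ctx in _CONTEXTS:
        sub = wide[["probe_set_id", "symbol",
                    f"{ctx}_ratio_a", f"{ctx}_ratio_b", f"{ctx}_sig_a", f"{ctx}_sig_b"]].copy()
        sub.columns = ["probe_set_id", "symbol", "ratio_a", "ratio_b", "sig_a", "sig_b"]
        sub.insert(2, "context", ctx)
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    out["sig_a"] = out["sig_a"].astype(bool)
    out["sig_b"] = out["sig_b"].astype(bool)
    return out


def load_table2() -> pd.DataFrame:
    """The packaged microarray-vs-qRT-PCR confirmation table (44 pairs).

    Columns: ``gene, region, microarray_ratio, qrtpcr_ratio,
    microarray_significant``.  For direction-agreement computations the
    microarray ratio plays the role of experiment A and the qRT-PCR ratio of
    experiment B.
    """
    with resources.as_file(_data_path("table2_qrtpcr.tsv")) as path:
        df = pd.read_csv(path, sep="\t", na_values=["ND"])
    df["microarray_significant"] = df["microarray_significant"].astype(bool)
    return df


# ----------------------------------------------------------------------
# Model / Results
# ----------------------------------------------------------------------

class ReciprocalConcordance:
    """Concordance model over matched results of the two reciprocal experiments.

    Construct from a tidy pair table (``from_pairs`` semantics of the default
    constructor), from two single-experiment result tables produced by
    :class:`~congenic.diffexpr.CongenicDE` (:meth:`from_results`), or from the
    packaged published candidate table (:meth:`from_fixture`).

    ``fit(alpha=0.05)`` applies the dual-significance selection and computes
    the agreement statistics.
    """

    def __init__(self, pairs: pd.DataFrame):
        required = {"probe_set_id", "context", "ratio_a", "ratio_b"}
        missing = required - set(pairs.columns)
        if missing:
            raise ValidationError(f"pair table missing column(s) {sorted(missing)}")
        self.pairs = pairs.reset_index(drop=True)

    @classmethod
    def from_results(cls, results_a: pd.DataFrame, results_b: pd.DataFrame) -> "ReciprocalConcordance":
        """Match two tidy single-experiment result tables on (probe set, context).

        Both tables must carry ``probe_set_id, context, signed_fc, p`` oriented
        to the common allele convention (as :class:`CongenicDE` emits them).
        """
        key = ["probe_set_id", "context"]
        a = results_a[key + ["signed_fc", "p"]].rename(
            columns={"signed_fc": "ratio_a", "p": "p_a"})
        b = results_b[key + ["signed_fc", "p"]].rename(
            columns={"signed_fc": "ratio_b", "p": "p_b"})
        pairs = a.merge(b, on=key, how="inner")
        if pairs.empty:
            raise ValidationError("the two result sets share no (probe set, context) pairs")
        return cls(pairs)

    @classmethod
    def from_fixture(cls) -> "ReciprocalConcordance":
        return cls(load_table3())

    def fit(self, alpha: float = 0.05) -> "ConcordanceResults":
        records = select_concordant(self.pairs, alpha=alpha)
        combined = self.pairs[self.pairs["context"] == COMBINED]
        n_same, n_total = direction_agreement(combined)
        r2 = log_ratio_correlation(combined) if len(_complete(combined)) >= 3 else float("nan")
        return ConcordanceResults(self, alpha, records, n_same, n_total, r2)


class ConcordanceResults:
    """Results of :meth:`ReciprocalConcordance.fit`."""

    def __init__(self, model, alpha, records, n_same, n_total, r_squared):
        self.model = model
        self.alpha = alpha
        self.records = records
        self.n_same_direction = n_same
        self.n_pairs = n_total
        self.r_squared = r_squared

    @property
    def n_selected(self) -> int:
        return int(self.records["selected"].sum())

    @property
    def selected_ids(self) -> list[str]:
        return self.records.loc[self.records["selected"], "probe_set_id"].tolist()

    @property
    def combined_discordance(self) -> int:
        return combined_direction_discordance(self.model.pairs)

    def context_histogram(self) -> dict[str, int]:
        """How often each context qualifies among selected probe sets."""
        hist: dict[str, int] = {}
        for ctxs in self.records["qualifying_contexts"]:
            for c in ctxs:
                hist[c] = hist.get(c, 0) + 1
        return dict(sorted(hist.items()))

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_pairs": self.n_pairs,
            "n_same_direction": self.n_same_direction,
            "r_squared": self.r_squared,
            "n_selected": self.n_selected,
            "combined_discordance": self.combined_discordance,
            "qualifying_context_histogram": self.context_histogram(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def summary(self) -> str:
        return "\n".join(
            [
                f"Reciprocal-congenic concordance (alpha = {self.alpha:g})",
                f"  selected probe sets:        {self.n_selected}",
                f"  combined-context pairs:     {self.n_pairs}",
                f"  same direction (combined):  {self.n_same_direction}",
                f"  discordant (combined):      {self.combined_discordance}",
                f"  R^2 of log2 ratios:         {self.r_squared:.4f}",
            ]
        )

    def __repr__(self) -> str:
        return (
            f"<ConcordanceResults: {self.n_selected} selected, "
            f"R^2={self.r_squared:.3f}, {self.n_same_direction}/{self.n_pairs} same direction>"
        )
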