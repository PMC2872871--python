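"""Detection filtering, two-group differential testing, FDR, ratio conventions.

The analysis contrasts animals carrying the iP allele of the introgressed
interval against animals carrying the iNP allele, per brain region and on the
per-animal average across regions (the "combined" context, which gains power
for effects shared in direction across regions).  All differences are oriented
iP-allele-carrier minus iNP-allele-carrier, so a positive value means higher
expression with the iP interval.

Fold changes use the signed convention: fc = 2**log2_diff is reported as-is
when >= 1 and as -1/fc otherwise, so magnitudes are symmetric about +/-1.

Multiple testing is controlled by Benjamini-Hochberg within each family,
where a family is one locus class (the in-interval "cis" universe or the
rest-of-genome "trans" universe) in one context, after detection filtering.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import annotation as _ann
from ._stats import estimate_variance_prior
from .errors import ConfigurationError, ValidationError
from .expression import COMBINED, GROUP_INP, GROUP_IP, ExpressionMatrix, REGIONS

__all__ = [
    "detection_filter",
    "average_regions",
    "differential_test",
    "bh_fdr",
    "signed_fold_change",
    "to_log2",
    "relative_difference",
    "summarize_counts",
    "CongenicDE",
    "CongenicDEResults",
]

logger = logging.getLogger(__name__)

METHODS = ("student", "welch", "moderated")

#: Columns of a differential-test result table.
RESULT_COLUMNS = ["probe_set_id", "context", "log2_diff", "signed_fc", "t", "df", "p", "q"]


# ----------------------------------------------------------------------
# Ratio conventions
# ----------------------------------------------------------------------

def signed_fold_change(log2_diff):
    """Signed fold change of a log2 difference.

    fc = 2**log2_diff; returned as fc when fc >= 1 and as -1/fc otherwise,
    so |result| >= 1 always and down-regulation mirrors up-regulation.
    Accepts scalars or arrays.
    """
    ld = np.asarray(log2_diff, dtype=float)
    if not np.isfinite(ld).all():
        raise ValidationError("log2_diff must be finite")
    fc = np.power(2.0, np.abs(ld))
    out = np.where(ld >= 0, fc, -fc)
    return out.item() if np.isscalar(log2_diff) or out.ndim == 0 else out

def to_log2(signed_fc):
    """Inverse of :func:`signed_fold_change`: sign(s) * log2(|s|).

    Signed ratios inside (-1, 1) violate the convention and are rejected.
    """
    s = np.asarray(signed_fc, dtype=float)
    if (np.abs(s) < 1).any():
        bad = np.asarray(s)[np.abs(s) < 1]
        raise ValidationError(f"|signed_fc| must be >= 1; offending value(s) {bad!r}")
    out = np.sign(s) * np.log2(np.abs(s))
    return out.item() if np.isscalar(signed_fc) or out.ndim == 0 else out


def relative_difference(mean_a_linear, mean_b_linear):
    """Relative difference (E_b - E_a) / E_a of two linear-scale means."""
    a = np.asarray(mean_a_linear, dtype=float)
    b = np.asarray(mean_b_linear, dtype=float)
    if (a <= 0).any():
        raise ValidationError("reference mean must be positive")
    out = (b - a) / a
    return out.item() if np.isscalar(mean_a_linear) or out.ndim == 0 else out


# ----------------------------------------------------------------------
# Detection filter
# ----------------------------------------------------------------------

def detection_filter(
    m: ExpressionMatrix,
    scope: str = "region",
    min_fraction: float = 1.0 / 3.0,
) -> list[str]:
    """Probe sets reliably detected often enough to be analyzed.

    ``scope="region"`` (matrix restricted to a single region): retain a probe
    set iff it is present on at least *min_fraction* of the arrays in at least
    one of the two groups.

    ``scope="combined"`` (full matrix): retain iff present on at least
    *min_fraction* of the arrays in at least one brain region in at least one
    group.
    """
    if m.detection is None:
        raise ConfigurationError("detection filtering requested but no detection calls present")
    if not 0 < min_fraction <= 1:
        raise ValidationError(f"min_fraction must be in (0, 1], got {min_fraction}")
    det = m.detection
    keep = np.zeros(det.shape[0], dtype=bool)
    if scope == "region":
        regions = m.samples["region"].unique()
        if len(regions) != 1:
            raise ValidationError(
                f"scope='region' requires a single-region matrix, found {sorted(regions)}"
            )
        cells = [m.samples.index[m.samples["group"] == g] for g in (GROUP_IP, GROUP_INP)]
    elif scope == "combined":
        cells = [
            m.samples.index[(m.samples["group"] == g) & (m.samples["region"] == r)]
            for g in (GROUP_IP, GROUP_INP)
            for r in m.samples["region"].unique()
        ]
    else:
        raise ValidationError(f"unknown scope {scope!r}; expected 'region' or 'combined'")
    for cols in cells:
        if len(cols) == 0:
            continue
        frac = det[cols].to_numpy().mean(axis=1)
        # small epsilon so e.g. 2 of 6 arrays passes a 1/3 threshold exactly
        keep |= frac + 1e-12 >= min_fraction
    return [pid for pid, k in zip(det.index, keep) if k]


# ----------------------------------------------------------------------
# Region averaging
# ----------------------------------------------------------------------

def average_regions(m: ExpressionMatrix, regions: Optional[Iterable[str]] = None) -> ExpressionMatrix:
    """Average each animal's log2 values across brain regions.

    Returns a matrix with one pseudo-sample per animal (region set to
    ``"combined"``), the arithmetic mean on the log2 scale — equivalently the
    geometric mean of linear values.  Every animal must have a sample in every
    configured region.  Detection calls do not average and are dropped; the
    combined-scope detection filter operates on the unaveraged matrix.
    """
    regions = tuple(regions) if regions is not None else tuple(sorted(m.samples["region"].unique()))
    sheet = m.samples
    cols, rows = [], []
    for animal, sub in sheet.groupby("animal_id", sort=True):
        have = set(sub["region"])
        for r in regions:
            if r not in have:
                raise ValidationError(f"animal {animal!r} has no sample in region {r!r}")
        sample_ids = [sub.index[sub["region"] == r][0] for r in regions]
        cols.append(m.values[sample_ids].mean(axis=1))
        rows.append(
            {
                "sample_id": f"{animal}__combined",
                "animal_id": animal,
                "group": sub["group"].iloc[0],
                "region": COMBINED,
            }
        )
    values = pd.concat(cols, axis=1)
    values.columns = [r["sample_id"] for r in rows]
    return ExpressionMatrix(values, pd.DataFrame(rows))


# ----------------------------------------------------------------------
# Two-group tests
# ----------------------------------------------------------------------

def _group_arrays(m: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    a_cols = m.samples.index[m.samples["group"] == GROUP_IP]
    b_cols = m.samples.index[m.samples["group"] == GROUP_INP]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValidationError(
            f"both groups need >= 2 samples; got {len(a_cols)} iP-allele and "
            f"{len(b_cols)} iNP-allele carriers"
        )
    return m.values[a_cols].to_numpy(), m.values[b_cols].to_numpy()


def differential_test(m: ExpressionMatrix, method: str = "moderated", context: Optional[str] = None) -> pd.DataFrame:
    """Per-probe-set two-group test on a single-context matrix.

    The matrix must hold one context: either one brain region, or the output
    of :func:`average_regions`.  Differences are oriented iP-allele-carrier
    minus iNP-allele-carrier.  Returns a DataFrame with columns
    ``probe_set_id, context, log2_diff, signed_fc, t, df, p`` (q is attached
    later, per multiple-testing family).

    Methods
    -------
    ``student`` : pooled-variance two-sample t-test.
    ``welch``   : unequal-variance t-test (Welch-Satterthwaite df).
    ``moderated`` : pooled-variance t with empirical-Bayes shrinkage of the
        per-probe-set variances toward a common prior (see ``_stats``); falls
        back to ``student`` when the prior has no finite solution.
    """
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; expected one of {METHODS}")
    contexts = set(m.samples["region"].unique())
    if len(contexts) != 1:
        raise ValidationError(f"differential_test needs a single context, found {sorted(contexts)}")
    if context is None:
        context = next(iter(contexts))
    a, b = _group_arrays(m)
    n1, n2 = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)

    if method == "welch":
        both_const = (v1 == 0) & (v2 == 0)
        if (both_const & (diff != 0)).any():
            bad = [m.probe_set_ids[i] for i in np.nonzero(both_const & (diff != 0))[0]]
            raise ValidationError(
                f"welch df undefined for zero-variance, unequal-mean probe set(s) {bad}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
            se2 = v1 / n1 + v2 / n2
            df = np.where(
                se2 > 0,
                se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)),
                n1 + n2 - 2,
            )
    else:
        d = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
        if method == "moderated":
            prior = estimate_variance_prior(s2, d)
            if prior.finite:
                s_tilde2 = (prior.d0 * prior.s0_squared + d * s2) / (prior.d0 + d)
                df = np.full_like(s2, prior.d0 + d)
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = diff / np.sqrt(s_tilde2 * (1.0 / n1 + 1.0 / n2))
                p = 2.0 * stats.t.sf(np.abs(t), df)
            else:
                logger.info(
                    "moderated test: no finite prior df (log-variance spread within "
                    "sampling noise); falling back to the student test"
                )
                method = "student"
        if method == "student":
            with np.errstate(divide="ignore", invalid="ignore"):
                t = diff / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
            df = np.full_like(s2, d)
            p = 2.0 * stats.t.sf(np.abs(t), df)

    # Degenerate convention: both groups constant and equal -> no evidence.
    degen = ~np.isfinite(t) & (diff == 0)
    t = np.where(degen, 0.0, t)
    p = np.where(degen, 1.0, p)
    # Constant but unequal (student/moderated with zero shrunk variance): t=inf, p=0.
    p = np.where(~np.isfinite(t) & (diff != 0), 0.0, p)
    p = np.clip(p, 0.0, 1.0)

    return pd.DataFrame(
        {
            "probe_set_id": m.probe_set_ids,
            "context": context,
            "log2_diff": diff,
            "signed_fc": signed_fold_change(diff),
            "t": t,
            "df": df,
            "p": p,
        }
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values for one testing family."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
# Table-1-style count summary
# ----------------------------------------------------------------------

def summarize_counts(results: pd.DataFrame, threshold: float = 0.25,
                     regions: Iterable[str] = REGIONS) -> pd.DataFrame:
    """Count significant probe sets per region and in the combined analysis.

    *results* is a tidy result table (one locus class) covering the regional
    contexts and ``"combined"``, with a ``q`` column.  Returns one row per
    statistic: per-region totals, per-region "only in that region", the
    any-region and multi-region aggregates, the combined total, and the count
    significant only in the combined analysis.
    """
    regions = list(regions)
    sig = results[results["q"] <= threshold]
    by_region = {
        r: set(sig.loc[sig["context"] == r, "probe_set_id"]) for r in regions
    }
    combined = set(sig.loc[sig["context"] == COMBINED, "probe_set_id"])
    any_region = set().union(*by_region.values()) if by_region else set()
    counts = {pid: sum(pid in s for s in by_region.values()) for pid in any_region}
    multiple = {pid for pid, c in counts.items() if c > 1}
    rows = []
    for r in regions:
        only = {pid for pid in by_region[r] if counts[pid] == 1}
        rows.append({"statistic": "total", "context": r, "count": len(by_region[r])})
        rows.append({"statistic": "single_region_only", "context": r, "count": len(only)})
    rows += [
        {"statistic": "total", "context": "at_least_one_region", "count": len(any_region)},
        {"statistic": "total", "context": "multiple_regions", "count": len(multiple)},
        {"statistic": "total", "context": COMBINED, "count": len(combined)},
        {"statistic": "only_significant_in_combined", "context": COMBINED,
         "count": len(combined - any_region)},
    ]
    return pd.DataFrame(rows, columns=["statistic", "context", "count"])


# ----------------------------------------------------------------------
# Model / Results
# ----------------------------------------------------------------------

class CongenicDE:
    """Differential-expression model for one congenic-vs-background experiment.

    Orchestrates the full single-experiment analysis: locus classification of
    every probe set against the introgressed interval, detection filtering,
    per-region and region-averaged two-group tests, and BH FDR within each
    (locus class, context) family.

    Parameters
    ----------
    matrix
        :class:`~congenic.expression.ExpressionMatrix` with samples from all
        configured brain regions.
    annotations
        Probe-set annotations (list of
        :class:`~congenic.annotation.ProbeSetAnnotation`), or a precomputed
        locus-class Series indexed by probe_set_id.
    interval
        Introgressed interval; defaults to the chromosome 4 QTL interval.
    method
        ``student`` | ``welch`` | ``moderated`` (default).
    min_detection_fraction
        Detection-filter threshold (default 1/3).  If the matrix carries no
        detection calls, filtering is disabled with a logged warning.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        annotations,
        interval: _ann.GenomicInterval = _ann.DEFAULT_INTERVAL,
        method: str = "moderated",
        min_detection_fraction: float = 1.0 / 3.0,
        regions: Optional[Iterable[str]] = None,
    ):
        if method not in METHODS:
            raise ValidationError(f"unknown method {method!r}")
        self.matrix = matrix
        if isinstance(annotations, pd.Series):
            self.locus_class = annotations
        else:
            self.locus_class = _ann.classify_table(annotations, interval)
        missing = set(matrix.probe_set_ids) - set(self.locus_class.index)
        if missing:
            raise ValidationError(
                f"{len(missing)} probe set(s) in the matrix lack annotations, "
                f"e.g. {sorted(missing)[:5]}"
            )
        self.interval = interval
        self.method = method
        self.min_detection_fraction = min_detection_fraction
        self.regions = tuple(regions) if regions is not None else tuple(
            sorted(matrix.samples["region"].unique())
        )

    def fit(self, fdr_threshold: float = 0.25) -> "CongenicDEResults":
        m = self.matrix
        filtering = m.detection is not None
        if not filtering:
            logger.warning("no detection calls: detection filtering disabled")
        tables = []
        universes = {}
        class_of = self.locus_class.reindex(m.values.index)
        for locus in (_ann.CIS, _ann.TRANS):
            ids = [p for p in m.probe_set_ids if class_of[p] == locus]
            if not ids:
                continue
            sub_all = m.subset_probe_sets(ids)
            for region in self.regions:
                sub = sub_all.subset_region(region)
                keep = (
                    detection_filter(sub, "region", self.min_detection_fraction)
                    if filtering
                    else ids
                )
                universes[(locus, region)] = len(keep)
                if not keep:
                    continue
                res = differential_test(sub.subset_probe_sets(keep), self.method)
                res["q"] = bh_fdr(res["p"].to_numpy())
                res.insert(1, "locus_class", locus)
                tables.append(res)
            keep = (
                detection_filter(sub_all, "combined", self.min_detection_fraction)
                if filtering
                else ids
            )
            universes[(locus, COMBINED)] = len(keep)
            if keep:
                avg = average_regions(sub_all.subset_probe_sets(keep), self.regions)
                res = differential_test(avg, self.method)
                res["q"] = bh_fdr(res["p"].to_numpy())
                res.insert(1, "locus_class", locus)
                tables.append(res)
        table = (
            pd.concat(tables, ignore_index=True)
            if tables
            else pd.DataFrame(columns=["probe_set_id", "locus_class"] + RESULT_COLUMNS[1:])
        )
        for (locus, ctx), n in sorted(universes.items()):
            logger.info("family %s/%s: %d probe sets analyzed", locus, ctx, n)
        return CongenicDEResults(self, table, universes, fdr_threshold)


class CongenicDEResults:
    """Results of :meth:`CongenicDE.fit`.

    Attributes
    ----------
    table
        Tidy DataFrame ``probe_set_id, locus_class, context, log2_diff,
        signed_fc, t, df, p, q`` over every analyzed family.
    family_sizes
        Mapping (locus_class, context) -> number of probe sets analyzed
        (i.e. surviving the detection filter) in that FDR family.
    """

    def __init__(self, model: CongenicDE, table: pd.DataFrame,
                 family_sizes: dict, fdr_threshold: float):
        self.model = model
        self.table = table
        self.family_sizes = family_sizes
        self.fdr_threshold = fdr_threshold

    def counts(self, locus_class: str = _ann.CIS, threshold: Optional[float] = None) -> pd.DataFrame:
        """Table-1-style significant-probe-set counts for one locus class."""
        thr = self.fdr_threshold if threshold is None else threshold
        sub = self.table[self.table["locus_class"] == locus_class]
        return summarize_counts(sub, thr, self.model.regions)

    def significant(self, locus_class: Optional[str] = None,
                    context: Optional[str] = None,
                    threshold: Optional[float] = None) -> pd.DataFrame:
        thr = self.fdr_threshold if threshold is None else threshold
        sub = self.table[self.table["q"] <= thr]
        if locus_class is not None:
            sub = sub[sub["locus_class"] == locus_class]
        if context is not None:
            sub = sub[sub["context"] == context]
        return sub.reset_index(drop=True)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        lines = [
            f"Congenic differential expression ({self.model.method} test, "
            f"FDR <= {self.fdr_threshold:g})",
            f"  interval: {self.model.interval}",
        ]
        for locus in (_ann.CIS, _ann.TRANS):
            sub = self.table[self.table["locus_class"] == locus]
            if sub.empty:
                continue
            lines.append(f"  {locus} universe:")
            for ctx in list(self.model.regions) + [COMBINED]:
                n_family = self.family_sizes.get((locus, ctx), 0)
                n_sig = int((sub.loc[sub["context"] == ctx, "q"] <= self.fdr_threshold).sum())
                lines.append(f"    {ctx:<18} {n_sig:>5} significant of {n_family} analyzed")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<CongenicDEResults: {len(self.table)} tests over {len(self.family_sizes)} families>"
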