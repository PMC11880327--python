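"""Per-region benchmarking of predicted against reference TCR structures.

A prediction set is summarised as a per-record, per-region RMSD table:
CDR loops are measured anchor-aligned (spline up-sampled when a loop pair
differs in length, which can happen when a predictor mis-models loop
numbering); framework and whole-chain values are measured after a
whole-chain backbone superposition, the framework being every IMGT
position outside the three CDR loop ranges. On top of the table sit the
comparison statistics used to contrast predictors: sub-threshold counts,
two-model quadrant classification, hypothetical best-of-ensemble rates,
the pooled t statistic with two-tailed p, and identity-RMSD trend
stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import DistanceMatrix, GeometryError, kabsch, loop_distance, _matched_coords
from .model import (
    CDR_LOOP_POSITIONS,
    REGION_NAMES,
    StructureError,
    TcrRecord,
    extract_region,
)

logger = logging.getLogger(__name__)

CHAIN_SUFFIX = {"alpha": "alpha", "beta": "beta"}

#: region columns of a benchmark table, per chain: framework, three CDRs
#: and the whole chain.
REPORT_REGIONS = tuple(
    f"{name}_{chain}"
    for chain in ("alpha", "beta")
    for name in ("FW", "CDR1", "CDR2", "CDR3", "whole")
)


class BenchmarkError(StructureError):
    pass


class PairingError(BenchmarkError):
    pass


@dataclass
class RegionRmsdReport:
    """record_id x region RMSD table (Angstrom) for one predictor."""

    model_name: str
    table: pd.DataFrame  # index: record ids; columns: REPORT_REGIONS

    @property
    def record_ids(self) -> list[str]:
        return [str(i) for i in self.table.index]

    def values(self, region: str) -> pd.Series:
        if region not in self.table.columns:
            raise BenchmarkError(f"unknown region {region!r}")
        return self.table[region]

    def means(self) -> pd.Series:
        return self.table.mean(skipna=True)

    def stds(self) -> pd.Series:
        return self.table.std(skipna=True, ddof=1)

    def n_missing(self) -> int:
        return int(self.table.isna().sum().sum())

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"mean": self.means(), "std": self.stds()})
        out.attrs["n_missing_cells"] = self.n_missing()
        return out


def _chain_rmsds(pred, ref) -> tuple[float, float]:
    """(framework, whole-chain) RMSD after whole-chain backbone superposition."""
    pm, pr = _matched_coords(pred.residues, ref.residues)
    if len(pm) < 3:
        raise GeometryError("fewer than 3 matched backbone atoms in chain")
    rotation, translation, whole = kabsch(pm, pr)
    fw_pred = [r for r in pred.residues if r.imgt_number not in CDR_LOOP_POSITIONS]
    fw_ref = [r for r in ref.residues if r.imgt_number not in CDR_LOOP_POSITIONS]
    fm, fr = _matched_coords(fw_pred, fw_ref)
    if len(fm) == 0:
        raise GeometryError("no matched framework atoms")
    moved = fm @ rotation.T + translation
    fw = float(np.sqrt(np.mean(np.sum((moved - fr) ** 2, axis=1))))
    return fw, whole


def region_report(
    predictions: Sequence[TcrRecord],
    references: Sequence[TcrRecord],
    model_name: str = "model",
) -> RegionRmsdReport:
    """Per-record, per-region RMSD of predictions against references.

    Records are paired by ``record_id``; an id present on one side only is
    a pairing error. A region that fails to extract or measure is recorded
    as missing (NaN), excluded from column means, and counted in the
    report summary.
    """
    ref_by_id = {r.record_id: r for r in references}
    pred_by_id = {p.record_id: p for p in predictions}
    if set(ref_by_id) != set(pred_by_id):
        only_pred = sorted(set(pred_by_id) - set(ref_by_id))
        only_ref = sorted(set(ref_by_id) - set(pred_by_id))
        raise PairingError(
            f"unpaired record ids: predictions-only {only_pred}, references-only {only_ref}"
        )
    rows = {}
    n_failed = 0
    for rid in (p.record_id for p in predictions):
        pred, ref = pred_by_id[rid], ref_by_id[rid]
        row: dict[str, float] = {}
        for chain in ("alpha", "beta"):
            try:
                fw, whole = _chain_rmsds(pred.chain(chain), ref.chain(chain))
            except (GeometryError, StructureError) as exc:
                logger.warning("%s %s chain: %s", rid, chain, exc)
                fw = whole = float("nan")
                n_failed += 2
            row[f"FW_{chain}"] = fw
            row[f"whole_{chain}"] = whole
            for region in REGION_NAMES:
                try:
                    lp = extract_region(pred, chain, region)
                    lr = extract_region(ref, chain, region)
                    row[f"{region}_{chain}"] = loop_distance(lp, lr).value
                except (GeometryError, StructureError) as exc:
                    logger.warning("%s %s %s: %s", rid, chain, region, exc)
                    row[f"{region}_{chain}"] = float("nan")
                    n_failed += 1
        rows[rid] = row
    table = pd.DataFrame.from_dict(rows, orient="index")[list(REPORT_REGIONS)]
    if n_failed:
        logger.info("%s: %d region cells missing (excluded from means)", model_name, n_failed)
    return RegionRmsdReport(model_name=model_name, table=table)


def subthreshold_count(
    report: RegionRmsdReport, region: str, threshold: float = 2.0
) -> tuple[int, float]:
    """(count, fraction) of records with region RMSD strictly below threshold.

    Missing cells are excluded from both numerator and denominator.
    """
    values = report.values(region).dropna()
    count = int((values < threshold).sum())
    return count, count / len(values) if len(values) else float("nan")


@dataclass
class QuadrantSummary:
    """Two-model classification of records against an RMSD threshold:
    both below (green), both at-or-above (red), or rescued by one model only."""

    model_a: str
    model_b: str
    region: str
    threshold: float
    both_below: int
    both_at_or_above: int
    only_a_below: int
    only_b_below: int

    @property
    def n(self) -> int:
        return self.both_below + self.both_at_or_above + self.only_a_below + self.only_b_below

    def to_dict(self) -> dict:
        return {
            "model_a": self.model_a,
            "model_b": self.model_b,
            "region": self.region,
            "threshold": self.threshold,
            "both_below": self.both_below,
            "both_at_or_above": self.both_at_or_above,
            "only_a_below": self.only_a_below,
            "only_b_below": self.only_b_below,
        }


def _paired_values(
    report_a: RegionRmsdReport, report_b: RegionRmsdReport, region: str
) -> tuple[pd.Series, pd.Series]:
    if set(report_a.record_ids) != set(report_b.record_ids):
        raise PairingError("reports cover different record ids")
    a = report_a.values(region)
    b = report_b.values(region).reindex(a.index)
    keep = a.notna() & b.notna()
    return a[keep], b[keep]


def quadrant_classify(
    report_a: RegionRmsdReport,
    report_b: RegionRmsdReport,
    region: str,
    threshold: float = 2.0,
) -> QuadrantSummary:
    a, b = _paired_values(report_a, report_b, region)
    below_a, below_b = a < threshold, b < threshold
    return QuadrantSummary(
        model_a=report_a.model_name,
        model_b=report_b.model_name,
        region=region,
        threshold=threshold,
        both_below=int((below_a & below_b).sum()),
        both_at_or_above=int((~below_a & ~below_b).sum()),
        only_a_below=int((below_a & ~below_b).sum()),
        only_b_below=int((~below_a & below_b).sum()),
    )


def ensemble_best(
    report_a: RegionRmsdReport,
    report_b: RegionRmsdReport,
    region: str,
    threshold: float = 2.0,
) -> float:
    """Success fraction of a hypothetical oracle picking, per record, the
    better of the two models' loops: fraction with min(a, b) < threshold."""
    a, b = _paired_values(report_a, report_b, region)
    if len(a) == 0:
        return float("nan")
    return float((np.minimum(a, b) < threshold).mean())


@dataclass
class ModelComparison:
    model_a: str
    model_b: str
    region: str
    t_value: float
    p_value: float
    n: int


def rmsd_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    model_a: str = "a",
    model_b: str = "b",
    region: str = "",
    welch: bool = False,
    ddof: int = 1,
) -> ModelComparison:
    """Pooled t statistic between two per-record RMSD samples.

    Default form: ``t = |mean_a - mean_b| / sqrt((var_a + var_b) / n)``
    with two-tailed ``p = 2 * sf(t, n - 1)`` — variances pooled by the
    common sample size and n-1 degrees of freedom. ``welch=True`` switches
    to the standard Welch unequal-variance test for comparison; it is
    never the default.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise BenchmarkError("need two equal-length 1-D RMSD samples")
    n = len(a)
    if n < 2:
        raise BenchmarkError("need at least 2 paired values")
    if welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return ModelComparison(model_a, model_b, region, float(abs(t)), float(p), n)
    va, vb = a.var(ddof=ddof), b.var(ddof=ddof)
    t = abs(a.mean() - b.mean()) / np.sqrt((va + vb) / n)
    p = 2.0 * stats.t.sf(t, df=n - 1)
    return ModelComparison(model_a, model_b, region, float(t), float(p), n)


@dataclass
class TrendReport:
    """Identity-RMSD trend: Pearson correlation overall and split into
    high-/low-identity strata, plus the linear fit over all pairs."""

    pcc_all: float
    pcc_high: float
    pcc_low: float
    split: float
    slope: float
    intercept: float
    n_all: int
    n_high: int
    n_low: int
    undefined_strata: list[str]


def _safe_pcc(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> tuple[float, bool]:
    if len(x) < min_n or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), True
    return float(stats.pearsonr(x, y).statistic), False


def identity_rmsd_trend(
    pairs: Sequence[tuple[float, float]],
    split: float = 0.65,
) -> TrendReport:
    """Correlation between pairwise sequence identity and structural RMSD,
    stratified at an identity split (default 0.65).

    A zero-variance or too-small stratum yields an undefined (NaN) PCC and
    is flagged rather than raising.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise BenchmarkError("need >= 3 (identity, RMSD) pairs")
    ident, rmsd = arr[:, 0], arr[:, 1]
    undefined: list[str] = []
    pcc_all, bad = _safe_pcc(ident, rmsd)
    if bad:
        undefined.append("all")
    hi = ident > split
    lo = ident < split
    pcc_high, bad = _safe_pcc(ident[hi], rmsd[hi])
    if bad:
        undefined.append("high")
    pcc_low, bad = _safe_pcc(ident[lo], rmsd[lo])
    if bad:
        undefined.append("low")
    if np.ptp(ident) > 0:
        fit = stats.linregress(ident, rmsd)
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope = intercept = float("nan")
        undefined.append("fit")
    return TrendReport(
        pcc_all=pcc_all,
        pcc_high=pcc_high,
        pcc_low=pcc_low,
        split=split,
        slope=slope,
        intercept=intercept,
        n_all=len(arr),
        n_high=int(hi.sum()),
        n_low=int(lo.sum()),
        undefined_strata=undefined,
    )


def embed_tsne(
    matrix: DistanceMatrix,
    perplexity: float = 10.0,
    seed: int = 0,
    labels: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """2-D t-SNE embedding of a precomputed distance matrix.

    Visualisation only: the ``label`` column is the greedy-cluster label
    passed in by the caller, passed through untouched and never re-derived
    from the embedding.
    """
    from sklearn.manifold import TSNE

    n = len(matrix)
    if n <= 3 * perplexity:
        raise BenchmarkError(
            f"need more than {int(3 * perplexity)} items for perplexity {perplexity}"
        )
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        random_state=seed,
    )
    coords = tsne.fit_transform(matrix.values)
    out = pd.DataFrame(coords, index=matrix.ids, columns=["tsne1", "tsne2"])
    if labels is not None:
        if len(labels) != n:
            raise BenchmarkError("labels length does not match matrix")
        out["label"] = np.asarray(labels)
    return out
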