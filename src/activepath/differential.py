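"""Per-group differential-abundance statistics.

Fold changes on the raw intensity scale, Welch t-tests against a (possibly
pooled) control, the two-fold/significance selection filter, coefficient of
variation QC, and one-way ANOVA with Bonferroni-corrected pairwise
comparisons.  The gene-level output table is what the subnetwork stage
consumes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from activepath.io_formats import IntensityStudy, ProteinGeneMap

logger = logging.getLogger(__name__)

_P_FLOOR = 2.2e-16  # keep p strictly positive for downstream z-conversion


class UndefinedFoldError(ValueError):
    """Fold change undefined: a side is all-missing or the control mean is 0."""


class UndefinedCVError(ValueError):
    """CV undefined: fewer than two observations or zero mean."""


class InsufficientObservationsError(ValueError):
    """A test requires more non-missing observations than are available."""


@dataclass
class FilterParams:
    """Selection-filter and testing parameters.

    ``fold_threshold`` is inclusive ("at least"): a fold of exactly 2.0 (or
    0.5) passes.  ``collapse`` controls how multiple spots mapping to one
    gene are reduced: ``"min_p"`` keeps the most significant spot's p and its
    fold; ``"mean"`` averages folds and combines p by the minimum.
    ``log_scale`` switches the t-test to log-transformed intensities.
    """

    fold_threshold: float = 2.0
    alpha: float = 0.05
    min_obs_per_group: int = 3
    collapse: str = "min_p"
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_obs_per_group < 2:
            raise ValueError("min_obs_per_group must be >= 2")
        if self.collapse not in {"min_p", "mean"}:
            raise ValueError(f"unknown collapse rule {self.collapse!r}")


def _clean(values: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    return arr[~np.isnan(arr)]


def fold_change(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Ratio of case mean to control mean on the raw intensity scale."""
    case = _clean(case_values)
    control = _clean(control_values)
    if case.size == 0 or control.size == 0:
        raise UndefinedFoldError("fold change needs >= 1 non-missing value per side")
    control_mean = float(control.mean())
    if control_mean <= 0:
        raise UndefinedFoldError(f"control mean must be > 0, got {control_mean}")
    return float(case.mean()) / control_mean


def independent_t_test(
    case_values: Sequence[float],
    control_values: Sequence[float],
    min_obs: int = 3,
) -> float:
    """Two-sided Welch t-test p-value; identical constant groups give p = 1."""
    case = _clean(case_values)
    control = _clean(control_values)
    if case.size < min_obs or control.size < min_obs:
        raise InsufficientObservationsError(
            f"need >= {min_obs} non-missing observations per side, "
            f"got {case.size} vs {control.size}"
        )
    if case.var(ddof=1) == 0 and control.var(ddof=1) == 0:
        # degenerate: Welch statistic is 0/0
        return 1.0 if case.mean() == control.mean() else _P_FLOOR
    p = stats.ttest_ind(case, control, equal_var=False).pvalue
    return float(max(min(p, 1.0), _P_FLOOR))


def coefficient_of_variation(values: Sequence[float]) -> float:
    """100 x sample standard deviation / mean (percent)."""
    vals = _clean(values)
    if vals.size < 2:
        raise UndefinedCVError("CV needs >= 2 non-missing values")
    mean = float(vals.mean())
    if mean == 0:
        raise UndefinedCVError("CV undefined for zero mean")
    return 100.0 * float(vals.std(ddof=1)) / mean


def two_fold_filter(table: pd.DataFrame, params: FilterParams | None = None) -> pd.DataFrame:
    """Keep rows with |fold| beyond the (inclusive) threshold and p < alpha.

    Expects ``fold_change`` and ``p_value`` columns.  Row order is preserved;
    the operation is idempotent.
    """
    params = params or FilterParams()
    keep = selection_mask(
        table["fold_change"].to_numpy(dtype=float),
        table["p_value"].to_numpy(dtype=float),
        params,
    )
    return table.loc[keep].copy()


def selection_mask(fold: np.ndarray, p: np.ndarray, params: FilterParams) -> np.ndarray:
    fold = np.asarray(fold, dtype=float)
    p = np.asarray(p, dtype=float)
    beyond = (fold >= params.fold_threshold) | (fold <= 1.0 / params.fold_threshold)
    return beyond & (p < params.alpha)


def _welch_p_matrix(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Row-wise Welch p-values for two protein x sample blocks with NaNs."""
    res = stats.ttest_ind(case, control, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance rows come back NaN; resolve per the constant-group contract
    bad = np.isnan(p)
    if np.any(bad):
        cm = np.nanmean(case[bad], axis=1)
        km = np.nanmean(control[bad], axis=1)
        p[bad] = np.where(np.isclose(cm, km), 1.0, _P_FLOOR)
    return np.clip(p, _P_FLOOR, 1.0)


def group_differential(
    study: IntensityStudy,
    pg_map: ProteinGeneMap,
    group: str,
    control_group: str | Iterable[str],
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """Gene-level differential table for one group against control(s).

    Per testable protein: fold change (case mean / control mean) and a Welch
    t-test p-value, then collapsed to genes via the protein->gene map (the
    ``collapse`` rule in :class:`FilterParams` resolves multi-spot genes).
    Unmapped and under-observed proteins are excluded with a logged count.

    Returns a DataFrame indexed by gene with columns ``protein_id``,
    ``fold_change``, ``p_value`` and ``selected``.
    """
    params = params or FilterParams()
    case = study.group_matrix(group)
    control = study.group_matrix(control_group)

    unmapped = pg_map.unmapped(study.protein_ids)
    if unmapped:
        logger.info(
            "%s vs %s: excluding %d unmapped protein(s)", group, control_group, len(unmapped)
        )
    mapped = np.array([p in pg_map for p in study.protein_ids])

    n_case = np.sum(~np.isnan(case), axis=1)
    n_control = np.sum(~np.isnan(control), axis=1)
    testable = (n_case >= params.min_obs_per_group) & (n_control >= params.min_obs_per_group)
    n_untestable = int(np.sum(mapped & ~testable))
    if n_untestable:
        logger.info(
            "%s vs %s: excluding %d protein(s) with < %d observations per side",
            group, control_group, n_untestable, params.min_obs_per_group,
        )
    usable = mapped & testable
    if not np.any(usable):
        raise ValueError(f"no testable mapped proteins for {group} vs {control_group}")

    case_u = case[usable]
    control_u = control[usable]
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.nanmean(case_u, axis=1) / np.nanmean(control_u, axis=1)
    if params.log_scale:
        with np.errstate(divide="ignore"):
            p = _welch_p_matrix(np.log(case_u), np.log(control_u))
    else:
        p = _welch_p_matrix(case_u, control_u)

    proteins = [pid for pid, u in zip(study.protein_ids, usable) if u]
    spot = pd.DataFrame(
        {
            "protein_id": proteins,
            "gene": [pg_map[pid] for pid in proteins],
            "fold_change": fold,
            "p_value": p,
        }
    )
    gene_table = _collapse_to_genes(spot, params)
    gene_table["selected"] = selection_mask(
        gene_table["fold_change"].to_numpy(), gene_table["p_value"].to_numpy(), params
    )
    gene_table["group"] = group
    return gene_table


def _collapse_to_genes(spot: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    if params.collapse == "min_p":
        best = spot.loc[spot.groupby("gene")["p_value"].idxmin()]
        out = best.set_index("gene")[["protein_id", "fold_change", "p_value"]]
    else:  # mean fold, min p
        grouped = spot.groupby("gene")
        out = pd.DataFrame(
            {
                "protein_id": grouped["protein_id"].first(),
                "fold_change": grouped["fold_change"].mean(),
                "p_value": grouped["p_value"].min(),
            }
        )
    return out.sort_index()


def write_gene_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the gene-significance TSV: gene, group, fold, p, selected."""
    out = table.reset_index().rename(columns={"index": "gene"})
    cols = ["gene", "group", "fold_change", "p_value", "selected"]
    out = out[[c for c in cols if c in out.columns]].sort_values("gene")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return table.set_index("gene")


def anova_pairwise(
    study: IntensityStudy, params: FilterParams | None = None
) -> pd.DataFrame:
    """One-way ANOVA per protein plus Bonferroni-corrected pairwise Welch tests.

    Pairwise p-values are multiplied by the number of group pairs and capped
    at 1.  Proteins lacking ``min_obs_per_group`` observations in any group
    are skipped with a logged count.
    """
    params = params or FilterParams()
    labels = study.group_labels()
    if len(labels) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    blocks = {g: study.group_matrix(g) for g in labels}

    rows = []
    n_skipped = 0
    for i, pid in enumerate(study.protein_ids):
        samples = {g: _clean(blocks[g][i]) for g in labels}
        if any(v.size < params.min_obs_per_group for v in samples.values()):
            n_skipped += 1
            continue
        if all(v.var(ddof=1) == 0 for v in samples.values()):
            anova_p = 1.0
        else:
            anova_p = float(stats.f_oneway(*samples.values()).pvalue)
            if np.isnan(anova_p):
                anova_p = 1.0
        for a, b in pairs:
            p_raw = independent_t_test(samples[a], samples[b], min_obs=params.min_obs_per_group)
            rows.append(
                {
                    "protein_id": pid,
                    "anova_p": anova_p,
                    "group_a": a,
                    "group_b": b,
                    "p_raw": p_raw,
                    "p_corr": min(1.0, m * p_raw),
                }
            )
    if n_skipped:
        logger.info("ANOVA skipped %d protein(s) with insufficient observations", n_skipped)
    if not rows:
        raise InsufficientObservationsError("no protein has enough observations in every group")
    return pd.DataFrame(rows)
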