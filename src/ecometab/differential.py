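"""Fold-change screening and differential-feature consolidation.

Discriminant groups (typically control vs stress at matching sampling
times) are compared feature by feature on raw group means: fold change
FC = mean(test) / mean(control), with a pseudo-count policy for zero
control means, and a Welch t-test on log abundance supplying the
volcano p-value.  Features passing |FC| >= threshold in a comparison
form a per-comparison differential set; counting how often each feature
recurs across comparisons and keeping those seen at least twice (or
simply deduplicating) yields the consolidated differential list (dMEs).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .feature_io import FeatureMatrix

logger = logging.getLogger(__name__)


def default_pseudocount(fm: FeatureMatrix | pd.DataFrame) -> float:
    """Half the smallest positive abundance in the table."""
    X = fm.abundance if isinstance(fm, FeatureMatrix) else fm
    pos = X.values[X.values > 0]
    if pos.size == 0:
        raise ValueError("no positive abundances in table")
    return float(pos.min() / 2.0)


def fold_change(
    a: pd.DataFrame | np.ndarray,
    b: pd.DataFrame | np.ndarray,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature fold change of group b relative to control group a.

    Means are taken over replicates (rows) on raw, pre-scaling
    abundances.  A zero mean on either side is replaced by the
    pseudo-count; features with both means zero are excluded and logged.
    """
    a = pd.DataFrame(a)
    b = pd.DataFrame(b)
    if list(a.columns) != list(b.columns):
        raise ValueError("mismatched feature sets between groups")
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    both_zero = (mean_a == 0) & (mean_b == 0)
    if both_zero.any():
        logger.info("%d features undetected in both groups excluded", both_zero.sum())
    ma = mean_a[~both_zero].where(mean_a[~both_zero] > 0, pseudocount)
    mb = mean_b[~both_zero].where(mean_b[~both_zero] > 0, pseudocount)
    fc = mb / ma
    return pd.DataFrame(
        {"mean_control": mean_a[~both_zero], "mean_test": mean_b[~both_zero],
         "fc": fc, "log2fc": np.log2(fc)}
    )


@dataclass
class DifferentialSet:
    comparison: tuple[str, str]      # (control label, test label)
    table: pd.DataFrame              # fc, log2fc, p, passes per feature
    fc_threshold: float
    p_threshold: float | None

    @property
    def passing(self) -> list[str]:
        return list(self.table.index[self.table["passes"]])

    @property
    def n_differential(self) -> int:
        return int(self.table["passes"].sum())


def volcano(
    fm: FeatureMatrix,
    control_samples: Sequence[str],
    test_samples: Sequence[str],
    comparison: tuple[str, str] | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float | None = 0.05,
    pseudocount: float | None = None,
) -> DifferentialSet:
    """Fold-change + Welch-t screening of one group comparison.

    A feature passes when FC >= threshold or FC <= 1/threshold and (if p
    filtering is enabled and both groups have >= 2 replicates) the
    log-abundance Welch t-test p-value is below ``p_threshold``.  With
    fewer replicates the p-filter is disabled and logged.
    """
    if pseudocount is None:
        pseudocount = default_pseudocount(fm)
    A = fm.abundance.loc[list(control_samples)]
    B = fm.abundance.loc[list(test_samples)]
    tab = fold_change(A, B, pseudocount=pseudocount)

    use_p = p_threshold is not None and len(A) >= 2 and len(B) >= 2
    if p_threshold is not None and not use_p:
        logger.warning("fewer than 2 replicates per group: FC-only mode")
    if use_p:
        # undetected values are imputed at half the feature's smallest
        # positive abundance (per-variable half-min) before the log
        # transform, so a dropout does not swamp the within-group variance
        sub = pd.concat([A[tab.index], B[tab.index]])
        feat_floor = sub.where(sub > 0).min(axis=0).fillna(pseudocount) / 2.0
        la = np.log(A[tab.index].where(A[tab.index] > 0, feat_floor, axis=1).values)
        lb = np.log(B[tab.index].where(B[tab.index] > 0, feat_floor, axis=1).values)
        import warnings

        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # identical groups trigger scipy's near-constant-input warning;
            # the resulting NaN p is mapped to 1 below
            warnings.simplefilter("ignore", RuntimeWarning)
            _, pvals = stats.ttest_ind(lb, la, equal_var=False)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        tab["p"] = pvals
    else:
        tab["p"] = np.nan

    fc_pass = (tab["fc"] >= fc_threshold) | (tab["fc"] <= 1.0 / fc_threshold)
    tab["passes"] = fc_pass & (tab["p"] <= p_threshold) if use_p else fc_pass
    tab = tab.reindex(tab["log2fc"].abs().sort_values(ascending=False).index)
    if comparison is None:
        comparison = ("control", "test")
    return DifferentialSet(
        comparison=comparison,
        table=tab,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold if use_p else None,
    )


def default_comparisons(
    fm: FeatureMatrix,
    control: str = "C27",
    stress: Sequence[str] = ("C16", "C4"),
    times: Sequence[str] = ("T14", "T21", "T28"),
) -> list[tuple[str, str]]:
    """Control-vs-stress comparisons at matching (late) times.

    Returns (control group label, test group label) pairs such as
    ``("C27_T14", "C16_T14")`` for every stress concentration and time
    present in the metadata.
    """
    groups = fm.group_samples(by=("concentration", "time"))
    pairs = []
    for t in times:
        ctrl = f"{control}_{t}"
        if ctrl not in groups:
            continue
        for c in stress:
            test = f"{c}_{t}"
            if test in groups:
                pairs.append((ctrl, test))
    return pairs


def run_comparisons(
    fm: FeatureMatrix,
    comparisons: Sequence[tuple[str, str]] | None = None,
    fc_threshold: float = 2.0,
    p_threshold: float | None = 0.05,
    pseudocount: float | None = None,
) -> list[DifferentialSet]:
    """Volcano-screen a list of (control group, test group) label pairs."""
    if comparisons is None:
        comparisons = default_comparisons(fm)
    if not comparisons:
        raise ValueError("no comparisons to run")
    groups = fm.group_samples(by=("concentration", "time"))
    out = []
    for ctrl, test in comparisons:
        for lbl in (ctrl, test):
            if lbl not in groups:
                raise KeyError(f"group {lbl!r} not present in metadata")
        out.append(
            volcano(
                fm,
                groups[ctrl],
                groups[test],
                comparison=(ctrl, test),
                fc_threshold=fc_threshold,
                p_threshold=p_threshold,
                pseudocount=pseudocount,
            )
        )
    return out


def comparison_frequency(
    sets: Sequence[DifferentialSet],
) -> tuple[pd.Series, pd.Series]:
    """How often each feature recurs as differential across comparisons.

    Returns (per-feature frequency, histogram frequency -> #features).
    """
    if not sets:
        raise ValueError("need at least one differential set")
    counts = Counter()
    for s in sets:
        counts.update(s.passing)
    freq = pd.Series(counts, dtype=int).sort_values(ascending=False)
    freq.index.name = "feature"
    hist = freq.value_counts().sort_index()
    hist.index.name = "frequency"
    return freq, hist


@dataclass
class DMEList:
    table: pd.DataFrame          # feature, frequency, comparisons, direction
    mode: str
    min_frequency: int

    @property
    def features(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def consolidate_dmes(
    sets: Sequence[DifferentialSet],
    min_frequency: int = 2,
    mode: str = "frequency_filter",
) -> DMEList:
    """Consolidate per-comparison hits into the unique differential list.

    ``frequency_filter`` keeps features recurring in >= ``min_frequency``
    comparisons; ``dedup_all`` keeps every distinct differential feature.
    Both are useful bookkeeping conventions, so the chosen mode is
    recorded on the result.
    """
    if mode not in ("frequency_filter", "dedup_all"):
        raise ValueError(f"unknown mode {mode!r}")
    freq, _ = comparison_frequency(sets)
    hits: dict[str, dict] = {}
    for s in sets:
        name = f"{s.comparison[0]}_vs_{s.comparison[1]}"
        for feat in s.passing:
            rec = hits.setdefault(feat, {"comparisons": [], "n_up": 0, "n_down": 0})
            rec["comparisons"].append(name)
            if s.table.loc[feat, "log2fc"] >= 0:
                rec["n_up"] += 1
            else:
                rec["n_down"] += 1
    rows = []
    for feat, rec in hits.items():
        f = len(rec["comparisons"])
        if mode == "frequency_filter" and f < min_frequency:
            continue
        direction = "up" if rec["n_up"] >= rec["n_down"] else "down"
        if rec["n_up"] and rec["n_down"]:
            direction = "mixed"
        rows.append(
            {
                "feature": feat,
                "frequency": f,
                "comparisons": ";".join(rec["comparisons"]),
                "direction": direction,
            }
        )
    table = pd.DataFrame(rows, columns=["feature", "frequency", "comparisons", "direction"])
    if len(table):
        table = table.sort_values(
            ["frequency", "feature"], ascending=[False, True], kind="stable"
        ).set_index("feature")
    else:
        table = table.set_index("feature")
    return DMEList(table=table, mode=mode, min_frequency=min_frequency)
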