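"""Composition and expression statistics across experimental groups.

Cell-type proportions within a sample are compositional: one type growing
forces the others to shrink, so chi-square / Fisher assumptions fail.
Permutation tests sidestep this.  Two designs are covered:

* ``permutation_test_two``: two groups, cell-level label shuffles.  The
  statistic per cell type is the log2 fold-difference (log2FD) of its
  proportion between groups; the permutation p-value counts shuffles at
  least as extreme as observed, BH-FDR corrected across cell types, with
  a percentile bootstrap confidence interval.  A type is called
  significant when FDR < 0.05 and |log2FD| > 0.58 (about 1.5-fold).
* ``permutation_test_multi``: three or more groups with replicate
  samples; a one-way ANOVA F on per-sample proportions is recomputed
  under permutations of the sample-to-group assignment.

Marker expression within a cell type is compared by a two-way fixed
effects ANOVA (group x marker) on per-sample means with Tukey HSD
post-hoc contrasts between groups within each marker.

Implementation note: shuffling cell-level group labels and counting cells
per type is distributionally identical to drawing per-type counts from a
multivariate hypergeometric distribution, and resampling cells within a
group equals a multinomial draw over its type proportions; both tests use
these exact count-level formulations for speed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .events import EventTable

log = logging.getLogger(__name__)

__all__ = [
    "permutation_test_two",
    "permutation_test_multi",
    "prep_for_stats",
    "run_stats",
]

FDR_CUT_DEFAULT = 0.05
LFC_CUT_DEFAULT = 0.58


def _get_labels(events: EventTable, label_col: str) -> np.ndarray:
    if events.obs is None or label_col not in events.obs.columns:
        raise ValueError(f"events.obs lacks a {label_col!r} column")
    lab = events.obs[label_col].to_numpy()
    if pd.isna(lab).any():
        raise ValueError("every cell must carry a final label")
    return lab


def _group_of_cells(events: EventTable, group_var: str) -> np.ndarray:
    """Per-cell group value looked up from sample_meta via sample_id."""
    if group_var not in events.sample_meta.columns:
        raise ValueError(f"sample_meta lacks column {group_var!r}")
    lut = events.sample_meta[group_var]
    return lut.loc[events.sample_id].to_numpy()


def permutation_test_two(
    events: EventTable,
    group_var: str,
    groups: tuple,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    label_col: str = "final_label",
    fdr_cut: float = FDR_CUT_DEFAULT,
    lfc_cut: float = LFC_CUT_DEFAULT,
) -> pd.DataFrame:
    """Two-group composition test with log2FD, permutation p and bootstrap CI.

    For each cell type ``t``: ``log2FD_t = log2(p_t,g1 / p_t,g2)`` on
    within-group proportions, using the pseudo-proportion ``0.5 / N_g``
    when a type is empty in a group (flagged in the output).  ``n_perm``
    cell-level shuffles of the group assignment give
    ``p = (1 + #{|perm| >= |obs|}) / (n_perm + 1)``, BH-adjusted across
    types; ``n_boot`` within-group resamples give the percentile CI.
    """
    lab = _get_labels(events, label_col)
    grp = _group_of_cells(events, group_var)
    g1, g2 = groups
    # canonical internal order makes the test exactly antisymmetric:
    # swapping the caller's group order negates log2FD and preserves p
    flip = str(g1) > str(g2)
    if flip:
        g1, g2 = g2, g1
    in1, in2 = grp == g1, grp == g2
    if not in1.any() or not in2.any():
        raise ValueError(f"both groups must be present; got counts "
                         f"{int(in1.sum())} and {int(in2.sum())}")
    used = in1 | in2
    lab, in1 = lab[used], in1[used]
    types, t_idx = np.unique(lab, return_inverse=True)
    n1, n2 = int(in1.sum()), int((~in1).sum())
    c1 = np.bincount(t_idx[in1], minlength=len(types)).astype(float)
    c2 = np.bincount(t_idx[~in1], minlength=len(types)).astype(float)
    absent = (c1 + c2) == 0
    if absent.any():
        warnings.warn(
            "cell types absent from both groups dropped: "
            + ", ".join(types[absent])
        )
        types, c1, c2 = types[~absent], c1[~absent], c2[~absent]

    rng = np.random.default_rng(seed)

    def log2fd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        p1 = np.where(a > 0, a / n1, 0.5 / n1)
        p2 = np.where(b > 0, b / n2, 0.5 / n2)
        return np.log2(p1 / p2)

    obs = log2fd(c1, c2)
    total = (c1 + c2).astype(int)
    # cell-level shuffle == multivariate hypergeometric counts in group 1
    perm_c1 = rng.multivariate_hypergeometric(total, n1, size=n_perm).astype(float)
    perm_fd = log2fd(perm_c1, total - perm_c1)
    p = (1.0 + (np.abs(perm_fd) >= np.abs(obs)).sum(axis=0)) / (n_perm + 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]

    # percentile bootstrap: within-group multinomial resamples
    b1 = rng.multinomial(n1, c1 / n1, size=n_boot).astype(float)
    b2 = rng.multinomial(n2, c2 / n2, size=n_boot).astype(float)
    boot = log2fd(b1, b2)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)

    if flip:
        obs = -obs
        c1, c2 = c2, c1
        n1, n2 = n2, n1
        lo, hi = -hi, -lo
    out = pd.DataFrame(
        {
            "cell_type": types,
            "n_group1": c1.astype(int),
            "n_group2": c2.astype(int),
            "log2fd": obs,
            "p": p,
            "fdr": fdr,
            "ci_lo": lo,
            "ci_hi": hi,
            "pseudo_count": (c1 == 0) | (c2 == 0),
        }
    )
    out["significant"] = (out["fdr"] < fdr_cut) & (out["log2fd"].abs() > lfc_cut)
    return out


def permutation_test_multi(
    events: EventTable,
    group_var: str,
    sample_var: str = "sample_id",
    n_perm: int = 1000,
    seed: int = 0,
    label_col: str = "final_label",
) -> pd.DataFrame:
    """ANOVA-permutation composition test across three or more groups.

    Per cell type, the one-way ANOVA F statistic over per-sample
    proportions is compared with its distribution under ``n_perm`` random
    permutations of the sample-to-group assignment.  Cell types whose
    per-sample proportions are constant carry no information and are
    skipped.
    """
    lab = _get_labels(events, label_col)
    if sample_var == "sample_id":
        samples = events.sample_id
    else:
        samples = _group_of_cells(events, sample_var)
    sample_ids = pd.unique(samples)
    grp_per_sample = (
        events.sample_meta[group_var].loc[sample_ids].to_numpy()
        if sample_var == "sample_id"
        else pd.Series(
            _group_of_cells(events, group_var), index=samples
        ).groupby(level=0).first().loc[sample_ids].to_numpy()
    )
    glevels, gidx = np.unique(grp_per_sample, return_inverse=True)
    if len(glevels) < 3:
        raise ValueError("need >= 3 groups; use permutation_test_two for 2")
    counts_per_group = np.bincount(gidx)
    if (counts_per_group < 2).any():
        bad = glevels[counts_per_group < 2]
        raise ValueError(
            "groups with a single sample have no within-group variance: "
            + ", ".join(map(str, bad))
        )

    # per-sample proportion matrix (samples x types)
    ct = pd.crosstab(pd.Series(samples), pd.Series(lab)).reindex(sample_ids)
    prop = ct.div(ct.sum(axis=1), axis=0)
    P = prop.to_numpy()
    types = list(prop.columns)

    def f_stats(assign: np.ndarray) -> np.ndarray:
        """Vectorized one-way F per column of P for a group assignment."""
        k = len(glevels)
        n = len(assign)
        grand = P.mean(axis=0)
        ss_b = np.zeros(P.shape[1])
        ss_w = np.zeros(P.shape[1])
        for g in range(k):
            sub = P[assign == g]
            m = sub.mean(axis=0)
            ss_b += len(sub) * (m - grand) ** 2
            ss_w += ((sub - m) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ss_b / (k - 1)) / (ss_w / (n - k))

    obs_f = f_stats(gidx)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(P.shape[1])
    for _ in range(n_perm):
        exceed += f_stats(rng.permutation(gidx)) >= obs_f
    p = (1.0 + exceed) / (n_perm + 1.0)

    out = pd.DataFrame({"cell_type": types, "F": obs_f, "p": p})
    degenerate = ~np.isfinite(obs_f) | (np.nanvar(P, axis=0) == 0)
    if degenerate.any():
        warnings.warn(
            "cell types with constant per-sample proportions skipped: "
            + ", ".join(np.asarray(types)[degenerate])
        )
        out.loc[degenerate, ["F", "p"]] = np.nan
    return out


# ----------------------------------------------------------------------
# marker-expression ANOVA
# ----------------------------------------------------------------------

def prep_for_stats(
    events: EventTable,
    markers: Sequence[str] | None = None,
    group_var: str = "group",
    label_col: str = "final_label",
    replicate_unit: str = "sample",
) -> pd.DataFrame:
    """Long-format expression table for :func:`run_stats`.

    With ``replicate_unit='sample'`` (recommended) expression is averaged
    to one value per sample x marker x cell type; ``'cell'`` keeps every
    cell as a row, which inflates power to the point where everything is
    significant -- a warning says so.
    """
    if replicate_unit not in ("sample", "cell"):
        raise ValueError("replicate_unit must be 'sample' or 'cell'")
    if replicate_unit == "cell":
        warnings.warn(
            "using cells as replicates will not be revealing in most cases: "
            "with tens of thousands of pseudo-replicates every contrast "
            "becomes significant"
        )
    markers = list(markers) if markers is not None else list(events.markers)
    lab = _get_labels(events, label_col)
    grp = _group_of_cells(events, group_var)
    long = events.to_frame()[["sample_id"] + markers]
    long["cell_type"] = lab
    long["group"] = grp
    long = long.melt(
        id_vars=["sample_id", "cell_type", "group"],
        value_vars=markers,
        var_name="marker",
        value_name="expression",
    )
    if replicate_unit == "cell":
        return long
    agg = (
        long.groupby(["cell_type", "group", "sample_id", "marker"], observed=True)[
            "expression"
        ]
        .mean()
        .reset_index()
    )
    return agg


def _tukey_within_marker(
    sub: pd.DataFrame, mse: float, df_resid: float
) -> pd.DataFrame:
    """Tukey HSD contrasts between groups within one marker.

    Uses the studentized-range distribution with the two-way ANOVA's
    residual mean square, not a per-subset error estimate.
    """
    means = sub.groupby("group", observed=True)["expression"].agg(["mean", "count"])
    groups = list(means.index)
    k = len(groups)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            na, nb = means.loc[a, "count"], means.loc[b, "count"]
            diff = means.loc[a, "mean"] - means.loc[b, "mean"]
            se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
            q = abs(diff) / se if se > 0 else np.inf
            p_adj = sps.studentized_range.sf(q, k, df_resid)
            rows.append(
                dict(group_a=a, group_b=b, diff=diff, q=q, p_adj=float(np.clip(p_adj, 0, 1)))
            )
    return pd.DataFrame(rows)


@dataclass
class ExpressionStats:
    """Two-way ANOVA tables and Tukey contrasts, one entry per cell type."""

    anova: dict[str, pd.DataFrame]
    tukey: dict[str, pd.DataFrame]

    def significant_anova(self, alpha: float = 0.05) -> pd.DataFrame:
        rows = []
        for ct, tab in self.anova.items():
            for effect in tab.index:
                if effect == "Residual":
                    continue
                rows.append(
                    dict(
                        cell_type=ct,
                        effect=effect,
                        F=tab.loc[effect, "F"],
                        p=tab.loc[effect, "PR(>F)"],
                        significant=tab.loc[effect, "PR(>F)"] < alpha,
                    )
                )
        return pd.DataFrame(rows)


def run_stats(long: pd.DataFrame, alpha: float = 0.05) -> ExpressionStats:
    """Two-way fixed-effects ANOVA (group x marker) per cell type + Tukey.

    Empty cell-type x group x marker combinations are dropped (logged);
    Tukey HSD compares group pairs within each marker using the model's
    residual mean square.
    """
    required = {"cell_type", "group", "marker", "expression"}
    if not required <= set(long.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    anova_tables: dict[str, pd.DataFrame] = {}
    tukey_tables: dict[str, pd.DataFrame] = {}
    for ct, sub in long.groupby("cell_type", observed=True):
        counts = sub.groupby(["group", "marker"], observed=True).size()
        if (counts == 0).any():  # pandas drops empties; kept for clarity
            log.info("dropping empty combinations in cell type %s", ct)
        if sub["group"].nunique() < 2 or sub["marker"].nunique() < 1:
            log.info("cell type %s lacks contrastable groups; skipped", ct)
            continue
        if sub["marker"].nunique() > 1:
            model = ols("expression ~ C(group) * C(marker)", data=sub).fit()
        else:
            model = ols("expression ~ C(group)", data=sub).fit()
        try:
            tab = anova_lm(model, typ=2)
        except Exception as exc:
            log.warning("ANOVA failed for cell type %s: %s", ct, exc)
            continue
        anova_tables[ct] = tab
        mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
        df_resid = tab.loc["Residual", "df"]
        pieces = []
        for marker, msub in sub.groupby("marker", observed=True):
            if msub["group"].nunique() < 2:
                continue
            t = _tukey_within_marker(msub, mse, df_resid)
            t.insert(0, "marker", marker)
            pieces.append(t)
        tukey_tables[ct] = (
            pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame()
        )
    return ExpressionStats(anova=anova_tables, tukey=tukey_tables)
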