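"""Relative quantification of array-card qPCR data (ddCT approach).

Each sample/card combination is normalized against its own global median:
dCT[m, s] = Ct[m, s] - median over non-control microRNAs of card(m) in
sample s. Lower Ct means more transcript, so a negative ddCT
(experimental minus reference group mean) corresponds to up-regulation and
log2 fold change = -ddCT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import ValidationError
from .io import CtMatrix
from .stats import kruskal_wallis

__all__ = [
    "DeltaCtMatrix",
    "card_median_normalizer",
    "compute_delta_ct",
    "differential_expression",
    "kruskal_group_screen",
    "DIFFEXP_COLUMNS",
]

DIFFEXP_COLUMNS = [
    "mir_id",
    "n_exp",
    "n_ref",
    "mean_dct_exp",
    "mean_dct_ref",
    "ddct",
    "log2fc",
    "linear_fc",
    "t_stat",
    "df",
    "p_value",
    "testable",
]


@dataclass
class DeltaCtMatrix:
    """Median-normalized dCT values with the same axes as the CtMatrix.

    Control wells receive dCT too but stay flagged and are excluded from
    every downstream statistic.
    """

    dct: pd.DataFrame
    card: pd.Series
    is_control: pd.Series

    @property
    def mir_ids(self) -> list:
        return list(self.dct.index)

    @property
    def sample_ids(self) -> list:
        return list(self.dct.columns)

    def noncontrol(self) -> pd.DataFrame:
        return self.dct.loc[~self.is_control.to_numpy(bool)]


def card_median_normalizer(
    ctm: CtMatrix, sample, card, include_controls: bool = False
) -> float:
    """Median Ct of the (by default non-control) microRNAs of one card in
    one sample; NaN (UNDEFINED) when no value is available. An even count
    of values yields the mean of the central pair."""
    if sample not in ctm.ct.columns:
        raise ValidationError(f"unknown sample {sample!r}")
    on_card = ctm.card == card
    if not on_card.any():
        raise ValidationError(f"unknown card {card!r}")
    if not include_controls:
        on_card &= ~ctm.is_control.astype(bool)
    vals = ctm.ct.loc[on_card, sample]
    return float(vals.median(skipna=True)) if vals.notna().any() else float("nan")


def compute_delta_ct(ctm: CtMatrix, include_controls_in_normalizer: bool = False) -> DeltaCtMatrix:
    """Per-card global median normalization of every sample.

    dCT is MISSING exactly where Ct is MISSING or the card normalizer is
    undefined for that sample.
    """
    dct = pd.DataFrame(
        np.nan, index=ctm.ct.index, columns=ctm.ct.columns, dtype=float
    )
    control = ctm.is_control.to_numpy(bool)
    for card in pd.unique(ctm.card):
        rows = (ctm.card == card).to_numpy(bool)
        norm_rows = rows if include_controls_in_normalizer else (rows & ~control)
        normalizer = ctm.ct.loc[norm_rows].median(axis=0, skipna=True)
        dct.loc[rows] = ctm.ct.loc[rows].sub(normalizer, axis=1)
    return DeltaCtMatrix(dct=dct, card=ctm.card.copy(), is_control=ctm.is_control.copy())


def differential_expression(
    dctm: DeltaCtMatrix,
    meta: pd.DataFrame,
    exp_group: str = "experimental",
    ref_group: str = "sham",
    flavor: str = "student",
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-microRNA ddCT statistics and a two-sided two-sample t-test on
    the dCT values of the two groups.

    Vectorized over microRNAs; assays with fewer than ``min_per_group``
    non-missing values in either group (or zero variance in both groups
    preventing a finite statistic) are flagged testable=False with NaN
    statistics kept where defined. Control wells are excluded.
    """
    for g in (exp_group, ref_group):
        if g not in set(meta["group"]):
            raise ValidationError(f"group {g!r} absent from metadata")
    dct = dctm.noncontrol()
    exp_cols = [s for s in dct.columns if meta.at[s, "group"] == exp_group]
    ref_cols = [s for s in dct.columns if meta.at[s, "group"] == ref_group]
    xe = dct[exp_cols].to_numpy(float)
    xr = dct[ref_cols].to_numpy(float)

    ne = np.sum(~np.isnan(xe), axis=1)
    nr = np.sum(~np.isnan(xr), axis=1)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        me = np.nanmean(xe, axis=1)
        mr = np.nanmean(xr, axis=1)
        ve = np.nanvar(xe, axis=1, ddof=1)
        vr = np.nanvar(xr, axis=1, ddof=1)
    testable = (ne >= max(min_per_group, 2)) & (nr >= max(min_per_group, 2))

    ddct = me - mr
    log2fc = -ddct
    with np.errstate(all="ignore"):
        if flavor == "student":
            df = (ne + nr - 2).astype(float)
            sp2 = ((ne - 1) * ve + (nr - 1) * vr) / df
            se = np.sqrt(sp2 * (1.0 / ne + 1.0 / nr))
        elif flavor == "welch":
            se = np.sqrt(ve / ne + vr / nr)
            df = (ve / ne + vr / nr) ** 2 / (
                (ve / ne) ** 2 / (ne - 1) + (vr / nr) ** 2 / (nr - 1)
            )
        else:
            raise ValidationError(f"unknown t-test flavor {flavor!r}")
        t = ddct / se
        p = 2.0 * sps.t.sf(np.abs(t), df)

    # degenerate variance conventions (match stats.two_sample_t_test)
    both_const = testable & (ve == 0.0) & (vr == 0.0)
    eq = both_const & (ddct == 0.0)
    t[eq], p[eq] = 0.0, 1.0
    neq = both_const & (ddct != 0.0)
    t[neq] = np.sign(ddct[neq]) * np.inf
    p[neq] = 0.0

    out = pd.DataFrame(
        {
            "mir_id": dct.index,
            "n_exp": ne,
            "n_ref": nr,
            "mean_dct_exp": me,
            "mean_dct_ref": mr,
            "ddct": ddct,
            "log2fc": log2fc,
            "linear_fc": np.exp2(log2fc),
            "t_stat": np.where(testable, t, np.nan),
            "df": np.where(testable, df, np.nan),
            "p_value": np.where(testable, p, np.nan),
            "testable": testable,
        }
    )[DIFFEXP_COLUMNS]
    return out.set_index("mir_id")


def kruskal_group_screen(
    dctm: DeltaCtMatrix,
    meta: pd.DataFrame,
    groups=("naive", "sham", "experimental"),
) -> pd.DataFrame:
    """Kruskal-Wallis H and p per microRNA across the given groups;
    fewer than two groups with data marks the assay NOT_TESTABLE."""
    dct = dctm.noncontrol()
    cols = {g: [s for s in dct.columns if meta.at[s, "group"] == g] for g in groups}
    rows = []
    for mir, vals in dct.iterrows():
        gs = [vals[c].dropna().to_numpy() for c in cols.values()]
        gs = [g for g in gs if len(g)]
        if len(gs) < 2 or sum(len(g) for g in gs) < 3:
            rows.append((mir, np.nan, np.nan, False))
            continue
        res = kruskal_wallis(gs)
        rows.append((mir, res.statistic, res.p_value, True))
    return pd.DataFrame(
        rows, columns=["mir_id", "H", "p_value", "testable"]
    ).set_index("mir_id")
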