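"""Five-stage candidate filter cascade with full per-microRNA provenance.

Stages, in fixed order:

1. NOT_EXPRESSED  — no detectable expression in any sample.
2. MISSINGNESS    — too few valid values per group for a t-test.
3. T_TEST         — two-sided two-sample t-test on dCT not significant.
4. FOLD_CHANGE    — log2 fold change strictly inside the (-band, +band)
                    no-effect band.
5. CONFOUND_CORR  — dCT of experimental animals rank-correlates with
                    seizure burden (count or duration): the assay may only
                    reflect intrinsic epilepsy severity and is excluded.
6. MIN_CT         — expression too weak (minimum raw Ct above the ceiling).

Every non-control microRNA ends in exactly one bin (a stage or RETAINED);
statistics are recorded for the stages an assay actually reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import CtMatrix
from .normalization import DeltaCtMatrix, differential_expression
from .stats import spearman

__all__ = [
    "CascadeConfig",
    "FilterTrace",
    "STAGES",
    "filter_not_expressed",
    "filter_missingness",
    "filter_differential",
    "filter_effect_size",
    "filter_seizure_correlation",
    "filter_min_ct",
    "run_cascade",
    "screening_hits",
]

log = logging.getLogger(__name__)

STAGES = (
    "NOT_EXPRESSED",
    "MISSINGNESS",
    "T_TEST",
    "FOLD_CHANGE",
    "CONFOUND_CORR",
    "MIN_CT",
)


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds of the filter cascade; defaults follow the screening
    protocol (alpha 0.05, log2 fold-change no-effect band of half-width 1,
    seizure-correlation exclusion at r > 0.5 with p < alpha, Ct ceiling 30).
    """

    alpha: float = 0.05
    lfc_band: float = 1.0
    confound_r_threshold: float = 0.5
    confound_mode: str = "positive_only"  # or "absolute"
    ct_ceiling: float = 30.0
    ct_ceiling_mode: str = "min_over_samples"  # or "all_samples"
    min_per_group: int = 2
    presence_rule: str = "any_valid_ct"  # or "median_below_lod"
    lod: float = 40.0
    t_flavor: str = "student"
    t_on: str = "dct"  # or "raw_ct"
    spearman_p_method: str = "auto"
    exp_group: str = "experimental"
    ref_group: str = "sham"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.lfc_band < 0:
            raise ValidationError("lfc_band must be >= 0")
        if self.confound_r_threshold <= 0 or self.ct_ceiling <= 0 or self.lod <= 0:
            raise ValidationError("thresholds must be positive")
        for fld, allowed in (
            ("confound_mode", ("positive_only", "absolute")),
            ("ct_ceiling_mode", ("min_over_samples", "all_samples")),
            ("presence_rule", ("any_valid_ct", "median_below_lod")),
            ("t_on", ("dct", "raw_ct")),
        ):
            if getattr(self, fld) not in allowed:
                raise ValidationError(f"{fld} must be one of {allowed}")


@dataclass
class FilterTrace:
    """Per-microRNA cascade provenance.

    ``table`` is indexed by microRNA id with a ``removed_at`` bin and the
    statistics computed at the stages the assay reached; ``stage_counts``
    maps each stage, in order, to the number removed there.
    """

    table: pd.DataFrame
    stage_counts: dict
    retained: list = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.table)

    def check_conservation(self) -> bool:
        return sum(self.stage_counts.values()) + len(self.retained) == self.n_input


def _ct_ceiling_fails(ct_row: pd.Series, mode: str, ceiling: float) -> bool:
    """True when a microRNA fails the Ct-ceiling condition."""
    vals = ct_row.dropna()
    if mode == "min_over_samples":
        return vals.empty or float(vals.min()) > ceiling
    # all_samples: every sample must have a valid Ct <= ceiling
    return ct_row.isna().any() or bool((vals > ceiling).any())


def filter_not_expressed(ctm: CtMatrix, cfg: CascadeConfig, subset=None) -> set:
    """Stage 1: assays without detectable expression in any sample."""
    ct = ctm.ct.loc[list(subset)] if subset is not None else ctm.ct.loc[ctm.noncontrol_ids()]
    if cfg.presence_rule == "any_valid_ct":
        detected = (ct < cfg.lod).any(axis=1)
    else:  # median_below_lod: missing wells count as at-LOD
        med = ct.fillna(cfg.lod).median(axis=1)
        detected = med < cfg.lod
    return set(ct.index[~detected])


def filter_missingness(
    ctm: CtMatrix, meta: pd.DataFrame, cfg: CascadeConfig, subset=None
) -> set:
    """Stage 2: fewer than min_per_group valid Ct values in the
    experimental or the reference group."""
    ct = ctm.ct.loc[list(subset)] if subset is not None else ctm.ct.loc[ctm.noncontrol_ids()]
    removed = set()
    for grp in (cfg.exp_group, cfg.ref_group):
        cols = [s for s in ct.columns if meta.at[s, "group"] == grp]
        n_ok = ct[cols].notna().sum(axis=1)
        removed |= set(ct.index[n_ok < cfg.min_per_group])
    return removed


def filter_differential(
    dctm_or_ct, meta: pd.DataFrame, cfg: CascadeConfig, subset=None
) -> tuple[set, pd.DataFrame]:
    """Stage 3: t-test on dCT (or raw Ct under cfg.t_on='raw_ct');
    removed iff p >= alpha (strict-pass)."""
    diff = differential_expression(
        dctm_or_ct,
        meta,
        exp_group=cfg.exp_group,
        ref_group=cfg.ref_group,
        flavor=cfg.t_flavor,
        min_per_group=cfg.min_per_group,
    )
    if subset is not None:
        diff = diff.loc[[m for m in subset if m in diff.index]]
    removed = set(diff.index[~diff["testable"] | ~(diff["p_value"] < cfg.alpha)])
    return removed, diff


def filter_effect_size(diff: pd.DataFrame, cfg: CascadeConfig, subset=None) -> set:
    """Stage 4: log2 fold change strictly inside (-band, band) indicates no
    relevant change; boundary values are retained."""
    d = diff.loc[list(subset)] if subset is not None else diff
    inside = d["log2fc"].abs() < cfg.lfc_band
    return set(d.index[inside])


def filter_seizure_correlation(
    dctm: DeltaCtMatrix,
    burden: pd.DataFrame,
    meta: pd.DataFrame,
    cfg: CascadeConfig,
    subset=None,
) -> tuple[set, pd.DataFrame]:
    """Stage 5: exclude assays whose experimental-group dCT rank-correlates
    with seizure count or duration (r above threshold with p < alpha).

    positive_only mode (default) tests the signed r; absolute mode |r|.
    Assays with fewer than 3 complete pairs skip the stage with a warning.
    """
    if burden is None or burden.empty:
        raise ConfigurationError("seizure burden unavailable: stage 5 cannot run")
    exp_samples = [
        s
        for s in dctm.sample_ids
        if meta.at[s, "group"] == cfg.exp_group and s in burden.index
    ]
    mirs = list(subset) if subset is not None else list(dctm.noncontrol().index)
    count = burden.loc[exp_samples, "seizure_count"].to_numpy(float)
    dur = burden.loc[exp_samples, "seizure_duration"].to_numpy(float)
    removed = set()
    rows = []
    for mir in mirs:
        x = dctm.dct.loc[mir, exp_samples].to_numpy(float)
        stats = {}
        hit = False
        for name, cov in (("seizfreq", count), ("seizdur", dur)):
            rec = spearman(x, cov, p_method=cfg.spearman_p_method)
            stats[f"r_{name}"], stats[f"p_{name}"] = rec.r, rec.p_value
            if rec.n_pairs < 3:
                log.warning("stage 5 skipped for %s (%d pairs)", mir, rec.n_pairs)
                continue
            if np.isnan(rec.r):
                continue
            r_eff = abs(rec.r) if cfg.confound_mode == "absolute" else rec.r
            if r_eff > cfg.confound_r_threshold and rec.p_value < cfg.alpha:
                hit = True
        if hit:
            removed.add(mir)
        rows.append({"mir_id": mir, **stats})
    table = pd.DataFrame(rows).set_index("mir_id") if rows else pd.DataFrame(
        columns=["r_seizfreq", "p_seizfreq", "r_seizdur", "p_seizdur"]
    )
    return removed, table


def filter_min_ct(ctm: CtMatrix, cfg: CascadeConfig, subset=None) -> set:
    """Stage 6: weakly expressed assays (raw Ct above the ceiling)."""
    ct = ctm.ct.loc[list(subset)] if subset is not None else ctm.ct.loc[ctm.noncontrol_ids()]
    return {
        m for m in ct.index if _ct_ceiling_fails(ct.loc[m], cfg.ct_ceiling_mode, cfg.ct_ceiling)
    }


def run_cascade(
    ctm: CtMatrix,
    dctm: DeltaCtMatrix,
    meta: pd.DataFrame,
    burden: pd.DataFrame,
    cfg: CascadeConfig | None = None,
) -> FilterTrace:
    """Apply the five-stage cascade in fixed order and return the trace.

    Retained candidates are ordered by ascending t-test p-value. Statistics
    for a stage are only recorded for assays that reached it.
    """
    cfg = cfg or CascadeConfig()
    mirs = ctm.noncontrol_ids()
    table = pd.DataFrame(
        {
            "removed_at": pd.Series("RETAINED", index=mirs, dtype=object),
            "p_ttest": np.nan,
            "log2fc": np.nan,
            "r_seizfreq": np.nan,
            "p_seizfreq": np.nan,
            "r_seizdur": np.nan,
            "p_seizdur": np.nan,
            "min_ct": np.nan,
        }
    )
    table.index.name = "mir_id"
    stage_counts: dict[str, int] = {}
    alive: list = list(mirs)

    def mark(removed: set, stage: str):
        nonlocal alive
        removed = removed & set(alive)
        table.loc[sorted(removed), "removed_at"] = stage
        stage_counts[stage] = len(removed)
        alive = [m for m in alive if m not in removed]
        log.info("stage %-13s removed %4d, remaining %4d", stage, len(removed), len(alive))

    mark(filter_not_expressed(ctm, cfg, subset=alive), "NOT_EXPRESSED")
    mark(filter_missingness(ctm, meta, cfg, subset=alive), "MISSINGNESS")

    source = dctm if cfg.t_on == "dct" else _raw_as_delta(ctm)
    removed3, diff = filter_differential(source, meta, cfg, subset=alive)
    table.loc[diff.index, "p_ttest"] = diff["p_value"]
    table.loc[diff.index, "log2fc"] = diff["log2fc"]
    mark(removed3, "T_TEST")

    mark(filter_effect_size(diff, cfg, subset=alive), "FOLD_CHANGE")

    removed5, corr = filter_seizure_correlation(dctm, burden, meta, cfg, subset=alive)
    for col in ("r_seizfreq", "p_seizfreq", "r_seizdur", "p_seizdur"):
        if col in corr.columns:
            table.loc[corr.index, col] = corr[col]
    mark(removed5, "CONFOUND_CORR")

    min_ct = ctm.ct.loc[alive].min(axis=1, skipna=True)
    table.loc[alive, "min_ct"] = min_ct
    mark(filter_min_ct(ctm, cfg, subset=alive), "MIN_CT")

    retained = sorted(alive, key=lambda m: (table.at[m, "p_ttest"], m))
    trace = FilterTrace(table=table, stage_counts=stage_counts, retained=retained)
    assert trace.check_conservation()
    return trace


def _raw_as_delta(ctm: CtMatrix) -> DeltaCtMatrix:
    """Wrap raw Ct so the differential test can run un-normalized."""
    return DeltaCtMatrix(dct=ctm.ct.copy(), card=ctm.card, is_control=ctm.is_control)


def screening_hits(diff: pd.DataFrame, ctm: CtMatrix, cfg: CascadeConfig | None = None) -> set:
    """Headline screening rule, reported separately from the cascade:
    significantly regulated assays (p < alpha) meeting the Ct-ceiling
    condition under cfg.ct_ceiling_mode."""
    cfg = cfg or CascadeConfig()
    hits = set()
    for mir, row in diff.iterrows():
        if not row["testable"] or not (row["p_value"] < cfg.alpha):
            continue
        if _ct_ceiling_fails(ctm.ct.loc[mir], cfg.ct_ceiling_mode, cfg.ct_ceiling):
            continue
        hits.add(mir)
    return hits
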