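"""Candidate x phenotype association analysis: Spearman correlation
matrix with the screening significance rule (|r| > 0.5 and p < 0.05),
per-candidate BH-FDR screens, pooled and per-model differential tests,
and PCA of behavior or expression profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, ValidationError
from .normalization import DeltaCtMatrix, differential_expression
from .stats import benjamini_hochberg, spearman

__all__ = [
    "CORRELATION_COLUMNS",
    "PcaResult",
    "correlation_matrix",
    "flag_significant",
    "cross_model_mir_screen",
    "pooled_group_test",
    "per_model_tests",
    "run_pca",
]

log = logging.getLogger(__name__)

CORRELATION_COLUMNS = ["x_name", "y_name", "n_pairs", "r", "p", "q", "flagged"]


def _assemble_parameters(
    phenotypes: pd.DataFrame | None,
    burden: pd.DataFrame | None,
    samples,
) -> pd.DataFrame:
    """Phenotype parameters plus seizure-burden covariates as one wide
    samples x parameters frame (burden defined only for experimental
    samples; others stay MISSING and drop out pairwise)."""
    parts = []
    if phenotypes is not None:
        parts.append(phenotypes.reindex(samples))
    if burden is not None and not burden.empty:
        parts.append(
            burden.rename(
                columns={"seizure_count": "Seizures_n", "seizure_duration": "Seizures_duration"}
            ).reindex(samples)
        )
    if not parts:
        raise ValidationError("no phenotype parameters supplied")
    return pd.concat(parts, axis=1)


def correlation_matrix(
    dctm: DeltaCtMatrix,
    phenotypes: pd.DataFrame,
    burden: pd.DataFrame | None = None,
    candidates=None,
    samples=None,
    p_method: str = "auto",
) -> pd.DataFrame:
    """Spearman r and p for every (candidate microRNA, parameter) pair with
    pairwise-complete deletion; pairs with fewer than 3 complete pairs get
    NaN r/p (UNDEFINED) and a warning."""
    samples = list(samples) if samples is not None else list(dctm.sample_ids)
    mirs = list(candidates) if candidates is not None else list(dctm.noncontrol().index)
    params = _assemble_parameters(phenotypes, burden, samples)
    rows = []
    for mir in mirs:
        x = dctm.dct.loc[mir, samples].to_numpy(float)
        for par in params.columns:
            rec = spearman(
                x, params[par].to_numpy(float), p_method=p_method, x_name=mir, y_name=par
            )
            if rec.n_pairs < 3:
                log.warning("UNDEFINED correlation (%s, %s): %d pairs", mir, par, rec.n_pairs)
            rows.append((mir, par, rec.n_pairs, rec.r, rec.p_value, np.nan, False))
    return pd.DataFrame(rows, columns=CORRELATION_COLUMNS)


def flag_significant(
    table: pd.DataFrame,
    r_threshold: float = 0.5,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Apply the significance rule: (r < -r_threshold or r > r_threshold)
    and (q < alpha when fdr else p < alpha). Returns a copy with the
    ``flagged`` column set (and q filled when fdr)."""
    out = table.copy()
    if fdr:
        out["q"] = benjamini_hochberg(out["p"].to_numpy(float))
    pcol = out["q"] if fdr else out["p"]
    r = out["r"]
    out["flagged"] = ((r < -r_threshold) | (r > r_threshold)) & (pcol < alpha)
    out["flagged"] = out["flagged"].fillna(False).astype(bool)
    return out


def cross_model_mir_screen(
    dctm: DeltaCtMatrix,
    mir_id: str,
    phenotypes: pd.DataFrame,
    burden: pd.DataFrame | None = None,
    samples=None,
    p_method: str = "auto",
    r_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One candidate against all phenotype parameters across pooled
    samples, with BH q-values over that candidate's parameter family."""
    if mir_id not in dctm.dct.index:
        raise ValidationError(f"unknown candidate {mir_id!r}")
    table = correlation_matrix(
        dctm, phenotypes, burden, candidates=[mir_id], samples=samples, p_method=p_method
    )
    return flag_significant(table, r_threshold=r_threshold, alpha=alpha, fdr=True)


def pooled_group_test(
    dctm: DeltaCtMatrix,
    meta: pd.DataFrame,
    mir_id: str,
    exp_group: str = "experimental",
    ref_group: str = "sham",
    flavor: str = "student",
) -> pd.Series:
    """Two-tailed unpaired t-test on one candidate's dCT, all models pooled."""
    diff = differential_expression(
        _subset(dctm, mir_id), meta, exp_group=exp_group, ref_group=ref_group, flavor=flavor
    )
    return diff.loc[mir_id]


def per_model_tests(
    dctm: DeltaCtMatrix,
    meta: pd.DataFrame,
    mir_id: str,
    exp_group: str = "experimental",
    ref_group: str = "sham",
    flavor: str = "student",
) -> pd.DataFrame:
    """The pooled test stratified by model: one record per model present."""
    rows = {}
    for model in pd.unique(meta["model"]):
        cols = [s for s in dctm.sample_ids if meta.at[s, "model"] == model]
        sub = DeltaCtMatrix(
            dct=dctm.dct.loc[[mir_id], cols],
            card=dctm.card.loc[[mir_id]],
            is_control=dctm.is_control.loc[[mir_id]],
        )
        groups_here = {meta.at[s, "group"] for s in cols}
        if not {exp_group, ref_group} <= groups_here:
            log.warning("model %s lacks both groups; skipped", model)
            continue
        rows[model] = differential_expression(
            sub, meta.loc[cols], exp_group=exp_group, ref_group=ref_group, flavor=flavor
        ).loc[mir_id]
    out = pd.DataFrame(rows).T
    out.index.name = "model"
    return out


def _subset(dctm: DeltaCtMatrix, mir_id: str) -> DeltaCtMatrix:
    if mir_id not in dctm.dct.index:
        raise ValidationError(f"unknown candidate {mir_id!r}")
    return DeltaCtMatrix(
        dct=dctm.dct.loc[[mir_id]],
        card=dctm.card.loc[[mir_id]],
        is_control=dctm.is_control.loc[[mir_id]],
    )


@dataclass
class PcaResult:
    """PCA of a samples x variables matrix.

    ``loadings`` is variables x components, ``scores`` samples x components,
    ``explained`` the explained-variance fractions (non-increasing). The
    sign convention fixes each loading vector's largest-magnitude element
    positive so reruns and plots are reproducible.
    """

    variables: list
    sample_ids: list
    loadings: np.ndarray
    scores: np.ndarray
    explained: np.ndarray
    mean: np.ndarray
    scale: np.ndarray

    def processed(self) -> np.ndarray:
        """The centered/scaled matrix the decomposition was fit on."""
        return self.scores @ self.loadings.T


def run_pca(
    data: pd.DataFrame,
    standardize: bool = True,
    impute: str = "mean",
    n_components: int | None = None,
) -> PcaResult:
    """PCA of a samples x variables table.

    Missing values are mean-imputed by default ("complete_case" drops
    samples with any missing value). With standardization, zero-variance
    variables are dropped with a warning. Components come from the
    spectral decomposition of the covariance of the processed data.
    """
    if impute == "complete_case":
        data = data.dropna(axis=0, how="any")
    elif impute != "mean":
        raise ValidationError(f"unknown imputation policy {impute!r}")
    data = data.dropna(axis=1, how="all")
    X = data.to_numpy(float)
    if impute == "mean":
        col_mean = np.nanmean(X, axis=0)
        nan_pos = np.isnan(X)
        X[nan_pos] = np.take(col_mean, np.nonzero(nan_pos)[1])
    keep = np.ones(X.shape[1], dtype=bool)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    if standardize:
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping zero-variance variables: {list(data.columns[~keep])}",
                stacklevel=2,
            )
    if X.shape[0] < 2 or keep.sum() < 2:
        raise DegenerateInputError("PCA needs >=2 samples and >=2 usable variables")
    X = X[:, keep]
    mean = X.mean(axis=0)
    scale = sd[keep] if standardize else np.ones(keep.sum())
    Xp = (X - mean) / scale
    k = n_components or min(Xp.shape[0] - 1, Xp.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xp)
    loadings = pca.components_.T
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return PcaResult(
        variables=list(data.columns[keep]),
        sample_ids=list(data.index),
        loadings=loadings,
        scores=scores,
        explained=pca.explained_variance_ratio_.copy(),
        mean=mean,
        scale=np.asarray(scale, float),
    )
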