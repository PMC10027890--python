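"""Synthetic array-card qPCR data with known planted structure.

The generator emulates a two-card ~750-assay microRNA screen on small
rodent cohorts: per-microRNA baseline Ct levels, per-(sample, card) batch
shifts removed by median normalization, limit-of-detection censoring,
completely-at-random dropout, planted differential expression (lower Ct =
more transcript, so up-regulation subtracts cycles in the experimental
group), microRNAs whose experimental-group dCT rank-correlates with
seizure burden (Gaussian copula), and phenotype parameters rank-correlated
with chosen microRNAs. The planted truth is returned alongside the data so
recovery through the full pipeline can be measured.

All randomness flows from one master seed through named child streams.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import ValidationError
from .io import CtMatrix
from .normalization import DeltaCtMatrix

__all__ = [
    "PhenotypeSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "spearman_to_pearson",
    "simulate_screening_dataset",
    "simulate_phenotypes",
    "simulate_validation_cohorts",
]


def spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal Pearson correlation that induces a given Spearman
    correlation: rho_p = 2 sin(pi * rho_s / 6)."""
    if not (-1.0 < rho_s < 1.0):
        raise ValidationError("target rank correlation must lie in (-1, 1)")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass(frozen=True)
class PhenotypeSpec:
    """One phenotype parameter: optionally linked to the i-th planted DE
    microRNA (``linked`` int index, or an explicit microRNA id, or None)
    at a target Spearman correlation with that microRNA's dCT, mapped to a
    marginal: "normal", "percent" (in [0, 100]) or "positive" (lognormal,
    e.g. BDNF pg/ml)."""

    name: str
    linked: object = None
    rho: float = 0.0
    marginal: str = "normal"


DEFAULT_PHENOTYPES = (
    PhenotypeSpec("weight_gain", 0, 0.8, "normal"),
    PhenotypeSpec("SI", 0, -0.8, "normal"),
    PhenotypeSpec("SP_percentage", 0, -0.8, "percent"),
    PhenotypeSpec("BDNF", 0, -0.8, "positive"),
    PhenotypeSpec("NB"),
    PhenotypeSpec("BUR"),
    PhenotypeSpec("OF_distance"),
    PhenotypeSpec("OF_rearing"),
    PhenotypeSpec("OF_immobile"),
    PhenotypeSpec("OF_center"),
    PhenotypeSpec("BWB_WB"),
    PhenotypeSpec("BWB_entries"),
    PhenotypeSpec("BWB_stretching"),
    PhenotypeSpec("BWB_LT"),
    PhenotypeSpec("EPM_stretching"),
    PhenotypeSpec("EPM_head_dip"),
    PhenotypeSpec("EPM_closedarms"),
    PhenotypeSpec("EPM_openarms"),
    PhenotypeSpec("EPM_open1_3"),
    PhenotypeSpec("Adrenal_glands"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the generator.

    Defaults mirror the screening cohort (naive 5 / sham 5 / experimental
    6 animals, ~750 assays plus 6 controls on two cards, LOD at cycle 40)
    and the four validation cohorts (sham/experimental 12/12, 12/11,
    12/13 and 6/4).
    """

    n_mirs: int = 750
    n_controls: int = 6
    n_naive: int = 5
    n_sham: int = 5
    n_experimental: int = 6
    screening_model: str = "electrical_post_SE"
    baseline_mean_range: tuple = (18.0, 39.0)
    baseline_sd_range: tuple = (0.3, 1.0)
    lod: float = 40.0
    fraction_not_expressed: float = 0.2
    missing_rate: float = 0.05
    n_de: int = 20
    ddct_effect: float = 2.0
    de_sd: float = 0.5
    n_confounded: int = 10
    confound_rho: float = 0.9
    confound_group_effect: float = 2.0
    batch_shift_sd: float = 1.0
    burden_count_mean: float = 15.0
    burden_seizure_len_s: float = 35.0
    phenotypes: tuple = DEFAULT_PHENOTYPES
    validation_sizes: tuple = (
        ("kindling_focal", 12, 12),
        ("kindling_generalized", 12, 11),
        ("chemical_post_SE", 12, 13),
        ("electrical_post_SE", 6, 4),
    )
    n_validation_candidates: int = 11
    n_cross_model: int = 1
    n_single_model: int = 2
    validation_effect: float = 1.5
    validation_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.fraction_not_expressed <= 1.0):
            raise ValidationError("fraction_not_expressed must lie in [0, 1]")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValidationError("missing_rate must lie in [0, 1]")
        n_ne = int(self.fraction_not_expressed * self.n_mirs)
        if self.n_de + self.n_confounded + n_ne > self.n_mirs:
            raise ValidationError(
                "n_de + n_confounded + not-expressed exceed n_mirs"
            )
        for v in (self.ddct_effect, self.de_sd, self.confound_group_effect,
                  self.batch_shift_sd, self.validation_effect, self.validation_sd):
            if not math.isfinite(v):
                raise ValidationError("effect parameters must be finite")
        if not (-1.0 < self.confound_rho < 1.0):
            raise ValidationError("confound_rho must lie in (-1, 1)")
        for spec in self.phenotypes:
            if spec.linked is not None and not (-1.0 < spec.rho < 1.0):
                raise ValidationError(
                    f"phenotype {spec.name}: target correlation outside (-1, 1)"
                )


@dataclass
class SyntheticTruth:
    """Planted labels and effect sizes, recorded exactly as used."""

    labels: dict
    planted_ddct: dict
    planted_burden_rho: dict
    phenotype_links: dict = field(default_factory=dict)

    def mirs_with(self, label: str) -> list:
        return [m for m, lab in self.labels.items() if lab == label]

    @property
    def de_mirs(self) -> list:
        return [m for m, lab in self.labels.items() if lab in ("de_up", "de_down")]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "labels": self.labels,
                    "planted_ddct": self.planted_ddct,
                    "planted_burden_rho": self.planted_burden_rho,
                    "phenotype_links": {
                        k: list(v) for k, v in self.phenotype_links.items()
                    },
                },
                fh,
                indent=2,
            )
            fh.write("\n")


def _streams(seed: int, names: tuple) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Normal scores of the ranks of x (missing -> 0, the median score)."""
    z = np.zeros_like(x, dtype=float)
    ok = ~np.isnan(x)
    n = ok.sum()
    if n:
        r = sps.rankdata(x[ok])
        z[ok] = sps.norm.ppf(r / (n + 1.0))
    return z


def _apply_marginal(u: np.ndarray, marginal: str, rng: np.random.Generator) -> np.ndarray:
    if marginal == "normal":
        return sps.norm.ppf(u)
    if marginal == "percent":
        return 100.0 * u
    if marginal == "positive":
        # lognormal marginal, e.g. BDNF concentrations around 500 pg/ml
        return np.exp(math.log(500.0) + 0.4 * sps.norm.ppf(u))
    raise ValidationError(f"unknown marginal {marginal!r}")


def simulate_screening_dataset(cfg: SimulationConfig):
    """Generate one screening cohort.

    Returns (CtMatrix, sample metadata, seizure burden, SyntheticTruth);
    bit-identical for identical configs (including the seed).
    """
    cfg.validate()
    rngs = _streams(cfg.seed, ("labels", "baseline", "batch", "noise", "burden", "missing"))

    mirs = [f"miR-{i:04d}" for i in range(1, cfg.n_mirs + 1)]
    controls = [f"control-{i}" for i in range(1, cfg.n_controls + 1)]
    all_ids = mirs + controls
    half = cfg.n_mirs // 2
    card = pd.Series(
        ["A"] * half + ["B"] * (cfg.n_mirs - half)
        + ["A"] * (cfg.n_controls // 2) + ["B"] * (cfg.n_controls - cfg.n_controls // 2),
        index=all_ids,
    )
    is_control = pd.Series([False] * cfg.n_mirs + [True] * cfg.n_controls, index=all_ids)

    samples = (
        [f"naive_{i+1}" for i in range(cfg.n_naive)]
        + [f"sham_{i+1}" for i in range(cfg.n_sham)]
        + [f"exp_{i+1}" for i in range(cfg.n_experimental)]
    )
    groups = (
        ["naive"] * cfg.n_naive + ["sham"] * cfg.n_sham
        + ["experimental"] * cfg.n_experimental
    )
    meta = pd.DataFrame(
        {"group": groups, "model": cfg.screening_model},
        index=pd.Index(samples, name="sample_id"),
    )
    exp_idx = np.array([g == "experimental" for g in groups])

    # planted labels on disjoint random subsets
    n_ne = int(cfg.fraction_not_expressed * cfg.n_mirs)
    perm = rngs["labels"].permutation(cfg.n_mirs)
    ne_set = [mirs[i] for i in perm[:n_ne]]
    de_set = [mirs[i] for i in perm[n_ne : n_ne + cfg.n_de]]
    conf_set = [mirs[i] for i in perm[n_ne + cfg.n_de : n_ne + cfg.n_de + cfg.n_confounded]]
    labels = {m: "null" for m in mirs}
    labels.update({m: "not_expressed" for m in ne_set})
    n_up = (cfg.n_de + 1) // 2
    planted_ddct = {}
    for j, m in enumerate(de_set):
        up = j < n_up
        labels[m] = "de_up" if up else "de_down"
        planted_ddct[m] = -cfg.ddct_effect if up else cfg.ddct_effect
    for m in conf_set:
        labels[m] = "confounded"
        planted_ddct[m] = -cfg.confound_group_effect
    burden_rho = {m: cfg.confound_rho for m in conf_set}

    # seizure burden for experimental animals via a shared latent severity
    n_exp = cfg.n_experimental
    u = rngs["burden"].standard_normal(n_exp)
    counts = sps.poisson.ppf(sps.norm.cdf(u), cfg.burden_count_mean).astype(int)
    seiz_len = cfg.burden_seizure_len_s * np.exp(
        0.3 * rngs["burden"].standard_normal(n_exp)
    )
    burden = pd.DataFrame(
        {
            "seizure_count": counts,
            "seizure_duration": counts * seiz_len,
        },
        index=pd.Index([s for s, e in zip(samples, exp_idx) if e], name="sample_id"),
    )

    # Ct = baseline + batch(sample, card) + group effect + noise
    n_s = len(samples)
    base_mean = rngs["baseline"].uniform(*cfg.baseline_mean_range, cfg.n_mirs + cfg.n_controls)
    base_mean[cfg.n_mirs:] = 20.0  # stable control wells
    base_sd = rngs["baseline"].uniform(*cfg.baseline_sd_range, cfg.n_mirs + cfg.n_controls)
    base_sd[cfg.n_mirs:] = 0.15
    batch = {c: rngs["batch"].normal(0.0, cfg.batch_shift_sd, n_s) for c in ("A", "B")}

    ct = np.empty((len(all_ids), n_s))
    rho_p = spearman_to_pearson(cfg.confound_rho)
    for i, m in enumerate(all_ids):
        lab = labels.get(m, "control")
        if lab == "not_expressed":
            ct[i] = np.nan  # the assay never crosses threshold
            continue
        sd = cfg.de_sd if lab in ("de_up", "de_down", "confounded") else base_sd[i]
        if lab == "confounded":
            eps = rngs["noise"].standard_normal(n_s)
            z = eps.copy()
            z[exp_idx] = rho_p * u + math.sqrt(1.0 - rho_p**2) * eps[exp_idx]
            noise = sd * z
        else:
            noise = sd * rngs["noise"].standard_normal(n_s)
        row = base_mean[i] + batch[card[m]] + noise
        if m in planted_ddct:
            row = row + np.where(exp_idx, planted_ddct[m], 0.0)
        ct[i] = row

    ct[ct >= cfg.lod] = np.nan
    if cfg.missing_rate > 0:
        drop = rngs["missing"].random(ct.shape) < cfg.missing_rate
        ct[drop] = np.nan
    np.clip(ct, 1.0, None, out=ct)

    ctm = CtMatrix(
        ct=pd.DataFrame(ct, index=pd.Index(all_ids, name="mir_id"), columns=samples),
        card=card,
        is_control=is_control,
    )
    truth = SyntheticTruth(
        labels=labels, planted_ddct=planted_ddct, planted_burden_rho=burden_rho
    )
    return ctm, meta, burden, truth


def simulate_phenotypes(
    cfg: SimulationConfig, dctm: DeltaCtMatrix, truth: SyntheticTruth
) -> pd.DataFrame:
    """Phenotype table over the dCT matrix's samples.

    Linked parameters are drawn by Gaussian copula against the linked
    microRNA's dCT at the configured target Spearman correlation and then
    mapped to their marginal; unlinked parameters are independent noise.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(7)[-1])
    samples = dctm.sample_ids
    n = len(samples)
    # integer links resolve against the best-expressed differential plants
    # (lowest mean dCT): these are the ones the screen actually retains
    de = sorted(
        truth.de_mirs,
        key=lambda m: (float(np.nan_to_num(dctm.dct.loc[m].mean(), nan=np.inf)), m),
    )
    cols = {}
    for spec in cfg.phenotypes:
        if spec.linked is None:
            cols[spec.name] = _apply_marginal(rng.random(n), spec.marginal, rng)
            continue
        mir = de[spec.linked] if isinstance(spec.linked, int) else spec.linked
        if mir not in dctm.dct.index:
            raise ValidationError(f"phenotype {spec.name}: linked microRNA {mir} absent")
        zx = _normal_scores(dctm.dct.loc[mir, samples].to_numpy(float))
        rho_p = spearman_to_pearson(spec.rho)
        zy = rho_p * zx + math.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
        cols[spec.name] = _apply_marginal(sps.norm.cdf(zy), spec.marginal, rng)
        truth.phenotype_links[spec.name] = (mir, spec.rho)
    out = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    return out


def simulate_validation_cohorts(cfg: SimulationConfig):
    """Four single-card validation cohorts over a shared candidate set.

    The first ``n_cross_model`` candidates carry the planted effect in all
    models (cross-model replicable); the next ``n_single_model`` each carry
    it in exactly one model; the rest are null. Returns an ordered dict
    model -> (CtMatrix, metadata, phenotypes, truth).
    """
    cfg.validate()
    cands = [f"cand-{i:02d}" for i in range(1, cfg.n_validation_candidates + 1)]
    cross = cands[: cfg.n_cross_model]
    single = cands[cfg.n_cross_model : cfg.n_cross_model + cfg.n_single_model]
    models = [m for m, _, _ in cfg.validation_sizes]
    single_model_of = {m: models[j % len(models)] for j, m in enumerate(single)}

    out = {}
    streams = np.random.SeedSequence(cfg.seed).spawn(12)[8:12]
    for (model, n_sham, n_exp), child in zip(cfg.validation_sizes, streams):
        rng = np.random.default_rng(child)
        samples = [f"{model}_sham_{i+1}" for i in range(n_sham)] + [
            f"{model}_exp_{i+1}" for i in range(n_exp)
        ]
        groups = ["sham"] * n_sham + ["experimental"] * n_exp
        meta = pd.DataFrame(
            {"group": groups, "model": model},
            index=pd.Index(samples, name="sample_id"),
        )
        exp_idx = np.array([g == "experimental" for g in groups])
        labels = {}
        base = rng.uniform(20.0, 28.0, len(cands))
        ct = np.empty((len(cands), len(samples)))
        planted = {}
        for i, c in enumerate(cands):
            if c in cross:
                eff, lab = -cfg.validation_effect, "cross_model"
            elif c in single and single_model_of[c] == model:
                eff, lab = -cfg.validation_effect, f"single_model:{model}"
            elif c in single:
                eff, lab = 0.0, f"single_model:{single_model_of[c]}"
            else:
                eff, lab = 0.0, "null"
            labels[c] = lab
            planted[c] = eff
            ct[i] = (
                base[i]
                + rng.normal(0.0, cfg.validation_sd, len(samples))
                + np.where(exp_idx, eff, 0.0)
            )
        ct[ct >= cfg.lod] = np.nan
        ctm = CtMatrix(
            ct=pd.DataFrame(ct, index=pd.Index(cands, name="mir_id"), columns=samples),
            card=pd.Series("A", index=cands),
            is_control=pd.Series(False, index=cands),
        )
        truth = SyntheticTruth(
            labels=labels, planted_ddct=planted, planted_burden_rho={}
        )
        # small per-model phenotype panel; BDNF tracks the first
        # cross-model candidate so the pooled FDR screen has a signal
        pheno = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
        zx = _normal_scores(ct[cands.index(cross[0])] if cross else rng.standard_normal(len(samples)))
        rho_p = spearman_to_pearson(0.6)
        for name, marg in (("BDNF", "positive"), ("weight_gain", "normal"),
                           ("SI", "normal"), ("SP_percentage", "percent")):
            if name == "BDNF" and cross:
                zy = rho_p * zx + math.sqrt(1.0 - rho_p**2) * rng.standard_normal(len(samples))
                pheno[name] = _apply_marginal(sps.norm.cdf(zy), marg, rng)
                truth.phenotype_links[name] = (cross[0], 0.6)
            else:
                pheno[name] = _apply_marginal(rng.random(len(samples)), marg, rng)
        out[model] = (ctm, meta, pheno, truth)
    return out
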