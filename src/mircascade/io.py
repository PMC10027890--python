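"""Tabular input/output with strict validation.

All file formats are plain CSV (RFC-4180, UTF-8, header row mandatory,
decimal point only). The long dialect is canonical for Ct tables; a wide
dialect (one row per microRNA, one column per sample) is accepted as a
convenience. The literal tokens "Undetermined", "NA" and empty cells map
to MISSING (NaN); missing is a first-class state because the cascade
filters on missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "CtMatrix",
    "GROUPS",
    "MODELS",
    "MISSING_TOKENS",
    "read_ct_table",
    "write_ct_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_phenotypes",
    "write_phenotypes",
    "read_seizure_burden",
    "write_seizure_burden",
    "write_filter_trace",
    "write_candidates",
    "write_correlations",
    "read_correlations",
    "write_run_summary",
]

GROUPS = ("naive", "sham", "experimental")
MODELS = (
    "electrical_post_SE",
    "chemical_post_SE",
    "kindling_focal",
    "kindling_generalized",
)

#: case-insensitive spellings accepted for group labels
GROUP_ALIASES = {
    "naive": "naive",
    "naïve": "naive",
    "ctr": "naive",
    "control": "naive",
    "sham": "sham",
    "experimental": "experimental",
    "exp": "experimental",
    "se": "experimental",
}

MISSING_TOKENS = ("Undetermined", "NA", "")

CT_MAX = 45.0


@dataclass
class CtMatrix:
    """Raw Ct values, microRNAs x samples, with card assignment.

    ``ct`` is a DataFrame indexed by microRNA id with one column per sample;
    MISSING wells are NaN. ``card`` maps each microRNA to its array card and
    ``is_control`` flags control/spike-in wells (excluded from all
    downstream statistics).
    """

    ct: pd.DataFrame
    card: pd.Series
    is_control: pd.Series

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.ct.index.has_duplicates:
            dups = self.ct.index[self.ct.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate microRNA ids: {dups[:5]}")
        if self.ct.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        if not self.card.index.equals(self.ct.index):
            missing = self.ct.index.difference(self.card.index).tolist()
            raise ValidationError(f"card assignment missing for {missing[:5]}")
        if not self.is_control.index.equals(self.ct.index):
            raise ValidationError("is_control must cover every microRNA")
        vals = self.ct.to_numpy(dtype=float)
        bad = np.argwhere(~np.isnan(vals) & ((vals <= 0.0) | (vals > CT_MAX)))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"Ct out of range (0, {CT_MAX}] at "
                f"({self.ct.index[i]}, {self.ct.columns[j]}): {vals[i, j]}"
            )

    @property
    def mir_ids(self) -> list:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list:
        return list(self.ct.columns)

    def noncontrol_ids(self) -> list:
        return list(self.ct.index[~self.is_control.to_numpy(bool)])


def _parse_ct_cell(token, where: str, ct_cap: float | None) -> float:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return np.nan
    s = str(token).strip()
    if s in MISSING_TOKENS:
        return ct_cap if ct_cap is not None else np.nan
    try:
        return float(s)
    except ValueError:
        raise FormatError(f"unparseable Ct value {s!r} at {where}") from None


def read_ct_table(path, dialect: str = "long", ct_cap: float | None = None) -> CtMatrix:
    """Read a Ct table.

    long dialect columns: mir_id, sample_id, card, is_control, ct.
    wide dialect columns: mir_id, card, is_control, then one column per
    sample. ``ct_cap`` optionally substitutes a fixed Ct for MISSING tokens
    instead of NaN.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect == "long":
        need = {"mir_id", "sample_id", "card", "is_control", "ct"}
        if not need.issubset(df.columns):
            raise FormatError(f"long Ct table needs columns {sorted(need)}")
        dup = df.duplicated(subset=["mir_id", "sample_id"])
        if dup.any():
            row = df[dup].iloc[0]
            raise FormatError(
                f"duplicate (mir, sample) pair ({row.mir_id}, {row.sample_id})"
            )
        df["_ct"] = [
            _parse_ct_cell(v, f"({m}, {s})", ct_cap)
            for v, m, s in zip(df["ct"], df["mir_id"], df["sample_id"])
        ]
        mir_order = df["mir_id"].drop_duplicates()
        sample_order = df["sample_id"].drop_duplicates()
        ct = (
            df.pivot(index="mir_id", columns="sample_id", values="_ct")
            .reindex(index=mir_order, columns=sample_order)
        )
        ct.columns.name = None
        meta = df.drop_duplicates("mir_id").set_index("mir_id")
        conflict = df.groupby("mir_id")["card"].nunique()
        if (conflict > 1).any():
            raise ValidationError(
                f"microRNA on more than one card: "
                f"{conflict[conflict > 1].index.tolist()[:5]}"
            )
        card = meta["card"].reindex(ct.index)
        is_control = _parse_bool(meta["is_control"]).reindex(ct.index)
    elif dialect == "wide":
        need = {"mir_id", "card", "is_control"}
        if not need.issubset(df.columns):
            raise FormatError(f"wide Ct table needs columns {sorted(need)}")
        if df["mir_id"].duplicated().any():
            raise FormatError("duplicate mir_id rows in wide Ct table")
        df = df.set_index("mir_id")
        card = df["card"]
        is_control = _parse_bool(df["is_control"])
        samples = [c for c in df.columns if c not in ("card", "is_control")]
        ct = pd.DataFrame(
            {
                s: [
                    _parse_ct_cell(v, f"({m}, {s})", ct_cap)
                    for m, v in zip(df.index, df[s])
                ]
                for s in samples
            },
            index=df.index,
        )
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    return CtMatrix(ct=ct, card=card, is_control=is_control)


def _parse_bool(col: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = col.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = col[out.isna()].iloc[0]
        raise FormatError(f"unparseable boolean {bad!r} in is_control")
    return out.astype(bool)


def write_ct_table(ctm: CtMatrix, path, dialect: str = "long") -> None:
    if dialect == "long":
        long = ctm.ct.stack(future_stack=True).rename("ct").reset_index()
        long.columns = ["mir_id", "sample_id", "ct"]
        long["card"] = long["mir_id"].map(ctm.card)
        long["is_control"] = long["mir_id"].map(ctm.is_control)
        long = long[["mir_id", "sample_id", "card", "is_control", "ct"]]
        long.to_csv(path, index=False)
    elif dialect == "wide":
        wide = ctm.ct.copy()
        wide.insert(0, "is_control", ctm.is_control)
        wide.insert(0, "card", ctm.card)
        wide.to_csv(path, index=True, index_label="mir_id")
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")


def read_sample_metadata(path, aliases: bool = True) -> pd.DataFrame:
    """Sample metadata: index sample_id, columns group and model."""
    df = pd.read_csv(path, dtype=str)
    need = {"sample_id", "group", "model"}
    if not need.issubset(df.columns):
        raise FormatError(f"metadata needs columns {sorted(need)}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    df = df.set_index("sample_id")
    if aliases:
        df["group"] = df["group"].str.strip().str.lower().map(GROUP_ALIASES)
    if not df["group"].isin(GROUPS).all():
        bad = df.loc[~df["group"].isin(GROUPS), "group"].dropna().tolist()
        raise ValidationError(f"unknown group label(s): {sorted(set(map(str, bad)))}")
    if df["group"].isna().any():
        raise ValidationError("unknown group label (no alias match)")
    if not df["model"].isin(MODELS).all():
        bad = sorted(set(df.loc[~df["model"].isin(MODELS), "model"]))
        raise ValidationError(f"unknown model label(s): {bad}")
    return df[["group", "model"]]


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.reset_index(names="sample_id").to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Long phenotype CSV (sample_id, parameter, value) -> wide DataFrame
    samples x parameters; empty/NA cells stay MISSING."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    need = {"sample_id", "parameter", "value"}
    if not need.issubset(df.columns):
        raise FormatError(f"phenotype table needs columns {sorted(need)}")
    if df.duplicated(subset=["sample_id", "parameter"]).any():
        raise FormatError("duplicate (sample, parameter) pair in phenotypes")
    vals = []
    for v, s, p in zip(df["value"], df["sample_id"], df["parameter"]):
        s_ = str(v).strip()
        if s_ in MISSING_TOKENS:
            vals.append(np.nan)
        else:
            try:
                x = float(s_)
            except ValueError:
                raise FormatError(f"unparseable value {v!r} at ({s}, {p})") from None
            if not np.isfinite(x):
                raise ValidationError(f"non-finite phenotype value at ({s}, {p})")
            vals.append(x)
    df["_v"] = vals
    wide = df.pivot(index="sample_id", columns="parameter", values="_v")
    wide = wide.reindex(
        index=df["sample_id"].drop_duplicates(),
        columns=df["parameter"].drop_duplicates(),
    )
    wide.columns.name = None
    wide.index.name = "sample_id"
    return wide


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    long = pheno.stack(future_stack=True).rename("value").reset_index()
    long.columns = ["sample_id", "parameter", "value"]
    long.to_csv(path, index=False)


def read_seizure_burden(
    path, meta: pd.DataFrame | None = None, strict: bool = True
) -> pd.DataFrame:
    """Seizure burden per experimental sample: seizure_count (int >= 0) and
    seizure_duration (seconds >= 0). With metadata supplied, rows for
    non-experimental samples raise (strict) or are dropped."""
    df = pd.read_csv(path)
    need = {"sample_id", "seizure_count", "seizure_duration"}
    if not need.issubset(df.columns):
        raise FormatError(f"burden table needs columns {sorted(need)}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in seizure burden")
    df = df.set_index("sample_id")
    if (df["seizure_count"] < 0).any() or (df["seizure_duration"] < 0).any():
        raise ValidationError("seizure counts and durations must be >= 0")
    if (df["seizure_count"] != df["seizure_count"].astype(int)).any():
        raise ValidationError("seizure_count must be an integer")
    df["seizure_count"] = df["seizure_count"].astype(int)
    df["seizure_duration"] = df["seizure_duration"].astype(float)
    if meta is not None:
        exp = set(meta.index[meta["group"] == "experimental"])
        offending = [s for s in df.index if s not in exp]
        if offending:
            if strict:
                raise ValidationError(
                    f"seizure burden rows for non-experimental samples: "
                    f"{offending[:5]}"
                )
            df = df.drop(index=offending)
    return df[["seizure_count", "seizure_duration"]]


def write_seizure_burden(burden: pd.DataFrame, path) -> None:
    burden.reset_index(names="sample_id").to_csv(path, index=False)


TRACE_COLUMNS = [
    "mir_id",
    "removed_at",
    "p_ttest",
    "log2fc",
    "r_seizfreq",
    "p_seizfreq",
    "r_seizdur",
    "p_seizdur",
    "min_ct",
]


def write_filter_trace(trace, path) -> None:
    """Write the per-microRNA cascade trace as CSV (fixed column order)."""
    tab = trace.table.reset_index(names="mir_id")
    tab[TRACE_COLUMNS].to_csv(path, index=False)


def write_candidates(candidates, path) -> None:
    pd.DataFrame({"mir_id": list(candidates)}).to_csv(path, index=False)


def write_correlations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_correlations(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_run_summary(summary: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=False, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
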