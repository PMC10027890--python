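#!/usr/bin/env python
"""Associate retained candidates with behavior and biochemistry: Spearman
correlation matrix (with seizure-burden covariates), significance flags
(|r| > 0.5 and p < 0.05), and PCA of the phenotype panel and of the
candidate dCT profiles. Writes tables under results/associations/."""

import argparse
from pathlib import Path

import pandas as pd

from mircascade import io as mio
from mircascade.association import correlation_matrix, flag_significant, run_pca
from mircascade.normalization import compute_delta_ct


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--screen", type=Path, default=Path("results/screen"))
    ap.add_argument("--out", type=Path, default=Path("results/associations"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ctm = mio.read_ct_table(args.data / "screening_ct.csv")
    meta = mio.read_sample_metadata(args.data / "screening_samples.csv")
    burden = mio.read_seizure_burden(args.data / "screening_burden.csv", meta=meta)
    pheno = mio.read_phenotypes(args.data / "screening_phenotypes.csv")
    cands = pd.read_csv(args.screen / "candidates.csv")["mir_id"].tolist()
    dctm = compute_delta_ct(ctm)

    table = flag_significant(correlation_matrix(dctm, pheno, burden, candidates=cands))
    mio.write_correlations(table, args.out / "correlations.csv")
    flagged = table[table["flagged"]]
    print(f"{len(table)} candidate x parameter records, {len(flagged)} flagged")
    for _, r in flagged.iterrows():
        sign = "positive" if r["r"] > 0 else "negative"
        print(f"  {r['x_name']} ~ {r['y_name']}: {sign} r={r['r']:+.2f}, p={r['p']:.3g}")

    for tag, data in (
        ("behavior", pheno.reindex(list(ctm.ct.columns))),
        ("mirs", dctm.dct.loc[cands].T),
    ):
        pca = run_pca(data, standardize=True)
        pd.DataFrame(
            pca.scores, index=pca.sample_ids,
            columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
        ).to_csv(args.out / f"pca_{tag}_scores.csv", index_label="sample_id")
        pd.DataFrame(
            {"component": [f"PC{i+1}" for i in range(len(pca.explained))],
             "explained_fraction": pca.explained},
        ).to_csv(args.out / f"pca_{tag}_variance.csv", index=False)
        print(f"PCA ({tag}): PC1/PC2 explain "
              f"{pca.explained[0]:.0%}/{pca.explained[1]:.0%} of variance")


if __name__ == "__main__":
    main()
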