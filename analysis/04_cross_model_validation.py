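#!/usr/bin/env python
"""Cross-model validation of the replicable candidate: pool the four
validation cohorts, run the two-tailed unpaired t-test pooled and per
model, and screen the candidate against the phenotype panel with BH-FDR.
Writes tables under results/validation/."""

import argparse
from pathlib import Path

import pandas as pd

from mircascade import io as mio
from mircascade.association import cross_model_mir_screen, per_model_tests, pooled_group_test
from mircascade.normalization import DeltaCtMatrix, compute_delta_ct
from mircascade.simulate import SimulationConfig


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/validation"))
    ap.add_argument("--candidate", default="cand-01")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    models = [m for m, *_ in SimulationConfig().validation_sizes]
    cts, metas, phenos = [], [], []
    card = control = None
    for model in models:
        ctm = mio.read_ct_table(args.data / f"validation_{model}_ct.csv")
        metas.append(mio.read_sample_metadata(args.data / f"validation_{model}_samples.csv"))
        phenos.append(mio.read_phenotypes(args.data / f"validation_{model}_phenotypes.csv"))
        cts.append(compute_delta_ct(ctm).dct)
        card, control = ctm.card, ctm.is_control
    dctm = DeltaCtMatrix(dct=pd.concat(cts, axis=1), card=card, is_control=control)
    meta = pd.concat(metas)
    pheno = pd.concat(phenos)

    pooled = pooled_group_test(dctm, meta, args.candidate)
    per_model = per_model_tests(dctm, meta, args.candidate)
    screen = cross_model_mir_screen(dctm, args.candidate, pheno)

    pd.DataFrame([pooled]).assign(mir_id=args.candidate).to_csv(
        args.out / "pooled_test.csv", index=False
    )
    per_model.reset_index().to_csv(args.out / "per_model_tests.csv", index=False)
    mio.write_correlations(screen, args.out / "fdr_screen.csv")

    print(
        f"{args.candidate} pooled: ddCT={pooled['ddct']:+.2f}, "
        f"p={pooled['p_value']:.4f} (exp n={int(pooled['n_exp'])}, "
        f"sham n={int(pooled['n_ref'])})"
    )
    for model, rec in per_model.iterrows():
        print(f"  {model}: ddCT={rec['ddct']:+.2f}, p={rec['p_value']:.4f}")
    sig = screen[screen["q"] < 0.05]
    for _, r in sig.iterrows():
        print(f"  FDR screen: {r['y_name']} r={r['r']:+.2f}, q={r['q']:.3g}")


if __name__ == "__main__":
    main()
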