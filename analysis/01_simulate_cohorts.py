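#!/usr/bin/env python
"""Generate the synthetic study: one screening cohort (naive 5 / sham 5 /
experimental 6; ~750 assays + controls on two cards) with seizure burden
and phenotypes, plus four validation cohorts. Writes CSVs under
results/data/ and the planted truth as truth.json."""

import argparse
from pathlib import Path

from mircascade import io as mio
from mircascade.normalization import compute_delta_ct
from mircascade.simulate import (
    SimulationConfig,
    simulate_phenotypes,
    simulate_screening_dataset,
    simulate_validation_cohorts,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    ctm, meta, burden, truth = simulate_screening_dataset(cfg)
    pheno = simulate_phenotypes(cfg, compute_delta_ct(ctm), truth)
    mio.write_ct_table(ctm, args.out / "screening_ct.csv")
    mio.write_sample_metadata(meta, args.out / "screening_samples.csv")
    mio.write_seizure_burden(burden, args.out / "screening_burden.csv")
    mio.write_phenotypes(pheno, args.out / "screening_phenotypes.csv")
    truth.to_json(args.out / "screening_truth.json")
    n_miss = int(ctm.ct.isna().sum().sum())
    print(
        f"screening cohort: {ctm.ct.shape[0]} assays x {ctm.ct.shape[1]} samples, "
        f"{n_miss} missing wells ({n_miss / ctm.ct.size:.0%})"
    )

    for model, (vctm, vmeta, vpheno, vtruth) in simulate_validation_cohorts(cfg).items():
        mio.write_ct_table(vctm, args.out / f"validation_{model}_ct.csv")
        mio.write_sample_metadata(vmeta, args.out / f"validation_{model}_samples.csv")
        mio.write_phenotypes(vpheno, args.out / f"validation_{model}_phenotypes.csv")
        vtruth.to_json(args.out / f"validation_{model}_truth.json")
        print(f"validation cohort {model}: {vctm.ct.shape[1]} samples")


if __name__ == "__main__":
    main()
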