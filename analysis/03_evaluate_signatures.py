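#!/usr/bin/env python
"""Evaluate the discovered signatures: KM curves, log-rank, hazard ratios.

Scores each signature over all pretreatment samples (both arms pooled, the
scoring population fixing the gene means/SDs and the split median), then
compares high vs low groups per arm and endpoint.  The planted effects act
only on the treated arm, so the signatures should stratify that arm and
behave as null in the comparator arm.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gesig.cohort import align_cohort, read_clinical_table, read_expression_matrix
from gesig.pipeline import evaluate_signature, median_split, score_signature
from gesig.reporting import export_km_series


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--signatures", type=Path, default=Path("results/signatures.json"))
    ap.add_argument("--outdir", type=Path, default=Path("results/evaluation"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cohort = align_cohort(
        read_expression_matrix(args.cohort / "expression.tsv"),
        read_clinical_table(args.cohort / "clinical.tsv"),
    )
    sigs = json.loads(args.signatures.read_text())
    clin = cohort.clinical.data

    rows = []
    for name in ("favorable", "unfavorable"):
        genes = sigs[name]
        if not genes:
            print(f"{name}: empty signature, skipping")
            continue
        scores = median_split(score_signature(cohort.expression, genes, name))
        scores.frame().to_csv(args.outdir / f"scores_{name}.tsv", sep="\t", index=False)
        for arm in sorted(clin["arm"].unique()):
            arm_cohort = cohort.subset_samples(
                clin.loc[clin["arm"] == arm, "sample_id"].tolist()
            )
            for endpoint in ("DOR", "EFS", "PFS"):
                try:
                    cmp_ = evaluate_signature(arm_cohort, scores, endpoint)
                except Exception as exc:  # noqa: BLE001
                    print(f"  {name}/{arm}/{endpoint}: skipped ({exc})")
                    continue
                hr = cmp_.hazard_ratio
                rows.append(
                    {
                        "signature": name, "arm": arm, "endpoint": endpoint,
                        "n_high": cmp_.n_high, "n_low": cmp_.n_low,
                        "hr": hr.hr, "ci_low": hr.ci_low, "ci_high": hr.ci_high,
                        "logrank_p": cmp_.logrank.p_value,
                    }
                )
                export_km_series(
                    cmp_, args.outdir / f"km_{name}_{arm.replace('-', '')}_{endpoint}.tsv"
                )
                hr_txt = (
                    f"HR {hr.hr:.2f} ({hr.ci_low:.2f}-{hr.ci_high:.2f})"
                    if not hr.diverged else "HR diverged"
                )
                print(
                    f"  {name}/{arm}/{endpoint}: {hr_txt}, "
                    f"log-rank p = {cmp_.logrank.p_value:.2g}"
                )
    table = pd.DataFrame(rows)
    table.to_csv(args.outdir / "evaluation.tsv", sep="\t", index=False)
    print(f"wrote {args.outdir}/evaluation.tsv ({len(table)} comparisons)")


if __name__ == "__main__":
    main()
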