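#!/usr/bin/env python
"""Combined two-signature stratification and cell-of-origin subgroup analysis.

Cross-classifies treated patients by high/low favorable and unfavorable
scores (four groups; the favorable-high/unfavorable-low corner should do
best) and re-evaluates the favorable signature within GCB and non-GCB
subgroups using the median of the entire dataset, not per-subgroup medians.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gesig.cohort import align_cohort, read_clinical_table, read_expression_matrix
from gesig.pipeline import (
    combine_signatures,
    evaluate_combined_groups,
    median_split,
    score_signature,
    subgroup_analysis,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--signatures", type=Path, default=Path("results/signatures.json"))
    ap.add_argument("--outdir", type=Path, default=Path("results/subgroups"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cohort = align_cohort(
        read_expression_matrix(args.cohort / "expression.tsv"),
        read_clinical_table(args.cohort / "clinical.tsv"),
    )
    sigs = json.loads(args.signatures.read_text())
    if not (sigs["favorable"] and sigs["unfavorable"]):
        raise SystemExit("need both signatures; run 02_discover_signatures.py first")

    clin = cohort.clinical.data
    treated = cohort.subset_samples(
        clin.loc[clin["arm"] == "axi-cel", "sample_id"].tolist()
    )
    # medians and gene means/SDs from all pretreatment samples (entire dataset)
    s_fav = median_split(score_signature(cohort.expression, sigs["favorable"], "fav"))
    s_unf = median_split(score_signature(cohort.expression, sigs["unfavorable"], "unf"))

    from gesig.survstats import spearman_correlation

    rho, rho_p = spearman_correlation(s_fav.scores, s_unf.scores)
    print(f"favorable vs unfavorable score correlation: Spearman R = {rho:.3f} (p = {rho_p:.3g})")

    combined = combine_signatures(s_fav, s_unf, "fav", "unf")
    print("combined group sizes:", combined.counts)
    res = evaluate_combined_groups(cohort, combined, "PFS", reference="fav-high/unf-low")
    rows = [
        {"group": lv, "vs": "fav-high/unf-low", "logrank_chi2": r.chi_square,
         "logrank_p": r.p_value}
        for lv, r in res.items()
    ]
    pd.DataFrame(rows).to_csv(args.outdir / "combined_logrank.tsv", sep="\t", index=False)
    for row in rows:
        print(f"  {row['group']} vs reference: log-rank p = {row['logrank_p']:.3g}")

    sub = subgroup_analysis(treated, s_fav, "coo", "PFS")
    sub_rows = []
    for lv, cmp_ in sub.items():
        if cmp_ is None:
            print(f"  coo={lv}: skipped (too few samples)")
            continue
        hr = cmp_.hazard_ratio
        sub_rows.append(
            {"coo": lv, "n_high": cmp_.n_high, "n_low": cmp_.n_low, "hr": hr.hr,
             "ci_low": hr.ci_low, "ci_high": hr.ci_high,
             "logrank_p": cmp_.logrank.p_value}
        )
        print(
            f"  coo={lv}: favorable high-vs-low HR "
            f"{hr.hr:.2f}, log-rank p = {cmp_.logrank.p_value:.3g}"
        )
    pd.DataFrame(sub_rows).to_csv(args.outdir / "subgroup_coo.tsv", sep="\t", index=False)
    print(f"wrote {args.outdir}")


if __name__ == "__main__":
    main()
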