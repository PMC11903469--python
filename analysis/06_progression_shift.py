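#!/usr/bin/env python
"""Signature scores before treatment versus at disease progression.

Pools the pretreatment and at-progression expression matrices into one
scoring population, scores both signatures, and compares the two sample sets
with the two-sided Wilcoxon rank-sum test.  On the synthetic cohort the
progression samples are drawn from the same background distribution, so the
comparison illustrates the machinery (and its calibration) rather than a
planted shift.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from gesig.cohort import read_expression_matrix
from gesig.pipeline import progression_comparison, score_pre_post


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--signatures", type=Path, default=Path("results/signatures.json"))
    ap.add_argument("--out", type=Path, default=Path("results/progression_comparison.tsv"))
    args = ap.parse_args()

    pre = read_expression_matrix(args.cohort / "expression.tsv")
    post = read_expression_matrix(args.cohort / "expression_progression.tsv")
    sigs = json.loads(args.signatures.read_text())

    rows = []
    for name in ("favorable", "unfavorable"):
        genes = sigs[name]
        if not genes:
            continue
        pre_s, post_s = score_pre_post(pre, post, genes, name)
        res = progression_comparison(pre_s, post_s)
        rows.append(
            {"signature": name, "n_pre": res.n_pre, "n_post": res.n_post,
             "median_pre": res.median_pre, "median_post": res.median_post,
             "direction": res.direction, "wilcoxon_p": res.p_value,
             "low_power": res.low_power}
        )
        print(
            f"  {name}: median {res.median_pre:.3f} (pre) -> {res.median_post:.3f} "
            f"(progression), {res.direction}, Wilcoxon p = {res.p_value:.3g}"
        )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, sep="\t", index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
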