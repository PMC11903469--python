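"""Run orchestration, manifests and tabular report export.

This module formats and files results computed elsewhere — it performs no
statistics of its own.  A full analysis run writes TSV/JSON artifacts plus a
manifest (inputs, settings, seed, package version) so any run can be
replayed byte-identically (timestamps aside).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    align_cohort,
    dedup_subject_samples,
    qc_filter_coding_fraction,
    read_clinical_table,
    read_expression_matrix,
    write_clinical_table,
    write_expression_matrix,
)
from .pipeline import (
    PipelineError,
    SurvivalComparison,
    combine_signatures,
    derive_signatures,
    evaluate_signature,
    median_split,
    progression_comparison,
    score_pre_post,
    score_signature,
    subgroup_analysis,
)
from .simulate import SimulationConfig, generate_cohort, simulate_expression
from .survstats import KMCurve

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    command: str
    config: dict
    input_digests: dict[str, str]
    seed: int
    package_version: str
    started: str
    finished: str | None = None
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def export_km_series(comparison: SurvivalComparison, path=None) -> pd.DataFrame:
    """Step-function data series behind a high/low Kaplan-Meier plot.

    Each group starts at (0, 1.0); subsequent rows give the survival
    estimate just after each event time with at-risk and event counts.
    """
    frames = []
    for name, km in (("high", comparison.km_high), ("low", comparison.km_low)):
        df = pd.DataFrame(
            {
                "group": name,
                "time": np.concatenate([[0.0], km.times]),
                "survival": np.concatenate([[1.0], km.survival]),
                "at_risk": np.concatenate([[km.n], km.at_risk]),
                "events": np.concatenate([[0], km.events]),
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if path is not None:
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return out


def read_km_series(path) -> dict[str, KMCurve]:
    """Reconstruct the KM curves from an exported step series."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for name, grp in df.groupby("group"):
        grp = grp.sort_values("time")
        body = grp[grp["time"] > 0]
        out[str(name)] = KMCurve(
            times=body["time"].to_numpy(float),
            survival=body["survival"].to_numpy(float),
            at_risk=body["at_risk"].to_numpy(int),
            events=body["events"].to_numpy(int),
            censor_times=np.array([]),
            n=int(grp["at_risk"].iloc[0]),
        )
    return out


def _comparison_row(tag: str, arm: str, cmp_: SurvivalComparison) -> dict:
    hr = cmp_.hazard_ratio
    return {
        "signature": cmp_.signature_id,
        "analysis": tag,
        "arm": arm,
        "endpoint": cmp_.endpoint,
        "n_high": cmp_.n_high,
        "n_low": cmp_.n_low,
        "hr": hr.hr,
        "hr_ci_low": hr.ci_low,
        "hr_ci_high": hr.ci_high,
        "hr_p": hr.p_value,
        "logrank_chi2": cmp_.logrank.chi_square,
        "logrank_p": cmp_.logrank.p_value,
        "hr_diverged": hr.diverged,
    }


def run_full_analysis(config: dict, outdir) -> Path:
    """End-to-end discovery and evaluation run; returns the run directory.

    ``config`` either names input files ("expression", "clinical") or
    simulation settings (anything accepted by SimulationConfig under
    "simulate"); common keys: "seed", "mixing_r", "n_alphas", "ratio_min",
    "n_progression" (simulated at-progression samples for the score-shift
    comparison).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(
        command="run_full_analysis",
        config=dict(config),
        input_digests={},
        seed=seed,
        package_version=__version__,
        started=_dt.datetime.now().isoformat(timespec="seconds"),
    )

    post_expr = None
    truth = None
    if "expression" in config and "clinical" in config:
        expr = read_expression_matrix(config["expression"])
        clinical = read_clinical_table(config["clinical"])
        manifest.input_digests = {
            "expression": _sha256(Path(config["expression"])),
            "clinical": _sha256(Path(config["clinical"])),
        }
        clinical = qc_filter_coding_fraction(clinical)
        clinical = dedup_subject_samples(clinical)
        cohort = align_cohort(expr, clinical)
    else:
        sim_kwargs = dict(config.get("simulate", {}))
        sim_kwargs.setdefault("seed", seed)
        sim = SimulationConfig(**sim_kwargs)
        cohort, truth = generate_cohort(sim)
        n_prog = int(config.get("n_progression", 17))
        if n_prog:
            prog_cfg = SimulationConfig(
                **{**sim_kwargs, "n_samples": n_prog, "seed": seed + 10_000,
                   "panel_seed": sim.seed, "timepoint": "progression"},
            )
            post_expr, _ = simulate_expression(prog_cfg)
            post_expr = _relabel_samples(post_expr, prefix="P")
        write_expression_matrix(cohort.expression, outdir / "expression.tsv")
        write_clinical_table(cohort.clinical, outdir / "clinical.tsv")
        manifest.outputs += ["expression.tsv", "clinical.tsv"]

    # discovery on the CAR-T arm pretreatment samples
    clin = cohort.clinical.data
    disc_ids = clin.loc[
        (clin["arm"] == "axi-cel") & (clin["timepoint"] == "pretreatment"),
        "sample_id",
    ].tolist()
    if len(disc_ids) < 20:
        raise PipelineError("too few CAR-T-arm pretreatment samples for discovery")
    disc_cohort = cohort.subset_samples(disc_ids)
    pair = derive_signatures(
        disc_cohort,
        mixing_r=float(config.get("mixing_r", 0.9)),
        seed=seed,
        n_alphas=int(config.get("n_alphas", 100)),
        ratio_min=float(config.get("ratio_min", 0.01)),
        log_transform=bool(config.get("log_transform", False)),
    )
    (outdir / "signatures.json").write_text(
        json.dumps(pair.to_dict(), indent=2) + "\n"
    )
    manifest.outputs.append("signatures.json")

    # scoring over all pretreatment samples (both arms pooled), then
    # evaluation per arm and endpoint
    pre_ids = clin.loc[clin["timepoint"] == "pretreatment", "sample_id"].tolist()
    pre_cohort = cohort.subset_samples(pre_ids)
    rows = []
    for sig_name, genes in (
        ("favorable", pair.favorable),
        ("unfavorable", pair.unfavorable),
    ):
        if not genes:
            logger.warning("signature %s is empty; skipping evaluation", sig_name)
            continue
        scores = median_split(
            score_signature(pre_cohort.expression, genes, signature_id=sig_name)
        )
        scores.frame().to_csv(
            outdir / f"scores_{sig_name}.tsv", sep="\t", index=False
        )
        manifest.outputs.append(f"scores_{sig_name}.tsv")
        for arm in sorted(set(clin["arm"])):
            arm_ids = clin.loc[
                (clin["arm"] == arm) & (clin["timepoint"] == "pretreatment"),
                "sample_id",
            ].tolist()
            arm_cohort = cohort.subset_samples(arm_ids)
            for endpoint in ("DOR", "EFS", "PFS"):
                try:
                    cmp_ = evaluate_signature(arm_cohort, scores, endpoint)
                except (PipelineError, Exception) as exc:  # noqa: BLE001
                    logger.warning(
                        "evaluation skipped (%s, %s, %s): %s",
                        sig_name, arm, endpoint, exc,
                    )
                    continue
                rows.append(_comparison_row("overall", arm, cmp_))
                km_name = f"km_{sig_name}_{arm.replace('-', '')}_{endpoint}.tsv"
                export_km_series(cmp_, outdir / km_name)
                manifest.outputs.append(km_name)
    pd.DataFrame(rows).to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
    manifest.outputs.append("evaluation.tsv")

    # univariate screen on the CAR-T arm, PFS
    from .survstats import univariate_gene_screen

    screen, skipped = univariate_gene_screen(disc_cohort, "PFS", mode="median_split")
    screen.to_csv(outdir / "univariate_screen_pfs.tsv", sep="\t", index=False)
    manifest.outputs.append("univariate_screen_pfs.tsv")

    # combined grouping and cell-of-origin subgroups (CAR-T arm, PFS)
    if pair.favorable and pair.unfavorable:
        s_fav = median_split(
            score_signature(pre_cohort.expression, pair.favorable, "favorable")
        )
        s_unf = median_split(
            score_signature(pre_cohort.expression, pair.unfavorable, "unfavorable")
        )
        combined = combine_signatures(s_fav, s_unf, "fav", "unf")
        json.dump(
            combined.counts, (outdir / "combined_groups.json").open("w"), indent=2
        )
        manifest.outputs.append("combined_groups.json")
        sub = subgroup_analysis(disc_cohort, s_fav, "coo", "PFS")
        sub_rows = [
            _comparison_row(f"coo={lv}", "axi-cel", cmp_)
            for lv, cmp_ in sub.items()
            if cmp_ is not None
        ]
        pd.DataFrame(sub_rows).to_csv(
            outdir / "subgroup_coo.tsv", sep="\t", index=False
        )
        manifest.outputs.append("subgroup_coo.tsv")

    # pre vs progression score shift on simulated progression samples
    if post_expr is not None and pair.unfavorable:
        prog_rows = []
        for sig_name, genes in (
            ("favorable", pair.favorable),
            ("unfavorable", pair.unfavorable),
        ):
            if not genes:
                continue
            pre_s, post_s = score_pre_post(
                pre_cohort.expression, post_expr, genes, signature_id=sig_name
            )
            res = progression_comparison(pre_s, post_s)
            prog_rows.append(asdict(res))
        pd.DataFrame(prog_rows).to_csv(
            outdir / "progression_comparison.tsv", sep="\t", index=False
        )
        manifest.outputs.append("progression_comparison.tsv")

    manifest.finished = _dt.datetime.now().isoformat(timespec="seconds")
    manifest.write(outdir / "manifest.json")
    return outdir


def _relabel_samples(expr, prefix: str):
    from .cohort import ExpressionMatrix

    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        sample_ids=[f"{prefix}{s}" for s in expr.sample_ids],
        values=expr.values.copy(),
        unit_label=expr.unit_label,
    )
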