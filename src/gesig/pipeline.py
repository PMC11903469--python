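"""Signature discovery and evaluation pipeline.

Orchestrates the full analysis: per-endpoint elastic-net Cox fits with
cross-validated alpha, sign-stratified intersection of the selected
transcripts across DOR/EFS/PFS into a favorable and an unfavorable
signature, mean-scaled signature scoring, median-split stratification, and
the downstream survival comparisons (overall, combined, per molecular
subgroup, and pre- vs at-progression score shifts).

Published-list mode: the favorable 6-gene and unfavorable 17-gene
signatures reported for CD19 CAR T-cell therapy in large B-cell lymphoma
ship as bundled gene lists ("ges6", "ges17"), together with the
gene-level RNA-seq variants without the CD45 isoform transcripts ("ges5",
"ges16"), so user-prepared expression exports can be scored without
re-running discovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import Cohort, ExpressionMatrix, ENDPOINTS, _check_endpoint
from .coxnet import (
    CVResult,
    PenalizedCoxFit,
    PenaltySpec,
    cross_validate_alpha,
    extract_signed_transcripts,
    fit_penalized_cox,
)
from .survstats import (
    HazardRatioResult,
    KMCurve,
    LogRankResult,
    StatisticsError,
    cox_hr_two_group,
    kaplan_meier,
    logrank_test,
    wilcoxon_rank_sum,
)

PUBLISHED_SIGNATURES = ("ges6", "ges17", "ges5", "ges16")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage cannot run on the given cohort."""


def load_published_signature(name: str) -> list[str]:
    """Load one of the bundled published gene lists (see PUBLISHED_SIGNATURES)."""
    if name not in PUBLISHED_SIGNATURES:
        raise ValueError(f"unknown signature {name!r}; available: {PUBLISHED_SIGNATURES}")
    text = resources.files("gesig.genelists").joinpath(f"{name}.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


# ---------------------------------------------------------------------------
# discovery


@dataclass
class SignaturePair:
    """Cross-endpoint intersection of penalized-Cox-selected transcripts."""

    favorable: list[str]
    unfavorable: list[str]
    per_endpoint: dict[str, dict[str, list[str]]]
    cv: dict[str, CVResult]
    settings: dict
    fits: dict[str, "PenalizedCoxFit"] = None  # refit-at-selected-alpha per endpoint

    def to_dict(self) -> dict:
        """JSON-ready record making a discovery run fully replayable."""
        out = {
            "favorable": self.favorable,
            "unfavorable": self.unfavorable,
            "per_endpoint": self.per_endpoint,
            "settings": self.settings,
            "cv": {
                ep: {
                    "alphas": cv.alphas.tolist(),
                    "mean_c_index": _json_floats(cv.mean_c_index),
                    "fold_c_index": [_json_floats(r) for r in cv.fold_c_index],
                    "selected_alpha": cv.selected_alpha,
                    "n_folds": cv.n_folds,
                    "seed": cv.seed,
                }
                for ep, cv in self.cv.items()
            },
        }
        if self.fits:
            out["coefficients"] = {
                ep: {
                    fit.gene_ids[j]: fit.beta[j]
                    for j in fit.support
                }
                for ep, fit in self.fits.items()
            }
            out["converged"] = {ep: bool(f.converged) for ep, f in self.fits.items()}
        return out


def _json_floats(arr) -> list:
    """Floats with NaN mapped to None for strict-JSON serialization."""
    return [float(v) if np.isfinite(v) else None for v in np.asarray(arr, float)]


def intersect_signed_lists(
    per_endpoint: dict[str, dict[str, list[str]]],
    gene_order: list[str],
    key: str,
) -> list[str]:
    """Genes selected with the same sign for every endpoint, in panel order."""
    common: set[str] | None = None
    for ep in per_endpoint:
        sel = set(per_endpoint[ep][key])
        common = sel if common is None else common & sel
    return [g for g in gene_order if g in (common or set())]


def _model_matrix(expr: ExpressionMatrix, log_transform: bool) -> np.ndarray:
    """Samples x genes modeling matrix (optionally log2(x+1))."""
    X = expr.values.T.copy()
    if log_transform:
        X = np.log2(X + 1.0)
    return X


def derive_signatures(
    cohort: Cohort,
    mixing_r: float = 0.9,
    seed: int = 0,
    n_alphas: int = 100,
    ratio_min: float = 0.01,
    n_folds: int = 5,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    log_transform: bool = False,
    min_events: int = 10,
) -> SignaturePair:
    """Discover favorable/unfavorable signatures by cross-endpoint intersection.

    For each endpoint the eligible subset is taken (samples with the
    endpoint observed or censored; DOR is restricted to responders by
    construction), genes are standardized on that subset, alpha is chosen
    by cross-validated C-index, the model is refit at the selected alpha on
    the full eligible subset, and the non-zero coefficients are split by
    sign.  The favorable signature is the intersection of the three
    per-endpoint favorable lists; likewise for unfavorable.
    """
    per_endpoint: dict[str, dict[str, list[str]]] = {}
    cvs: dict[str, CVResult] = {}
    fits: dict[str, PenalizedCoxFit] = {}
    gene_order = cohort.expression.gene_ids
    X_full = _model_matrix(cohort.expression, log_transform)

    for endpoint in ENDPOINTS:
        mask, t, e = cohort.clinical.endpoint_arrays(endpoint)
        if e.sum() < min_events:
            raise PipelineError(
                f"endpoint {endpoint}: only {int(e.sum())} events "
                f"(need >= {min_events})"
            )
        X = X_full[mask]
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"endpoint {endpoint}: dropped {int((~keep).sum())} zero-variance genes",
                stacklevel=2,
            )
        genes = [g for g, k in zip(gene_order, keep) if k]
        Xk = X[:, keep]
        Xs = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0)
        cv = cross_validate_alpha(
            Xs, t, e, mixing_r=mixing_r, n_folds=n_folds, seed=seed,
            n_alphas=n_alphas, ratio_min=ratio_min, tol=tol, max_iter=max_iter,
        )
        fit = fit_penalized_cox(
            Xs, t, e, PenaltySpec(mixing_r=mixing_r, alpha=cv.selected_alpha),
            tol=tol, max_iter=max_iter, gene_ids=genes,
            feature_sd=Xk.std(axis=0),
        )
        fav, unfav = extract_signed_transcripts(fit)
        per_endpoint[endpoint] = {"favorable": fav, "unfavorable": unfav}
        cvs[endpoint] = cv
        fits[endpoint] = fit

    return SignaturePair(
        favorable=intersect_signed_lists(per_endpoint, gene_order, "favorable"),
        unfavorable=intersect_signed_lists(per_endpoint, gene_order, "unfavorable"),
        per_endpoint=per_endpoint,
        cv=cvs,
        fits=fits,
        settings={
            "mixing_r": mixing_r,
            "seed": seed,
            "n_alphas": n_alphas,
            "ratio_min": ratio_min,
            "n_folds": n_folds,
            "log_transform": log_transform,
            "tol": tol,
        },
    )


# ---------------------------------------------------------------------------
# scoring and stratification


@dataclass
class SignatureScores:
    """Per-sample mean-scaled signature scores, optionally median-split."""

    sample_ids: list[str]
    scores: np.ndarray
    signature_id: str
    scope_note: str
    group: np.ndarray | None = None  # "high"/"low" after median_split
    median: float | None = None

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "score": self.scores})
        df["signature_id"] = self.signature_id
        if self.group is not None:
            df["group"] = self.group
        return df


def score_signature(
    expr: ExpressionMatrix, genes: list[str], signature_id: str = "signature"
) -> SignatureScores:
    """Mean of per-gene z-scores: score_s = (1/m) sum_i (x_is - u_i) / sd_i.

    The gene means u_i and standard deviations sd_i (denominator n - 1) are
    computed over all samples of ``expr`` — the scoring population.  Missing
    genes and zero-variance genes are fatal.
    """
    missing = [g for g in genes if g not in expr.gene_ids]
    if missing:
        raise PipelineError(f"signature genes absent from matrix: {missing}")
    if not genes:
        raise PipelineError("empty signature")
    sub = expr.subset_genes(genes)
    vals = sub.values
    u = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = [g for g, s in zip(genes, sd.ravel()) if s == 0]
    if flat:
        raise PipelineError(f"zero standard deviation for signature genes: {flat}")
    scores = ((vals - u) / sd).mean(axis=0)
    return SignatureScores(
        sample_ids=list(expr.sample_ids),
        scores=scores,
        signature_id=signature_id,
        scope_note=f"means/SDs from all {expr.n_samples} samples of the scoring population",
    )


def median_split(scores: SignatureScores, median: float | None = None) -> SignatureScores:
    """Assign high (> median) / low (<= median) groups.

    By default the median comes from the scoring population itself; for
    subgroup analyses pass the median computed on the entire dataset.
    """
    if len(scores.sample_ids) < 2:
        raise PipelineError("median split needs at least two samples")
    med = float(np.median(scores.scores)) if median is None else float(median)
    group = np.where(scores.scores > med, "high", "low")
    return SignatureScores(
        sample_ids=scores.sample_ids,
        scores=scores.scores,
        signature_id=scores.signature_id,
        scope_note=scores.scope_note,
        group=group,
        median=med,
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class SurvivalComparison:
    """High-vs-low survival comparison for one endpoint."""

    endpoint: str
    km_high: KMCurve
    km_low: KMCurve
    logrank: LogRankResult
    hazard_ratio: HazardRatioResult
    n_high: int
    n_low: int
    signature_id: str = ""


def evaluate_signature(
    cohort: Cohort,
    scores: SignatureScores,
    endpoint: str,
    min_samples: int = 10,
) -> SurvivalComparison:
    """KM curves, log-rank test and unstratified Cox HR for high vs low."""
    _check_endpoint(endpoint)
    if scores.group is None:
        raise PipelineError("scores must be median-split before evaluation")
    score_map = dict(zip(scores.sample_ids, scores.group))
    mask, t, e = cohort.clinical.endpoint_arrays(endpoint)
    ids = [s for s, m in zip(cohort.sample_ids, mask) if m]
    grp = np.array([score_map.get(s) for s in ids], dtype=object)
    if any(g is None for g in grp):
        raise PipelineError("some endpoint samples have no signature score")
    if len(ids) < min_samples:
        raise PipelineError(
            f"endpoint {endpoint} available for only {len(ids)} scored samples"
        )
    high = grp == "high"
    if high.all() or not high.any():
        raise PipelineError("one group is empty after endpoint restriction")
    return SurvivalComparison(
        endpoint=endpoint,
        km_high=kaplan_meier(t[high], e[high]),
        km_low=kaplan_meier(t[~high], e[~high]),
        logrank=logrank_test(t[high], e[high], t[~high], e[~high]),
        hazard_ratio=cox_hr_two_group(high, t, e),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        signature_id=scores.signature_id,
    )


@dataclass
class CombinedGroups:
    """Cross-classification of two median-split score sets."""

    sample_ids: list[str]
    labels: np.ndarray  # e.g. "A-high/B-low"
    level_names: list[str]
    counts: dict[str, int]


def combine_signatures(
    scores_a: SignatureScores, scores_b: SignatureScores,
    name_a: str = "A", name_b: str = "B",
) -> CombinedGroups:
    """Four-level grouping from two median-split signatures on the same samples."""
    if scores_a.group is None or scores_b.group is None:
        raise PipelineError("both score sets must be median-split")
    if scores_a.sample_ids != scores_b.sample_ids:
        raise PipelineError("score sets cover different samples")
    labels = np.array(
        [
            f"{name_a}-{ga}/{name_b}-{gb}"
            for ga, gb in zip(scores_a.group, scores_b.group)
        ],
        dtype=object,
    )
    level_names = [
        f"{name_a}-{ga}/{name_b}-{gb}"
        for ga in ("high", "low")
        for gb in ("high", "low")
    ]
    counts = {lv: int((labels == lv).sum()) for lv in level_names}
    return CombinedGroups(
        sample_ids=list(scores_a.sample_ids),
        labels=labels,
        level_names=level_names,
        counts=counts,
    )


def evaluate_combined_groups(
    cohort: Cohort, combined: CombinedGroups, endpoint: str,
    reference: str | None = None, min_samples: int = 5,
) -> dict[str, LogRankResult]:
    """Pairwise log-rank of each combined level against a reference level."""
    _check_endpoint(endpoint)
    label_map = dict(zip(combined.sample_ids, combined.labels))
    mask, t, e = cohort.clinical.endpoint_arrays(endpoint)
    ids = [s for s, m in zip(cohort.sample_ids, mask) if m]
    lab = np.array([label_map[s] for s in ids], dtype=object)
    nonempty = [lv for lv in combined.level_names if (lab == lv).sum() >= min_samples]
    if reference is None:
        reference = nonempty[0]
    out: dict[str, LogRankResult] = {}
    ref = lab == reference
    for lv in nonempty:
        if lv == reference:
            continue
        sel = lab == lv
        out[lv] = logrank_test(t[ref], e[ref], t[sel], e[sel])
    return out


def subgroup_analysis(
    cohort: Cohort,
    scores: SignatureScores,
    subgroup_field: str = "coo",
    endpoint: str = "PFS",
    min_samples: int = 10,
) -> dict[str, SurvivalComparison | None]:
    """Evaluate high vs low within each level of a clinical subgroup.

    The caller must have median-split the scores with the median of the
    entire dataset (not per subgroup); levels with too few endpoint-available
    samples are skipped (None) with a warning.
    """
    if scores.group is None:
        raise PipelineError("scores must be median-split before subgroup analysis")
    if subgroup_field not in cohort.clinical.data.columns:
        raise PipelineError(f"unknown subgroup field {subgroup_field!r}")
    levels = [
        lv for lv in pd.unique(cohort.clinical.data[subgroup_field]) if pd.notna(lv)
    ]
    out: dict[str, SurvivalComparison | None] = {}
    for lv in levels:
        ids = cohort.clinical.data.loc[
            cohort.clinical.data[subgroup_field] == lv, "sample_id"
        ].tolist()
        sub_cohort = cohort.subset_samples(ids)
        keep = [s in set(ids) for s in scores.sample_ids]
        sub_scores = SignatureScores(
            sample_ids=[s for s, k in zip(scores.sample_ids, keep) if k],
            scores=scores.scores[np.asarray(keep)],
            signature_id=scores.signature_id,
            scope_note=scores.scope_note,
            group=scores.group[np.asarray(keep)],
            median=scores.median,
        )
        try:
            out[str(lv)] = evaluate_signature(
                sub_cohort, sub_scores, endpoint, min_samples=min_samples
            )
        except (PipelineError, StatisticsError) as exc:
            warnings.warn(f"subgroup {lv!r} skipped: {exc}", stacklevel=2)
            out[str(lv)] = None
    return out


# ---------------------------------------------------------------------------
# progression comparison


@dataclass
class ProgressionComparison:
    """Wilcoxon rank-sum comparison of signature scores pre vs at progression."""

    signature_id: str
    statistic: float
    p_value: float
    n_pre: int
    n_post: int
    median_pre: float
    median_post: float
    direction: str  # "increased" | "decreased" | "unchanged" at progression
    low_power: bool
    scope_note: str


def score_pre_post(
    pre_expr: ExpressionMatrix, post_expr: ExpressionMatrix, genes: list[str],
    signature_id: str = "signature",
) -> tuple[SignatureScores, SignatureScores]:
    """Score two sample sets with pooled means/SDs (one scoring population)."""
    shared = set(pre_expr.sample_ids) & set(post_expr.sample_ids)
    if shared:
        raise PipelineError(f"pre/post sample sets overlap: {sorted(shared)[:5]}")
    if pre_expr.gene_ids != post_expr.gene_ids:
        raise PipelineError("pre/post matrices must share the same gene panel")
    pooled = ExpressionMatrix(
        gene_ids=list(pre_expr.gene_ids),
        sample_ids=list(pre_expr.sample_ids) + list(post_expr.sample_ids),
        values=np.concatenate([pre_expr.values, post_expr.values], axis=1),
        unit_label=pre_expr.unit_label,
    )
    pooled_scores = score_signature(pooled, genes, signature_id=signature_id)
    n_pre = pre_expr.n_samples
    note = (
        f"means/SDs pooled over {n_pre} pretreatment + "
        f"{post_expr.n_samples} progression samples"
    )
    pre = SignatureScores(
        sample_ids=list(pre_expr.sample_ids),
        scores=pooled_scores.scores[:n_pre],
        signature_id=signature_id,
        scope_note=note,
    )
    post = SignatureScores(
        sample_ids=list(post_expr.sample_ids),
        scores=pooled_scores.scores[n_pre:],
        signature_id=signature_id,
        scope_note=note,
    )
    return pre, post


def progression_comparison(
    pre_scores: SignatureScores, post_scores: SignatureScores
) -> ProgressionComparison:
    """Two-sided Wilcoxon rank-sum of progression vs pretreatment scores."""
    x = np.asarray(post_scores.scores, float)
    y = np.asarray(pre_scores.scores, float)
    if x.size == 0 or y.size == 0:
        raise PipelineError("both sample sets must be non-empty")
    stat, p = wilcoxon_rank_sum(x, y)
    med_pre = float(np.median(y))
    med_post = float(np.median(x))
    if med_post > med_pre:
        direction = "increased"
    elif med_post < med_pre:
        direction = "decreased"
    else:
        direction = "unchanged"
    return ProgressionComparison(
        signature_id=pre_scores.signature_id,
        statistic=float(stat),
        p_value=float(p),
        n_pre=int(y.size),
        n_post=int(x.size),
        median_pre=med_pre,
        median_post=med_post,
        direction=direction,
        low_power=min(x.size, y.size) < 5,
        scope_note=pre_scores.scope_note,
    )
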