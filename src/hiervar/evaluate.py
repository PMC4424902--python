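"""ROC evaluation of variant rankings against latent causal status.

Reproduces the headline comparison: ROC curves and AUCs of the
hierarchical z-value ranking versus the C-score-only baseline (scores
of variants carried by at least one case; all other variants rank
last), averaged over simulation replicates for each strength of the
score-causal association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .io import (
    AnnotationTable,
    GenotypeMatrix,
    PhenotypeTable,
    check_aligned,
)
from .model import HierarchicalShrinkageRanker
from .simulate import (
    CausalModelParams,
    assign_causal,
    dichotomize,
    generate_cscores,
    generate_genotypes,
    simulate_phenotype,
)

logger = logging.getLogger(__name__)

#: Number of equispaced FPR gridpoints used for vertical ROC averaging.
FPR_GRID_SIZE = 101


@dataclass
class RocResult:
    """One ROC curve: FPR/TPR points plus the tie-aware AUC."""

    method: str
    rr_config: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC curve must be non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0):
            raise ValueError("ROC curve must start at (0, 0)")
        if not (self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ValueError("ROC curve must end at (1, 1)")


@dataclass
class ComparisonSummary:
    """Replicate-averaged AUCs and vertically averaged curves per method/config."""

    table: pd.DataFrame  # method, rr_config, mean_auc, mc_se_auc, n_replicates
    curves: pd.DataFrame  # method, rr_config, fpr, tpr (averaged on the grid)
    n_skipped: int = 0


def mann_whitney_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC as the tie-aware Mann-Whitney concordance probability.

    Fraction of (causal, non-causal) pairs ranked concordantly, with
    half credit for ties; identical to the trapezoidal area under the
    full ROC step curve.
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth)
    n1 = int(truth.sum())
    n0 = len(truth) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one causal and one non-causal variant")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    return float((ranks[truth == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_from_scores(
    scores: np.ndarray,
    truth: np.ndarray,
    method: str = "",
    rr_config: float = float("nan"),
) -> RocResult:
    """Full ROC step curve (no dropped thresholds) with Mann-Whitney AUC."""
    truth = np.asarray(truth)
    if truth.sum() == 0 or truth.sum() == len(truth):
        raise ValueError("need at least one causal and one non-causal variant")
    fpr, tpr, _ = skm.roc_curve(truth, scores, drop_intermediate=False)
    return RocResult(method, rr_config, fpr, tpr, mann_whitney_auc(scores, truth))


def cscore_baseline_scores(
    scores: AnnotationTable,
    genotypes: GenotypeMatrix,
    labels: PhenotypeTable,
) -> tuple[np.ndarray, np.ndarray]:
    """C-score ranking restricted to variants carried by at least one case.

    Variants never carried by a case receive a sentinel strictly below
    the minimum score so they rank last (keeping the variant universe —
    and hence the ROC truth denominator — identical across methods).
    Returns ``(baseline_scores, carried_in_case)`` aligned to the
    genotype variant order.
    """
    check_aligned(genotypes, scores)
    aligned = scores.reindex(list(genotypes.variant_ids))
    case = labels.case_status.astype(bool)
    carried = ((genotypes.dosages > 0) & case[:, None]).any(axis=0)
    out = aligned.scores.copy()
    sentinel = aligned.scores.min() - 1.0
    out[~carried] = sentinel
    return out, carried


def average_roc(curves: list[RocResult], grid_size: int = FPR_GRID_SIZE) -> dict:
    """Vertical averaging on a fixed FPR grid.

    Each step curve is evaluated right-continuously at the gridpoints
    (the achieved TPR at FPR <= gridpoint); TPRs are averaged pointwise
    and per-replicate AUCs are averaged arithmetically with a
    Monte-Carlo standard error sd/sqrt(R).
    """
    if not curves:
        raise ValueError("need at least one curve")
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = np.empty((len(curves), grid_size))
    for i, c in enumerate(curves):
        idx = np.searchsorted(c.fpr, grid, side="right") - 1
        tprs[i] = c.tpr[np.maximum(idx, 0)]
    aucs = np.array([c.auc for c in curves])
    return {
        "fpr_grid": grid,
        "mean_tpr": tprs.mean(axis=0),
        "mean_auc": float(aucs.mean()),
        "mc_se_auc": float(aucs.std(ddof=1) / np.sqrt(len(aucs))) if len(aucs) > 1 else 0.0,
        "n_replicates": len(curves),
    }


def _replicate_seed_sequence(master_seed: int, rr: float, rep: int) -> np.random.SeedSequence:
    """Counter-based child stream keyed by (RR config, replicate index).

    Keying by the RR value (not its position in the grid) means adding
    a configuration never perturbs another configuration's draws.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(int(round(rr * 1000)), rep))


def run_experiment(config) -> dict:
    """Run the full simulation-evaluation grid.

    For each configured score-causal relative risk and each replicate:
    draw (or reuse) the cohort, assign causal status, simulate the
    phenotype and median-split labels, fit the hierarchical model, and
    compute ROC/AUC for both the hierarchical z-ranking and the C-score
    baseline against the replicate's latent causal truth. Failed
    replicates are skipped (more than 10% skipped in a configuration is
    an error).

    Returns a dict with the summary/ROC/fit DataFrames (matching the
    writer's column contracts) and per-replicate AUCs.
    """
    from .config import SimulationConfig  # local import to avoid cycle

    assert isinstance(config, SimulationConfig)
    config.validate()
    cohort = config.cohort
    fixed_geno = fixed_scores = None
    if config.fix_cohort:
        ss = np.random.SeedSequence(config.master_seed, spawn_key=(0,))
        rg, rs = (np.random.default_rng(c) for c in ss.spawn(2))
        fixed_geno = generate_genotypes(cohort, rng=rg)
        fixed_scores = generate_cscores(
            cohort.n_variants, cohort.score_shape, cohort.score_scale,
            rng=rs, variant_ids=list(fixed_geno.variant_ids),
        )

    summary_rows = []
    curve_rows = []
    fit_rows = []
    auc_records = []
    total_skipped = 0
    for rr in config.rr_grid:
        causal = CausalModelParams(
            causal_fraction=config.causal_fraction,
            score_rr=rr, mu=config.mu, sd_carrier=config.sd_carrier,
        )
        curves_h: list[RocResult] = []
        curves_b: list[RocResult] = []
        skipped = 0
        for rep in range(config.replicates):
            ss = _replicate_seed_sequence(config.master_seed, rr, rep)
            rng_g, rng_s, rng_c, rng_p = (np.random.default_rng(c) for c in ss.spawn(4))
            try:
                if config.fix_cohort:
                    geno, scores = fixed_geno, fixed_scores
                else:
                    geno = generate_genotypes(cohort, rng=rng_g)
                    scores = generate_cscores(
                        cohort.n_variants, cohort.score_shape, cohort.score_scale,
                        rng=rng_s, variant_ids=list(geno.variant_ids),
                    )
                truth = assign_causal(scores, causal, rng=rng_c)
                if truth.is_causal.sum() in (0, len(truth.is_causal)):
                    raise ValueError("degenerate causal assignment")
                phen = simulate_phenotype(geno, truth, causal, rng=rng_p)
                phen.case_status = dichotomize(phen.y_continuous)
                est = HierarchicalShrinkageRanker(
                    penalty=config.penalty,
                    penalty_strength=config.penalty_strength,
                    tau2=config.tau2,
                    diag_v=config.diag_v,
                )
                est.fit(
                    geno.dosages, phen.case_status, scores=scores.scores,
                    variant_ids=list(geno.variant_ids),
                )
                base, carried = cscore_baseline_scores(scores, geno, phen)
                ch = roc_from_scores(est.z_, truth.is_causal, "hierarchical", rr)
                cb = roc_from_scores(base, truth.is_causal, "cscore_only", rr)
            except Exception as exc:  # noqa: BLE001 - replicate isolation
                skipped += 1
                logger.warning("skipping replicate %d at rr=%s: %s", rep, rr, exc)
                continue
            curves_h.append(ch)
            curves_b.append(cb)
            if len(curves_h) == 1:
                # per-variant table from the first successful replicate
                for j, vid in enumerate(geno.variant_ids):
                    fit_rows.append({
                        "variant_id": vid,
                        "score": scores.scores[j],
                        "true_causal": int(truth.is_causal[j]),
                        "beta_hat": est.beta_hat_[j],
                        "beta_tilde": est.beta_tilde_[j],
                        "se": est.se_[j],
                        "z": est.z_[j],
                        "carried_in_case": int(carried[j]),
                    })
        if skipped > 0.10 * config.replicates:
            raise RuntimeError(
                f"more than 10% of replicates failed at rr={rr} ({skipped} skipped)"
            )
        total_skipped += skipped
        for method, curves in (("hierarchical", curves_h), ("cscore_only", curves_b)):
            avg = average_roc(curves)
            summary_rows.append({
                "method": method, "rr_config": rr,
                "mean_auc": avg["mean_auc"], "mc_se_auc": avg["mc_se_auc"],
                "n_replicates": avg["n_replicates"],
            })
            for f, t in zip(avg["fpr_grid"], avg["mean_tpr"]):
                curve_rows.append({
                    "method": method, "rr_config": rr, "fpr": f, "tpr": t,
                })
            auc_records.append({
                "method": method, "rr_config": rr,
                "aucs": np.array([c.auc for c in curves]),
            })

    return {
        "summary": pd.DataFrame(summary_rows),
        "roc": pd.DataFrame(curve_rows),
        "fit": pd.DataFrame(fit_rows),
        "aucs": auc_records,
        "n_skipped": total_skipped,
    }


def plot_roc(roc_table: pd.DataFrame, path) -> None:
    """ROC figure: solid = hierarchical, dashed = C-score baseline.

    Colors follow the association strength (blue = weakest RR, then
    green, red for the default grid).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    palette = ["tab:blue", "tab:green", "tab:red", "tab:purple", "tab:orange"]
    rrs = sorted(roc_table["rr_config"].unique())
    fig, ax = plt.subplots(figsize=(6, 6))
    for i, rr in enumerate(rrs):
        color = palette[i % len(palette)]
        for method, style in (("hierarchical", "-"), ("cscore_only", "--")):
            sub = roc_table[
                (roc_table["rr_config"] == rr) & (roc_table["method"] == method)
            ]
            label = f"RR={rr} ({'hierarchical z' if method == 'hierarchical' else 'C-score only'})"
            ax.plot(sub["fpr"], sub["tpr"], style, color=color, label=label)
    ax.plot([0, 1], [0, 1], color="0.7", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
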