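"""End-to-end pipeline: simulate a cohort, score it, estimate posteriors,
summarize reliability and fit the latent factor models, writing one
directory of report tables plus a run manifest."""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import battery_io, bayes, cohort, latent, reliability, scoring

logger = logging.getLogger(__name__)


def group_posterior_table(
    sessions: list[cohort.SessionRecord],
    conditions=None,
    draws: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Group-level posterior mean and 95% CI per battery condition and day."""
    conditions = conditions or latent.FEATURE_COLUMNS
    lookup = {}
    for s in sessions:
        lookup[(s.participant_id, s.day, s.task)] = s
    pids = sorted({s.participant_id for s in sessions})
    rng = np.random.default_rng(seed)
    rows = []
    for name, task, condition, metric in conditions:
        for day in sorted({s.day for s in sessions}):
            ests = []
            for pid in pids:
                sess = lookup.get((pid, day, task))
                if sess is None:
                    continue
                est = reliability.participant_estimate(
                    sess, condition, metric, draws, int(rng.integers(2**31))
                )
                if est is not None:
                    ests.append(est)
            if not ests:
                continue
            g = bayes.group_average(ests)
            rows.append(
                {
                    "condition": name,
                    "metric": metric,
                    "day": day,
                    "mean": g.mean,
                    "ci_low": g.ci_low,
                    "ci_high": g.ci_high,
                    "n_participants": len(ests),
                }
            )
    return pd.DataFrame(rows)


def run_demo(
    outdir: str | Path,
    n_participants: int = 50,
    seed: int = 1,
    draws: int = 2000,
    k_components: int = 6,
    cohort_config: dict | None = None,
    make_plots: bool = False,
) -> dict:
    """Run the full battery pipeline on a synthetic two-day cohort.

    Writes sessions, scores, posteriors, reliability tables and factor
    loadings under ``outdir`` and returns the run manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    profiles = cohort.sample_cohort(
        n_participants, config=cohort_config, seed=int(rng.integers(2**31))
    )
    sessions = cohort.simulate_study(
        profiles, seed=int(rng.integers(2**31)), config=cohort_config
    )
    battery_io.write_sessions(sessions, outdir / "sessions.csv")

    scores = scoring.score_table(sessions)
    battery_io.write_scores(scores, outdir / "scores.csv")

    posteriors = group_posterior_table(
        sessions, draws=draws, seed=int(rng.integers(2**31))
    )
    battery_io._atomic_write_text(
        outdir / "posteriors.csv", posteriors.to_csv(index=False, lineterminator="\n")
    )

    ages = {p.participant_id: p.age for p in profiles}
    report = reliability.reliability_report(
        sessions, ages=ages, draws=draws, seed=int(rng.integers(2**31))
    )
    pearson_df = pd.DataFrame(
        [{"task": t, "pearson_r": r} for t, r in sorted(report.pearson_r.items())]
    )
    battery_io._atomic_write_text(
        outdir / "pearson.csv", pearson_df.to_csv(index=False, lineterminator="\n")
    )
    diff_df = pd.DataFrame(
        [
            {
                "condition": d.condition,
                "metric": d.kind,
                "mean_diff": d.mean_diff,
                "hdi_low": d.hdi_low,
                "hdi_high": d.hdi_high,
                "contains_zero": d.contains_zero,
            }
            for d in report.differences
        ]
    )
    battery_io._atomic_write_text(
        outdir / "crossday_differences.csv", diff_df.to_csv(index=False, lineterminator="\n")
    )

    X = latent.build_feature_matrix(scores)
    pca = latent.fit_pca(X, k=k_components)
    ica = latent.fit_ica(X, k=k_components, seed=int(rng.integers(2**31)), restarts=8)
    tree = latent.cluster_loadings(pca)
    pca.loadings.to_csv(outdir / "pca_loadings.csv")
    ica.loadings.to_csv(outdir / "ica_loadings.csv")
    pd.DataFrame(
        {"component": np.arange(1, len(pca.scree) + 1), "explained_variance_pct": pca.scree}
    ).to_csv(outdir / "scree.csv", index=False)
    np.savetxt(outdir / "loading_linkage.csv", tree.linkage, delimiter=",")

    if make_plots:
        from . import plots

        if "mot" in report.bland_altman:
            plots.bland_altman_plot(
                report.bland_altman["mot"], title="mot", path=outdir / "bland_altman_mot.png"
            )
        plots.scree_plot(pca, path=outdir / "scree.png")
        plots.loading_dendrogram(tree, path=outdir / "dendrogram.png")

    manifest = {
        "seed": seed,
        "n_participants": n_participants,
        "draws": draws,
        "k_components": k_components,
        "config_hash": battery_io.config_hash(cohort_config or {}),
        "python": platform.python_version(),
        "n_sessions": len(sessions),
        "n_trials": int(sum(len(s.trials) for s in sessions)),
        "n_score_rows": int(len(scores)),
        "n_observations": int(X.data.shape[0]),
        "n_variables": int(X.data.shape[1]),
        "n_stable": report.n_stable,
        "n_conditions": report.n_conditions,
        "pca_top6_variance_pct": float(np.sum(pca.scree[:k_components])),
    }
    battery_io._atomic_write_text(
        outdir / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info(
        "demo run complete: %d sessions, %d trials, config %s",
        manifest["n_sessions"], manifest["n_trials"], manifest["config_hash"],
    )
    return manifest
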