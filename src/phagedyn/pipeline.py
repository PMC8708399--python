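"""End-to-end orchestration: read → adjust → score → anova → ordinate →
classify → repeatability → report.

A :class:`PipelineConfig` is fully serialisable; a run archives its config
next to the outputs, every output file carries the config hash and seed in
a leading comment line, and identical config + inputs give identical
outputs.  All randomness flows from one top-level seed expanded into
per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, ordination, scoring
from .anova import GrowthFactorModel
from .curves import PlateExperiment, baseline_adjust, read_plate_table, write_scores_table
from .features import extract_pattern_features

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, provenance: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r} ({provenance}): {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    plate_paths: tuple = ()            # (plate_csv, metadata_tsv) pairs
    out_dir: str = "phagedyn_out"
    baseline_mode: str = "blank_timewise"
    nmds_k: int = 2
    nmds_restarts: int = 20
    nmds_max_iter: int = 300
    nmds_tol: float = 1e-7
    cluster_k: int | None = None       # None -> gap-statistic selection
    k_sub: int | None = 5              # None -> gap-statistic selection in 3..6
    gap_b: int = 100
    n_perm: int = 999
    od_thresh: float = 0.1
    kill_thresh: float = 0.1
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("nmds", "select_k", "subcluster", "envfit")
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _write_tsv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# phagedyn {stamp}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig,
                 plates: list[PlateExperiment] | None = None) -> Path:
    """Run every stage and write the output directory.

    ``plates`` may be passed directly (e.g. fresh from the simulator);
    otherwise they are read from ``config.plate_paths``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config={config.config_hash()} seed={config.seed}"
    seeds = _stage_seeds(config.seed)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                     "stage_seeds": seeds}

    def stage(name, provenance, fn):
        try:
            res = fn()
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, provenance, e) from e
        return res

    # --- read ---------------------------------------------------------
    if plates is None:
        def _read():
            got = []
            for plate_csv, meta_tsv in config.plate_paths:
                got.append(read_plate_table(plate_csv, meta_tsv))
            if not got:
                raise ValueError("no input plates configured")
            return got
        plates = stage("read", str([p for p, _ in config.plate_paths]), _read)
    logger.info("read: %d plates, %d curves", len(plates),
                sum(len(p.curves) for p in plates))

    # --- baseline adjust ---------------------------------------------
    adjusted = stage(
        "baseline_adjust", "plates",
        lambda: [p if p.adjusted else baseline_adjust(p, config.baseline_mode)
                 for p in plates],
    )

    # --- score --------------------------------------------------------
    def _score():
        results = []
        for p in adjusted:
            results.extend(scoring.score_plate(p))
        return results
    results = stage("score", "adjusted plates", _score)
    write_scores_table(results, out / "scores.tsv")
    agg = scoring.aggregate_scores(results)
    _write_tsv(agg, out / "scores_aggregate.tsv", stamp)
    corr = scoring.score_correlation(results)
    summary["score_correlation"] = corr
    summary["n_scores"] = len(results)
    logger.info("score: %d results, r(PhageScore, virulence)=%.3f", len(results), corr)

    # --- anova --------------------------------------------------------
    scores_df = pd.DataFrame(
        {
            "phage_id": [r.key.phage_id for r in results],
            "bacterium_id": [r.key.bacterium_id for r in results],
            "moi": [r.key.moi for r in results],
            "phage_score": [r.phage_score for r in results],
            "virulence_score": [r.virulence_score for r in results],
        }
    )
    summary["anova"] = {}
    for resp in ("phage_score", "virulence_score"):
        table = stage(
            "anova", resp,
            lambda resp=resp: GrowthFactorModel.from_dataframe(scores_df, resp).fit(),
        )
        _write_tsv(table.to_frame(), out / f"anova_{resp}.tsv", stamp)
        summary["anova"][resp] = {
            t: {"df": d, "F": f, "p": p}
            for t, d, f, p in zip(table.terms, table.df, table.f, table.p)
        }

    # --- ordinate -----------------------------------------------------
    analysis = [c for p in adjusted for c in p.curves
                if c.key.role in ("treatment", "bacteria_control")]
    d = ordination.curve_distance_matrix(analysis)
    ordr = stage(
        "ordinate", f"{len(analysis)} curves",
        lambda: ordination.nmds(
            d, k=config.nmds_k, n_restarts=config.nmds_restarts,
            max_iter=config.nmds_max_iter, tol=config.nmds_tol,
            seed=seeds["nmds"],
        ),
    )
    coords = pd.DataFrame(
        {
            "phage_id": [c.key.phage_id for c in analysis],
            "bacterium_id": [c.key.bacterium_id for c in analysis],
            "moi": [c.key.moi for c in analysis],
            "replicate": [c.key.replicate for c in analysis],
            "role": [c.key.role for c in analysis],
            **{f"axis{i + 1}": ordr.coords[:, i] for i in range(config.nmds_k)},
        }
    )
    _write_tsv(coords, out / "coordinates.tsv", stamp)
    summary["stress"] = ordr.stress
    summary["stress_quality"] = ordr.fit_quality
    logger.info("ordinate: n=%d stress=%.4f (%s)", len(analysis), ordr.stress,
                ordr.fit_quality)

    # envfit of the three factors (treatment wells only, which all carry
    # a phage, a bacterium and a positive MOI)
    trt_idx = [i for i, c in enumerate(analysis) if c.key.role == "treatment"]
    trt_res = ordination.OrdinationResult(
        coords=ordr.coords[trt_idx], stress=ordr.stress,
        n_restarts_used=ordr.n_restarts_used, seed=ordr.seed,
        converged=ordr.converged,
    )
    fits = []
    for name, vals in (
        ("phage", [analysis[i].key.phage_id for i in trt_idx]),
        ("bacterium", [analysis[i].key.bacterium_id for i in trt_idx]),
        ("moi", [analysis[i].key.moi for i in trt_idx]),
    ):
        ff = ordination.envfit_factor(trt_res, vals, name=name,
                                      n_perm=config.n_perm, seed=seeds["envfit"])
        fits.append({"variable": name, "kind": "categorical",
                     "r_squared": ff.r_squared, "p_perm": ff.p_perm})
    fv = ordination.envfit_vector(
        trt_res, np.log10([analysis[i].key.moi for i in trt_idx]),
        name="log10_moi", n_perm=config.n_perm, seed=seeds["envfit"],
    )
    fits.append({"variable": "log10_moi", "kind": "vector",
                 "r_squared": fv.r_squared, "p_perm": fv.p_perm})
    _write_tsv(pd.DataFrame(fits), out / "factor_fits.tsv", stamp)
    summary["envfit"] = fits

    pca = ordination.pca_variance(analysis, k=config.nmds_k)
    summary["pca_cumulative_fraction"] = pca.cumulative_fraction

    # --- classify -----------------------------------------------------
    def _classify():
        k = config.cluster_k
        if k is None:
            k = clustering.select_k(d, k_max=8, B=config.gap_b,
                                    seed=seeds["select_k"])
        assigns = clustering.assign_groups(
            analysis, k, config.od_thresh, config.kill_thresh
        )
        g3_idx = [i for i, a in enumerate(assigns) if a.group == 3]
        if g3_idx:
            subs = clustering.subcluster_group3(
                [analysis[i] for i in g3_idx],
                k_sub=config.k_sub or 5, auto_k=config.k_sub is None,
                B=config.gap_b, seed=seeds["subcluster"],
                od_thresh=config.od_thresh, kill_thresh=config.kill_thresh,
            )
            for i, s in zip(g3_idx, subs):
                assigns[i] = clustering.ClusterAssignment(
                    assigns[i].key, 3, s
                )
        return k, assigns
    k_used, assigns = stage("classify", f"{len(analysis)} curves", _classify)
    adf = pd.DataFrame(
        {
            "phage_id": [a.key.phage_id for a in assigns],
            "bacterium_id": [a.key.bacterium_id for a in assigns],
            "moi": [a.key.moi for a in assigns],
            "replicate": [a.key.replicate for a in assigns],
            "role": [a.key.role for a in assigns],
            "group": [a.group for a in assigns],
            "subgroup": [a.subgroup for a in assigns],
        }
    )
    _write_tsv(adf, out / "assignments.tsv", stamp)
    group_sizes = adf.groupby("group").size().to_dict()
    subgroup_sizes = (
        adf[adf["group"] == 3].groupby("subgroup").size().to_dict()
    )
    summary["k_selected"] = int(k_used)
    summary["group_sizes"] = {str(k): int(v) for k, v in group_sizes.items()}
    summary["subgroup_sizes"] = {str(k): int(v) for k, v in subgroup_sizes.items()}
    logger.info("classify: k=%d group sizes=%s", k_used, group_sizes)

    # mean curve per group (pattern overview)
    grid = analysis[0].grid
    mean_rows = {"time_h": grid.times}
    labels = [f"{a.group}" if a.subgroup == "none" else a.subgroup for a in assigns]
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        mean_rows[f"group_{lab}"] = np.mean([analysis[i].od for i in idx], axis=0)
    _write_tsv(pd.DataFrame(mean_rows), out / "group_mean_curves.tsv", stamp)

    # --- repeatability ------------------------------------------------
    trt_assigns = [a for a in assigns if a.key.role == "treatment"]
    rep = stage("repeatability", f"{len(trt_assigns)} assignments",
                lambda: clustering.repeatability(trt_assigns))
    _write_tsv(rep.per_combination, out / "repeatability.tsv", stamp)
    summary["n_discrepant_combinations"] = rep.n_discrepant
    logger.info("repeatability: %d discrepant combinations", rep.n_discrepant)

    # --- report -------------------------------------------------------
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=str)
    report = [
        f"phagedyn pipeline report ({stamp})",
        f"plates: {len(plates)}  curves analysed: {len(analysis)}",
        f"score correlation (PhageScore vs virulence): {corr:.3f}",
        f"NMDS stress: {summary['stress']:.4f} ({summary['stress_quality']})",
        f"PCA variance captured (first {config.nmds_k}): "
        f"{100 * summary['pca_cumulative_fraction']:.1f}%",
        f"clusters: k={k_used}, group sizes {summary['group_sizes']}, "
        f"subgroups {summary['subgroup_sizes']}",
        f"repeatability: {rep.n_discrepant} discrepant combinations",
    ]
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return out
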