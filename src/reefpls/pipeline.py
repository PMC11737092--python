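"""End-to-end pipeline driver: simulate/load -> filter -> CLR -> community
summaries -> Mantel screen -> MINT sPLS + LOGOCV -> per-trip CV stability.

Every stage writes plain TSV outputs into the run directory and records its
seed and wall time in ``run_log.json``; rerunning with the same config and
master seed reproduces the numeric outputs byte for byte.  Input files are
never modified.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as _io
from .containers import CountTable, EnvTable
from .community import (pairwise_wilcoxon, pca, permanova_pairwise, shannon,
                        euclidean_matrix, within_site_similarity)
from .mantel import mantel_screen
from .mint import MintSparsePLS, logocv_stability, stable_indicator_report
from .preprocess import clr_transform, filter_features, impute_env_by_trip_median
from .simulate import SimConfig, generate
from .spls import SparsePLS, similarity_matrix
from .stability import (build_model_grid, compare_stability, cv_stability,
                        model_inputs)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    outdir: str = "reefpls_run"
    input_dir: Optional[str] = None          # None -> simulate
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    # preprocessing
    pseudocount: float = 1.0
    min_rel_abundance: float = 1e-6
    # stage toggles
    run_community: bool = True
    run_mantel: bool = True
    run_mint: bool = True
    run_stability: bool = True
    # analysis settings
    keep_y: int = 50
    n_components: int = 2
    mantel_permutations: int = 999
    permanova_permutations: int = 999
    cv_folds: int = 4
    cv_repeats: int = 50

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "sim" in data and isinstance(data["sim"], dict):
            data["sim"] = SimConfig(**data["sim"])
        return cls(**data)


def _effective_keep(requested: int, n_features: int) -> int:
    return min(requested, n_features)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all enabled stages; returns the run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": _config_dict(cfg), "stages": []}
    master = np.random.SeedSequence(cfg.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(
                       ("simulate", "permanova", "mantel", "stability"),
                       master.spawn(4))}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log["stages"].append({
                "name": name,
                "seconds": round(time.perf_counter() - t0, 3),
                "seed": stage_seeds.get(name),
            })
        return wrap

    state: dict = {}

    @stage("input")
    def _input():
        if cfg.input_dir is None:
            # the generator's own seed field governs the data draw so that a
            # dataset can be pinned independently of the analysis seeds
            ds = generate(cfg.sim)
            state["taxa"], state["go"], state["env"] = (
                ds.taxa_counts, ds.go_counts, ds.env)
        else:
            state["taxa"], state["go"], state["env"] = _io.read_dataset(cfg.input_dir)

    @stage("preprocess")
    def _preprocess():
        for label in ("taxa", "go"):
            table, report = filter_features(
                state[label], min_rel_abundance=cfg.min_rel_abundance)
            state[label] = table
            report.to_csv(outdir / f"filter_report_{label}.tsv", sep="\t",
                          index=False)
            clr = clr_transform(table, pseudocount=cfg.pseudocount)
            state[f"clr_{label}"] = clr
            clr.values.to_csv(outdir / f"clr_{label}.tsv", sep="\t")
        state["env"] = impute_env_by_trip_median(state["env"])
        _io.write_env_table(state["env"], outdir / "env_used.tsv")

    if cfg.run_community:
        @stage("community")
        def _community():
            taxa = state["taxa"]
            res = pca(state["clr_taxa"])
            res.scores.to_csv(outdir / "pca_scores_taxa.tsv", sep="\t")
            pd.Series(res.explained_variance_ratio,
                      index=res.scores.columns, name="evr").to_csv(
                outdir / "pca_evr_taxa.tsv", sep="\t")
            d = euclidean_matrix(res.scores)
            permanova_pairwise(
                d, taxa.samples["trip"], n_perm=cfg.permanova_permutations,
                seed=stage_seeds["permanova"],
            ).to_csv(outdir / "permanova_pairwise_trips.tsv", sep="\t", index=False)
            div = pd.Series(
                {s: shannon(taxa.counts.loc[s]) for s in taxa.sample_ids},
                name="shannon")
            div.rename_axis("sample_id").to_csv(outdir / "shannon_taxa.tsv", sep="\t")
            groups = {t: div[taxa.samples["trip"] == t].to_numpy()
                      for t in sorted(taxa.samples["trip"].unique())}
            pairwise_wilcoxon(groups).to_csv(
                outdir / "shannon_wilcoxon_trips.tsv", sep="\t", index=False)
            summaries = []
            for label, levels in (("taxa", ["genus", "family", "phylum"]),
                                  ("go", ["rank5", "rank4", "rank3"])):
                table = state[label]
                available = [lv for lv in levels if lv in table.rank_names]
                for lv in available:
                    values, summary = within_site_similarity(table, lv)
                    summary["dataset"] = label
                    summaries.append(summary)
            pd.DataFrame(summaries).to_csv(
                outdir / "within_site_similarity.tsv", sep="\t", index=False)

    if cfg.run_mantel:
        @stage("mantel")
        def _mantel():
            latlon = state["taxa"].samples.groupby("site")[["lat", "lon"]].first()
            screen = mantel_screen(
                {"taxonomy": state["taxa"], "go": state["go"]},
                state["env"], latlon,
                n_perm=cfg.mantel_permutations, seed=stage_seeds["mantel"],
            )
            screen.to_csv(outdir / "mantel_screen.tsv", sep="\t", index=False)
            wide = screen.pivot(index="variable", columns="dataset", values="rho")
            mask = screen.pivot(index="variable", columns="dataset",
                                values="significant")
            wide.where(mask).to_csv(outdir / "mantel_rho_significant.tsv", sep="\t")

    if cfg.run_mint:
        @stage("mint")
        def _mint():
            env = state["env"]
            for label in ("taxa", "go"):
                table = state[label]
                X = env.for_samples(table.samples)
                Y = state[f"clr_{label}"].values
                studies = table.samples["trip"]
                keep = _effective_keep(cfg.keep_y, Y.shape[1])
                model = MintSparsePLS(n_components=cfg.n_components,
                                      keep_y=keep).fit(X, Y, studies)
                sim = similarity_matrix(model, X, Y)
                ordered = sim.values.loc[sim.row_order, sim.col_order]
                ordered.to_csv(outdir / f"mint_similarity_{label}.tsv", sep="\t")
                scores = logocv_stability(X, Y, studies,
                                          estimator=model, component=1)
                scores.to_csv(outdir / f"logocv_stability_{label}.tsv", sep="\t")
                report = stable_indicator_report(scores, sim)
                report.to_csv(outdir / f"stable_indicators_{label}.tsv", sep="\t")
                state[f"mint_model_{label}"] = model

    if cfg.run_stability:
        @stage("stability")
        def _stability():
            env = state["env"]
            specs = build_model_grid(state["taxa"], state["go"], env)
            rng = np.random.default_rng(stage_seeds["stability"])
            results: dict = {}
            rows = []
            for spec in specs:
                table = state["taxa" if spec.dataset == "taxonomy" else "go"]
                X, Y = model_inputs(spec, table, env,
                                    pseudocount=cfg.pseudocount)
                keep = _effective_keep(cfg.keep_y, Y.shape[1])
                est = SparsePLS(n_components=cfg.n_components, keep_y=keep)
                res = cv_stability(X, Y, estimator=est, n_folds=cfg.cv_folds,
                                   n_repeats=cfg.cv_repeats,
                                   seed=int(rng.integers(2 ** 31)),
                                   trip=spec.trip, dataset=spec.dataset)
                results[(spec.trip, spec.dataset)] = res
                res.stability.rename_axis("feature").to_csv(
                    outdir / f"cv_stability_{spec.dataset}_{spec.trip}.tsv",
                    sep="\t")
            for trip in sorted({s.trip for s in specs}):
                comp = compare_stability(results[(trip, "taxonomy")],
                                         results[(trip, "go")])
                rows.append(asdict(comp))
            pd.DataFrame(rows).to_csv(outdir / "cv_stability_summary.tsv",
                                      sep="\t", index=False)

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return outdir


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    if d["sim"].get("indicator_env_vars") is not None:
        d["sim"]["indicator_env_vars"] = list(d["sim"]["indicator_env_vars"])
    return d
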