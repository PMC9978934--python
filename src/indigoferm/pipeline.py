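"""End-to-end orchestration: dataset -> paper-style analysis artifacts.

``run_pipeline`` takes a :class:`RunConfig`, generates (or imports) a
fermentation dataset, and runs every downstream stage in order: dye scoring,
per-window composition with "Others" aggregation, alpha diversity, RDA,
co-occurrence networks, predicted metagenome, subpathway ratio screens, the
KO-dyeing correlation screen, the NAD(P)-oxidoreductase filter, and
taxon-contribution day ratios.  Every artifact is written as TSV under the
output directory with a provenance log line; identical config + seed gives
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ifio
from .community_metrics import (AnalysisThresholds, FeatureTable,
                                aggregate_others, alpha_diversity_series,
                                relative_abundance)
from .cooccurrence import Network, build_network, export_network
from .function_link import (contribution_day_ratio, filter_oxidoreductases,
                            format_day_ratio, ko_phenotype_correlation,
                            aggregate_subpathways, pathway_ratio_screen,
                            predict_metagenome)
from .ordination import RDAResult, encode_environment, fit_rda, transform_community
from .synthetic_data import (CausalFunctionModel, EnvDynamicsParams,
                             FermentationDesign, SyntheticDataset,
                             default_causal_model, default_design,
                             default_taxa, simulate_dataset)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]

DEFAULT_WINDOWS = (("early", 1, 7), ("late", 10, 209))


@dataclass
class RunConfig:
    """Everything a run needs: thresholds, generation block, seed, windows."""

    out_dir: str = "indigoferm_run"
    master_seed: int = 0
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    windows: tuple = DEFAULT_WINDOWS
    # synthetic-generation block (used when import paths are absent)
    n_taxa: int = 40
    n_kos: int = 300
    n_causal: int = 5
    design: FermentationDesign | None = None
    env_params: EnvDynamicsParams = field(default_factory=EnvDynamicsParams)
    causal: CausalFunctionModel | None = None
    # import mode
    counts_path: str | None = None
    meta_path: str | None = None
    genome_path: str | None = None
    dye_path: str | None = None
    pathway_map_path: str | None = None
    annotations_path: str | None = None
    # stage options
    alpha_replicates: int = 10
    network_mode: str = "level"
    ko_corr_mode: str = "diff"

    @property
    def import_mode(self) -> bool:
        return self.counts_path is not None

    def config_hash(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    return obj


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (flat keys matching the fields;
    ``thresholds`` as a nested mapping)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "thresholds" in raw:
        kwargs["thresholds"] = AnalysisThresholds(**raw.pop("thresholds"))
    if "env_params" in raw:
        kwargs["env_params"] = EnvDynamicsParams(**raw.pop("env_params"))
    if "windows" in raw:
        kwargs["windows"] = tuple(tuple(w) for w in raw.pop("windows"))
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs.update(raw)
    return RunConfig(**kwargs)


@dataclass
class RunReport:
    """In-memory results of a pipeline run plus artifact paths."""

    config_hash: str
    seed: int
    composition: dict[str, pd.DataFrame]
    alpha: pd.DataFrame
    rda: dict[str, RDAResult]
    networks: dict[str, Network]
    subpathways: pd.DataFrame
    pathway_screens: dict[str, pd.DataFrame]
    ko_hits: pd.DataFrame
    oxidoreductase_hits: pd.DataFrame
    contribution_ratios: pd.DataFrame
    artifacts: dict[str, str]


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> RunReport:
    out = ifio.ensure_dir(config.out_dir)
    artifacts: dict[str, str] = {}
    th = config.thresholds
    seed = config.master_seed
    logger.info("thresholds in effect: %s", th)

    def _write(name, writer, *args):
        path = out / name
        writer(*args, path)
        artifacts[name] = str(path)
        logger.info("wrote %s", path)

    stage = "load"
    try:
        if config.import_mode:
            _stage("import dataset")
            table = ifio.load_feature_table(config.counts_path, config.meta_path)
            genome = ifio.load_genome_content(config.genome_path)
            dye = ifio.load_dye_series(config.dye_path)
            pmap = (ifio.load_pathway_map(config.pathway_map_path)
                    if config.pathway_map_path else None)
            ann = (ifio.load_annotations(config.annotations_path)
                   if config.annotations_path else None)
            environments = None
            dataset = None
        else:
            _stage("synthetic generation")
            design = config.design or default_design()
            causal = config.causal or default_causal_model(
                n_kos=config.n_kos, n_causal=config.n_causal)
            dataset = simulate_dataset(
                design=design, params=config.env_params, causal=causal,
                taxa=default_taxa(config.n_taxa, seed=seed),
                n_kos=config.n_kos, seed=seed)
            table, genome, dye = (dataset.feature_table, dataset.genome_content,
                                  dataset.dye_series)
            pmap, ann = dataset.pathway_map, dataset.annotations
            environments = dataset.environment
            _write("feature_table.tsv", lambda t, p: ifio.write_feature_table(
                t, p, str(p).replace("feature_table.tsv", "sample_metadata.tsv")), table)
            artifacts["sample_metadata.tsv"] = str(out / "sample_metadata.tsv")
            _write("genome_content.tsv", ifio.write_genome_content, genome)
            _write("dye_series.tsv", ifio.write_dye_series, dye)
            _write("pathway_map.tsv", ifio.write_pathway_map, pmap)
            _write("ko_annotations.tsv", ifio.write_annotations, ann)
            truth = {"causal_kos": sorted(dataset.truth["causal_kos"]),
                     "seed": dataset.truth["seed"]}
            (out / "truth.json").write_text(json.dumps(truth, indent=2))
            artifacts["truth.json"] = str(out / "truth.json")

        stage = "composition"
        _stage(stage)
        rel = relative_abundance(table)
        composition = {}
        for name, lo, hi in config.windows:
            sub = table.window(lo, hi)
            if not sub.samples:
                logger.warning("window %s has no samples; skipped", name)
                continue
            comp = aggregate_others(relative_abundance(sub), th.others_cutoff)
            composition[name] = comp
            _write(f"composition_{name}.tsv",
                   lambda c, p: c.rename_axis("taxon_id").to_csv(p, sep="\t"), comp)

        stage = "alpha diversity"
        _stage(stage)
        alpha = alpha_diversity_series(table, th, replicates=config.alpha_replicates,
                                       seed=seed)
        _write("alpha_diversity.tsv", lambda a, p: a.to_csv(p, sep="\t"), alpha)

        stage = "ordination"
        _stage(stage)
        rda_results: dict[str, RDAResult] = {}
        env_lookup = ({e.batch_id: e.records for e in environments}
                      if environments else None)
        design_for_env = (config.design or default_design()) if not config.import_mode else None
        for name, lo, hi in config.windows:
            sub = table.window(lo, hi)
            if len(sub.samples) < 4:
                logger.warning("window %s too small for RDA; skipped", name)
                continue
            meta = sub.sample_meta.loc[sub.samples]
            bran_days = (design_for_env.bran_days if design_for_env
                         else (5, 19, 51, 85, 194))
            X = encode_environment(None, meta, bran_days=bran_days)
            Y = transform_community(relative_abundance(sub))
            res = fit_rda(Y, X)
            rda_results[name] = res
            eig = pd.DataFrame({
                "axis": [f"RDA{i+1}" for i in range(len(res.constrained_eigenvalues))],
                "eigenvalue": res.constrained_eigenvalues,
                "explained_pct": res.axis_explained,
            })
            _write(f"rda_{name}_eigenvalues.tsv",
                   lambda e, p: e.to_csv(p, sep="\t", index=False), eig)
            _write(f"rda_{name}_site_scores.tsv",
                   lambda s, p: s.rename_axis("sample_id").to_csv(p, sep="\t"),
                   res.site_scores)
            _write(f"rda_{name}_species_scores.tsv",
                   lambda s, p: s.rename_axis("taxon_id").to_csv(p, sep="\t"),
                   res.species_scores)
            _write(f"rda_{name}_biplot.tsv",
                   lambda s, p: s.rename_axis("variable").to_csv(p, sep="\t"),
                   res.biplot_scores)

        stage = "networks"
        _stage(stage)
        networks: dict[str, Network] = {}
        for name, lo, hi in config.windows:
            sub = table.window(lo, hi)
            for batch in sorted(set(sub.sample_meta.loc[sub.samples, "batch_id"])):
                samples = [s for s in sub.samples
                           if sub.sample_meta.loc[s, "batch_id"] == batch]
                if len(samples) < 3:
                    continue
                ordered = sorted(samples, key=lambda s: sub.sample_meta.loc[s, "day"])
                rel_b = relative_abundance(sub.subset_samples(ordered))
                key = f"{name}_{batch}"
                net = build_network(rel_b, th, period=key, mode=config.network_mode)
                networks[key] = net
                export_network(net, out / f"network_{key}.tsv", fmt="edge_tsv")
                artifacts[f"network_{key}.tsv"] = str(out / f"network_{key}.tsv")

        stage = "predicted metagenome"
        _stage(stage)
        kt, contrib = predict_metagenome(rel, genome)
        _write("pred_metagenome_unstrat.tsv", ifio.write_ko_table, kt)
        _write("pred_metagenome_contrib.legacy.tsv", ifio.write_contrib_table, contrib)

        stage = "subpathway screens"
        _stage(stage)
        pathway_screens: dict[str, pd.DataFrame] = {}
        if pmap is not None:
            sub_tab = aggregate_subpathways(kt, pmap)
            _write("subpathway_abundance.tsv",
                   lambda s, p: s.rename_axis("subpathway").to_csv(p, sep="\t"), sub_tab)
            # enrichment of the earliest-reducing batch on day 3, vs the others
            meta = table.sample_meta
            day3 = meta.index[meta["day"] == 3]
            batches = sorted(set(meta.loc[day3, "batch_id"]))
            ref_batch = "B3" if "B3" in batches else (batches[0] if batches else None)
            if ref_batch is not None and len(batches) > 1:
                ref_sample = day3[meta.loc[day3, "batch_id"] == ref_batch][0]
                for other in batches:
                    if other == ref_batch:
                        continue
                    other_sample = day3[meta.loc[day3, "batch_id"] == other][0]
                    screen, undefined = pathway_ratio_screen(
                        sub_tab[ref_sample], sub_tab[other_sample], th.pathway_ratio_min)
                    if undefined:
                        logger.warning("ratio undefined for subpathway(s): %s", undefined)
                    key = f"{ref_batch}_vs_{other}_day3"
                    pathway_screens[key] = screen
                    _write(f"pathway_screen_{key}.tsv",
                           lambda s, p: s.to_csv(p, sep="\t", index=False), screen)
        else:
            sub_tab = None

        stage = "KO-phenotype screen"
        _stage(stage)
        dye_meta = dye.copy()
        if "batch_id" not in dye_meta.columns:
            dye_meta = dye_meta.join(table.sample_meta[["batch_id", "day"]])
        hits, r_by_ko = ko_phenotype_correlation(
            kt, dye_meta, min_r=th.ko_r_min, mode=config.ko_corr_mode,
            annotations=ann)
        hits_df = pd.DataFrame(
            [{"ko_id": h.ko_id, "r": h.r, "n_pairs": h.n_pairs, "symbol": h.symbol,
              "description": h.description, "ec_numbers": ";".join(h.ec_numbers)}
             for h in hits],
            columns=["ko_id", "r", "n_pairs", "symbol", "description", "ec_numbers"])
        _write("ko_hits.tsv", lambda h, p: h.to_csv(p, sep="\t", index=False), hits_df)

        stage = "oxidoreductase filter"
        _stage(stage)
        if ann is not None:
            kept, unann = filter_oxidoreductases(hits, ann)
            if unann:
                logger.warning("%d hit(s) lacked annotation", len(unann))
        else:
            kept = []
        oxido_df = pd.DataFrame(
            [{"ko_id": h.ko_id, "r": h.r, "symbol": h.symbol,
              "description": h.description, "ec_numbers": ";".join(h.ec_numbers)}
             for h in kept],
            columns=["ko_id", "r", "symbol", "description", "ec_numbers"])
        _write("oxidoreductase_hits.tsv",
               lambda h, p: h.to_csv(p, sep="\t", index=False), oxido_df)

        stage = "contribution ratios"
        _stage(stage)
        ratio_rows = []
        meta = table.sample_meta
        for h in kept:
            for batch, (day_a, day_b) in {"B3": (2, 3), "B4": (3, 4)}.items():
                sa = meta.index[(meta["batch_id"] == batch) & (meta["day"] == day_a)]
                sb = meta.index[(meta["batch_id"] == batch) & (meta["day"] == day_b)]
                if len(sa) == 0 or len(sb) == 0:
                    continue
                sel = contrib[(contrib["sample_id"] == sb[0])
                              & (contrib["ko_id"] == h.ko_id)]
                if sel.empty:
                    continue
                top_taxon = sel.loc[sel["contributed_count"].idxmax(), "taxon_id"]
                ratio = contribution_day_ratio(contrib, h.ko_id, top_taxon, sa[0], sb[0])
                ratio_rows.append({
                    "ko_id": h.ko_id, "taxon_id": top_taxon, "batch_id": batch,
                    "day_a": day_a, "day_b": day_b,
                    "ratio": format_day_ratio(ratio)})
        ratios_df = pd.DataFrame(
            ratio_rows, columns=["ko_id", "taxon_id", "batch_id", "day_a", "day_b", "ratio"])
        _write("contribution_ratios.tsv",
               lambda r, p: r.to_csv(p, sep="\t", index=False), ratios_df)

        stage = "manifest"
        manifest = {
            "config_hash": config.config_hash(),
            "master_seed": seed,
            "thresholds": _as_jsonable(th),
            "artifacts": sorted(artifacts),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        artifacts["manifest.json"] = str(out / "manifest.json")
    except Exception:
        logger.error("pipeline aborted in stage %r; partial outputs under %s",
                     stage, out)
        raise

    return RunReport(
        config_hash=config.config_hash(), seed=seed, composition=composition,
        alpha=alpha, rda=rda_results, networks=networks,
        subpathways=sub_tab if sub_tab is not None else pd.DataFrame(),
        pathway_screens=pathway_screens, ko_hits=hits_df,
        oxidoreductase_hits=oxido_df, contribution_ratios=ratios_df,
        artifacts=artifacts,
    )
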