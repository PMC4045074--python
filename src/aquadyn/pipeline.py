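"""End-to-end orchestration of the full analysis.

:func:`run_all` executes the stages in dependency order --

    rarefy -> diversity -> stats / spatial / temporal -> core-select
           -> associate -> ioam

-- on either on-disk inputs or a freshly generated synthetic campaign,
writing every stage product (CSV tables, PHYLIP distance matrices, a
GraphML network) into the output directory together with a manifest of
SHA-256 content hashes and the resolved configuration.  The master seed
deterministically derives a per-stage seed by hashing the stage name,
so disabling one stage never changes another's randomness.

Rarefaction events are streamed twice (they are reproducible from their
per-event seeds), so no more than one full-size event is ever resident.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .association import (AssociationParams, cluster_timeseries, extract_clusters,
                          filter_core_otus, network_stats, robust_associations)
from .diversity import alpha_diversity, average_distance, beta_matrix
from .ioam import (compare_models, monthly_alpha_envelope,
                   occupancy_from_profiles, event_averaged_profiles)
from .rarefaction import RarefactionPlan, rarefaction_report, rarefy
from .spatial import PipeNetwork, distance_decay, site_specific_otus
from .stats import anosim, beta_dispersion, core_selection_curve, permanova
from .temporal import dwtp_divergence, time_lag_curve

log = logging.getLogger("aquadyn")

__all__ = ["RunConfig", "run_all", "stage_seed"]

_ALL_STAGES = ("diversity", "stats", "spatial", "temporal",
               "coreselect", "associate", "ioam")


def stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    # inputs: either a synthetic spec (kwargs for SyntheticSpec) or file paths
    synthetic: dict | None = None
    otu_table: str | None = None
    otu_format: str = "wide"
    metadata: str | None = None
    tree: str | None = None
    pipe_inventory: str | None = None
    # rarefaction
    depth: int | None = None          # None: depth of the shallowest sample
    events_diversity: int = 100
    events_association: int = 100
    # stage parameters
    stages: dict = field(default_factory=lambda: {s: True for s in _ALL_STAGES})
    beta_metrics: tuple = ("bray_curtis", "jaccard",
                           "unweighted_unifrac", "weighted_unifrac")
    reference_year: float = 2011.0
    association: dict = field(default_factory=dict)
    ioam_permutations: int = 200
    core_mode: str = "detection_frequency"
    core_thresholds: tuple = tuple(np.round(np.arange(0.02, 1.01, 0.07), 3))

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["beta_metrics"] = list(self.beta_metrics)
        data["core_thresholds"] = [float(t) for t in self.core_thresholds]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every enabled stage; return the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        manifest[name] = _sha256(path)

    def fail(stage: str, exc: Exception):
        (out / "manifest_partial.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- inputs ----------------------------------------------------------
    tree = inventory = None
    if config.synthetic is not None:
        from .synthetic import SyntheticSpec, generate

        kwargs = dict(config.synthetic)
        kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
        data = generate(SyntheticSpec(**kwargs))
        table, meta, tree, inventory = (data.table, data.metadata,
                                        data.tree, data.inventory)
    else:
        if not (config.otu_table and config.metadata):
            raise ValueError("need otu_table and metadata paths (or a synthetic spec)")
        table = aio.read_otu_table(config.otu_table, config.otu_format)
        meta = aio.read_metadata(config.metadata)
        if config.tree:
            tree = aio.read_tree(config.tree)
        if config.pipe_inventory:
            inventory = aio.read_pipe_inventory(config.pipe_inventory)
    metrics = [m for m in config.beta_metrics
               if tree is not None or not m.endswith("unifrac")]

    # ---- rarefaction plans ----------------------------------------------
    depth = config.depth or int(table.sample_totals().min())
    retained, report = rarefaction_report(table, depth)
    plan_div = RarefactionPlan(depth, config.events_diversity,
                               stage_seed(config.seed, "rarefy"))
    plan_assoc = RarefactionPlan(depth, config.events_association,
                                 stage_seed(config.seed, "rarefy_assoc"))
    (out / "rarefaction_report.json").write_text(json.dumps(
        {"depth": depth, "retained": len(retained),
         "dropped": report.dropped_samples}, indent=2))
    emit("rarefaction_report", out / "rarefaction_report.json")
    log.info("rarefy: depth %d, %d samples retained, %d events (diversity)",
             depth, len(retained), plan_div.n_events)
    sub_meta_rows = meta.for_samples(retained)

    # ---- diversity: averaged alpha and beta over events ------------------
    avg_dms = {}
    try:
        alpha_sum = None
        beta_sums = {m: None for m in metrics}
        n_ev = 0
        for ev in rarefy(table, plan_div):
            n_ev += 1
            a = alpha_diversity(ev)
            alpha_sum = a if alpha_sum is None else alpha_sum + a
            for m in metrics:
                dm = beta_matrix(ev, m, tree)
                beta_sums[m] = dm.data if beta_sums[m] is None \
                    else beta_sums[m] + dm.data
        alpha = alpha_sum / n_ev
        alpha.to_csv(out / "alpha_diversity.csv")
        emit("alpha_diversity", out / "alpha_diversity.csv")
        from .distances import DistanceMatrix

        for m in metrics:
            avg_dms[m] = DistanceMatrix(retained, beta_sums[m] / n_ev, m)
            aio.write_distance_matrix(avg_dms[m], out / f"beta_{m}.dist")
            emit(f"beta_{m}", out / f"beta_{m}.dist")
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        fail("diversity", exc)

    # ---- grouping statistics ---------------------------------------------
    if config.enabled("stats"):
        try:
            seed = stage_seed(config.seed, "stats")
            rows = []
            for m, dm in avg_dms.items():
                for grouping in ("month_index", "location", "season", "sector"):
                    g = sub_meta_rows[grouping].to_numpy()
                    pm = permanova(dm, g, seed=seed, grouping=grouping)
                    an = anosim(dm, g, seed=seed, grouping=grouping)
                    rows.append((m, grouping, pm.extras["r_squared"], pm.statistic,
                                 pm.p_value, an.statistic, an.p_value))
                    disp = beta_dispersion(dm, g, grouping=grouping)
                    if disp.tukey is not None:
                        disp.tukey.to_csv(out / f"dispersion_{m}_{grouping}.csv",
                                          index=False)
                        emit(f"dispersion_{m}_{grouping}",
                             out / f"dispersion_{m}_{grouping}.csv")
            pd.DataFrame(rows, columns=["metric", "grouping", "permanova_r2",
                                        "permanova_f", "permanova_p", "anosim_r",
                                        "anosim_p"]).to_csv(
                out / "grouping_stats.csv", index=False)
            emit("grouping_stats", out / "grouping_stats.csv")
        except Exception as exc:  # noqa: BLE001
            fail("stats", exc)

    # ---- spatial ----------------------------------------------------------
    if config.enabled("spatial") and inventory is not None:
        try:
            from .spatial import location_average_distance

            net = PipeNetwork(inventory, config.reference_year)
            frames = []
            for m, dm in avg_dms.items():
                loc_dm = location_average_distance(
                    dm, sub_meta_rows["location"], sub_meta_rows["month_index"])
                for sector in sorted(set(sub_meta_rows["sector"]) - {"DWTP"}):
                    locs = sorted(set(sub_meta_rows.loc[
                        sub_meta_rows["sector"] == sector, "location"]))
                    if len(locs) < 3:
                        continue
                    dd = distance_decay(net, loc_dm, locs)
                    dd.insert(0, "sector", sector)
                    dd.insert(0, "beta_metric", m)
                    frames.append(dd)
            pd.concat(frames, ignore_index=True).to_csv(
                out / "distance_decay.csv", index=False)
            emit("distance_decay", out / "distance_decay.csv")
            sub = table.select_samples(retained)
            site_specific_otus(sub, sub_meta_rows["location"]).to_csv(
                out / "site_specific.csv", index=False)
            emit("site_specific", out / "site_specific.csv")
        except Exception as exc:  # noqa: BLE001
            fail("spatial", exc)

    # ---- temporal ---------------------------------------------------------
    if config.enabled("temporal"):
        try:
            for m, dm in avg_dms.items():
                time_lag_curve(dm, meta).to_csv(out / f"lag_curve_{m}.csv")
                emit(f"lag_curve_{m}", out / f"lag_curve_{m}.csv")
                if (sub_meta_rows["sector"] == "DWTP").any():
                    dwtp_divergence(dm, meta).to_csv(
                        out / f"dwtp_divergence_{m}.csv", index=False)
                    emit(f"dwtp_divergence_{m}", out / f"dwtp_divergence_{m}.csv")
        except Exception as exc:  # noqa: BLE001
            fail("temporal", exc)

    # ---- core selection ----------------------------------------------------
    if config.enabled("coreselect"):
        try:
            sub = table.select_samples(retained)
            curve = core_selection_curve(sub, config.core_thresholds,
                                         config.core_mode)
            curve.to_csv(out / "core_selection.csv", index=False)
            emit("core_selection", out / "core_selection.csv")
        except Exception as exc:  # noqa: BLE001
            fail("coreselect", exc)

    # ---- association network ----------------------------------------------
    assignment = None
    if config.enabled("associate"):
        try:
            import networkx as nx

            params = AssociationParams(seed=stage_seed(config.seed, "associate"),
                                       **config.association)
            core = filter_core_otus(list(rarefy(table, plan_assoc)),
                                    params.min_detection)
            net = robust_associations(rarefy(table, plan_assoc), params,
                                      core_otus=core)
            net.edges_dataframe().to_csv(out / "association_edges.tsv",
                                         sep="\t", index=False)
            emit("association_edges", out / "association_edges.tsv")
            nx.write_graphml(net.graph, out / "association_network.graphml")
            emit("association_network", out / "association_network.graphml")
            assignment = extract_clusters(net)
            pd.Series(assignment.labels, name="cluster").rename_axis("otu").to_csv(
                out / "clusters.csv")
            emit("clusters", out / "clusters.csv")
            stats = network_stats(net, assignment)
            stats["degrees"] = stats["degrees"].to_dict()
            (out / "network_stats.json").write_text(json.dumps(
                {k: v for k, v in stats.items()}, indent=2, default=str))
            emit("network_stats", out / "network_stats.json")
            sub = table.select_samples(retained)
            cluster_timeseries(sub, meta, assignment).to_csv(
                out / "cluster_timeseries.csv")
            emit("cluster_timeseries", out / "cluster_timeseries.csv")
        except Exception as exc:  # noqa: BLE001
            fail("associate", exc)

    # ---- occupancy-abundance ----------------------------------------------
    if config.enabled("ioam"):
        try:
            abund, detect, sample_ids, otu_ids = event_averaged_profiles(
                rarefy(table, plan_assoc))
            month = meta.column("month_index", sample_ids)
            points = occupancy_from_profiles(abund, detect, otu_ids, month)
            compare_models(points).to_csv(out / "ioam_models.csv", index=False)
            emit("ioam_models", out / "ioam_models.csv")
            if config.ioam_permutations:
                env = monthly_alpha_envelope(
                    rarefy(table, plan_assoc), meta,
                    n_reps=config.ioam_permutations,
                    seed=stage_seed(config.seed, "ioam"))
                env.to_csv(out / "ioam_envelope.csv")
                emit("ioam_envelope", out / "ioam_envelope.csv")
        except Exception as exc:  # noqa: BLE001
            fail("ioam", exc)

    config.to_yaml(out / "config_resolved.yaml")
    emit("config_resolved", out / "config_resolved.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
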