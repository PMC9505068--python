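"""End-to-end study orchestration.

Two study templates are provided:

* the PK study: concentration–time profiles (loaded or simulated) are run
  through noncompartmental analysis, the two designated groups are
  compared parameter by parameter with pooled t-tests, and the full
  parameter matrix is ordinated by PCA;
* the network study: a background interactome (loaded or generated with
  planted modules) is restricted to its largest connected component, the
  reference module and each component module are mapped onto it, the
  separation profile is computed and, when a gene-set collection is
  supplied, over-representation tables and their significant-pathway
  overlap are added.

Both return a JSON-serialisable report; all randomness flows from the
seed embedded in the generator configs, so identical configurations give
identical reports.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import io as pio
from .enrichment import GeneSetCollection, enrich, significant_overlap
from .groupstats import group_summary, pca_scores
from .interactome import (
    Interactome,
    ProteinSet,
    largest_connected_component,
    load_edge_list,
)
from .nca import batch_nca
from .separation import separation_profile
from .synthetic import (
    NetSimConfig,
    PKSimConfig,
    generate_planted_network,
    simulate_profiles,
)

logger = logging.getLogger(__name__)

__all__ = ["PKStudyConfig", "NetworkStudyConfig", "run_pk_study", "run_network_study"]


@dataclass
class PKStudyConfig:
    """Inputs for the plasma-pharmacokinetics study stage.

    Exactly one of ``profiles_csv`` or ``simulation`` must be supplied.
    """

    profiles_csv: str | os.PathLike | None = None
    simulation: PKSimConfig | None = None
    pair: tuple[str, str] = ("DOX", "DOX+AR")
    alpha: float = 0.05
    lambda_z_selection: str | int | tuple[float, float] = "auto"

    def __post_init__(self) -> None:
        if (self.profiles_csv is None) == (self.simulation is None):
            raise ValueError("supply exactly one of profiles_csv or simulation")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class NetworkStudyConfig:
    """Inputs for the interactome separation / enrichment stage.

    The network comes either from an edge-list file or from the planted
    generator; the reference module and component modules come from files
    or in-memory protein sets.
    """

    edge_list: str | os.PathLike | None = None
    simulation: NetSimConfig | None = None
    module_a: str | os.PathLike | ProteinSet | None = None
    components: Sequence[str | os.PathLike | ProteinSet] = field(default_factory=tuple)
    gene_sets: GeneSetCollection | str | os.PathLike | None = None
    use_lcc: bool = True
    fdr: float = 0.01

    def __post_init__(self) -> None:
        if (self.edge_list is None) == (self.simulation is None):
            raise ValueError("supply exactly one of edge_list or simulation")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")


def _stage(report: dict, name: str, ok: bool, payload: dict | None = None, reason: str = "") -> None:
    report["stages"][name] = {"status": "ok" if ok else "failed"}
    if payload:
        report["stages"][name].update(payload)
    if reason:
        report["stages"][name]["reason"] = reason


def run_pk_study(cfg: PKStudyConfig) -> dict:
    """Profiles -> NCA -> group comparison -> PCA, with per-stage status."""
    report: dict = {"study": "pk", "stages": {}, "warnings": []}
    if cfg.simulation is not None:
        profiles = simulate_profiles(cfg.simulation)
        report["config"] = {"source": "simulated", "seed": cfg.simulation.seed,
                           "n_per_group": cfg.simulation.n_per_group,
                           "groups": list(cfg.simulation.groups)}
    else:
        profiles = pio.read_profiles_csv(cfg.profiles_csv)
        report["config"] = {"source": str(cfg.profiles_csv)}
    report["config"]["alpha"] = cfg.alpha
    report["config"]["pair"] = list(cfg.pair)

    batch = batch_nca(profiles, cfg.lambda_z_selection)
    _stage(report, "nca", True, {
        "n_subjects": int(len(batch.table)),
        "n_failed": int(len(batch.failures)),
        "failures": batch.failures.to_dict(orient="records"),
        "parameters": batch.table.to_dict(orient="records"),
    })
    if not batch.failures.empty:
        report["warnings"].append(
            f"{len(batch.failures)} subject(s) excluded from summaries"
        )

    try:
        summary = group_summary(batch.table, cfg.pair, alpha=cfg.alpha)
        _stage(report, "group_comparison", True, {
            "table": summary.reset_index().to_dict(orient="records"),
            "n_significant": int(summary["significant"].sum()),
        })
    except ValueError as exc:
        _stage(report, "group_comparison", False, reason=str(exc))

    try:
        pca = pca_scores(batch.table)
        _stage(report, "pca", True, {
            "explained_variance_ratio": pca.explained_variance_ratio[:5].tolist(),
            "scores": pca.scores.reset_index().to_dict(orient="records"),
            "dropped_columns": pca.dropped_columns,
        })
    except ValueError as exc:
        _stage(report, "pca", False, reason=str(exc))
    report["ok"] = all(s["status"] == "ok" for s in report["stages"].values())
    return report


def _resolve_set(spec: str | os.PathLike | ProteinSet) -> ProteinSet:
    if isinstance(spec, ProteinSet):
        return spec
    return pio.read_protein_set(spec)


def run_network_study(cfg: NetworkStudyConfig) -> dict:
    """Network -> LCC -> mapping -> separation profile (-> enrichment)."""
    report: dict = {"study": "network", "stages": {}, "warnings": []}
    expected_sign = None
    if cfg.simulation is not None:
        net, set_a, set_b, expected_sign = generate_planted_network(cfg.simulation)
        components = list(cfg.components) or [set_b]
        module_a: ProteinSet = set_a
        report["config"] = {"source": "simulated", "seed": cfg.simulation.seed,
                           "expected_sign": expected_sign}
    else:
        if not os.path.exists(cfg.edge_list):  # type: ignore[arg-type]
            raise FileNotFoundError(f"edge list not found: {cfg.edge_list}")
        net = load_edge_list(cfg.edge_list)
        if cfg.module_a is None or not cfg.components:
            raise ValueError("file-backed runs need module_a and components")
        module_a = _resolve_set(cfg.module_a)
        components = [_resolve_set(c) for c in cfg.components]
        report["config"] = {"source": str(cfg.edge_list)}
    report["config"]["fdr"] = cfg.fdr
    rep = net.report
    _stage(report, "network", True, {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_self_loops": rep.n_self_loops if rep else 0,
        "n_duplicate_edges": rep.n_duplicate_edges if rep else 0,
    })

    if cfg.use_lcc:
        net = largest_connected_component(net)
        _stage(report, "lcc", True, {"n_nodes": net.n_nodes, "n_edges": net.n_edges})

    try:
        profile = separation_profile(net, module_a, components)
        _stage(report, "separation", True, {
            "table": profile.to_dict(orient="records"),
            "n_separated": profile.attrs["n_separated"],
            "n_same_neighborhood": profile.attrs["n_same_neighborhood"],
            "n_flagged": profile.attrs["n_flagged"],
        })
    except ValueError as exc:
        _stage(report, "separation", False, reason=str(exc))
        report["ok"] = False
        return report

    if cfg.gene_sets is not None:
        collection = (
            cfg.gene_sets
            if isinstance(cfg.gene_sets, GeneSetCollection)
            else GeneSetCollection.from_gmt(cfg.gene_sets)
        )
        tables = {}
        try:
            tables[module_a.label] = enrich(module_a, collection)
            for comp in components:
                try:
                    tables[comp.label] = enrich(comp, collection)
                except ValueError as exc:
                    report["warnings"].append(f"enrichment skipped for {comp.label}: {exc}")
            payload = {
                label: t.to_dict(orient="records") for label, t in tables.items()
            }
            stage: dict = {"tables": payload}
            if 2 <= len(tables) <= 3:
                regions = significant_overlap(tables, cfg.fdr)
                stage["overlap_regions"] = {
                    "+".join(k): v for k, v in regions.items()
                }
            _stage(report, "enrichment", True, stage)
        except ValueError as exc:
            _stage(report, "enrichment", False, reason=str(exc))

    report["ok"] = all(s["status"] == "ok" for s in report["stages"].values())
    return report
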