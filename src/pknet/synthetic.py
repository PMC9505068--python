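"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the structure of an IV-bolus herb–drug disposition
study on a realistic scale:

* plasma profiles follow a biexponential disposition
  C(t) = (A e^{-alpha t} + B e^{-beta t}) * eps with multiplicative
  lognormal noise of a given CV, sampled on the dense early / sparse late
  schedule 0, 0.083, 0.25, 0.5, 1, 2, 4, 6, 8, 10, 24, 32, 48 h. The
  default macro-constants (A = 1470 ug/L, alpha = 3.0 /h, B = 25 ug/L,
  beta = ln2 / 31.5 /h, dose 5000 ug/kg i.v.) put C_max near 1500 ug/L,
  AUC_0-48h near 1250 ug/L*h and the terminal half-life at 31.5 h —
  typical of doxorubicin in the rat;
* tissue panels draw per-tissue lognormal concentrations whose geometric
  means follow the drug's known distribution pattern (kidney, spleen,
  heart high; liver intermediate; lung and skeletal muscle low), with
  per-group multiplicative effects (default: a 30% liver decrease in the
  treated group, 5% elsewhere);
* interactomes are random background graphs with two planted protein
  modules whose overlap or graph distance — and hence the expected sign
  of the separation score — is controlled by construction;
* calibration / QC batches are linear-response curves with proportional
  (heteroscedastic) noise over per-matrix validated ranges;
* gene-set collections are random sets with one optional planted set
  enriched for a given query.

Every generator is a pure function of its config: the top-level seed is
split deterministically (one child stream per subject / replicate), so
outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .bioval import QCBatch
from .enrichment import GeneSetCollection
from .interactome import Interactome, ProteinSet
from .nca import ConcentrationTimeProfile

__all__ = [
    "SCHEDULE_H",
    "PKSimConfig",
    "TissueSimConfig",
    "NetSimConfig",
    "CalibrationSimConfig",
    "simulate_profiles",
    "simulate_tissue_panel",
    "generate_planted_network",
    "generate_calibration_batch",
    "CalibrationBatch",
    "generate_gene_sets",
    "MATRIX_RANGES",
    "QC_LEVELS",
]

#: plasma sampling schedule (h): dense over the distribution phase,
#: sparse over the terminal phase
SCHEDULE_H = (0.0, 0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 24.0, 32.0, 48.0)

TISSUES = ("heart", "liver", "lung", "kidney", "spleen", "skeletal_muscle")


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of
    variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# --------------------------------------------------------------------------
# plasma pharmacokinetics


@dataclass
class PKSimConfig:
    """Biexponential IV-bolus simulation settings.

    ``group_effect`` maps a group name to multiplicative factors on the
    macro-constants ``a``, ``b``, ``alpha``, ``beta`` (absent keys mean no
    effect); the default of no effect anywhere reflects a study in which
    the co-administered herb leaves drug disposition unchanged.
    """

    n_per_group: int = 7
    dose: float = 5000.0  # ug/kg
    a: float = 1470.0  # ug/L
    alpha: float = 3.0  # 1/h
    b: float = 25.0  # ug/L
    beta: float = math.log(2) / 31.5  # 1/h, terminal t1/2 = 31.5 h
    proportional_cv: float = 0.10
    groups: tuple[str, ...] = ("DOX", "DOX+AR")
    group_effect: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    schedule: tuple[float, ...] = SCHEDULE_H
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.alpha > self.beta > 0):
            raise ValueError("require alpha > beta > 0")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("macro-constants A and B must be positive")
        if self.proportional_cv < 0:
            raise ValueError("proportional_cv must be non-negative")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.schedule[0] != 0:
            raise ValueError("sampling schedule must start at 0")


def simulate_profiles(cfg: PKSimConfig) -> list[ConcentrationTimeProfile]:
    """Draw one noisy biexponential profile per subject per group."""
    t = np.asarray(cfg.schedule, dtype=float)
    streams = np.random.SeedSequence(cfg.seed).spawn(
        len(cfg.groups) * cfg.n_per_group
    )
    profiles: list[ConcentrationTimeProfile] = []
    i = 0
    for group in cfg.groups:
        eff = cfg.group_effect.get(group, {})
        a = cfg.a * eff.get("a", 1.0)
        b = cfg.b * eff.get("b", 1.0)
        alpha = cfg.alpha * eff.get("alpha", 1.0)
        beta = cfg.beta * eff.get("beta", 1.0)
        clean = a * np.exp(-alpha * t) + b * np.exp(-beta * t)
        for j in range(cfg.n_per_group):
            rng = np.random.default_rng(streams[i])
            i += 1
            conc = clean * _lognormal_factors(rng, cfg.proportional_cv, t.size)
            profiles.append(
                ConcentrationTimeProfile(
                    subject_id=f"{group}-{j + 1:02d}",
                    group=group,
                    dose=cfg.dose,
                    times=t.copy(),
                    concentrations=conc,
                )
            )
    return profiles


# --------------------------------------------------------------------------
# tissue distribution


def _default_tissue_means() -> dict[str, float]:
    # ng/g at 48 h post-dose: kidney, spleen, heart high; liver middle;
    # lung and skeletal muscle low
    return {
        "kidney": 1250.0,
        "spleen": 1100.0,
        "heart": 950.0,
        "liver": 520.0,
        "lung": 230.0,
        "skeletal_muscle": 180.0,
    }


def _default_tissue_multipliers() -> dict[str, dict[str, float]]:
    # treated group: marked decrease in liver, slight decrease elsewhere
    return {
        "DOX+AR": {
            "liver": 0.70,
            "heart": 0.95,
            "kidney": 0.95,
            "spleen": 0.95,
            "lung": 0.95,
            "skeletal_muscle": 0.95,
        }
    }


@dataclass
class TissueSimConfig:
    """Per-tissue lognormal concentration panel with group effects.

    ``means`` are geometric means (ng/g); ``sigma`` is the lognormal
    scale on the natural-log axis; ``group_multipliers[group][tissue]``
    scales the mean (absent entries mean 1.0).
    """

    means: Mapping[str, float] = field(default_factory=_default_tissue_means)
    sigma: float = 0.2
    group_multipliers: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_tissue_multipliers
    )
    groups: tuple[str, ...] = ("DOX", "DOX+AR")
    n_per_group: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.means.values()):
            raise ValueError("tissue means must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        high = min(self.means.get(t, np.inf) for t in ("kidney", "spleen", "heart") if t in self.means)
        low = max(self.means.get(t, 0.0) for t in ("lung", "skeletal_muscle") if t in self.means)
        liver = self.means.get("liver")
        if liver is not None and not (high > liver > low):
            raise ValueError(
                "default tissue ordering requires kidney/spleen/heart > liver > lung/muscle"
            )


def simulate_tissue_panel(cfg: TissueSimConfig) -> pd.DataFrame:
    """Wide table: one row per subject, one column per tissue (ng/g)."""
    tissues = list(cfg.means)
    streams = np.random.SeedSequence(cfg.seed).spawn(len(cfg.groups) * cfg.n_per_group)
    rows = []
    i = 0
    for group in cfg.groups:
        mult = cfg.group_multipliers.get(group, {})
        for j in range(cfg.n_per_group):
            rng = np.random.default_rng(streams[i])
            i += 1
            noise = rng.normal(0.0, cfg.sigma, size=len(tissues))
            row = {"subject": f"{group}-{j + 1:02d}", "group": group}
            for tis, z in zip(tissues, noise):
                row[tis] = cfg.means[tis] * mult.get(tis, 1.0) * math.exp(z)
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# planted-module interactomes


@dataclass
class NetSimConfig:
    """Random background graph with two planted protein modules.

    With ``overlap_count == 0`` module B is connected to module A only
    through a spacer path of ``planted_distance - 1`` nodes, so the
    nearest cross-module distance is exactly ``planted_distance`` and,
    for distances >= 3 with dense intra-module wiring, the separation
    score is positive by construction. With full overlap the modules
    coincide and the score is negative.
    """

    n_background: int = 200
    background_model: str = "small_world"  # or "scale_free"
    module_size_a: int = 10
    module_size_b: int = 10
    intra_density: float = 0.6
    planted_distance: int = 4
    overlap_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.module_size_a, self.module_size_b) < 1:
            raise ValueError("module sizes must be >= 1")
        if not 0 <= self.overlap_count <= min(self.module_size_a, self.module_size_b):
            raise ValueError("overlap_count must not exceed the smaller module")
        if self.overlap_count == 0 and self.planted_distance < 1:
            raise ValueError("planted_distance must be >= 1 for disjoint modules")
        if not 0 <= self.intra_density <= 1:
            raise ValueError("intra_density must lie in [0, 1]")
        if self.background_model not in ("small_world", "scale_free"):
            raise ValueError("background_model must be 'small_world' or 'scale_free'")


def _wire_module(g: nx.Graph, nodes: list[str], density: float, rng: np.random.Generator) -> None:
    # spanning path guarantees intra-module connectivity; extra edges to
    # the requested density
    for u, v in zip(nodes, nodes[1:]):
        g.add_edge(u, v)
    for i in range(len(nodes)):
        for j in range(i + 2, len(nodes)):
            if rng.random() < density:
                g.add_edge(nodes[i], nodes[j])


def generate_planted_network(
    cfg: NetSimConfig,
) -> tuple[Interactome, ProteinSet, ProteinSet, str | None]:
    """Background graph plus two planted modules and the expected sign of
    their separation score ("positive", "negative", or None when the
    construction does not force a sign)."""
    rng = np.random.default_rng(cfg.seed)
    nx_seed = int(rng.integers(2**31 - 1))
    if cfg.background_model == "small_world":
        bg = nx.connected_watts_strogatz_graph(cfg.n_background, 4, 0.1, seed=nx_seed)
    else:
        bg = nx.barabasi_albert_graph(cfg.n_background, 2, seed=nx_seed)
    g = nx.relabel_nodes(bg, {i: f"BG{i:04d}" for i in bg.nodes})

    a_nodes = [f"A{i:03d}" for i in range(cfg.module_size_a)]
    _wire_module(g, a_nodes, cfg.intra_density, rng)
    anchor = f"BG{int(rng.integers(cfg.n_background)):04d}"
    g.add_edge(a_nodes[0], anchor)

    if cfg.overlap_count > 0:
        shared = list(a_nodes[: cfg.overlap_count])
        fresh = [f"B{i:03d}" for i in range(cfg.module_size_b - cfg.overlap_count)]
        b_nodes = shared + fresh
        if fresh:
            _wire_module(g, b_nodes, cfg.intra_density, rng)
    else:
        b_nodes = [f"B{i:03d}" for i in range(cfg.module_size_b)]
        _wire_module(g, b_nodes, cfg.intra_density, rng)
        # spacer path: the only route between the modules, fixing d(A,B)
        chain = [a_nodes[0]]
        chain += [f"S{i:03d}" for i in range(cfg.planted_distance - 1)]
        chain.append(b_nodes[0])
        for u, v in zip(chain, chain[1:]):
            g.add_edge(u, v)

    full_overlap = (
        cfg.overlap_count == cfg.module_size_a == cfg.module_size_b
    )
    if full_overlap:
        expected = "negative"
    elif cfg.overlap_count == 0 and cfg.planted_distance >= 3:
        expected = "positive"
    else:
        expected = None
    return (
        Interactome(graph=g, provenance=f"planted({cfg.background_model})"),
        ProteinSet(label="module_A", members=frozenset(a_nodes)),
        ProteinSet(label="module_B", members=frozenset(b_nodes)),
        expected,
    )


# --------------------------------------------------------------------------
# calibration / QC batches

#: validated concentration ranges per biological matrix (ng/mL for plasma,
#: ng/g for tissues)
MATRIX_RANGES: dict[str, tuple[float, float]] = {
    "plasma": (5.0, 5000.0),
    "liver": (20.0, 2400.0),
    "heart": (20.0, 2400.0),
    "kidney": (50.0, 6000.0),
    "spleen": (20.0, 2400.0),
    "lung": (20.0, 2400.0),
    "skeletal_muscle": (20.0, 2400.0),
}

#: QC nominal levels (LLOQ, low, medium, high) per matrix
QC_LEVELS: dict[str, tuple[float, float, float, float]] = {
    "plasma": (5.0, 10.0, 500.0, 4000.0),
    "liver": (20.0, 40.0, 400.0, 2000.0),
    "heart": (20.0, 40.0, 400.0, 2000.0),
    "kidney": (50.0, 100.0, 1000.0, 5000.0),
    "spleen": (20.0, 40.0, 400.0, 2000.0),
    "lung": (20.0, 40.0, 400.0, 2000.0),
    "skeletal_muscle": (20.0, 40.0, 400.0, 2000.0),
}


@dataclass
class CalibrationSimConfig:
    """Linear-response assay truth for one biological matrix."""

    matrix_label: str = "plasma"
    slope: float = 0.0116263  # response per ng/mL
    intercept: float = 0.0132798
    cv: float = 0.05  # proportional response noise
    bias: float = 0.0  # fractional measurement bias of QC results
    n_levels: int = 8
    n_days: int = 3
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_label not in MATRIX_RANGES:
            raise ValueError(f"unknown matrix {self.matrix_label!r}")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


@dataclass
class CalibrationBatch:
    """Generated calibration points and QC replicates for one matrix."""

    calibration: pd.DataFrame  # columns: matrix, level, response
    qc: pd.DataFrame  # columns: matrix, level_kind, day, nominal, measured

    def qc_batches(self) -> dict[str, QCBatch]:
        """One pooled QCBatch per level kind (LLOQ/low/medium/high)."""
        out: dict[str, QCBatch] = {}
        for kind, sub in self.qc.groupby("level_kind", sort=False):
            out[str(kind)] = QCBatch(
                matrix_label=str(sub["matrix"].iloc[0]),
                nominal=float(sub["nominal"].iloc[0]),
                replicates=tuple(
                    (int(d), float(m)) for d, m in zip(sub["day"], sub["measured"])
                ),
            )
        return out


def generate_calibration_batch(cfg: CalibrationSimConfig) -> CalibrationBatch:
    """Simulate an 8-point calibration curve (geometric spacing over the
    matrix's validated range) and a 4-level x 5-replicate x 3-day QC set
    with proportional noise and an optional fractional bias."""
    low, high = MATRIX_RANGES[cfg.matrix_label]
    levels = np.geomspace(low, high, cfg.n_levels)
    rng_cal, rng_qc = (
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(2)
    )
    responses = (cfg.slope * levels + cfg.intercept) * _lognormal_factors(
        rng_cal, cfg.cv, levels.size
    )
    calibration = pd.DataFrame(
        {"matrix": cfg.matrix_label, "level": levels, "response": responses}
    )
    kinds = ("LLOQ", "low", "medium", "high")
    rows = []
    for kind, nominal in zip(kinds, QC_LEVELS[cfg.matrix_label]):
        for day in range(1, cfg.n_days + 1):
            measured = (
                nominal
                * (1.0 + cfg.bias)
                * _lognormal_factors(rng_qc, cfg.cv, cfg.n_replicates)
            )
            for m in measured:
                rows.append(
                    {
                        "matrix": cfg.matrix_label,
                        "level_kind": kind,
                        "day": day,
                        "nominal": nominal,
                        "measured": float(m),
                    }
                )
    return CalibrationBatch(calibration=calibration, qc=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# gene-set collections


def generate_gene_sets(
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 50),
    universe: Sequence[str] | int = 2000,
    planted_overlap: int = 0,
    query: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[GeneSetCollection, str | None]:
    """Random gene-set collection, optionally with one set planted to
    overlap a query by ``planted_overlap`` members.

    Returns the collection and the planted set's name (None when nothing
    was planted).
    """
    rng = np.random.default_rng(seed)
    if isinstance(universe, int):
        ids = [f"G{i:05d}" for i in range(universe)]
    else:
        ids = sorted(universe)
    lo, hi = set_size_range
    if not 1 <= lo <= hi <= len(ids):
        raise ValueError("invalid set_size_range for this universe")
    sets: dict[str, frozenset[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(ids, size=size, replace=False)
        sets[f"set_{i + 1:03d}"] = frozenset(members.tolist())
    planted_name: str | None = None
    if planted_overlap > 0:
        if query is None:
            raise ValueError("planting requires a query set")
        q = sorted(set(query) & set(ids))
        if planted_overlap > len(q):
            raise ValueError("planted_overlap exceeds the mapped query size")
        planted_name = f"set_{n_sets + 1:03d}"
        size = max(int(rng.integers(lo, hi + 1)), planted_overlap)
        hit = rng.choice(q, size=planted_overlap, replace=False).tolist()
        rest_pool = sorted(set(ids) - set(query))
        rest = rng.choice(rest_pool, size=size - planted_overlap, replace=False).tolist()
        sets[planted_name] = frozenset(hit + rest)
    collection = GeneSetCollection(sets=sets, universe=frozenset(ids))
    return collection, planted_name
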