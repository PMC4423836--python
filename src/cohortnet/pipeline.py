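"""End-to-end orchestration: recode -> select -> map -> complexity.

A single :class:`PipelineConfig` (loadable from YAML) drives the whole
analysis: read or simulate a cohort, expand it to indicator variables,
evolve a representative train/test split and a predictive feature mask,
train the Auto-CM on the selected indicators plus the Event/No_Event pair,
and build the MST, Meta-MST and per-group MRG complexity contrast.  Every
stochastic stage derives its seed from the single pipeline seed, so a
fixed config yields byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .autocm import saturating_C, similarity_matrix, train_autocm
from .datamodel import (
    EVENT_LABEL,
    NO_EVENT_LABEL,
    CohortTable,
    IndicatorMatrix,
    expand_indicators,
    load_schema,
    read_cohort,
    write_indicators,
)
from .ga import GAConfig
from .graphs import (
    GroupContrast,
    group_complexity_contrast,
    hub_nodes,
    meta_mst,
    mst_from_similarity,
    write_complexity,
    write_dot,
    write_edge_list,
    write_graphml,
)
from .learners import LearnerBank
from .synthdata import SimConfig, generate_cohort, nphs2_like_config
from .twist import FeatureMask, optimize_split, select_features, stratified_split

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything one run needs.  Exactly one of ``cohort_path`` (with
    ``schema_path``) or ``sim_config`` must be provided."""

    seed: int
    cohort_path: str | None = None
    schema_path: str | None = None
    sim_config: SimConfig | None = None
    outdir: str = "cohortnet_run"
    split_ga: GAConfig | None = None  # None -> stratified split, no T&T search
    select_ga: GAConfig = field(default_factory=lambda: GAConfig(population_size=30, generations=60))
    bank: LearnerBank = field(default_factory=LearnerBank)
    skip_selection: bool = False
    cost_kind: str = "misclassification"
    autocm_C: float | str = "auto"
    autocm_max_epochs: int = 1000
    autocm_tol: float = 1e-6
    k_resamples: int = 10
    drop_fraction: float = 0.1
    support_threshold: int = 9
    mrg_floor: float = 0.33
    target_fraction: float = 0.5

    def __post_init__(self):
        has_path = self.cohort_path is not None
        has_sim = self.sim_config is not None
        if has_path == has_sim:
            raise PipelineError("provide exactly one of cohort_path or sim_config")
        if has_path and self.schema_path is None:
            raise PipelineError("cohort_path requires schema_path")


@dataclass
class ResultBundle:
    """All in-memory products of one run plus the output directory."""

    config: PipelineConfig
    cohort: CohortTable
    indicators: IndicatorMatrix
    mask: FeatureMask
    split_membership: np.ndarray
    fitness_trace: np.ndarray
    mst: "object"
    meta: "object"
    contrast: GroupContrast
    hub_list: list[tuple[str, int]]
    dropped_constant: list[str]
    outdir: Path


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage seeds below 2**31 derived from the run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_full(config: PipelineConfig) -> ResultBundle:
    """Execute the full pipeline and write all artifacts to ``outdir``."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    timings: dict[str, float] = {}

    # --- stage 1: cohort -------------------------------------------------
    t = time.time()
    try:
        if config.sim_config is not None:
            config.sim_config.seed = seeds[0]
            cohort, truth = generate_cohort(config.sim_config)
            truth.to_json(outdir / "planted_truth.json")
        else:
            schema, outcome_col = load_schema(config.schema_path)
            cohort = read_cohort(config.cohort_path, schema, outcome_col)
    except Exception as exc:  # noqa: BLE001 - stage-named diagnostics
        raise PipelineError(f"cohort stage failed: {exc}") from exc
    timings["cohort"] = time.time() - t
    logger.info("cohort: %d rows (%d cases / %d controls), %d variables",
                cohort.n, cohort.n_cases, cohort.n_controls, len(cohort.variables))

    # --- stage 2: recode --------------------------------------------------
    t = time.time()
    try:
        indicators = expand_indicators(cohort, include_outcome=True)
    except Exception as exc:
        raise PipelineError(f"recode stage failed: {exc}") from exc
    timings["recode"] = time.time() - t
    logger.info("recode: %d indicator columns (+2 outcome nodes)",
                len(indicators.feature_columns))

    # --- stage 3: split + selection --------------------------------------
    t = time.time()
    features = indicators.feature_frame()
    # columns constant over the whole sample can never inform anything
    live = features.columns[(features.max() != features.min()).to_numpy()]
    dropped_constant = [c for c in features.columns if c not in set(live)]
    if dropped_constant:
        logger.info("selection: dropped %d constant column(s): %s",
                    len(dropped_constant), dropped_constant)
    features = features[live]
    try:
        if config.split_ga is not None:
            split_ga = GAConfig(**{**config.split_ga.__dict__, "seed": seeds[1]})
            split, _ = optimize_split(
                features.to_numpy(), cohort.outcome, split_ga, config.bank,
                config.target_fraction, config.cost_kind,
            )
        else:
            split = stratified_split(cohort.outcome, config.target_fraction, seeds[1])
        if config.skip_selection:
            mask = FeatureMask(np.ones(features.shape[1], dtype=np.int8), list(features.columns))
            trace = np.array([])
        else:
            select_ga = GAConfig(**{**config.select_ga.__dict__, "seed": seeds[2]})
            mask, ga_result = select_features(
                features.to_numpy(), cohort.outcome, split, select_ga,
                config.bank, config.cost_kind,
            )
            mask = FeatureMask(mask.bits, list(features.columns))
            trace = ga_result.trace
    except Exception as exc:
        raise PipelineError(f"selection stage failed: {exc}") from exc
    timings["selection"] = time.time() - t
    logger.info("selection: %d of %d indicator columns retained",
                len(mask.selected), features.shape[1])

    # --- stage 4: similarity map ------------------------------------------
    t = time.time()
    try:
        map_frame = indicators.data[mask.selected + [EVENT_LABEL, NO_EVENT_LABEL]]
        C = saturating_C(map_frame) if config.autocm_C == "auto" else float(config.autocm_C)
        model = train_autocm(
            map_frame, C=C, max_epochs=config.autocm_max_epochs, tol=config.autocm_tol,
        )
        sim = similarity_matrix(model)
        mst = mst_from_similarity(sim)
        meta = meta_mst(
            map_frame,
            k=config.k_resamples,
            drop_fraction=config.drop_fraction,
            support_threshold=config.support_threshold,
            seed=seeds[3],
            autocm_kwargs={"C": config.autocm_C, "max_epochs": config.autocm_max_epochs,
                           "tol": config.autocm_tol},
        )
    except Exception as exc:
        raise PipelineError(f"map stage failed: {exc}") from exc
    timings["map"] = time.time() - t

    # --- stage 5: per-group complexity ------------------------------------
    t = time.time()
    try:
        contrast = group_complexity_contrast(
            indicators.data[mask.selected],  # outcome columns excluded
            cohort.outcome,
            floor=config.mrg_floor,
            autocm_kwargs={"C": config.autocm_C, "max_epochs": config.autocm_max_epochs,
                           "tol": config.autocm_tol},
        )
    except Exception as exc:
        raise PipelineError(f"complexity stage failed: {exc}") from exc
    timings["complexity"] = time.time() - t

    hubs = hub_nodes(mst, top_k=10)

    # --- artifacts ---------------------------------------------------------
    write_indicators(indicators, outdir / "indicators")
    (outdir / "mask.json").write_text(json.dumps(
        {"selected": mask.selected, "removed": mask.removed,
         "dropped_constant": dropped_constant}, indent=1))
    np.savetxt(outdir / "fitness_trace.csv", trace, delimiter=",",
               header="best_fitness", comments="")
    (outdir / "split.json").write_text(json.dumps(
        {"membership": split.membership.tolist(),
         "train_cases": int(cohort.outcome[split.train_idx].sum()),
         "train_controls": int((1 - cohort.outcome[split.train_idx]).sum()),
         "test_cases": int(cohort.outcome[split.test_idx].sum()),
         "test_controls": int((1 - cohort.outcome[split.test_idx]).sum())}, indent=1))
    sim.to_frame().to_csv(outdir / "similarity.tsv", sep="\t")
    write_edge_list(mst, outdir / "mst_edges.tsv")
    write_graphml(mst, outdir / "mst.graphml")
    write_dot(mst, outdir / "mst.dot")
    write_edge_list(meta, outdir / "meta_mst_edges.tsv")
    write_edge_list(contrast.case_graph, outdir / "mrg_case_edges.tsv")
    write_edge_list(contrast.control_graph, outdir / "mrg_control_edges.tsv")
    (outdir / "complexity.json").write_text(json.dumps(contrast.to_dict(), indent=1))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_rows": cohort.n,
        "n_cases": cohort.n_cases,
        "n_controls": cohort.n_controls,
        "n_indicator_columns": len(indicators.feature_columns),
        "n_selected": len(mask.selected),
        "autocm_C": C,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t0, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    bundle = ResultBundle(
        config=config, cohort=cohort, indicators=indicators, mask=mask,
        split_membership=split.membership, fitness_trace=trace, mst=mst,
        meta=meta, contrast=contrast, hub_list=hubs,
        dropped_constant=dropped_constant, outdir=outdir,
    )
    report = run_report(bundle)
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    (outdir / "report.txt").write_text(_format_report(report))
    return bundle


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def _event_exclusive_nodes(tree, event: str, other: str) -> list[str]:
    """Nodes whose only tree path to the outcome reaches ``event`` without
    passing ``other`` — the directly associated branch of that outcome."""
    import networkx as nx

    if event not in tree or other not in tree:
        return []
    pruned = tree.copy()
    pruned.remove_node(other)
    comp = nx.node_connected_component(pruned, event)
    return sorted(c for c in comp if c != event)


def run_report(bundle: ResultBundle) -> dict:
    """Human-readable summary of a completed run."""
    mask = bundle.mask
    per_parent: dict[str, dict[str, list[str]]] = {}
    for label in mask.labels:
        parent, _ = bundle.indicators.parent_of(label)
        entry = per_parent.setdefault(parent, {"selected": [], "removed": []})
        entry["selected" if label in set(mask.selected) else "removed"].append(label)

    mst = bundle.mst
    event_path: list[str] = []
    if EVENT_LABEL in mst and NO_EVENT_LABEL in mst:
        import networkx as nx

        event_path = nx.shortest_path(mst, EVENT_LABEL, NO_EVENT_LABEL)

    meta_edges = bundle.meta.number_of_edges()
    report = {
        "n_selected": len(mask.selected),
        "n_removed": len(mask.removed),
        "selection_by_parent": {
            p: {"selected": len(v["selected"]), "removed": len(v["removed"])}
            for p, v in sorted(per_parent.items())
        },
        "hubs": [{"node": n, "degree": d} for n, d in bundle.hub_list],
        "event_to_noevent_path": event_path,
        "event_branch": _event_exclusive_nodes(mst, EVENT_LABEL, NO_EVENT_LABEL),
        "noevent_branch": _event_exclusive_nodes(mst, NO_EVENT_LABEL, EVENT_LABEL),
        "meta_mst_edges": meta_edges,
        "meta_mst_note": "no stable edges at threshold" if meta_edges == 0 else "",
        "delta_H": bundle.contrast.delta_H,
        "delta_E_G": bundle.contrast.delta_E_G,
        "case_complexity": bundle.contrast.case.to_dict(),
        "control_complexity": bundle.contrast.control.to_dict(),
    }
    return report


def _format_report(report: dict) -> str:
    lines = [
        f"selected indicators : {report['n_selected']}",
        f"removed indicators  : {report['n_removed']}",
        f"meta-MST edges      : {report['meta_mst_edges']}"
        + (f"  ({report['meta_mst_note']})" if report["meta_mst_note"] else ""),
        f"delta H (ctrl-case) : {report['delta_H']:+.4f}",
        f"delta E_G (ctrl-case): {report['delta_E_G']:+.2f}",
        "top hubs:",
    ]
    for h in report["hubs"][:5]:
        lines.append(f"  {h['node']}  degree {h['degree']}")
    if report["event_to_noevent_path"]:
        lines.append("Event <-> No_Event path: " + " -- ".join(report["event_to_noevent_path"]))
    return "\n".join(lines) + "\n"


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    Recognized top-level keys mirror the dataclass fields; ``sim_config``,
    ``split_ga``, ``select_ga`` and ``bank`` may be nested mappings, and
    ``sim_config: nphs2`` requests the study-shaped default cohort.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = dict(raw)
    sim = kwargs.pop("sim_config", None)
    if sim == "nphs2":
        kwargs["sim_config"] = nphs2_like_config()
    elif isinstance(sim, dict):
        kwargs["sim_config"] = SimConfig(**sim)
    for key, cls in (("split_ga", GAConfig), ("select_ga", GAConfig), ("bank", LearnerBank)):
        if isinstance(kwargs.get(key), dict):
            sub = kwargs[key]
            if cls is LearnerBank and "enabled" in sub:
                sub["enabled"] = tuple(sub["enabled"])
            kwargs[key] = cls(**sub)
    return PipelineConfig(**kwargs)
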