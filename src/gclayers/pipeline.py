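"""End-to-end driver chaining all analysis stages.

simulate → preprocess → assign → network → layers → cml → survive.
Each stage reads the previous stage's declared outputs, writes its own
files under the output directory, and contributes a block to the final
machine-readable report. Identical config + seed gives a byte-identical
report.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, preprocess as pp, report as rp, subtypes, synthetic
from .cml import build_cml, cluster_cml, crosstab
from .config import PipelineConfig, stage_seed
from .layers import extract_layers, redundancy_report
from .matrix import ExpressionMatrix
from .network import (
    build_functional_nodes,
    forward_bic_search,
    ml_spanning_tree,
    node_activity,
    partition_branches,
)
from .survival import compare_activities, hazard_ratio, kaplan_meier, logrank_test, plot_km

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "DependencyError"]


class DependencyError(RuntimeError):
    """A stage's required upstream outputs are unavailable."""


def _require(art: dict, key: str, stage: str):
    if key not in art:
        raise DependencyError(
            f"stage {stage!r} requires {key!r}; enable the producing stage"
        )
    return art[key]


def _stage_simulate(cfg: PipelineConfig, out: Path, art: dict) -> dict:
    sc = cfg.simulate
    seed = stage_seed(cfg.seed, "simulate")
    defaults = synthetic.DEFAULT_LAYER_SPECS
    if (
        sc.layer_sizes == [sp.n_genes for sp in defaults]
        and sc.layer_groups == [sp.n_groups for sp in defaults]
    ):
        specs = [dataclasses.replace(sp, effect_size=sc.effect_size) for sp in defaults]
    else:
        specs = [
            synthetic.LayerSpec(n, g, effect_size=sc.effect_size)
            for n, g in zip(sc.layer_sizes, sc.layer_groups)
        ]
    n_background = sc.total_genes - sum(sc.layer_sizes)
    if n_background < 0:
        raise ValueError("total_genes smaller than the sum of layer sizes")
    matrix, truth = synthetic.generate_cohort(
        n_samples=sc.n_samples,
        layer_specs=specs,
        n_background_genes=n_background,
        noise_sd=sc.noise_sd,
        subtype_props=sc.subtype_props,
        subtype_layers=sc.subtype_layers,
        seed=seed,
    )
    if sc.missing_rate > 0:
        matrix = synthetic.inject_missing(matrix, sc.missing_rate, seed=seed + 1)
    clinical = synthetic.attach_survival(
        truth,
        driving_layer=sc.survival_layer,
        log_hazard_ratios=sc.log_hazard_ratios,
        baseline_rate=sc.baseline_rate,
        censor_rate=sc.censor_rate,
        seed=seed + 2,
    )
    rng = np.random.default_rng(seed + 3)
    n_hide = int(round(sc.unlabeled_fraction * sc.n_samples))
    hidden = set(
        rng.choice(clinical["sample_id"], size=n_hide, replace=False)
    )
    clinical["subtype"] = [
        "" if s in hidden else sub
        for s, sub in zip(clinical["sample_id"], clinical["subtype"])
    ]
    io.write_expression(matrix, out / "expression.tsv")
    io.write_clinical(clinical, out / "clinical.tsv")
    truth.to_json(out / "truth.json")
    io.write_gmt(synthetic.truth_gmt(truth), out / "truth_sets.gmt")
    art.update(matrix=matrix, clinical=clinical, truth=truth,
               annotation=synthetic.truth_gmt(truth))
    return {
        "n_samples": matrix.n_samples,
        "n_genes": matrix.n_genes,
        "n_missing": matrix.n_missing,
        "n_unlabeled": len(hidden),
        "subtype_truth": rp.group_size_report(pd.Series(truth.subtype)),
    }


def _stage_preprocess(cfg: PipelineConfig, out: Path, art: dict) -> dict:
    pc = cfg.preprocess
    seed = stage_seed(cfg.seed, "preprocess")
    matrix: ExpressionMatrix = _require(art, "matrix", "preprocess")
    n0 = matrix.n_genes
    if not pc.pre_logged:
        matrix = pp.log2_transform(matrix, offset=pc.log2_offset)
    matrix = pp.filter_valid(matrix, min_fraction=pc.min_valid_fraction)
    if matrix.n_missing:
        matrix = pp.impute_missing(
            matrix, width=pc.impute_width, downshift=pc.impute_downshift, seed=seed
        )
    matrix = pp.select_most_variable(matrix, n=pc.top_n)
    io.write_expression(matrix, out / "processed.tsv")
    art["processed"] = matrix
    return {
        "n_genes_in": n0,
        "n_genes_kept": matrix.n_genes,
        "n_samples": matrix.n_samples,
    }


def _stage_assign(cfg: PipelineConfig, out: Path, art: dict) -> dict:
    ac = cfg.assign
    seed = stage_seed(cfg.seed, "assign")
    matrix: ExpressionMatrix = _require(art, "processed", "assign")
    clinical: pd.DataFrame = _require(art, "clinical", "assign")
    known = clinical.set_index("sample_id")["subtype"]
    known = known[known != ""]
    # SAM needs >= 2 labeled samples per class; rarer subtypes still get
    # centroids and can be assigned, they just do not shape the panel
    counts = known.value_counts()
    sam_labels = known[known.map(counts) >= 2]
    if set(sam_labels) != set(known):
        log.warning("subtype(s) %s have < 2 labeled samples; excluded from SAM",
                    sorted(set(known) - set(sam_labels)))
    sam = subtypes.sam_multiclass(
        matrix, sam_labels, n_permutations=ac.n_permutations, fdr=ac.fdr, seed=seed
    )
    panel = sam.significant if (ac.panel == "sam" and len(sam.significant) >= 3) else matrix.genes
    centroids = subtypes.compute_centroids(matrix, known, panel)
    assignments = subtypes.assign_samples(matrix, centroids, known=known)
    assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
    art["assignments"] = assignments
    art["subtype_labels"] = assignments.set_index("sample_id")["assigned_subtype"]
    return {
        "sam_s0": sam.s0,
        "n_sam_significant": len(sam.significant),
        "panel_size": len(panel),
        "subtype_distribution": rp.group_size_report(art["subtype_labels"]),
    }


def _stage_network(cfg: PipelineConfig, out: Path, art: dict) -> dict:
    nc = cfg.network
    matrix: ExpressionMatrix = _require(art, "processed", "network")
    tree = ml_spanning_tree(matrix)
    net = forward_bic_search(tree, matrix, max_added_edges=nc.max_added_edges)
    branches = partition_branches(
        net.graph,
        max_branch_size=nc.max_branch_size,
        min_branch_size=nc.min_branch_size,
        n_branches=nc.n_branches,
    )
    annotation = art.get("annotation")
    nodes = None
    if annotation:
        nodes = build_functional_nodes(
            matrix, branches, annotation,
            q_threshold=nc.enrichment_q, all_branch_genes=nc.all_branch_genes,
        )
        activities = node_activity(
            matrix, {f"node_{n.branch_id}": n.genes for n in nodes}
        )
        activities.to_csv(out / "node_activities.tsv", sep="\t")
        art["node_activities"] = activities
        art["functional_nodes"] = nodes
    edges = pd.DataFrame(
        [
            {"gene_a": a, "gene_b": b, "delta_bic": net.edge_gain.get((a, b), float("nan"))}
            for a, b in net.edges
        ]
    )
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    import networkx as nx

    nx.write_graphml(net.graph, out / "network.graphml")
    art["network"] = net
    art["branches"] = branches
    return {
        "n_edges_tree": tree.graph.number_of_edges(),
        "n_edges_final": net.graph.number_of_edges(),
        "bic": net.bic,
        "n_branches": len(set(branches.values())),
        "node_functions": {
            str(n.branch_id): n.main_function for n in (nodes or [])
        },
    }


def _stage_layers(cfg: PipelineConfig, out: Path, art: dict) -> dict:
    lc = cfg.layers
    seed = stage_seed(cfg.seed, "layers")
    matrix: ExpressionMatrix = _require(art, "processed", "layers")
    layers = extract_layers(
        matrix,
        max_layers=lc.max_layers,
        k_range=lc.k_range,
        stop_pac=lc.stop_pac,
        s=lc.sparsity,
        n_resample=lc.n_resample,
        p_sample=lc.p_sample,
        n_starts=lc.n_starts,
        n_tune_permutations=lc.n_tune_permutations,
        weight_threshold_frac=lc.weight_threshold_frac,
        min_pool=lc.min_pool,
        seed=seed,
    )
    summary = {}
    for layer in layers:
        pd.DataFrame(
            {"gene_id": layer.genes, "weight": layer.weights.loc[layer.genes]}
        ).to_csv(out / f"layer{layer.index}_genes.tsv", sep="\t", index=False)
        layer.labels.rename("group").rename_axis("sample_id").to_csv(
            out / f"layer{layer.index}_labels.tsv", sep="\t"
        )
        if layer.consensus is not None:
            layer.consensus.consensus[layer.k].to_csv(
                out / f"layer{layer.index}_consensus.tsv", sep="\t"
            )
        summary[str(layer.index)] = {
            "n_genes": layer.n_genes,
            "k": layer.k,
            "pac": layer.pac,
            "groups": rp.group_size_report(layer.labels),
        }
    art["layers"] = layers
    return {"n_layers": len(layers), "layers": summary}


def _stage_cml(cfg: PipelineConfig, out: Path, art: dict) -> dict:
    cc = cfg.cml
    seed = stage_seed(cfg.seed, "cml")
    matrix: ExpressionMatrix = _require(art, "processed", "cml")
    layers = _require(art, "layers", "cml")
    available = [layer.index for layer in layers]
    include = [i for i in cc.include_layers if i in available]
    if not include:
        include = available
    if include != list(cc.include_layers):
        log.warning("CML includes layers %s (requested %s)", include, cc.include_layers)
    redundancy = redundancy_report(layers, warn_threshold=cc.redundancy_warn)
    genes = build_cml(layers, include)
    labels, ccres = cluster_cml(
        matrix, genes, k_range=cc.k_range,
        n_resample=cc.n_resample, p_sample=cc.p_sample, seed=seed,
    )
    pd.Series(genes, name="gene_id").to_csv(out / "cml_genes.tsv", sep="\t", index=False)
    labels.rename("cml_group").rename_axis("sample_id").to_csv(
        out / "cml_labels.tsv", sep="\t"
    )
    art["cml_labels"] = labels
    art["cml_genes"] = genes
    block: dict = {
        "included_layers": include,
        "n_genes": len(genes),
        "k": ccres.k_star,
        "pac": ccres.pac[ccres.k_star],
        "groups": rp.group_size_report(labels, decimals=2),
        "redundancy": rp.jsonify(redundancy.to_dict(orient="records")),
    }
    if "subtype_labels" in art:
        xt = crosstab(labels, art["subtype_labels"], seed=seed + 1)
        xt.table.to_csv(out / "cml_by_subtype.tsv", sep="\t")
        block["crosstab_subtype"] = {
            "test": xt.test,
            "statistic": xt.statistic,
            "p_value": xt.p_value,
            "table": rp.jsonify(xt.table),
        }
    return block


def _stage_survive(cfg: PipelineConfig, out: Path, art: dict) -> dict:
    clinical: pd.DataFrame = _require(art, "clinical", "survive")
    times = clinical.set_index("sample_id")["os_months"]
    events = clinical.set_index("sample_id")["event"]
    block: dict = {"n_events": int(events.sum()), "n_subjects": int(len(events))}

    def _survival_block(labels: pd.Series, name: str) -> dict:
        common = [s for s in labels.index if s in times.index]
        lab = labels.loc[common]
        t, e = times.loc[common].to_numpy(), events.loc[common].to_numpy()
        res: dict = {"groups": {}}
        for g in sorted(lab.unique()):
            m = (lab == g).to_numpy()
            curve = kaplan_meier(t[m], e[m])
            res["groups"][str(g)] = {
                "n": int(m.sum()),
                "events": int(e[m].sum()),
                "median_os": curve.median if curve.median is not None else "not reached",
            }
        if lab.nunique() >= 2:
            lr = logrank_test(t, e, lab.to_numpy())
            res["logrank"] = {"statistic": lr.statistic, "df": lr.df, "p_value": lr.p_value}
        if lab.nunique() == 2 and e.sum() > 0:
            hr = hazard_ratio(t, e, lab.to_numpy())
            res["cox"] = {"hr": hr.hr, "ci": list(hr.ci), "p_value": hr.p_value}
        if cfg.survive.plots:
            plot_km(t, e, lab.to_numpy(), out / f"km_{name}.png")
        return res

    if "cml_labels" in art:
        block["cml"] = _survival_block(art["cml_labels"], "cml")
    if "subtype_labels" in art:
        block["subtype"] = _survival_block(art["subtype_labels"], "subtype")
    if "layers" in art:
        block["layers"] = {
            str(layer.index): _survival_block(layer.labels, f"layer{layer.index}")
            for layer in art["layers"]
        }
    if "node_activities" in art and "cml_labels" in art:
        acts = art["node_activities"]
        lab = art["cml_labels"]
        common = [s for s in lab.index if s in acts.columns]
        tests = {}
        for node in acts.index:
            res = compare_activities(
                acts.loc[node, common].to_numpy(), lab.loc[common].to_numpy()
            )
            tests[str(node)] = {"test": res.test, "statistic": res.statistic,
                                "p_value": res.p_value}
        block["node_activity_tests"] = tests
    return block


_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "assign": _stage_assign,
    "network": _stage_network,
    "layers": _stage_layers,
    "cml": _stage_cml,
    "survive": _stage_survive,
}


def run_pipeline(cfg: PipelineConfig, inputs: dict | None = None) -> dict:
    """Run the configured stages in order and return the report dict.

    ``inputs`` may pre-populate artifacts (e.g. a real ``matrix`` and
    ``clinical`` table instead of the simulate stage). Outputs, the
    resolved config, a MANIFEST of completed stages and ``report.json``
    are written under ``cfg.outdir``.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, cfg.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    cfg.to_yaml(out / "resolved_config.yaml")
    art: dict = dict(inputs or {})
    report: dict = {
        "schema_version": rp.SCHEMA_VERSION,
        "seed": cfg.seed,
        "config": cfg.model_dump(mode="json"),
        "stages": {},
    }
    completed: list[str] = []
    manifest = out / "MANIFEST"
    unknown = [s for s in cfg.stages if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}")
    try:
        for name in cfg.stages:
            log.info("stage %s starting", name)
            report["stages"][name] = _STAGES[name](cfg, out, art)
            completed.append(name)
            manifest.write_text("".join(f"{s}\n" for s in completed))
    except Exception as exc:
        manifest.write_text("".join(f"{s}\n" for s in completed))
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    rp.dump_report(report, out / "report.json")
    return report
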