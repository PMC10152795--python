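"""Command-line orchestration: train / predict / evaluate / select-features /
calibrate / explain / simulate / kgdist / gosim.

Every run writes a manifest JSON (subcommand, parameters, seeds, package
version) next to its outputs so results are reproducible from the
manifest alone.  Exit codes: 0 ok, 2 input error, 3 config error.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__, balanced_forest, evaluation, feature_search
from . import feature_model as fm
from . import go_similarity as gos
from . import interpretation as interp
from . import kg_distance as kg
from . import synthetic_data as synth

logger = logging.getLogger("bilocus")

EXIT_INPUT_ERROR = 2
EXIT_CONFIG_ERROR = 3


def _write_manifest(out_path: Path, subcommand: str, params: dict) -> None:
    manifest = {
        "tool": "bilocus",
        "version": __version__,
        "subcommand": subcommand,
        "params": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
    }
    manifest_path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _fail(code: int, message: str):
    click.echo(f"error: {message}", err=True)
    sys.exit(code)


def _load_labeled(path):
    try:
        combos = fm.read_combinations(path)
    except (OSError, fm.CombinationFormatError) as exc:
        _fail(EXIT_INPUT_ERROR, str(exc))
    return combos


def _split_classes(combos):
    pos = [c for c in combos if c.label == "disease_causing"]
    neg = [c for c in combos if c.label == "neutral"]
    if not pos or not neg:
        _fail(EXIT_INPUT_ERROR, "training data must contain both classes")
    return pos, neg


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="debug logging to stderr")
def cli(verbose: bool):
    """Pathogenicity prediction for bilocus variant combinations."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command()
@click.option("--combinations", "combo_path", required=True, type=click.Path(exists=True))
@click.option("--model-out", required=True, type=click.Path())
@click.option("--layout", default="production15", type=click.Choice(sorted(fm.LAYOUTS)))
@click.option("--n-trees", default=400, show_default=True)
@click.option("--max-depth", default=10, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--logo-report", type=click.Path(), default=None,
              help="also run gene-pair LOGO CV and write its JSON report")
def train(combo_path, model_out, layout, n_trees, max_depth, seed, logo_report):
    """Train the balanced forest on a labeled combination TSV."""
    combos = _load_labeled(combo_path)
    pos, neg = _split_classes(combos)
    lay = fm.LAYOUTS[layout]
    try:
        config = balanced_forest.ForestConfig(n_trees=n_trees, max_depth=max_depth, seed=seed)
    except ValueError as exc:
        _fail(EXIT_CONFIG_ERROR, str(exc))
    imputer = fm.fit_imputer(pos, neg, lay, strict=False)
    X_pos = fm.vectorize_all(pos, imputer)
    X_neg = fm.vectorize_all(neg, imputer)
    model = balanced_forest.train(X_pos, X_neg, config, lay, imputer)
    out = Path(model_out)
    balanced_forest.save_model(model, out)
    if logo_report:
        result = evaluation.run_logo_cv(combos, config, lay)
        Path(logo_report).write_text(json.dumps({
            "report": result.report.as_dict(),
            "roc_auc": result.curves.roc_auc,
            "average_precision": result.curves.average_precision,
            "skipped_folds": [list(k) for k in result.skipped_folds],
        }, indent=2) + "\n")
    _write_manifest(out, "train", {
        "combinations": combo_path, "layout": layout, "n_trees": n_trees,
        "max_depth": max_depth, "seed": seed,
    })
    click.echo(f"trained {config.n_trees}-tree balanced forest -> {model_out}")


def _load_zones(zones_path):
    if zones_path is None:
        return evaluation.PUBLISHED_ZONES
    data = json.loads(Path(zones_path).read_text())
    return evaluation.ConfidenceZones(thresholds=data["thresholds"])


@cli.command()
@click.option("--model", "model_path", required=True, type=click.Path(exists=True))
@click.option("--combinations", "combo_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--zones", "zones_path", type=click.Path(exists=True), default=None,
              help="zones JSON from `calibrate` (default: the published thresholds)")
def predict(model_path, combo_path, out_path, zones_path):
    """Per-row probability, class at 0.5, and confidence zone."""
    try:
        model = balanced_forest.load_model(model_path)
    except ValueError as exc:
        _fail(EXIT_INPUT_ERROR, str(exc))
    combos = _load_labeled(combo_path)
    zones = _load_zones(zones_path)
    out = Path(out_path)
    if combos:
        X = fm.vectorize_all(combos, model.imputer, model.layout)
        prob = model.predict_proba(X)
    else:
        prob = np.array([])
    frame = pd.DataFrame({
        "gene_a_id": [c.pair_key[0] for c in combos],
        "gene_b_id": [c.pair_key[1] for c in combos],
        "probability": prob,
        "class": [balanced_forest.classify(p) for p in prob],
        "zone": [evaluation.assign_zone(p, zones) for p in prob],
    })
    frame.to_csv(out, sep="\t", index=False)
    _write_manifest(out, "predict", {
        "model": model_path, "combinations": combo_path, "zones": zones_path,
    })


@cli.command()
@click.option("--combinations", "combo_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--layout", default="production15", type=click.Choice(sorted(fm.LAYOUTS)))
@click.option("--n-trees", default=400, show_default=True)
@click.option("--max-depth", default=10, show_default=True)
@click.option("--seed", default=0, show_default=True)
def evaluate(combo_path, out_path, layout, n_trees, max_depth, seed):
    """Gene-pair LOGO cross-validation report on a labeled TSV."""
    combos = _load_labeled(combo_path)
    _split_classes(combos)
    config = balanced_forest.ForestConfig(n_trees=n_trees, max_depth=max_depth, seed=seed)
    result = evaluation.run_logo_cv(combos, config, fm.LAYOUTS[layout])
    out = Path(out_path)
    out.write_text(json.dumps({
        "report": result.report.as_dict(),
        "roc_auc": result.curves.roc_auc,
        "average_precision": result.curves.average_precision,
        "skipped_folds": [list(k) for k in result.skipped_folds],
    }, indent=2) + "\n")
    _write_manifest(out, "evaluate", {
        "combinations": combo_path, "layout": layout, "n_trees": n_trees,
        "max_depth": max_depth, "seed": seed,
    })


@cli.command("select-features")
@click.option("--combinations", "combo_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--restarts", default=20, show_default=True)
@click.option("--neighbors", default=10, show_default=True)
@click.option("--stability-steps", default=20, show_default=True)
@click.option("--cv-folds", default=5, show_default=True)
@click.option("--forest-trees", default=100, show_default=True)
@click.option("--seed", default=0, show_default=True)
def select_features(combo_path, out_path, restarts, neighbors, stability_steps,
                    cv_folds, forest_trees, seed):
    """Wrapper feature search on a balanced sample of a labeled TSV.

    Defaults are a desk-scale profile; the reference configuration used
    10,000 restarts with 100 stability steps.
    """
    combos = _load_labeled(combo_path)
    pos, neg = _split_classes(combos)
    lay = fm.FULL20_LAYOUT
    imputer = fm.fit_imputer(pos, neg, lay, strict=False)
    rng = np.random.default_rng(seed)
    neg_sample = [neg[i] for i in rng.choice(len(neg), size=min(len(pos), len(neg)), replace=False)]
    X = np.vstack([fm.vectorize_all(pos, imputer), fm.vectorize_all(neg_sample, imputer)])
    y = np.array([1] * len(pos) + [0] * len(neg_sample))
    try:
        config = feature_search.SearchConfig(
            n_restarts=restarts, neighbors_per_step=neighbors,
            stability_steps=stability_steps, cv_folds=cv_folds,
            forest_trees=forest_trees, seed=seed,
        )
    except ValueError as exc:
        _fail(EXIT_CONFIG_ERROR, str(exc))
    result = feature_search.local_search(X, y, config)
    selected = [lay.features[i] for i in
                feature_search.mask_to_indices(result.best_mask, len(lay))]
    out = Path(out_path)
    out.write_text(json.dumps({
        "selected_features": selected,
        "objective_mean_f1": result.best_objective,
        "n_restarts": restarts,
        "cache": {"hits": result.cache.hits, "misses": result.cache.misses},
        "restart_final_objectives": [t[-1] for t in result.traces],
    }, indent=2) + "\n")
    _write_manifest(out, "select-features", {
        "combinations": combo_path, "restarts": restarts, "neighbors": neighbors,
        "stability_steps": stability_steps, "cv_folds": cv_folds,
        "forest_trees": forest_trees, "seed": seed,
    })
    click.echo(f"best subset ({len(selected)} features, mean F1 "
               f"{result.best_objective:.3f}): {', '.join(selected)}")


@cli.command()
@click.option("--model", "model_path", required=True, type=click.Path(exists=True))
@click.option("--combinations", "combo_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--densities", default="0.01,0.001", show_default=True,
              help="comma-separated target FP densities, strictest last")
def calibrate(model_path, combo_path, out_path, densities):
    """Confidence-zone thresholds from a neutral-only calibration TSV."""
    model = balanced_forest.load_model(model_path)
    combos = _load_labeled(combo_path)
    non_neutral = [c for c in combos if c.label != "neutral"]
    if non_neutral:
        _fail(EXIT_INPUT_ERROR,
              f"calibration set contains {len(non_neutral)} non-neutral rows "
              "(possible leakage from the training or positive set)")
    try:
        dens = [float(d) for d in densities.split(",")]
    except ValueError:
        _fail(EXIT_CONFIG_ERROR, f"bad densities {densities!r}")
    X = fm.vectorize_all(combos, model.imputer, model.layout)
    prob = model.predict_proba(X)
    fp_densities = {f"{(1 - d) * 100:g}%": d for d in dens}
    zones = evaluation.calibrate_zones(prob, fp_densities)
    out = Path(out_path)
    out.write_text(json.dumps({
        "thresholds": dict(zones.thresholds),
        "classification_threshold": zones.classification_threshold,
        "n_calibration": len(prob),
    }, indent=2) + "\n")
    _write_manifest(out, "calibrate", {
        "model": model_path, "combinations": combo_path, "densities": densities,
    })


@cli.command()
@click.option("--model", "model_path", required=True, type=click.Path(exists=True))
@click.option("--combinations", "combo_path", type=click.Path(exists=True), default=None,
              help="labeled TSV for per-class contribution distributions")
@click.option("--importance-out", type=click.Path(), default=None)
@click.option("--contributions-out", type=click.Path(), default=None)
@click.option("--class-label", default="disease_causing", show_default=True)
def explain(model_path, combo_path, importance_out, contributions_out, class_label):
    """Gini importance and local contribution distributions as TSV."""
    model = balanced_forest.load_model(model_path)
    if importance_out:
        report = interp.gini_importance(model)
        report.to_frame().to_csv(importance_out, sep="\t", index=False)
        _write_manifest(Path(importance_out), "explain", {"model": model_path})
    if contributions_out:
        if combo_path is None:
            _fail(EXIT_CONFIG_ERROR, "--contributions-out requires --combinations")
        combos = _load_labeled(combo_path)
        X = fm.vectorize_all(combos, model.imputer, model.layout)
        labels = np.array([c.label for c in combos])
        frame = interp.contribution_report(model, X, labels, class_label)
        frame.to_csv(contributions_out, sep="\t", index=False)
        _write_manifest(Path(contributions_out), "explain", {
            "model": model_path, "combinations": combo_path, "class_label": class_label,
        })


@cli.command()
@click.option("--out-dir", required=True, type=click.Path())
@click.option("--n-positive", default=50, show_default=True)
@click.option("--ratio", default=100, show_default=True,
              help="desk-scale default; pass 500 for the reference imbalance")
@click.option("--effect-scale", default=1.0, show_default=True)
@click.option("--seed", default=0, show_default=True)
def simulate(out_dir, n_positive, ratio, effect_scale, seed):
    """Write a synthetic labeled cohort TSV plus graph and ontology fixtures."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        spec = synth.CohortSpec(n_positive=n_positive, imbalance_ratio=ratio,
                                effect_scale=effect_scale, seed=seed)
    except ValueError as exc:
        _fail(EXIT_CONFIG_ERROR, str(exc))
    pos, neg = synth.gen_cohort(spec)
    fm.write_combinations(pos + neg, out / "cohort.tsv")
    g = synth.gen_knowledge_graph(seed=seed)
    pd.DataFrame(
        [(n, d["node_type"]) for n, d in g.nodes(data=True)],
        columns=["node_id", "node_type"],
    ).to_csv(out / "kg_nodes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(u, v, d.get("relation", "")) for u, v, d in g.edges(data=True)],
        columns=["node_id_1", "node_id_2", "relation"],
    ).to_csv(out / "kg_edges.tsv", sep="\t", index=False)
    ontology, corpus = synth.gen_ontology_corpus(seed=seed)
    rows = [(gene, t) for gene, ts in corpus.gene_terms.items() for t in sorted(ts)]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        out / "annotations.tsv", sep="\t", index=False)
    _write_manifest(out / "cohort.tsv", "simulate", {
        "n_positive": n_positive, "ratio": ratio,
        "effect_scale": effect_scale, "seed": seed,
    })
    click.echo(f"wrote {len(pos)} positive + {len(neg)} neutral combinations to {out}")


@cli.command()
@click.option("--nodes", "node_path", required=True, type=click.Path(exists=True))
@click.option("--edges", "edge_path", required=True, type=click.Path(exists=True))
@click.option("--pairs", "pairs_path", required=True, type=click.Path(exists=True),
              help="TSV with columns gene1, gene2")
@click.option("--out", "out_path", required=True, type=click.Path())
def kgdist(node_path, edge_path, pairs_path, out_path):
    """Normalized knowledge-graph distance for each gene pair."""
    try:
        g = kg.load_graph(node_path, edge_path)
        pairs = pd.read_csv(pairs_path, sep="\t", dtype=str)
        table = kg.pair_distances(g, pairs[["gene1", "gene2"]].itertuples(index=False, name=None))
    except (kg.GraphFormatError, KeyError, ValueError) as exc:
        _fail(EXIT_INPUT_ERROR, str(exc))
    table.to_csv(out_path, sep="\t", index=False, na_rep=".")
    _write_manifest(Path(out_path), "kgdist", {
        "nodes": node_path, "edges": edge_path, "pairs": pairs_path,
    })


@cli.command()
@click.option("--obo", "obo_path", required=True, type=click.Path(exists=True))
@click.option("--annotations", "ann_path", required=True, type=click.Path(exists=True))
@click.option("--pairs", "pairs_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def gosim(obo_path, ann_path, pairs_path, out_path):
    """BP/MF/CC SimGIC-BMA similarity for each gene pair."""
    try:
        ontology = gos.read_obo(obo_path)
        corpus = gos.AnnotationCorpus(ontology, gos.read_annotations(ann_path))
        pairs = pd.read_csv(pairs_path, sep="\t", dtype=str)
    except (OSError, ValueError, KeyError) as exc:
        _fail(EXIT_INPUT_ERROR, str(exc))
    rows = []
    for g1, g2 in pairs[["gene1", "gene2"]].itertuples(index=False, name=None):
        sims = gos.gene_pair_similarities(corpus, g1, g2)
        rows.append({"gene1": g1, "gene2": g2, **sims})
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False, na_rep=".")
    _write_manifest(Path(out_path), "gosim", {
        "obo": obo_path, "annotations": ann_path, "pairs": pairs_path,
    })


if __name__ == "__main__":
    cli()
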