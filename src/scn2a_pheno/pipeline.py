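"""End-to-end orchestration: harmonize → associate → similarity → reduce.

``run_all`` validates and loads every input before writing anything, runs the
four analysis stages with per-stage random streams spawned from one seed (so
changing, say, the permutation count never perturbs the PCA), writes a stable
output layout under the configured directory, and finishes with a
machine-readable manifest of input/output checksums.  Identical configuration
and inputs give identical manifests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .association import associate, fisher_2x2, location_associations
from .harmonize import (
    annotation_frequencies,
    build_phenotype_matrix,
    compare_term_frequencies,
    harmonize_cohort,
    to_long_table,
)
from .ontology import parse_obo
from .reduction import evaluate_component, fit_logistic_pca, predict_variant_function, select_m
from .similarity import SimilarityEngine, phenogram, run_similarity_suite
from .variants import ProteinTopology, build_variant_records, load_bundled_topology

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    ontology_path: str
    annotations_path: str
    variants_path: str
    outdir: str
    topology_path: str | None = None      # None -> bundled approximate topology
    evidence_path: str | None = None      # None -> functional_evidence column
    restrict_to: str | None = None        # e.g. the phenotypic-abnormality term
    q: float = 0.10                       # FDR level of every BH correction
    n_permutations: int = 100_000
    k: int = 3                            # logistic-PCA components
    m: float = 4.0                        # natural-parameter scale
    cv_m: bool = False                    # select m by 5-fold CV instead
    min_count: int = 2                    # minimum carriers for a PCA column
    phenogram_min_group: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.n_permutations < 1 or self.k < 1:
            raise ValueError("n_permutations and k must be >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", **kw)


def run_all(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    # -- load and validate everything up front --------------------------------
    ontology = parse_obo(config.ontology_path, restrict_to=config.restrict_to)
    annotations = pio.read_annotations(config.annotations_path)
    variants_df = pio.read_variants(config.variants_path)
    topology = (ProteinTopology.from_tsv(config.topology_path)
                if config.topology_path else load_bundled_topology())
    evidence = pio.read_evidence(config.evidence_path) if config.evidence_path else None
    records = build_variant_records(variants_df, topology=topology, evidence=evidence)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_similarity, seed_pca = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    # -- harmonize -------------------------------------------------------------
    sets = harmonize_cohort(ontology, annotations)
    n = len(sets)
    _write(to_long_table(sets), outdir / "harmonized" / "annotations_long.tsv", index=False)
    freq = {}
    for which in ("base_pos", "prop_pos", "base_neg", "prop_neg_full", "prop_neg_pruned"):
        freq[which] = annotation_frequencies(sets, which=which, n=n)
        _write(freq[which], outdir / "frequencies" / f"{which}.tsv")
    shift = compare_term_frequencies(freq["base_pos"], freq["prop_pos"], n, q=config.q)
    _write(shift, outdir / "frequencies" / "propagation_shift.tsv")

    matrix = build_phenotype_matrix(sets, min_count=1)

    # -- association -----------------------------------------------------------
    broad = {r.individual_id: r.broad for r in records}
    mask = matrix.index.map(lambda i: broad.get(i) in ("missense", "PTV"))
    class_matrix = matrix.loc[mask]
    is_ptv = pd.Series(
        [broad[i] == "PTV" for i in class_matrix.index], index=class_matrix.index
    )
    class_assoc = associate(class_matrix, is_ptv, q=config.q, analysis="PTV_vs_missense")
    _write(class_assoc, outdir / "association" / "class_associations.tsv", index=False)

    missense_ids = [r.individual_id for r in records if r.broad == "missense"]
    loc_groups: dict[str, set[str]] = {}
    for r in records:
        if r.broad != "missense" or r.location is None:
            continue
        if r.location.domain:
            loc_groups.setdefault(f"domain {r.location.domain}", set()).add(r.individual_id)
        if r.location.segment:
            loc_groups.setdefault(f"segment {r.location.segment}", set()).add(r.individual_id)
        if r.location.pore_loop:
            loc_groups.setdefault("pore loop", set()).add(r.individual_id)
    missense_matrix = matrix.loc[matrix.index.isin(missense_ids)]
    loc_assoc = location_associations(loc_groups, missense_matrix, q=config.q)
    _write(loc_assoc, outdir / "association" / "location_associations.tsv", index=False)

    # -- similarity ------------------------------------------------------------
    pos_sets = {ind: a.prop_pos for ind, a in sets.items()}
    engine = SimilarityEngine(ontology, freq["prop_pos"])
    suite = run_similarity_suite(
        pos_sets, records, engine,
        n_permutations=config.n_permutations, seed=seed_similarity,
    )
    _write(suite, outdir / "similarity" / "similarity_suite.tsv", index=False)

    by_variant: dict[str, set[str]] = {}
    for r in records:
        by_variant.setdefault(r.label, set()).add(r.individual_id)
    for label, members in sorted(by_variant.items()):
        if len(members) < config.phenogram_min_group or len(members) == len(pos_sets):
            continue
        gram = phenogram(members, pos_sets)
        safe = label.replace(".", "_").replace("*", "X").replace(">", "_")
        _write(gram, outdir / "similarity" / f"phenogram_{safe}.tsv")

    # -- reduction -------------------------------------------------------------
    pca_matrix = build_phenotype_matrix(sets, negative=False, min_count=config.min_count)
    m = config.m
    if config.cv_m:
        m, cv_table = select_m(pca_matrix, k=config.k, seed=seed_pca)
        _write(cv_table.rename("cv_deviance").to_frame(),
               outdir / "reduction" / "m_selection.tsv")
    model = fit_logistic_pca(pca_matrix, k=config.k, m=m, seed=seed_pca)
    scores = model.scores_frame()
    _write(scores, outdir / "reduction" / "scores.tsv")
    _write(model.loadings_frame(), outdir / "reduction" / "loadings.tsv")
    scree = pd.DataFrame({
        "component": [f"PC{j + 1}" for j in range(config.k)],
        "deviance_explained": model.deviance_explained_,
        "cumulative": model.cumulative_deviance_explained_,
    })
    _write(scree, outdir / "reduction" / "scree.tsv", index=False)

    groups = {r.individual_id: r.phenotype_group for r in records}
    functional = {r.individual_id: r.functional for r in records}
    evals: dict[str, dict] = {}
    for gname in sorted({g for g in groups.values() if g}):
        y = np.array([groups.get(i) == gname for i in scores.index], dtype=int)
        if 0 < y.sum() < len(y):
            evals[f"group:{gname}"] = {
                pc: evaluate_component(scores[pc].to_numpy(), y).to_dict()
                for pc in scores.columns
            }
    func_series = pd.Series(functional).reindex(scores.index)
    labeled = func_series[func_series.isin(["GoF", "LoF"])]
    prediction = None
    if labeled.nunique() == 2:
        per_pc = {}
        for pc in scores.columns:
            y = (labeled == "GoF").astype(int).to_numpy()
            s = scores.loc[labeled.index, pc].to_numpy()
            s = s if s[y == 1].mean() >= s[y == 0].mean() else -s
            per_pc[pc] = evaluate_component(s, y).to_dict()
        evals["function:GoF_vs_LoF"] = per_pc
        best_pc = max(per_pc, key=lambda pc: per_pc[pc]["auc"])
        variant_labels = {r.individual_id: r.label for r in records}
        prediction, pred_eval = predict_variant_function(
            scores[best_pc], func_series, variant_labels
        )
        prediction.insert(0, "component", best_pc)
        _write(prediction, outdir / "reduction" / "predicted_function.tsv")
    (outdir / "reduction" / "classifier_eval.json").write_text(
        json.dumps(evals, indent=2, sort_keys=True)
    )

    # -- manifest --------------------------------------------------------------
    inputs = {
        "ontology": config.ontology_path,
        "annotations": config.annotations_path,
        "variants": config.variants_path,
    }
    if config.topology_path:
        inputs["topology"] = config.topology_path
    if config.evidence_path:
        inputs["evidence"] = config.evidence_path
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "inputs": {k: {"path": str(v), "sha256": _sha256(Path(v))} for k, v in inputs.items()},
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
        "summary": {
            "n_individuals": n,
            "base_positive_annotations": int(sum(len(a.base_pos) for a in sets.values())),
            "propagated_positive_annotations": int(sum(len(a.prop_pos) for a in sets.values())),
            "unique_propagated_terms": int(len(freq["prop_pos"])),
            "significant_class_terms": int(class_assoc["significant"].sum()),
            "significant_location_terms": int(loc_assoc["significant"].sum()),
            "cumulative_deviance_explained": [float(x) for x in
                                              model.cumulative_deviance_explained_],
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
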