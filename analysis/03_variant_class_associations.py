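#!/usr/bin/env python
"""Associate phenotype terms with variant class and channel location.

Tests every propagated (positive and pruned-negative) term for association
with protein-truncating versus missense variants, and — within missense
carriers — with each channel domain, segment class and the S5–S6 pore loop,
using two-sided Fisher exact tests under Benjamini–Hochberg FDR 10%.
Writes results/association/.
"""
from __future__ import annotations

import argparse
from pathlib import Path

from scn2a_pheno.association import associate, location_associations
from scn2a_pheno.harmonize import build_phenotype_matrix, harmonize_cohort
from scn2a_pheno.io import read_annotations, read_variants
from scn2a_pheno.ontology import parse_obo
from scn2a_pheno.variants import build_variant_records, load_bundled_topology


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--q", type=float, default=0.10)
    args = ap.parse_args()

    src = args.results / "synthetic"
    out = args.results / "association"
    out.mkdir(parents=True, exist_ok=True)

    ontology = parse_obo(str(src / "ontology.obo"))
    sets = harmonize_cohort(ontology, read_annotations(src / "annotations.tsv"))
    records = build_variant_records(read_variants(src / "variants.tsv"),
                                    topology=load_bundled_topology())
    matrix = build_phenotype_matrix(sets)
    broad = {r.individual_id: r.broad for r in records}

    tested = matrix.loc[[i for i in matrix.index if broad[i] in ("missense", "PTV")]]
    ptv = {i for i, b in broad.items() if b == "PTV"}
    assoc = associate(tested, ptv & set(tested.index), q=args.q,
                      analysis="PTV_vs_missense")
    assoc.to_csv(out / "class_associations.tsv", sep="\t", index=False)

    sig = assoc[assoc.significant]
    n_ptv_dir = int((sig.direction == "group_enriched").sum())
    print(f"PTV vs missense ({int(len(ptv & set(tested.index)))} vs "
          f"{len(tested) - len(ptv & set(tested.index))}): "
          f"{len(sig)} significant terms at FDR {args.q:.0%} "
          f"({n_ptv_dir} PTV-enriched, {len(sig) - n_ptv_dir} missense-enriched)")
    top = sig.nsmallest(3, "p")[["term", "p", "odds_ratio"]]
    for _, row in top.iterrows():
        print(f"  {row['term']}: p={row['p']:.2e}, OR={row['odds_ratio']:.2f}")

    groups: dict[str, set[str]] = {}
    for r in records:
        if r.broad != "missense" or r.location is None:
            continue
        if r.location.domain:
            groups.setdefault(f"domain {r.location.domain}", set()).add(r.individual_id)
        if r.location.segment:
            groups.setdefault(f"segment {r.location.segment}", set()).add(r.individual_id)
        if r.location.pore_loop:
            groups.setdefault("pore loop", set()).add(r.individual_id)
    missense_matrix = matrix.loc[[i for i in matrix.index if broad[i] == "missense"]]
    loc = location_associations(groups, missense_matrix, q=args.q)
    loc.to_csv(out / "location_associations.tsv", sep="\t", index=False)
    loc_sig = loc[loc.significant]
    print(f"location analysis: {len(loc_sig)} significant location x term pairs "
          f"across {loc['location'].nunique()} locations")
    for _, row in loc_sig.nsmallest(3, "p").iterrows():
        print(f"  {row['location']} x {row['term']}: p={row['p']:.2e}")


if __name__ == "__main__":
    main()
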