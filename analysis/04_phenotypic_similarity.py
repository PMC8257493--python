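#!/usr/bin/env python
"""Permutation tests of phenotypic similarity for variant subgroups.

Scores every individual pair with best-match-average Resnik similarity under
propagated information content, then tests broad classes, channel domains and
segments, pore-loop carriers, and every recurrent variant (>= 2 carriers)
against the cohort permutation null.  Phenograms are written for recurrent
variants with >= 5 carriers.  Writes results/similarity/.
"""
from __future__ import annotations

import argparse
from pathlib import Path

from scn2a_pheno.harmonize import harmonize_cohort
from scn2a_pheno.io import read_annotations, read_variants
from scn2a_pheno.ontology import parse_obo, term_frequencies
from scn2a_pheno.similarity import (
    SimilarityEngine,
    phenogram,
    plot_phenogram,
    run_similarity_suite,
)
from scn2a_pheno.variants import build_variant_records, load_bundled_topology


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--permutations", type=int, default=20_000)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    src = args.results / "synthetic"
    out = args.results / "similarity"
    out.mkdir(parents=True, exist_ok=True)

    ontology = parse_obo(str(src / "ontology.obo"))
    sets = harmonize_cohort(ontology, read_annotations(src / "annotations.tsv"))
    records = build_variant_records(read_variants(src / "variants.tsv"),
                                    topology=load_bundled_topology())
    pos = {i: a.prop_pos for i, a in sets.items()}
    engine = SimilarityEngine(ontology, term_frequencies(pos))

    suite = run_similarity_suite(pos, records, engine,
                                 n_permutations=args.permutations, seed=args.seed)
    suite.to_csv(out / "similarity_suite.tsv", sep="\t", index=False)
    sig = suite[suite.p < 0.05].sort_values("p")
    print(f"{len(sig)}/{len(suite)} groups more phenotypically similar than "
          f"chance (p < 0.05, N = {args.permutations:,}):")
    for _, row in sig.iterrows():
        print(f"  {row['group']} (n={row['n']}): p={row['p']:.2g}")

    by_variant: dict[str, set[str]] = {}
    for r in records:
        by_variant.setdefault(r.label, set()).add(r.individual_id)
    for label, members in sorted(by_variant.items()):
        if len(members) < 5 or len(members) == len(pos):
            continue
        gram = phenogram(members, pos)
        safe = label.replace(".", "_").replace("*", "X")
        gram.to_csv(out / f"phenogram_{safe}.tsv", sep="\t")
        plot_phenogram(gram, out / f"phenogram_{safe}.png",
                       title=f"{label} (n={len(members)})")
        print(f"phenogram for {label}: "
              f"{int(gram['highlight'].sum())} terms at uncorrected p < 0.05")


if __name__ == "__main__":
    main()
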