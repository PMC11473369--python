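"""High-level drivers wiring the homology evidence stages together."""

from __future__ import annotations

import pandas as pd

from .evoclass import (assign_gene_age, assign_orf_age, classify_structure,
                       resolve_homologs)
from .io import FeatureTable
from .synthetic import ToyGenomes


def classify_genomes(toy: ToyGenomes, hominini: tuple[str, str] = ("human", "chimp"),
                     evalue_max: float = 1e-4, min_counterpart_reads: int = 10,
                     truncation_cutoff: float = 0.7,
                     denovo_rule: str = "all") -> pd.DataFrame:
    """Run homology resolution, age calls and structure calls end to end.

    Returns one row per planted query feature with its age (all features)
    and structure plus intact fractions (young sORFs only).
    """
    species = sorted(toy.sequences)
    all_features = FeatureTable(
        list(toy.genes.features) + [o.to_feature() for o in toy.orfs])
    orf_by_id = {o.orf_id: o for o in toy.orfs}

    rows = []
    query_ids = (list(toy.truth["feature_id"]) if len(toy.truth)
                 else [f.feature_id for f in all_features])
    queries = FeatureTable([all_features.get(fid) for fid in query_ids])
    evidence = resolve_homologs(
        queries, all_features, toy.mapping, toy.hits, toy.activity,
        target_species=species, counterpart_reads=toy.counterpart_reads,
        sequences=toy.sequences, evalue_max=evalue_max)

    for fid in query_ids:
        feat = all_features.get(fid)
        is_orf = fid in orf_by_id
        if is_orf:
            age = assign_orf_age(evidence, fid, feat.species,
                                 hominini=hominini,
                                 min_counterpart_reads=min_counterpart_reads)
        else:
            age = assign_gene_age(evidence, fid, feat.species,
                                  hominini=hominini)
        structure = None
        fractions: dict[str, float] = {}
        if is_orf and age in ("species_specific", "hominini_specific"):
            structure, fractions = classify_structure(
                orf_by_id[fid], evidence,
                truncation_cutoff=truncation_cutoff, rule=denovo_rule)
        rows.append({
            "feature_id": fid, "species": feat.species,
            "kind": "sorf" if is_orf else "gene", "age": age,
            "structure": structure,
            "intact_fractions": ";".join(
                f"{sp}:{frac:.4f}" for sp, frac in sorted(fractions.items())),
            "min_intact_fraction": (min(fractions.values())
                                    if fractions else None),
        })
    return pd.DataFrame(rows)
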