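"""Tissue-specificity (tau), recent tissue-enrichment calls and co-regulation.

tau = sum_i (1 - x_i / max_i x_i) / (n - 1) over n tissues; 0 for uniform
expression, 1 for single-tissue.  Genes with tau above the cutoff (default
0.75) whose maximal tissue is the focal one are 'tissue enriched'; a gene is
*recently* enriched when that holds in the focal species only.  Testis is
excluded by default before computing tau.

Co-regulation edges are Spearman correlations over pairwise-complete
observations, retained at |rho| > 0.5.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ribevol")

DEFAULT_EXCLUDED_TISSUES = frozenset({"testis"})


class EnrichmentError(ValueError):
    pass


def tau(atlas: pd.DataFrame, excluded_tissues=DEFAULT_EXCLUDED_TISSUES,
        cutoff: float = 0.75) -> pd.DataFrame:
    """Per-gene tau over a gene x tissue mean-expression table.

    All-zero genes are skipped with a warning; an argmax tie leaves the gene
    without a focal tissue (``argmax_tissue`` NaN, never ``enriched``).
    """
    keep_cols = [c for c in atlas.columns if c not in excluded_tissues]
    if len(keep_cols) < 2:
        raise EnrichmentError("need >=2 tissues after exclusion (n-1 divisor)")
    x = atlas[keep_cols].astype(float)
    if (x.to_numpy() < 0).any() or not np.isfinite(x.to_numpy()).all():
        raise EnrichmentError("expression must be finite and non-negative")
    maxima = x.max(axis=1)
    nonzero = maxima > 0
    if (~nonzero).any():
        logger.warning("tau: skipping %d all-zero genes", int((~nonzero).sum()))
    x = x.loc[nonzero]
    maxima = maxima.loc[nonzero]
    n = len(keep_cols)
    xhat = x.div(maxima, axis=0)
    tau_vals = (1.0 - xhat).sum(axis=1) / (n - 1)

    arr = x.to_numpy()
    top = arr.max(axis=1)
    ties = (arr == top[:, None]).sum(axis=1) > 1
    argmax = pd.Series(np.array(keep_cols)[arr.argmax(axis=1)], index=x.index)
    argmax[ties] = np.nan
    out = pd.DataFrame({
        "tau": tau_vals,
        "argmax_tissue": argmax,
        "enriched": (tau_vals > cutoff) & ~ties,
        "cutoff": cutoff,
    })
    out.index.name = "gene_id"
    return out


def recent_tissue_enriched(tau_by_species: dict[str, pd.DataFrame],
                           focal_tissue: str, focal_species: str) -> set[str]:
    """Genes enriched in the focal tissue in the focal species only.

    Genes missing a tau value in any comparison species are excluded
    (orthology incomplete) and logged.
    """
    if focal_species not in tau_by_species:
        raise EnrichmentError(f"no tau table for focal species {focal_species!r}")
    focal = tau_by_species[focal_species]
    candidates = set(focal.index[(focal["enriched"])
                                 & (focal["argmax_tissue"] == focal_tissue)])
    others = {sp: t for sp, t in tau_by_species.items() if sp != focal_species}
    selected = set()
    for gene in candidates:
        missing = [sp for sp, t in others.items() if gene not in t.index]
        if missing:
            logger.info("recent_tissue_enriched: %r lacks ortholog tau in %s",
                        gene, missing)
            continue
        if any(bool(t.loc[gene, "enriched"])
               and t.loc[gene, "argmax_tissue"] == focal_tissue
               for t in others.values()):
            continue
        selected.add(gene)
    return selected


def coexpression_network(normalized: pd.DataFrame, focus: set[str] | list[str],
                         min_samples: int = 20, rho_cutoff: float = 0.5,
                         raw_counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Spearman co-regulation partners for each focus gene.

    Genes with fewer than ``min_samples`` samples having >= 1 raw count are
    excluded; correlations use pairwise-complete observations (NaNs allowed
    in ``normalized``); edges kept at |rho| > ``rho_cutoff``; self edges and
    constant vectors are skipped.  Returns columns (focus_gene, partner,
    spearman_rho, n_pairs_used).
    """
    presence = raw_counts if raw_counts is not None else normalized
    detected = (presence.fillna(0) >= 1).sum(axis=1) >= min_samples
    universe = normalized.loc[detected]
    logger.info("coexpression: %d/%d genes detected in >=%d samples",
                int(detected.sum()), len(normalized), min_samples)
    edges = []
    mat = universe.to_numpy(dtype=float)
    index = list(universe.index)
    pos = {g: i for i, g in enumerate(index)}
    for fg in sorted(set(focus)):
        if fg not in pos:
            continue
        fvec = mat[pos[fg]]
        for partner, j in pos.items():
            if partner == fg:
                continue
            pvec = mat[j]
            ok = np.isfinite(fvec) & np.isfinite(pvec)
            n = int(ok.sum())
            if n < 3:
                continue
            a, b = fvec[ok], pvec[ok]
            if np.all(a == a[0]) or np.all(b == b[0]):
                continue
            rho = stats.spearmanr(a, b).statistic
            if np.isfinite(rho) and abs(rho) > rho_cutoff:
                edges.append({"focus_gene": fg, "partner": partner,
                              "spearman_rho": float(rho), "n_pairs_used": n})
    return pd.DataFrame(edges, columns=["focus_gene", "partner",
                                        "spearman_rho", "n_pairs_used"])
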