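"""Species-specific differential expression/translation and regulatory-mode calls.

A feature is significant when |fold change| >= 1.5 (|log2 FC| >= log2 1.5)
and BH-adjusted p < 0.05.  Among genes with a significant TE change in a
focal species, the mode is:

* buffering    — RNA also significant, RNA and TE change in opposite directions
* intensified  — RNA also significant, same direction
* exclusive    — RNA not significant (translation-only regulation)

The DE engines here (Welch t-test on log2 normalized counts; permutation
contrast for TE) are documented stand-ins: externally produced tables with
columns (feature_id, log2_fold_change, adjusted_p) are accepted anywhere a
DETable is.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import NormalizedMatrix
from .tevar import TEMatrix

logger = logging.getLogger("ribevol")

LOG2_FC_CUTOFF = math.log2(1.5)
ALPHA = 0.05

MODES = ("buffering", "exclusive", "intensified")


class RegulationError(ValueError):
    pass


def make_de_table(feature_ids, lfc, padj, fc_cutoff: float = 1.5,
                  alpha: float = ALPHA, contrast: str = "") -> pd.DataFrame:
    """Assemble a DETable and apply the significance rule."""
    df = pd.DataFrame({
        "feature_id": list(feature_ids),
        "log2_fold_change": np.asarray(lfc, dtype=float),
        "adjusted_p": np.asarray(padj, dtype=float),
    }).set_index("feature_id")
    df["contrast"] = contrast
    df["significant"] = ((df["log2_fold_change"].abs() >= math.log2(fc_cutoff))
                         & (df["adjusted_p"] < alpha))
    return df


def standin_de_test(norm: NormalizedMatrix, group_a: list[str],
                    group_b: list[str], fc_cutoff: float = 1.5,
                    alpha: float = ALPHA, contrast: str = "B_vs_A") -> pd.DataFrame:
    """Per-gene Welch t-test on log2(normalized + 1); lfc = mean(B) - mean(A).

    Zero-variance degenerate genes get p = 1 and are logged.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise RegulationError("need >=2 samples per side")
    a = np.log2(norm.values[list(group_a)].to_numpy(dtype=float) + 1.0)
    b = np.log2(norm.values[list(group_b)].to_numpy(dtype=float) + 1.0)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(b, a, axis=1, equal_var=False)
    degenerate = ~np.isfinite(pvals)
    if degenerate.any():
        logger.info("standin_de_test: %d zero-variance genes set to p=1",
                    int(degenerate.sum()))
        pvals = np.where(degenerate, 1.0, pvals)
    padj = stats.false_discovery_control(pvals, method="bh")
    return make_de_table(norm.values.index, lfc, padj, fc_cutoff, alpha, contrast)


def te_species_test(te: TEMatrix, focal_species: str, iterations: int = 10000,
                    seed: int | None = None, fc_cutoff: float = 1.5,
                    alpha: float = ALPHA) -> pd.DataFrame:
    """Focal-species vs pooled-others TE contrast with a permutation p-value.

    Effect = mean focal log2 TE - mean other log2 TE.  The null permutes the
    focal/other split over samples (two-sided, add-one corrected), BH across
    genes.  A stand-in for an interaction-model engine; interchangeable with
    an imported table.
    """
    labels = te.species_of.to_numpy()
    focal = labels == focal_species
    if focal.sum() < 2:
        raise RegulationError(
            f"need >=2 samples for focal species {focal_species!r}")
    if (~focal).sum() < 2:
        raise RegulationError("need >=2 samples outside the focal species")
    values = te.values.to_numpy(dtype=float)
    if te.scale != "log2":
        values = np.log2(values)

    def effect(mask: np.ndarray) -> np.ndarray:
        return values[:, mask].mean(axis=1) - values[:, ~mask].mean(axis=1)

    observed = effect(focal)
    rng = np.random.default_rng(seed)
    n_focal = int(focal.sum())
    n = len(labels)
    exceed = np.zeros(values.shape[0], dtype=int)
    for _ in range(iterations):
        idx = rng.choice(n, size=n_focal, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        exceed += np.abs(effect(mask)) >= np.abs(observed)
    pvals = (exceed + 1.0) / (iterations + 1.0)
    padj = stats.false_discovery_control(pvals, method="bh")
    return make_de_table(te.values.index, observed, padj, fc_cutoff, alpha,
                         contrast=f"{focal_species}_vs_others")


def classify_mode(rna: pd.DataFrame, ribo: pd.DataFrame, te: pd.DataFrame,
                  focal_species: str = "") -> pd.DataFrame:
    """Regulatory-mode call per gene; genes without a significant TE change
    (or missing from any table) get mode 'none'.

    The sign of a non-significant RNA fold change is never consulted.
    """
    out = []
    for gene in te.index:
        te_row = te.loc[gene]
        if gene not in rna.index or gene not in ribo.index:
            logger.warning("classify_mode: %r missing from RNA/Ribo tables", gene)
            mode = "none"
            rna_row = ribo_row = None
        else:
            rna_row = rna.loc[gene]
            ribo_row = ribo.loc[gene]
            if not te_row["significant"]:
                mode = "none"
            elif not rna_row["significant"]:
                mode = "exclusive"
            elif np.sign(rna_row["log2_fold_change"]) != np.sign(te_row["log2_fold_change"]):
                mode = "buffering"
            else:
                mode = "intensified"
        out.append({
            "gene_id": gene,
            "focal_species": focal_species,
            "rna_lfc": np.nan if rna_row is None else rna_row["log2_fold_change"],
            "rna_sig": False if rna_row is None else bool(rna_row["significant"]),
            "ribo_lfc": np.nan if ribo_row is None else ribo_row["log2_fold_change"],
            "ribo_sig": False if ribo_row is None else bool(ribo_row["significant"]),
            "te_lfc": te_row["log2_fold_change"],
            "te_sig": bool(te_row["significant"]),
            "mode": mode,
        })
    return pd.DataFrame(out).set_index("gene_id")


def classify_developmental(de_prenatal_vs_postnatal: pd.DataFrame,
                           de_other_context: pd.DataFrame | None = None) -> pd.Series:
    """Label features prenatal / postnatal / both / none.

    Contrast orientation: positive log2 FC = higher in the adult/postnatal
    side.  With two contexts supplied, evidence is pooled: significant
    downregulation (higher prenatal) in either context marks prenatal,
    significant upregulation marks postnatal, and conflicting directions
    across contexts yield 'both'.
    """
    tables = [de_prenatal_vs_postnatal]
    if de_other_context is not None:
        tables.append(de_other_context)
    index = tables[0].index
    for t in tables[1:]:
        index = index.union(t.index)
    labels = {}
    for feat in index:
        pre = post = False
        for t in tables:
            if feat not in t.index:
                continue
            row = t.loc[feat]
            if row["significant"]:
                if row["log2_fold_change"] < 0:
                    pre = True
                else:
                    post = True
        labels[feat] = ("both" if pre and post
                        else "prenatal" if pre
                        else "postnatal" if post
                        else "none")
    return pd.Series(labels, name="developmental_class")
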