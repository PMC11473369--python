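"""Per-gene translational efficiency, its between-species variance score, and
resampling/downsampling inference on gene groups.

TE is the ratio of normalized Ribo-seq to RNA-seq signal per matched sample
pair.  The per-gene score decomposes the variability of TE across species:

    te_var = Var_species(per-species mean TE)
             - mean_species(Var_within(TE) / n_samples)

i.e. the variance across species of the per-species mean, corrected by the
average sampling variance of those means.  Both variances use the n-1
denominator.  Negative scores are reported as-is (the subtraction estimator
is unbiased only without clamping).

Inference permutes whole samples: each iteration reassigns the sample ->
species labels (without replacement, preserving per-species sample counts),
recomputes every gene's score and the group median.  One-sided p-values are
the fraction of permuted medians strictly exceeding the observed one, then
BH-adjusted across the tested groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleTable
from .normalization import NormalizedMatrix

logger = logging.getLogger("ribevol")


class TEError(ValueError):
    pass


@dataclass
class TEMatrix:
    """Genes x matched-sample-pairs TE values.

    Columns are pairing keys; ``species_of`` maps each column to its species.
    Only genes passing the per-species zero filters carry values.
    """

    values: pd.DataFrame
    species_of: pd.Series
    scale: str = "log2"
    dropped_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.species_of = self.species_of.reindex(self.values.columns)
        if self.species_of.isna().any():
            raise TEError("species_of does not cover all TE columns")
        if self.scale not in ("linear", "log2"):
            raise TEError(f"unknown TE scale {self.scale!r}")

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for s in self.species_of:
            if s not in seen:
                seen.append(s)
        return seen


def zero_filter_mask(counts: pd.DataFrame, sample_species: pd.Series,
                     max_zero_reps: int = 3) -> pd.Series:
    """True for genes retained by the per-species zero rule.

    A gene is excluded when, within any single species' replicates, its raw
    counts have a median of 0 or contain ``max_zero_reps`` or more zeros.
    The zero pattern is invariant to positive per-sample scaling, so the rule
    may be applied to raw or normalized counts interchangeably.
    """
    keep = pd.Series(True, index=counts.index)
    for sp in sample_species.unique():
        cols = sample_species.index[sample_species == sp]
        sub = counts[cols]
        zeros = (sub == 0).sum(axis=1)
        med = sub.median(axis=1)
        keep &= (med > 0) & (zeros < max_zero_reps)
    return keep


def compute_te(rna: NormalizedMatrix, ribo: NormalizedMatrix,
               pairing: SampleTable, scale: str = "log2",
               pseudocount: float = 1.0, max_zero_reps: int = 3) -> TEMatrix:
    """TE per matched Ribo/RNA sample pair, after the zero-count filter.

    TE = (ribo + pseudocount) / (rna + pseudocount) per pair, log2 of that
    ratio when ``scale='log2'``.  Genes failing the zero rule in either assay
    within any species are dropped globally.
    """
    pairs = pairing.pairs()
    if pairs.empty:
        raise TEError("no matched Ribo/RNA sample pairs in sample sheet")
    unpaired = set(pairing.samples_for("RIBO")) - set(pairs["sample_id_ribo"])
    if unpaired:
        raise TEError(f"unpaired RIBO sample(s): {sorted(unpaired)}")

    genes = rna.values.index.intersection(ribo.values.index)
    rna_vals = rna.values.loc[genes, pairs["sample_id_rna"]]
    ribo_vals = ribo.values.loc[genes, pairs["sample_id_ribo"]]

    sp_rna = pd.Series(pairs["species"].to_numpy(), index=pairs["sample_id_rna"])
    sp_ribo = pd.Series(pairs["species"].to_numpy(), index=pairs["sample_id_ribo"])
    keep = (zero_filter_mask(rna_vals, sp_rna, max_zero_reps)
            & zero_filter_mask(ribo_vals, sp_ribo, max_zero_reps))
    dropped = list(genes[~keep])
    if not keep.any():
        raise TEError("all genes removed by the zero-count filter")
    logger.info("TE: %d/%d genes pass zero filters", int(keep.sum()), len(genes))

    rna_arr = rna_vals.loc[keep].to_numpy(dtype=float) + pseudocount
    ribo_arr = ribo_vals.loc[keep].to_numpy(dtype=float) + pseudocount
    te = ribo_arr / rna_arr
    if scale == "log2":
        te = np.log2(te)
    values = pd.DataFrame(te, index=genes[keep],
                          columns=pairs["pairing_key"].to_numpy())
    species_of = pd.Series(pairs["species"].to_numpy(),
                           index=pairs["pairing_key"].to_numpy())
    return TEMatrix(values, species_of, scale=scale, dropped_genes=dropped)


# ---------------------------------------------------------------------------
# Variance decomposition
# ---------------------------------------------------------------------------

def _tevar_from_arrays(values: np.ndarray, labels: np.ndarray,
                       species: list[str]) -> tuple[np.ndarray, np.ndarray,
                                                    np.ndarray, np.ndarray]:
    """Vectorized decomposition for a genes x samples array.

    Returns (te_var, across_var, avg_sampling_var, per-species means).
    Species with fewer than 2 samples are excluded from both terms.
    """
    means = []
    sampling = []
    used = []
    for sp in species:
        cols = labels == sp
        n = int(cols.sum())
        if n < 2:
            continue
        sub = values[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        means.append(m)
        sampling.append(v / n)
        used.append(sp)
    if len(used) < 2:
        raise TEError("need >=2 species with >=2 samples each")
    mean_mat = np.column_stack(means)
    across = mean_mat.var(axis=1, ddof=1)
    avg_sampling = np.column_stack(sampling).mean(axis=1)
    return across - avg_sampling, across, avg_sampling, mean_mat


def te_var(te: TEMatrix) -> pd.DataFrame:
    """Per-gene decomposition table.

    Columns: per-species mean TE and within-species variance, the across-
    species variance of the means, the average sampling variance, their
    difference ``te_var`` and the number of species used.
    """
    labels = te.species_of.to_numpy()
    species = te.species
    usable = [sp for sp in species if (labels == sp).sum() >= 2]
    skipped = sorted(set(species) - set(usable))
    if skipped:
        logger.warning("species excluded (fewer than 2 samples): %s", skipped)
    values = te.values.to_numpy(dtype=float)
    score, across, avg_sampling, mean_mat = _tevar_from_arrays(
        values, labels, species)
    out = pd.DataFrame(index=te.values.index)
    out.index.name = "gene_id"
    for j, sp in enumerate(usable):
        out[f"mean_te_{sp}"] = mean_mat[:, j]
        cols = labels == sp
        out[f"within_var_{sp}"] = values[:, cols].var(axis=1, ddof=1)
    out["across_species_variance"] = across
    out["avg_sampling_variance"] = avg_sampling
    out["te_var"] = score
    out["n_species_used"] = len(usable)
    return out


def group_median(results: pd.DataFrame, group: set[str] | list[str]) -> float:
    """Median te_var over group members present in the results table."""
    present = results.index.intersection(list(group))
    if present.empty:
        raise TEError("group has no genes in the results table")
    return float(results.loc[present, "te_var"].median())


# ---------------------------------------------------------------------------
# Resampling inference
# ---------------------------------------------------------------------------

def resample_group_pvalue(te: TEMatrix, groups: dict[str, set[str] | list[str]],
                          iterations: int = 10000,
                          seed: int | None = None) -> pd.DataFrame:
    """Permutation test of group median te_var against species exchange.

    Each iteration permutes the sample -> species assignment (all samples,
    without replacement, preserving species sizes) and recomputes every
    group's median score.  p = fraction of permuted medians strictly greater
    than the observed one (resolution floor 1/iterations); BH-adjusted
    across groups.
    """
    if iterations < 1:
        raise TEError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    values = te.values.to_numpy(dtype=float)
    labels = te.species_of.to_numpy()
    species = te.species
    gene_index = {g: i for i, g in enumerate(te.values.index)}

    group_rows: dict[str, np.ndarray] = {}
    for name, members in groups.items():
        rows = np.array([gene_index[g] for g in members if g in gene_index])
        if rows.size == 0:
            raise TEError(f"group {name!r} absent from the TE matrix")
        group_rows[name] = rows

    observed_scores, _, _, _ = _tevar_from_arrays(values, labels, species)
    observed = {name: float(np.median(observed_scores[rows]))
                for name, rows in group_rows.items()}

    exceed = {name: 0 for name in group_rows}
    for _ in range(iterations):
        perm = rng.permutation(labels)
        scores, _, _, _ = _tevar_from_arrays(values, perm, species)
        for name, rows in group_rows.items():
            if np.median(scores[rows]) > observed[name]:
                exceed[name] += 1

    names = list(group_rows)
    pvals = np.array([exceed[n] / iterations for n in names])
    fdr = stats.false_discovery_control(pvals, method="bh")
    return pd.DataFrame({
        "group": names,
        "n_genes": [group_rows[n].size for n in names],
        "observed_median": [observed[n] for n in names],
        "p_one_sided": pvals,
        "fdr_adjusted_p": fdr,
        "iterations": iterations,
    }).set_index("group")


def downsample_group_ci(te: TEMatrix, group: set[str] | list[str],
                        k_samples: int, iterations: int = 10000,
                        seed: int | None = None,
                        ci: float = 0.95) -> tuple[float, float]:
    """CI for the group median under per-species downsampling to k samples.

    Each iteration keeps ``k_samples`` samples per species (drawn without
    replacement), recomputes the score and takes the group median; returns
    the 2.5th/97.5th percentiles of those medians (for the default 95% CI).
    """
    rng = np.random.default_rng(seed)
    values = te.values.to_numpy(dtype=float)
    labels = te.species_of.to_numpy()
    species = te.species
    per_species_cols = {sp: np.flatnonzero(labels == sp) for sp in species}
    smallest = min(len(c) for c in per_species_cols.values())
    if k_samples > smallest:
        raise TEError(
            f"k_samples={k_samples} exceeds smallest species n={smallest}")
    if k_samples < 2:
        raise TEError("k_samples must be >= 2")

    gene_rows = np.array([i for i, g in enumerate(te.values.index)
                          if g in set(group)])
    if gene_rows.size == 0:
        raise TEError("group has no genes in the TE matrix")

    medians = np.empty(iterations)
    for it in range(iterations):
        cols = np.concatenate([
            rng.choice(c, size=k_samples, replace=False)
            for c in per_species_cols.values()])
        scores, _, _, _ = _tevar_from_arrays(
            values[:, cols], labels[cols], species)
        medians[it] = np.median(scores[gene_rows])
    alpha = (1.0 - ci) / 2.0
    lower, upper = np.quantile(medians, [alpha, 1.0 - alpha])
    return float(lower), float(upper)
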