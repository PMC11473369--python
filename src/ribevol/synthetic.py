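"""Synthetic fixtures with recorded ground truth.

Three generators cover every input the analysis consumes:

* :func:`simulate_counts` — paired RNA/Ribo negative-binomial count matrices
  for several species, with gene-wise log2 TE decomposed into a gene
  baseline, a between-species component and a within-replicate component,
  plus planted high-variance gene groups and regulatory-mode genes.
* :func:`simulate_toy_genomes` — toy multi-species genomes with planted
  orthologous / young / hominini-specific genes and sORFs whose
  counterparts are intact, truncated (de novo) or absent (orphan),
  together with the mapping, BLAST-like hit, activity and pooled-read
  evidence tables a homology run would produce.
* :func:`simulate_tissue_atlas` — a gene x tissue expression atlas with
  planted tissue-specific genes.

The negative binomial is parameterized by mean and dispersion with
variance = mu + mu^2 / dispersion.  Library size factors are drawn
log-uniformly from ``libsize_range`` and recorded in the truth.  A single
seed drives everything; identical configs and seeds give byte-identical
outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evoclass import ActivityTable, OrfModel, STOP_CODONS
from .io import (CountMatrix, Feature, FeatureTable, SampleTable, write_bed12,
                 write_counts, write_fasta, write_hits, write_mapping,
                 write_sample_sheet)

logger = logging.getLogger("ribevol")

REGULATION_MODES = ("buffering", "exclusive", "intensified")


class SimError(ValueError):
    pass


def _check_finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise SimError(f"non-finite value for field {name!r}: {value}")
    return float(value)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    n_species: int = 5
    samples_per_species: list[int] = field(default_factory=lambda: [5] * 5)
    n_genes: int = 1000
    mean_log_expression: float = 7.0
    dispersion: float = 10.0
    sigma_between: float = 0.5
    sigma_within: float = 0.2
    planted_groups: dict[str, dict] = field(default_factory=dict)
    planted_regulation: dict[str, dict] = field(default_factory=dict)
    libsize_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0
    gene_log_expression_sd: float = 1.0
    baseline_log2_te_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mean_log_expression", "dispersion", "sigma_between",
                     "sigma_within", "gene_log_expression_sd",
                     "baseline_log2_te_sd"):
            _check_finite(name, getattr(self, name))
        if self.dispersion <= 0:
            raise SimError("dispersion must be > 0")
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise SimError("sigma_between and sigma_within must be >= 0")
        if len(self.samples_per_species) != self.n_species:
            raise SimError("samples_per_species length must equal n_species")
        lo, hi = self.libsize_range
        _check_finite("libsize_range.lo", lo)
        _check_finite("libsize_range.hi", hi)
        if not (0 < lo <= hi):
            raise SimError("libsize_range must be positive with lo <= hi")
        planted = sum(int(g["n_genes"]) for g in self.planted_groups.values())
        planted += sum(int(g["n_genes"]) for g in self.planted_regulation.values())
        if planted > self.n_genes:
            raise SimError("planted gene counts exceed n_genes")
        for mode in self.planted_regulation:
            if mode not in REGULATION_MODES:
                raise SimError(f"unknown regulation mode {mode!r}")
        for name, g in self.planted_groups.items():
            _check_finite(f"planted_groups[{name}].sigma_between",
                          g.get("sigma_between", 0.0))

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]


@dataclass
class SimTruth:
    """Planted values behind a count simulation.

    ``genes`` — per-gene baseline expression/TE, group and regulation labels.
    ``species_log2_te`` — expected per-species log2 TE (baseline + species
    component + any planted TE shift).
    ``sample_log2_te`` — realized per-replicate log2 TE.
    ``size_factors`` — library size factor per simulated sample.
    """

    genes: pd.DataFrame
    species_log2_te: pd.DataFrame
    sample_log2_te: pd.DataFrame
    size_factors: pd.Series
    focal_species: str


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with variance mu + mu^2/dispersion; Poisson limit
    for very large dispersion."""
    if dispersion >= 1e6:
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, CountMatrix,
                                                SampleTable, SimTruth]:
    """Simulate paired RNA/Ribo count matrices plus sample sheet and truth.

    For gene g, species s, replicate r:
    ``log2 TE = mu_g + B_gs + W_gsr`` with ``B ~ N(0, sigma_between^2)``
    (group-specific sigma for planted groups) and ``W ~ N(0, sigma_within^2)``.
    RNA counts are NB with mean ``libsize * 2^E_gs``; Ribo counts NB with
    mean ``libsize * 2^(E_gs + log2 TE)``.  Regulation-mode genes add their
    ``rna_log2fc``/``te_log2fc`` in the first (focal) species only.
    """
    rng = np.random.default_rng(config.seed)
    species = config.species_names
    focal = species[0]
    G = config.n_genes

    gene_ids = [f"g{i:05d}" for i in range(G)]
    group = np.array(["background"] * G, dtype=object)
    sigma_b = np.full(G, config.sigma_between)
    reg_mode = np.array(["none"] * G, dtype=object)
    rna_fc = np.zeros(G)
    te_fc = np.zeros(G)

    cursor = 0
    for name, g in config.planted_groups.items():
        n = int(g["n_genes"])
        group[cursor:cursor + n] = name
        sigma_b[cursor:cursor + n] = float(g["sigma_between"])
        cursor += n
    for mode, g in config.planted_regulation.items():
        n = int(g["n_genes"])
        reg_mode[cursor:cursor + n] = mode
        rna_fc[cursor:cursor + n] = float(g["rna_log2fc"])
        te_fc[cursor:cursor + n] = float(g["te_log2fc"])
        cursor += n

    base_expr = rng.normal(config.mean_log_expression,
                           config.gene_log_expression_sd, size=G)
    mu = rng.normal(0.0, config.baseline_log2_te_sd, size=G)
    B = rng.normal(0.0, 1.0, size=(G, config.n_species)) * sigma_b[:, None]

    lo, hi = config.libsize_range
    sample_rows = []
    rna_cols: dict[str, np.ndarray] = {}
    ribo_cols: dict[str, np.ndarray] = {}
    sample_te_cols: dict[str, np.ndarray] = {}
    species_te = mu[:, None] + B
    libsizes: dict[str, float] = {}

    for si, sp in enumerate(species):
        te_shift = te_fc if sp == focal else 0.0
        rna_shift = rna_fc if sp == focal else 0.0
        for r in range(config.samples_per_species[si]):
            key = f"{sp}_LV_{r + 1}"
            W = rng.normal(0.0, config.sigma_within, size=G)
            log2_te = mu + B[:, si] + W + te_shift
            lib_rna = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            lib_ribo = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            rna_mean = lib_rna * np.exp2(base_expr + rna_shift)
            ribo_mean = lib_ribo * np.exp2(base_expr + rna_shift + log2_te)
            rna_id, ribo_id = f"{key}_RNA", f"{key}_RIBO"
            rna_cols[rna_id] = _nb_draw(rng, rna_mean, config.dispersion)
            ribo_cols[ribo_id] = _nb_draw(rng, ribo_mean, config.dispersion)
            sample_te_cols[key] = log2_te
            libsizes[rna_id] = lib_rna
            libsizes[ribo_id] = lib_ribo
            for assay, sid in (("RNA", rna_id), ("RIBO", ribo_id)):
                sample_rows.append({"sample_id": sid, "species": sp,
                                    "tissue": "LV", "assay": assay,
                                    "replicate": r + 1, "pairing_key": key})

    rna = CountMatrix(pd.DataFrame(rna_cols, index=gene_ids))
    ribo = CountMatrix(pd.DataFrame(ribo_cols, index=gene_ids))
    samples = SampleTable(pd.DataFrame(sample_rows))
    shift_mat = np.zeros((G, config.n_species))
    shift_mat[:, 0] = te_fc
    truth = SimTruth(
        genes=pd.DataFrame({
            "gene_id": gene_ids, "baseline_log2_te": mu,
            "base_log2_expression": base_expr, "group": group,
            "regulation_mode": reg_mode, "rna_log2fc": rna_fc,
            "te_log2fc": te_fc, "sigma_between": sigma_b,
        }).set_index("gene_id"),
        species_log2_te=pd.DataFrame(species_te + shift_mat, index=gene_ids,
                                     columns=species),
        sample_log2_te=pd.DataFrame(sample_te_cols, index=gene_ids),
        size_factors=pd.Series(libsizes, name="libsize"),
        focal_species=focal,
    )
    logger.info("simulated %d genes x %d species (%d sample pairs)",
                G, config.n_species, sum(config.samples_per_species))
    return rna, ribo, samples, truth


# ---------------------------------------------------------------------------
# Toy genomes
# ---------------------------------------------------------------------------

@dataclass
class SorfSpec:
    """One planted sORF.

    status: 'preserved' (translated everywhere), 'hominini' (translated in
    the hominini pair only), 'intact', 'de_novo' or 'orphan' (all three
    species-specific young, differing in counterpart structure).
    ``truncation_fraction`` applies to de novo cases and must be >= 0.7.
    """

    host_species: str
    status: str
    length_codons: int = 50
    truncation_fraction: float = 0.8
    start_codon: str = "ATG"

    def __post_init__(self) -> None:
        if self.status not in ("preserved", "hominini", "intact", "de_novo",
                               "orphan"):
            raise SimError(f"unknown sORF status {self.status!r}")
        if self.status == "de_novo" and self.truncation_fraction < 0.7:
            raise SimError("de novo truncation_fraction must be >= 0.7")
        if self.length_codons < 4:
            raise SimError("sORF too short")


@dataclass
class ToyGenomeSpec:
    species: list[str] = field(default_factory=lambda: ["human", "chimp",
                                                        "rhesus", "mouse",
                                                        "rat"])
    hominini: tuple[str, str] = ("human", "chimp")
    n_ortholog_genes: int = 5
    species_specific_genes: dict[str, int] = field(default_factory=dict)
    n_hominini_genes: int = 0
    sorfs: list[SorfSpec] = field(default_factory=list)
    gene_length: int = 300
    spacing: int = 60
    margin: int = 100

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise SimError("need at least 2 species")
        for hs in self.hominini:
            if hs not in self.species:
                raise SimError(f"hominini species {hs!r} not in species list")
        for sp in self.species_specific_genes:
            if sp not in self.species:
                raise SimError(f"unknown species {sp!r} in species_specific_genes")
        for s in self.sorfs:
            if s.host_species not in self.species:
                raise SimError(f"unknown sORF host species {s.host_species!r}")
            if s.status == "hominini" and s.host_species not in self.hominini:
                raise SimError("hominini sORFs must be hosted in a hominini "
                               "species")


@dataclass
class ToyGenomes:
    """Everything a homology run needs, plus the planted truth."""

    sequences: dict[str, dict[str, str]]
    genes: FeatureTable
    orfs: list[OrfModel]
    mapping: pd.DataFrame
    hits: pd.DataFrame
    activity: ActivityTable
    counterpart_reads: pd.DataFrame
    truth: pd.DataFrame


_NONSTOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in STOP_CODONS]


def _random_orf(rng: np.random.Generator, length_codons: int,
                start_codon: str = "ATG") -> str:
    body = rng.choice(_NONSTOP, size=length_codons - 1)
    return start_codon + "".join(body) + "TGA"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def simulate_toy_genomes(spec: ToyGenomeSpec, seed: int = 0) -> ToyGenomes:
    """Build toy genomes and the evidence tables a homology search would emit.

    Orthologous features share coordinates across species (colinear mapping
    rows, reciprocal hits at E = 1e-50).  Features absent from a species
    have independent random sequence there and no mapping/hit rows.  De novo
    sORF counterparts carry a premature stop at codon
    ``floor((1 - truncation_fraction) * length)``.
    """
    rng = np.random.default_rng(seed)
    chrom = "chr1"

    slots: list[dict] = []
    for i in range(spec.n_ortholog_genes):
        slots.append({"kind": "gene", "name": f"orth{i}",
                      "present": list(spec.species), "age": "preserved"})
    for sp, n in spec.species_specific_genes.items():
        for i in range(n):
            slots.append({"kind": "gene", "name": f"{sp}_young{i}",
                          "present": [sp], "age": "species_specific"})
    for i in range(spec.n_hominini_genes):
        slots.append({"kind": "gene", "name": f"hom{i}",
                      "present": list(spec.hominini), "age": "hominini_specific"})
    for i, s in enumerate(spec.sorfs):
        slots.append({"kind": "sorf", "name": f"sorf{i}", "sorf": s})

    slot_width = max(spec.gene_length,
                     max((3 * (s.length_codons + 1) for s in spec.sorfs),
                         default=0)) + spec.spacing
    total_len = spec.margin * 2 + slot_width * len(slots)
    sequences = {sp: list(_random_seq(rng, total_len)) for sp in spec.species}

    genes: list[Feature] = []
    orfs: list[OrfModel] = []
    mapping_rows: list[dict] = []
    hit_rows: list[dict] = []
    reads_rows: list[dict] = []
    truth_rows: list[dict] = []
    activity = ActivityTable(transcribed={sp: set() for sp in spec.species},
                             translated={sp: set() for sp in spec.species})

    def paste(species: str, start: int, seq: str) -> None:
        sequences[species][start:start + len(seq)] = list(seq)

    def add_mapping(fid: str, src: str, targets: list[str], start: int,
                    end: int) -> None:
        for tsp in targets:
            mapping_rows.append({
                "feature_id": fid, "source_species": src,
                "target_species": tsp, "target_chrom": chrom,
                "target_start": start, "target_end": end,
                "target_strand": "+", "colinear_flag": True})

    def add_hits(fid: str, others: list[str], length: int) -> None:
        for other_id in others:
            hit_rows.append({
                "qseqid": fid, "sseqid": other_id, "pident": 100.0,
                "length": length, "mismatch": 0, "gapopen": 0,
                "qstart": 1, "qend": length, "sstart": 1, "send": length,
                "evalue": 1e-50, "bitscore": 2 * length})

    for idx, slot in enumerate(slots):
        start = spec.margin + idx * slot_width

        if slot["kind"] == "gene":
            end = start + spec.gene_length
            shared = _random_seq(rng, spec.gene_length)
            present = slot["present"]
            ids = {sp: f"{slot['name']}_{sp}" for sp in present}
            for sp in present:
                paste(sp, start, shared)
                genes.append(Feature(ids[sp], sp, chrom, start, end, "+",
                                     biotype="protein_coding",
                                     feature_class="gene"))
                activity.transcribed[sp].add(ids[sp])
                others = [o for o in present if o != sp]
                add_mapping(ids[sp], sp, others, start, end)
                add_hits(ids[sp], [ids[o] for o in others], spec.gene_length)
                truth_rows.append({"feature_id": ids[sp], "species": sp,
                                   "kind": "gene", "true_age": slot["age"],
                                   "true_structure": None,
                                   "expected_intact_fraction": None})
            continue

        s: SorfSpec = slot["sorf"]
        host = s.host_species
        orf_nt = 3 * s.length_codons
        end = start + orf_nt + 3  # + stop codon
        orf_seq = _random_orf(rng, s.length_codons, s.start_codon)
        paste(host, start, orf_seq)

        host_gene_id = f"{slot['name']}_host_{host}"
        genes.append(Feature(host_gene_id, host, chrom, start, end, "+",
                             biotype="lncRNA", feature_class="gene"))
        activity.transcribed[host].add(host_gene_id)

        orf_id = f"{slot['name']}_{host}"
        orfs.append(OrfModel(orf_id, host_gene_id, host, chrom, "+",
                             [(start, start + orf_nt)],
                             start_codon=s.start_codon, n_samples_predicted=5))
        activity.translated[host].add(orf_id)

        others = [sp for sp in spec.species if sp != host]
        if s.status == "orphan":
            true_age, true_struct, expected_frac = "species_specific", "orphan", None
        elif s.status == "preserved":
            true_age, true_struct, expected_frac = "preserved", None, None
            counterpart_ids = {}
            for sp in others:
                paste(sp, start, orf_seq)
                cid = f"{slot['name']}_{sp}"
                counterpart_ids[sp] = cid
                orfs.append(OrfModel(cid, f"{slot['name']}_host_{sp}", sp,
                                     chrom, "+", [(start, start + orf_nt)],
                                     start_codon=s.start_codon,
                                     n_samples_predicted=5))
                genes.append(Feature(f"{slot['name']}_host_{sp}", sp, chrom,
                                     start, end, "+", biotype="lncRNA",
                                     feature_class="gene"))
                activity.translated[sp].add(cid)
                activity.transcribed[sp].add(f"{slot['name']}_host_{sp}")
                reads_rows.append({"feature_id": orf_id, "target_species": sp,
                                   "pooled_reads": 50})
            add_mapping(orf_id, host, others, start, start + orf_nt)
            add_hits(orf_id, list(counterpart_ids.values()), orf_nt)
        elif s.status == "hominini":
            # young, with intact aligned counterparts -> structure 'intact'
            true_age, true_struct, expected_frac = "hominini_specific", "intact", 1.0
            partner = [h for h in spec.hominini if h != host][0]
            paste(partner, start, orf_seq)
            pid = f"{slot['name']}_{partner}"
            orfs.append(OrfModel(pid, f"{slot['name']}_host_{partner}", partner,
                                 chrom, "+", [(start, start + orf_nt)],
                                 start_codon=s.start_codon,
                                 n_samples_predicted=5))
            genes.append(Feature(f"{slot['name']}_host_{partner}", partner,
                                 chrom, start, end, "+", biotype="lncRNA",
                                 feature_class="gene"))
            activity.translated[partner].add(pid)
            activity.transcribed[partner].add(f"{slot['name']}_host_{partner}")
            add_mapping(orf_id, host, others, start, start + orf_nt)
            add_hits(orf_id, [pid], orf_nt)
            reads_rows.append({"feature_id": orf_id, "target_species": partner,
                               "pooled_reads": 50})
            for sp in others:
                if sp == partner:
                    continue
                paste(sp, start, orf_seq)  # intact but untranslated counterpart
                reads_rows.append({"feature_id": orf_id, "target_species": sp,
                                   "pooled_reads": 0})
        else:  # intact / de_novo: species-specific young with aligned counterpart
            true_age = "species_specific"
            true_struct = s.status
            if s.status == "de_novo":
                # floor keeps the planted intact fraction <= 1 - truncation;
                # epsilon guards against 0.3 * L landing just under an integer
                stop_at = int(math.floor((1.0 - s.truncation_fraction)
                                         * s.length_codons + 1e-9))
                stop_at = max(1, stop_at)
                counterpart = (orf_seq[:3 * stop_at] + "TAA"
                               + orf_seq[3 * stop_at + 3:])
                expected_frac = stop_at / s.length_codons
            else:
                counterpart = orf_seq
                expected_frac = 1.0
            for sp in others:
                paste(sp, start, counterpart)
                reads_rows.append({"feature_id": orf_id, "target_species": sp,
                                   "pooled_reads": 0})
            add_mapping(orf_id, host, others, start, start + orf_nt)

        truth_rows.append({"feature_id": orf_id, "species": host,
                           "kind": "sorf", "true_age": true_age,
                           "true_structure": true_struct,
                           "expected_intact_fraction": expected_frac})

    return ToyGenomes(
        sequences={sp: {chrom: "".join(seq)} for sp, seq in sequences.items()},
        genes=FeatureTable(genes),
        orfs=orfs,
        mapping=pd.DataFrame(mapping_rows,
                             columns=["feature_id", "source_species",
                                      "target_species", "target_chrom",
                                      "target_start", "target_end",
                                      "target_strand", "colinear_flag"]),
        hits=pd.DataFrame(hit_rows, columns=["qseqid", "sseqid", "pident",
                                             "length", "mismatch", "gapopen",
                                             "qstart", "qend", "sstart",
                                             "send", "evalue", "bitscore"]),
        activity=activity,
        counterpart_reads=pd.DataFrame(
            reads_rows, columns=["feature_id", "target_species",
                                 "pooled_reads"]),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Tissue atlas
# ---------------------------------------------------------------------------

def simulate_tissue_atlas(n_genes: int, tissues: list[str], n_specific: int,
                          seed: int = 0, fold: float = 10.0,
                          noise_sd: float = 0.05,
                          base_expression: float = 5.0
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x tissue atlas with ``n_specific`` planted tissue-specific genes.

    Specific genes are expressed ``fold`` times higher in one designated
    tissue (cycled over the tissue list); the rest are near-uniform with
    multiplicative log-normal noise of scale ``noise_sd``.
    """
    if len(tissues) < 2:
        raise SimError("tau is undefined for a single tissue (n - 1 = 0)")
    if n_specific > n_genes:
        raise SimError("n_specific exceeds n_genes")
    rng = np.random.default_rng(seed)
    gene_ids = [f"t{i:05d}" for i in range(n_genes)]
    noise = (rng.lognormal(0.0, noise_sd, size=(n_genes, len(tissues)))
             if noise_sd > 0 else np.ones((n_genes, len(tissues))))
    values = base_expression * noise
    designated = pd.Series(np.nan, index=gene_ids, dtype=object,
                           name="designated_tissue")
    for i in range(n_specific):
        tissue_idx = i % len(tissues)
        values[i, tissue_idx] *= fold
        designated.iloc[i] = tissues[tissue_idx]
    atlas = pd.DataFrame(values, index=gene_ids, columns=tissues)
    atlas.index.name = "gene_id"
    return atlas, designated


# ---------------------------------------------------------------------------
# On-disk emission (CLI)
# ---------------------------------------------------------------------------

def write_simulation(outdir: str | Path, rna: CountMatrix, ribo: CountMatrix,
                     samples: SampleTable, truth: SimTruth) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(rna, outdir / "rna_counts.tsv")
    write_counts(ribo, outdir / "ribo_counts.tsv")
    write_sample_sheet(samples, outdir / "samples.tsv")
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
    truth.species_log2_te.rename_axis("gene_id").to_csv(
        outdir / "truth_species_log2_te.tsv", sep="\t")
    truth.size_factors.rename_axis("sample_id").to_csv(
        outdir / "truth_size_factors.tsv", sep="\t")


def write_toy_genomes(outdir: str | Path, toy: ToyGenomes) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, chroms in toy.sequences.items():
        write_fasta(chroms, outdir / f"{sp}.fa")
    write_bed12(FeatureTable([o.to_feature() for o in toy.orfs]),
                outdir / "orfs.bed")
    pd.DataFrame([{
        "orf_id": o.orf_id, "host_gene": o.host_gene, "species": o.species,
        "chrom": o.chrom, "strand": o.strand,
        "blocks": ";".join(f"{bs}-{be}" for bs, be in o.blocks),
        "start_codon": o.start_codon,
        "n_samples_predicted": o.n_samples_predicted,
    } for o in toy.orfs]).to_csv(outdir / "orfs.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "feature_id": f.feature_id, "species": f.species, "chrom": f.chrom,
        "start": f.start, "end": f.end, "strand": f.strand,
        "biotype": f.biotype, "feature_class": f.feature_class,
    } for f in toy.genes]).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    activity_rows = []
    for sp in toy.sequences:
        ids = toy.activity.transcribed.get(sp, set()) | \
            toy.activity.translated.get(sp, set())
        for fid in sorted(ids):
            activity_rows.append({
                "feature_id": fid, "species": sp,
                "transcribed": fid in toy.activity.transcribed.get(sp, set()),
                "translated": fid in toy.activity.translated.get(sp, set())})
    pd.DataFrame(activity_rows, columns=["feature_id", "species",
                                         "transcribed", "translated"]).to_csv(
        outdir / "activity.tsv", sep="\t", index=False)
    write_mapping(toy.mapping, outdir / "mapping.tsv")
    write_hits(toy.hits, outdir / "hits.tsv")
    toy.counterpart_reads.to_csv(outdir / "counterpart_reads.tsv", sep="\t",
                                 index=False)
    toy.truth.to_csv(outdir / "truth_features.tsv", sep="\t", index=False)


def load_toy_genomes(outdir: str | Path) -> ToyGenomes:
    """Read back a directory written by :func:`write_toy_genomes`."""
    from .io import read_fasta, read_hits, read_mapping

    outdir = Path(outdir)
    sequences = {fa.stem: read_fasta(fa) for fa in sorted(outdir.glob("*.fa"))}
    genes_df = pd.read_csv(outdir / "genes.tsv", sep="\t")
    genes = FeatureTable([
        Feature(r["feature_id"], r["species"], r["chrom"], int(r["start"]),
                int(r["end"]), r["strand"], biotype=r["biotype"],
                feature_class=r["feature_class"])
        for _, r in genes_df.iterrows()])
    orfs_df = pd.read_csv(outdir / "orfs.tsv", sep="\t")
    orfs = [OrfModel(
        r["orf_id"], r["host_gene"], r["species"], r["chrom"], r["strand"],
        [tuple(map(int, b.split("-"))) for b in r["blocks"].split(";")],
        start_codon=r["start_codon"],
        n_samples_predicted=int(r["n_samples_predicted"]))
        for _, r in orfs_df.iterrows()]
    act_df = pd.read_csv(outdir / "activity.tsv", sep="\t")
    activity = ActivityTable(
        transcribed={sp: set(act_df[(act_df["species"] == sp)
                                    & act_df["transcribed"]]["feature_id"])
                     for sp in sequences},
        translated={sp: set(act_df[(act_df["species"] == sp)
                                   & act_df["translated"]]["feature_id"])
                    for sp in sequences})
    truth_path = outdir / "truth_features.tsv"
    truth = (pd.read_csv(truth_path, sep="\t") if truth_path.exists()
             else pd.DataFrame())
    return ToyGenomes(
        sequences=sequences, genes=genes, orfs=orfs,
        mapping=read_mapping(outdir / "mapping.tsv"),
        hits=read_hits(outdir / "hits.tsv"),
        activity=activity,
        counterpart_reads=pd.read_csv(outdir / "counterpart_reads.tsv",
                                      sep="\t"),
        truth=truth,
    )
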