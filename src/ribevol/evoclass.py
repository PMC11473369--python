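"""Evolutionary classification of genes and sORFs from homology evidence.

Activity filters select 'actively transcribed' genes (mean FPKM >= 1 and
FPKM >= 0.5 in >= 3 replicates) and 'replicated' ORFs (predicted in >= 3
samples on an active host gene).  Redundant ORF isoforms sharing >= 90% of
their in-frame genomic positions are collapsed to one representative
(cognate AUG first, then longest, then lexicographic id).

Homology evidence combines two channels per (feature, target species):
a simplified coordinate-mapping (liftover-like) table and BLAST tabular
hits (best E-value <= 1e-4).  A homolog exists when either channel lands
on an active feature of the target species.  Ages: no homolog anywhere ->
species-specific; homolog activity confined to the hominini pair ->
hominini-specific; otherwise preserved.  Young sORFs additionally require
< 10 pooled Ribo-seq reads over every counterpart region.

Young sORF structures: no aligned counterpart -> orphan; counterpart open
reading frame truncated by >= 70% (first in-frame stop or frameshifting
gap) in the aligned species -> de novo; otherwise intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Feature, FeatureTable

logger = logging.getLogger("ribevol")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

AGES = ("species_specific", "hominini_specific", "preserved")
STRUCTURES = ("intact", "de_novo", "orphan")


class EvoClassError(ValueError):
    pass


@dataclass
class OrfModel:
    """A genomic ORF with frame information (0-based half-open blocks).

    Blocks cover the coding codons, stop codon excluded; their total span
    must be divisible by 3.
    """

    orf_id: str
    host_gene: str
    species: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    start_codon: str = "ATG"
    n_samples_predicted: int = 0
    biotype: str = "unannotated"

    def __post_init__(self) -> None:
        span = sum(be - bs for bs, be in self.blocks)
        if span % 3 != 0:
            raise EvoClassError(
                f"ORF {self.orf_id!r}: block span {span} not divisible by 3")
        self.start_codon = self.start_codon.upper().replace("U", "T")

    @property
    def is_cognate(self) -> bool:
        return self.start_codon == "ATG"

    @property
    def length_codons(self) -> int:
        return sum(be - bs for bs, be in self.blocks) // 3

    @property
    def start(self) -> int:
        return min(bs for bs, _ in self.blocks)

    @property
    def end(self) -> int:
        return max(be for _, be in self.blocks)

    def codon_start_positions(self) -> frozenset[tuple[int, str]]:
        """Genomic coordinates of each codon's first base, 5'->3', with strand."""
        coords: list[int] = []
        for bs, be in sorted(self.blocks):
            coords.extend(range(bs, be))
        if self.strand == "-":
            coords = coords[::-1]
        return frozenset((coords[i], self.strand) for i in range(0, len(coords), 3))

    def to_feature(self) -> Feature:
        return Feature(self.orf_id, self.species, self.chrom, self.start,
                       self.end, self.strand, sorted(self.blocks),
                       self.biotype, "sORF")


# ---------------------------------------------------------------------------
# Activity filters
# ---------------------------------------------------------------------------

def active_genes(fpkm_matrix: pd.DataFrame, sample_species: pd.Series,
                 min_reps: int = 3, fpkm_mean_min: float = 1.0,
                 fpkm_min_rep: float = 0.5) -> dict[str, set[str]]:
    """Actively transcribed gene sets per species.

    A gene is active in a species when its mean FPKM over that species'
    RNA replicates is >= ``fpkm_mean_min`` and at least ``min_reps``
    replicates have FPKM >= ``fpkm_min_rep``.
    """
    out: dict[str, set[str]] = {}
    for sp in sample_species.unique():
        cols = sample_species.index[sample_species == sp]
        if len(cols) < min_reps:
            raise EvoClassError(
                f"species {sp!r} has {len(cols)} replicates; the >= "
                f"{min_reps}-replicate rule is unsatisfiable (lower min_reps "
                "to override)")
        sub = fpkm_matrix[list(cols)]
        keep = ((sub.mean(axis=1) >= fpkm_mean_min)
                & ((sub >= fpkm_min_rep).sum(axis=1) >= min_reps))
        out[sp] = set(sub.index[keep])
        logger.info("active genes in %s: %d/%d", sp, len(out[sp]), len(sub))
    return out


def replicated_orfs(orfs: list[OrfModel], active: dict[str, set[str]],
                    min_samples: int = 3) -> list[OrfModel]:
    """ORFs predicted in >= min_samples samples whose host gene is active."""
    return [o for o in orfs
            if o.n_samples_predicted >= min_samples
            and o.host_gene in active.get(o.species, set())]


# ---------------------------------------------------------------------------
# ORF collapse
# ---------------------------------------------------------------------------

def _inframe_overlap(a: OrfModel, b: OrfModel) -> float:
    """Shared in-frame genomic positions relative to the shorter ORF."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0.0
    shared = len(a.codon_start_positions() & b.codon_start_positions())
    return shared / min(a.length_codons, b.length_codons)


def collapse_orfs(orfs: list[OrfModel],
                  overlap_cutoff: float = 0.9) -> dict[str, str]:
    """Group redundant in-frame ORF isoforms; map orf_id -> representative id.

    Two ORFs on the same strand and frame belong together when their shared
    in-frame genomic positions cover >= ``overlap_cutoff`` of the shorter
    ORF; grouping is the transitive closure of pairwise matches.  The
    representative is the cognate (AUG) ORF first, then the longest, then
    the lexicographically smallest orf_id.  Output is independent of input
    order.
    """
    ordered = sorted(orfs, key=lambda o: o.orf_id)
    parent = {o.orf_id: o.orf_id for o in ordered}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if _inframe_overlap(a, b) >= overlap_cutoff:
                ra, rb = find(a.orf_id), find(b.orf_id)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[OrfModel]] = {}
    for o in ordered:
        groups.setdefault(find(o.orf_id), []).append(o)
    result = {}
    for members in groups.values():
        rep = sorted(members,
                     key=lambda o: (not o.is_cognate, -o.length_codons, o.orf_id))[0]
        for o in members:
            result[o.orf_id] = rep.orf_id
    return result


# ---------------------------------------------------------------------------
# Homology evidence
# ---------------------------------------------------------------------------

@dataclass
class HomologyEvidence:
    """Evidence for one (query feature, target species) pair."""

    feature_id: str
    target_species: str
    liftover_status: str  # unique_full | partial_or_multiple | none
    blast_best_evalue: float | None = None
    target_feature: str | None = None
    target_transcribed: bool = False
    target_translated: bool = False
    counterpart_pooled_riboseq_reads: int | None = None
    counterpart_sequence: str | None = None
    robust: bool = False

    @property
    def aligned(self) -> bool:
        return self.liftover_status == "unique_full"


@dataclass
class ActivityTable:
    """Per-species activity flags for every feature in the homology universe.

    ``transcribed``/``translated`` map feature_id -> bool per species; the
    universe deliberately includes all transcribed genes and predicted ORFs
    of each species (not only active/replicated sets) to maximize homolog
    detection.
    """

    transcribed: dict[str, set[str]] = field(default_factory=dict)
    translated: dict[str, set[str]] = field(default_factory=dict)

    def is_transcribed(self, species: str, feature_id: str | None) -> bool:
        return feature_id is not None and feature_id in self.transcribed.get(species, set())

    def is_translated(self, species: str, feature_id: str | None) -> bool:
        return feature_id is not None and feature_id in self.translated.get(species, set())


def _longest_overlap_feature(features: FeatureTable, species: str, chrom: str,
                             start: int, end: int, strand: str) -> str | None:
    best = None
    best_len = 0
    for f in features:
        if f.species != species or f.chrom != chrom or f.strand != strand:
            continue
        ov = min(f.end, end) - max(f.start, start)
        if ov > best_len or (ov == best_len and ov > 0
                             and (best is None or f.feature_id < best)):
            best, best_len = f.feature_id, ov
    return best


def resolve_homologs(query_features: FeatureTable, all_features: FeatureTable,
                     mapping: pd.DataFrame, hits: pd.DataFrame,
                     activity: ActivityTable, target_species: list[str],
                     counterpart_reads: pd.DataFrame | None = None,
                     sequences: dict[str, dict[str, str]] | None = None,
                     evalue_max: float = 1e-4) -> list[HomologyEvidence]:
    """Build one evidence record per (query feature, other species).

    ``mapping`` rows mark liftover-like placements (colinear_flag True =
    fully and uniquely mapped, same strand/chromosome); ``hits`` is BLAST
    outfmt-6 with feature ids; ``counterpart_reads`` holds pooled Ribo-seq
    reads over counterpart regions (feature_id, target_species,
    pooled_reads).  ``sequences`` (species -> chrom -> sequence) enables
    counterpart sequence extraction for structure calls.
    """
    known = {f.feature_id for f in all_features} | {f.feature_id for f in query_features}
    species_of = {f.feature_id: f.species for f in all_features}
    bad = set(mapping["feature_id"]) - known
    if bad:
        raise EvoClassError(f"mapping rows for unknown feature(s): {sorted(bad)[:5]}")
    known_species = set(target_species) | {f.species for f in all_features} | \
        {f.species for f in query_features}
    bad_sp = set(mapping["target_species"]) - known_species
    if bad_sp:
        raise EvoClassError(f"mapping rows reference unknown species: {sorted(bad_sp)}")

    reads_lookup: dict[tuple[str, str], int] = {}
    if counterpart_reads is not None:
        for _, row in counterpart_reads.iterrows():
            reads_lookup[(row["feature_id"], row["target_species"])] = \
                int(row["pooled_reads"])

    evidence: list[HomologyEvidence] = []
    for f in query_features:
        for tsp in target_species:
            if tsp == f.species:
                continue
            rows = mapping[(mapping["feature_id"] == f.feature_id)
                           & (mapping["target_species"] == tsp)]
            if len(rows) == 0:
                status = "none"
            elif len(rows) == 1 and bool(rows.iloc[0]["colinear_flag"]):
                status = "unique_full"
            else:
                status = "partial_or_multiple"

            target_feature = None
            counterpart_seq = None
            if status == "unique_full":
                r = rows.iloc[0]
                target_feature = _longest_overlap_feature(
                    all_features, tsp, r["target_chrom"],
                    int(r["target_start"]), int(r["target_end"]),
                    r["target_strand"])
                if sequences is not None and tsp in sequences:
                    chrom_seq = sequences[tsp].get(r["target_chrom"])
                    if chrom_seq is not None:
                        counterpart_seq = Feature(
                            f.feature_id, tsp, r["target_chrom"],
                            int(r["target_start"]), int(r["target_end"]),
                            r["target_strand"]).sequence(chrom_seq)

            sub = hits[(hits["qseqid"] == f.feature_id)
                       & (hits["sseqid"].map(lambda s: species_of.get(s)) == tsp)]
            best_e = None
            blast_subject = None
            if len(sub):
                accepted = sub[sub["evalue"] <= evalue_max]
                best_e = float(sub["evalue"].min())
                if len(accepted):
                    blast_subject = accepted.sort_values(
                        ["evalue", "sseqid"]).iloc[0]["sseqid"]

            candidates = [c for c in (target_feature, blast_subject) if c is not None]
            transcribed = any(activity.is_transcribed(tsp, c) for c in candidates)
            translated = any(activity.is_translated(tsp, c) for c in candidates)
            robust = (status == "unique_full" and blast_subject is not None
                      and target_feature == blast_subject
                      and (transcribed or translated))
            evidence.append(HomologyEvidence(
                feature_id=f.feature_id, target_species=tsp,
                liftover_status=status, blast_best_evalue=best_e,
                target_feature=target_feature or blast_subject,
                target_transcribed=transcribed, target_translated=translated,
                counterpart_pooled_riboseq_reads=reads_lookup.get(
                    (f.feature_id, tsp),
                    0 if status == "unique_full" else None),
                counterpart_sequence=counterpart_seq, robust=robust))
    return evidence


def evidence_frame(evidence: list[HomologyEvidence]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_id": e.feature_id,
        "target_species": e.target_species,
        "liftover_status": e.liftover_status,
        "blast_best_evalue": e.blast_best_evalue,
        "target_feature": e.target_feature,
        "target_transcribed": e.target_transcribed,
        "target_translated": e.target_translated,
        "counterpart_pooled_riboseq_reads": e.counterpart_pooled_riboseq_reads,
        "robust": e.robust,
    } for e in evidence])


def _homolog_species(evidence: list[HomologyEvidence], feature_id: str,
                     flag: str) -> set[str]:
    found = set()
    for e in evidence:
        if e.feature_id != feature_id:
            continue
        channel = (e.aligned and e.target_feature is not None) or \
            (e.blast_best_evalue is not None)
        if channel and getattr(e, flag):
            found.add(e.target_species)
    return found


def assign_gene_age(evidence: list[HomologyEvidence], feature_id: str,
                    query_species: str,
                    hominini: tuple[str, str] = ("human", "chimp")) -> str:
    """Gene age from transcribed-homolog evidence."""
    homologs = _homolog_species(evidence, feature_id, "target_transcribed")
    if not homologs:
        return "species_specific"
    if query_species in hominini and homologs <= set(hominini):
        return "hominini_specific"
    return "preserved"


def assign_orf_age(evidence: list[HomologyEvidence], feature_id: str,
                   query_species: str,
                   hominini: tuple[str, str] = ("human", "chimp"),
                   min_counterpart_reads: int = 10) -> str:
    """sORF age from translated-homolog evidence plus counterpart reads.

    Any counterpart region with >= ``min_counterpart_reads`` pooled Ribo-seq
    reads vetoes a young call for that species.
    """
    homologs = _homolog_species(evidence, feature_id, "target_translated")
    high_reads = {
        e.target_species for e in evidence
        if e.feature_id == feature_id
        and e.counterpart_pooled_riboseq_reads is not None
        and e.counterpart_pooled_riboseq_reads >= min_counterpart_reads}
    if not homologs and not high_reads:
        return "species_specific"
    if (query_species in hominini and homologs and homologs <= set(hominini)
            and high_reads <= homologs):
        return "hominini_specific"
    return "preserved"


# ---------------------------------------------------------------------------
# sORF structure
# ---------------------------------------------------------------------------

def inframe_intact_fraction(length_codons: int, aligned_counterpart: str) -> float:
    """Fraction of the ORF's codons intact in an aligned counterpart.

    ``aligned_counterpart`` is the counterpart sequence aligned to the ORF's
    coding positions, with ``-`` marking deleted bases.  Walking 5'->3', the
    intact stretch ends at the first in-frame stop codon or at the first
    alignment gap whose length is not a multiple of 3 (a frameshift; no
    frame-restoration scanning is attempted).
    """
    if length_codons <= 0:
        raise EvoClassError("length_codons must be positive")
    seq = aligned_counterpart.upper().replace("U", "T")

    first_event = length_codons

    # frameshift: first maximal gap run with length % 3 != 0
    i = 0
    while i < len(seq):
        if seq[i] == "-":
            run_start = i
            while i < len(seq) and seq[i] == "-":
                i += 1
            if (i - run_start) % 3 != 0:
                first_event = min(first_event, run_start // 3)
                break
        else:
            i += 1

    # in-frame stop: read the gapless counterpart codon-wise; each codon is
    # attributed to the ORF codon of its first aligned base
    bases = [(c, pos) for pos, c in enumerate(seq) if c != "-"]
    for k in range(len(bases) // 3):
        codon = "".join(c for c, _ in bases[3 * k:3 * k + 3])
        orf_codon = bases[3 * k][1] // 3
        if orf_codon >= first_event:
            break
        if codon in STOP_CODONS:
            first_event = min(first_event, orf_codon)
            break

    # counterpart exhausted before the ORF ends
    available = len(bases) // 3
    if available < length_codons:
        first_event = min(first_event, available)
    return first_event / length_codons


def classify_structure(orf: OrfModel, evidence: list[HomologyEvidence],
                       truncation_cutoff: float = 0.7,
                       rule: str = "all") -> tuple[str, dict[str, float]]:
    """Structure class of a young sORF and its per-species intact fractions.

    ``rule='all'`` (default) requires the counterpart to be truncated by at
    least ``truncation_cutoff`` in every aligned species for a de novo call;
    ``rule='any'`` requires it in at least one.
    """
    if rule not in ("all", "any"):
        raise EvoClassError(f"unknown de novo rule {rule!r}")
    fractions: dict[str, float] = {}
    for e in evidence:
        if e.feature_id != orf.orf_id or not e.aligned:
            continue
        if e.counterpart_sequence is None:
            continue
        fractions[e.target_species] = inframe_intact_fraction(
            orf.length_codons, e.counterpart_sequence)
    if not fractions:
        return "orphan", fractions
    truncated = [frac <= (1.0 - truncation_cutoff) for frac in fractions.values()]
    agg = all if rule == "all" else any
    if agg(truncated):
        return "de_novo", fractions
    return "intact", fractions
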