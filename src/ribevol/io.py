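"""Readers, writers and validation for every external format the pipeline touches.

All genomic intervals are held internally as 0-based half-open coordinates.
GTF (1-based closed) is converted at the boundary in both directions; BED12 is
native.  Count, sample, mapping and hit tables are plain TSV; the hit table
follows the 12-column BLAST ``outfmt 6`` order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ribevol")

ASSAYS = frozenset({"RNA", "RIBO"})

#: Pipeline thresholds.  Every cutoff used downstream is configurable here;
#: the defaults are the published values.
DEFAULT_CONFIG: dict[str, float | int | str] = {
    "fpkm_min_rep": 0.5,
    "fpkm_mean_min": 1.0,
    "min_reps": 3,
    "tau_cutoff": 0.75,
    "fc_cutoff": 1.5,
    "alpha": 0.05,
    "overlap_collapse": 0.9,
    "truncation_cutoff": 0.7,
    "evalue_max": 1e-4,
    "min_counterpart_reads": 10,
    "iterations": 10000,
    "max_zero_reps": 3,
    "pseudocount": 1.0,
    "te_scale": "log2",
    "denovo_rule": "all",
}

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

MAPPING_COLUMNS = [
    "feature_id", "source_species", "target_species", "target_chrom",
    "target_start", "target_end", "target_strand", "colinear_flag",
]


class FormatError(ValueError):
    """Raised for malformed input files; carries file/line context."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# Core tabular types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Features x samples matrix of non-negative counts.

    ``counts`` may hold floats after length adjustment; raw input must be
    non-negative integers.  ``feature_lengths`` (nt) is optional and aligned
    to ``counts.index``.
    """

    counts: pd.DataFrame
    feature_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicated feature_id {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicated sample_id {dup!r}")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise FormatError("counts contain non-finite values")
        if (values < 0).any():
            raise FormatError("negative count encountered")
        if self.feature_lengths is not None:
            self.feature_lengths = self.feature_lengths.reindex(self.counts.index)
            if self.feature_lengths.isna().any():
                missing = self.feature_lengths.index[self.feature_lengths.isna()][0]
                raise FormatError(f"missing feature length for {missing!r}")
            if (self.feature_lengths <= 0).any():
                raise FormatError("feature lengths must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)].copy(),
                           self.feature_lengths)


@dataclass
class SampleTable:
    """Sample sheet: one row per sequencing sample.

    ``pairing_key`` links each RIBO sample to exactly one RNA sample of the
    same species and tissue.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "species", "tissue", "assay", "replicate",
                "pairing_key")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicated sample_id {dup!r}")
        bad = set(self.table["assay"]) - ASSAYS
        if bad:
            raise FormatError(f"unknown assay label(s): {sorted(bad)}")
        rna = self.table[self.table["assay"] == "RNA"]
        for _, row in self.table[self.table["assay"] == "RIBO"].iterrows():
            match = rna[(rna["pairing_key"] == row["pairing_key"])
                        & (rna["species"] == row["species"])
                        & (rna["tissue"] == row["tissue"])]
            if len(match) != 1:
                raise FormatError(
                    f"RIBO sample {row['sample_id']!r} pairing_key "
                    f"{row['pairing_key']!r} resolves to {len(match)} RNA "
                    "samples (expected exactly 1)")

    def samples_for(self, assay: str, species: str | None = None,
                    tissue: str | None = None) -> list[str]:
        t = self.table[self.table["assay"] == assay]
        if species is not None:
            t = t[t["species"] == species]
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        return list(t["sample_id"])

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for s in self.table["species"]:
            if s not in seen:
                seen.append(s)
        return seen

    def pairs(self) -> pd.DataFrame:
        """Matched (ribo_sample, rna_sample) per pairing_key with metadata."""
        ribo = self.table[self.table["assay"] == "RIBO"]
        rna = self.table[self.table["assay"] == "RNA"]
        merged = ribo.merge(rna, on=["pairing_key", "species", "tissue"],
                            suffixes=("_ribo", "_rna"))
        return merged[["pairing_key", "species", "tissue",
                       "sample_id_ribo", "sample_id_rna"]]


@dataclass
class Feature:
    """A genomic feature with exon/codon blocks (0-based half-open)."""

    feature_id: str
    species: str
    chrom: str
    start: int
    end: int
    strand: str
    blocks: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"
    feature_class: str = "gene"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FormatError(
                f"feature {self.feature_id!r}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")
        if not self.blocks:
            self.blocks = [(self.start, self.end)]
        prev_end = None
        for bs, be in self.blocks:
            if bs < self.start or be > self.end:
                raise FormatError(
                    f"feature {self.feature_id!r}: block ({bs},{be}) outside "
                    f"span [{self.start},{self.end})")
            if bs >= be:
                raise FormatError(f"feature {self.feature_id!r}: empty block ({bs},{be})")
            if prev_end is not None and bs < prev_end:
                raise FormatError(
                    f"feature {self.feature_id!r}: blocks unsorted/overlapping")
            prev_end = be

    @property
    def block_span(self) -> int:
        return sum(be - bs for bs, be in self.blocks)

    def sequence(self, chrom_seq: str) -> str:
        """Spliced sequence; minus-strand features are reverse-complemented."""
        seq = "".join(chrom_seq[bs:be] for bs, be in self.blocks)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class FeatureTable:
    features: list[Feature]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise FormatError(f"duplicated feature_id {f.feature_id!r}")
            seen.add(f.feature_id)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def by_species(self, species: str) -> "FeatureTable":
        return FeatureTable([f for f in self.features if f.species == species])


# ---------------------------------------------------------------------------
# TSV round-trips
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, lengths_path: str | Path | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float, np.integer, np.floating)))]
            line = int(bad.index.get_indexer([bad.index[0]])[0]) + 2 if len(bad) else None
            raise FormatError(f"non-numeric count in column {col!r}", path, line)
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = lt.iloc[:, 0].astype(int)
        lengths.index = lengths.index.astype(str)
    return CountMatrix(df, lengths)


def write_counts(cm: CountMatrix, path: str | Path,
                 lengths_path: str | Path | None = None) -> None:
    cm.counts.rename_axis("feature_id").to_csv(path, sep="\t")
    if lengths_path is not None and cm.feature_lengths is not None:
        cm.feature_lengths.rename("length").rename_axis("feature_id").to_csv(
            lengths_path, sep="\t")


def read_sample_sheet(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pairing_key": str})
    return SampleTable(df)


def write_sample_sheet(st: SampleTable, path: str | Path) -> None:
    st.table.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_hits(path: str | Path) -> pd.DataFrame:
    """BLAST tabular (outfmt 6) without header; qseqid/sseqid are feature ids."""
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)
    df["evalue"] = df["evalue"].astype(float)
    if (df["evalue"] < 0).any():
        raise FormatError("negative E-value", path)
    return df


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits[BLAST6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_mapping(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MAPPING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"mapping table missing columns: {missing}", path)
    df["colinear_flag"] = df["colinear_flag"].astype(bool)
    return df


def write_mapping(mapping: pd.DataFrame, path: str | Path) -> None:
    mapping[MAPPING_COLUMNS].to_csv(path, sep="\t", index=False)


def write_results(tables: Mapping[str, pd.DataFrame], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        logger.info("wrote %s (%d rows)", outdir / f"{name}.tsv", len(df))


# ---------------------------------------------------------------------------
# BED12 / GTF
# ---------------------------------------------------------------------------

def read_features(path: str | Path, species: str = "unknown") -> FeatureTable:
    """Dispatch on extension: ``.bed`` -> BED12, ``.gtf`` -> GTF."""
    path = Path(path)
    if path.suffix == ".bed":
        return read_bed12(path, species)
    if path.suffix == ".gtf":
        return read_gtf(path, species)
    raise FormatError(f"unrecognised feature file extension {path.suffix!r}", path)


def read_bed12(path: str | Path, species: str = "unknown") -> FeatureTable:
    features = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            cols = raw.split("\t")
            if len(cols) < 12:
                raise FormatError(f"BED12 needs 12 columns, got {len(cols)}", path, ln)
            chrom, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
            strand = cols[5]
            n_blocks = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError("blockCount does not match block lists", path, ln)
            blocks = [(start + off, start + off + size)
                      for off, size in zip(starts, sizes)]
            try:
                features.append(Feature(name, species, chrom, start, end, strand,
                                        blocks))
            except FormatError as exc:
                raise FormatError(str(exc), path, ln) from None
    return FeatureTable(features)


def write_bed12(table: FeatureTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in table:
            sizes = ",".join(str(be - bs) for bs, be in f.blocks)
            starts = ",".join(str(bs - f.start) for bs, be in f.blocks)
            fh.write("\t".join(map(str, [
                f.chrom, f.start, f.end, f.feature_id, 0, f.strand,
                f.start, f.end, "0,0,0", len(f.blocks), sizes, starts,
            ])) + "\n")


def read_gtf(path: str | Path, species: str = "unknown") -> FeatureTable:
    """Minimal GTF reader: one feature per gene/CDS line, exon lines as blocks."""
    parents: dict[str, Feature] = {}
    blocks: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            cols = raw.split("\t")
            if len(cols) != 9:
                raise FormatError(f"GTF needs 9 columns, got {len(cols)}", path, ln)
            chrom, _, kind, start1, end1, _, strand, _, attrs = cols
            start, end = int(start1) - 1, int(end1)  # 1-based closed -> half-open
            attr = _parse_gtf_attrs(attrs)
            fid = attr.get("gene_id")
            if fid is None:
                raise FormatError("missing gene_id attribute", path, ln)
            if kind in ("gene", "CDS", "sORF"):
                parents[fid] = Feature(
                    fid, species, chrom, start, end, strand,
                    blocks=[], biotype=attr.get("gene_biotype", "protein_coding"),
                    feature_class="gene" if kind == "gene" else kind)
                order.append(fid)
            elif kind == "exon":
                blocks.setdefault(fid, []).append((start, end))
    out = []
    for fid in order:
        f = parents[fid]
        if fid in blocks:
            f = Feature(f.feature_id, f.species, f.chrom, f.start, f.end,
                        f.strand, sorted(blocks[fid]), f.biotype, f.feature_class)
        out.append(f)
    return FeatureTable(out)


def write_gtf(table: FeatureTable, path: str | Path, source: str = "ribevol") -> None:
    with open(path, "w") as fh:
        for f in table:
            kind = "gene" if f.feature_class == "gene" else f.feature_class
            attrs = f'gene_id "{f.feature_id}"; gene_biotype "{f.biotype}";'
            fh.write("\t".join(map(str, [
                f.chrom, source, kind, f.start + 1, f.end, ".", f.strand, ".",
                attrs])) + "\n")
            if f.blocks != [(f.start, f.end)]:
                for bs, be in f.blocks:
                    fh.write("\t".join(map(str, [
                        f.chrom, source, "exon", bs + 1, be, ".", f.strand,
                        ".", attrs])) + "\n")


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip('"')
    return out


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path | None = None) -> dict:
    """Flat key-value config; unknown keys rejected, defaults filled in."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError("config must be a flat mapping", path)
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}", path)
        config.update(user)
    logger.info("config: %s", config)
    return config
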