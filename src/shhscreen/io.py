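"""Readers, writers and pipeline configuration.

Stage interchange uses headered TSV (diff-able, language-neutral); plate
data is long-format CSV.  Gene models are read from GFF3 (via gffutils,
exons grouped to genes through Parent chains) or BED12 (blockSizes /
blockStarts reconstructed); coordinates are 0-based half-open internally,
converted on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dosage import GeneModel
from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12 (format inferred from suffix).

    GFF3 exon features are grouped by gene through Parent chains; a
    ``species`` attribute on the gene line sets the species tag (default
    mouse).  Duplicate exon records are tolerated (union handles them).
    Genes with no exons are skipped with a warning; an empty file yields an
    empty collection with a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed12" if path.suffix.lower() == ".bed" else "gff3"
    if fmt == "gff3":
        return _read_gff3(path)
    if fmt == "bed12":
        return _read_bed12(path)
    raise FormatError(f"unknown gene-model format '{fmt}'")


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    text = path.read_text()
    if not text.strip():
        warnings.warn(f"{path}: empty gene-model file")
        return []
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc

    models = []
    for gene in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)  # GFF3 1-based inclusive -> 0-based half-open
            for e in db.children(gene, featuretype="exon")
        ]
        if not exons:
            warnings.warn(f"{path}: gene {gene.id} has no exons; skipped")
            continue
        species = gene.attributes.get("species", ["mouse"])[0]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=sorted(set(exons)),
                species_tag=species,
            )
        )
    return models


def _read_bed12(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        lines = [ln for ln in fh]
    if not any(ln.strip() for ln in lines):
        warnings.warn(f"{path}: empty gene-model file")
        return []
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise FormatError(f"{path}:{lineno}: expected 12 BED fields, got {len(parts)}")
        try:
            chrom, start = parts[0], int(parts[1])
            name, strand = parts[3], parts[5]
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparseable BED12 fields ({exc})") from exc
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise FormatError(f"{path}:{lineno}: blockCount does not match block lists")
        exons = [(start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)]
        models.append(
            GeneModel(
                gene_id=name,
                chromosome=chrom,
                strand=strand if strand in "+-" else "+",
                exons=exons,
            )
        )
    return models


def write_gff3(models, path) -> None:
    """Write gene models as GFF3 with gene/exon features and species tags."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.gene_id};species={m.species_tag}"
            fh.write(
                f"{m.chromosome}\tshhscreen\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(sorted(m.exons), 1):
                fh.write(
                    f"{m.chromosome}\tshhscreen\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.e{i};Parent={m.gene_id}\n"
                )


def write_bed12(models, path) -> None:
    with open(path, "w") as fh:
        for m in models:
            exons = sorted(m.exons)
            start, end = exons[0][0], exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - start) for s, _ in exons)
            fh.write(
                f"{m.chromosome}\t{start}\t{end}\t{m.gene_id}\t0\t{m.strand}\t"
                f"{start}\t{end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# tabular interchange
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_counts_tsv(path) -> pd.DataFrame:
    """Genes x samples count matrix with gene_id as first column."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: counts TSV must have a gene_id column")
    return df.set_index("gene_id")


def read_sample_meta_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "genotype"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample metadata missing columns {sorted(missing)}")
    return df


def read_ortholog_map_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"human_id", "mouse_id"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: ortholog map missing columns {sorted(missing)}")
    return df


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration; round-trips losslessly through
    YAML/JSON via :meth:`to_dict` / :meth:`from_dict`."""

    outdir: str = "out"
    seed: int = 0
    # thresholds
    strong_z: float = 2.0
    weak_z: float = 1.0
    alpha: float = 0.1
    fpkm_cut: float = 1.0
    tpm_cut: float = 1.0
    bin_lo: float = 1.3
    bin_hi: float = 1.7
    min_wells: int = 8
    # flags
    transchromosomic: bool = False
    # simulation block (None -> inputs must be provided as files)
    simulate: dict | None = None
    # input files (used when simulate is None)
    plates_files: list[str] = field(default_factory=list)
    assay_file: str | None = None
    counts_file: str | None = None
    samples_file: str | None = None
    genes_file: str | None = None
    orthologs_file: str | None = None
    models_file: str | None = None
    control_label: str = "GFP"

    def validate(self) -> None:
        if self.strong_z < self.weak_z or self.weak_z <= 0:
            raise ConfigError("thresholds must satisfy strong_z >= weak_z > 0")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.bin_lo >= self.bin_hi:
            raise ConfigError("dosage bins must satisfy bin_lo < bin_hi")
        if min(self.fpkm_cut, self.tpm_cut) <= 0:
            raise ConfigError("FPKM/TPM cuts must be > 0")
        if self.min_wells < 1:
            raise ConfigError("min_wells must be >= 1")
        if self.simulate is None and not self.plates_files:
            raise ConfigError("either a simulate block or input files are required")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
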