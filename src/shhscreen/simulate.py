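"""Synthetic data generators for plate screens and trisomic count matrices.

Two generators provide every input the downstream stages consume:

``simulate_plates``
    96-well dual-luciferase plates laid out as in the screen design: two to
    three dedicated control rows per plate and one row (eight technical
    replicate wells) per cDNA.  Each well's Fluc/Rluc ratio is
    baseline x plate factor x edge factor x cDNA effect x well noise, with
    log-normal multiplicative noise (ratios are strictly positive and every
    modeled effect is multiplicative).

``simulate_counts``
    Negative-binomial genes x samples count matrices for trisomic vs euploid
    littermates with strictly copy-proportional expectation
    (E[trisomic]/E[euploid] = copies/2), optional transchromosomic read
    partitioning (the third copy emitted as a human-tagged row), and
    segmental deletions restoring two copies.

Both generators draw from a single ``numpy.random.default_rng`` stream per
call and are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosage import GeneModel
from .errors import ConfigError

PLATE_COLUMNS = ["plate", "row", "col", "cdna", "treatment", "fluc", "rluc"]


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log1p(cv * cv)
    return np.exp(rng.normal(-0.5 * s2, math.sqrt(s2), size))


# ---------------------------------------------------------------------------
# plate screens
# ---------------------------------------------------------------------------

@dataclass
class PlateSimConfig:
    """Configuration for the dual-luciferase plate simulator.

    Defaults mirror the screen design: 8x12 plates, eight replicate wells
    (one row) per cDNA, dedicated GFP control rows.  Noise magnitudes are
    plate-to-plate scale SD 0.15 (log scale), well CV 0.10 and a 5%
    multiplicative elevation of peripheral wells; the underlying study does
    not report these magnitudes, so they are exposed here as configuration.
    """

    n_cdnas: int
    n_rows: int = 8
    n_cols: int = 12
    replicates_per_cdna: int = 8
    control_label: str = "GFP"
    control_rows: int = 2
    plate_scale_sd: float = 0.15
    edge_gradient: float = 0.05
    well_noise_cv: float = 0.10
    effect_map: dict[str, float] = field(default_factory=dict)
    baseline_ratio: float = 1.0
    treatment: str = "SAG"
    rluc_baseline: float = 1000.0
    cdna_names: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_cdnas < 1:
            raise ConfigError("n_cdnas must be >= 1")
        if not (1 <= self.control_rows < self.n_rows):
            raise ConfigError("control_rows must leave at least one cDNA row")
        if self.replicates_per_cdna > self.n_cols:
            raise ConfigError("replicates_per_cdna cannot exceed n_cols (one row per cDNA)")
        if self.n_rows * self.n_cols < self.replicates_per_cdna:
            raise ConfigError("plate too small for replicates_per_cdna")
        if min(self.plate_scale_sd, self.well_noise_cv) < 0:
            raise ConfigError("noise SD/CV parameters must be >= 0")
        if self.edge_gradient <= -1:
            raise ConfigError("edge_gradient must be > -1 (multiplicative bias 1+edge_gradient)")
        if self.baseline_ratio <= 0 or self.rluc_baseline <= 0:
            raise ConfigError("baseline_ratio and rluc_baseline must be > 0")
        for gene, eff in self.effect_map.items():
            if eff <= 0:
                raise ConfigError(f"effect for {gene} must be > 0 (1.0 = null)")

    def resolved_names(self) -> list[str]:
        if self.cdna_names is not None:
            if len(self.cdna_names) != self.n_cdnas:
                raise ConfigError("cdna_names length must equal n_cdnas")
            names = list(self.cdna_names)
        else:
            names = [f"C{i + 1:03d}" for i in range(self.n_cdnas)]
        if self.control_label in names:
            raise ConfigError("control_label collides with a cDNA name")
        return names


def simulate_plates(cfg: PlateSimConfig) -> pd.DataFrame:
    """Simulate a screen and return a long-format well table.

    Columns: plate, row, col, cdna, treatment, fluc, rluc.  Control wells
    fill the first ``control_rows`` rows of every plate; each cDNA occupies
    ``replicates_per_cdna`` wells of one row on one plate.  Peripheral wells
    (first/last row or column) get the multiplicative bias
    ``1 + edge_gradient``.
    """
    cfg.validate()
    names = cfg.resolved_names()
    unknown = set(cfg.effect_map) - set(names) - {cfg.control_label}
    if unknown:
        raise ConfigError(f"effect_map references unknown cDNAs: {sorted(unknown)}")

    rng = np.random.default_rng(cfg.seed)
    rows_avail = cfg.n_rows - cfg.control_rows
    n_plates = math.ceil(cfg.n_cdnas / rows_avail)

    plate_ids, rows, cols, cdnas, plate_idx = [], [], [], [], []
    for p in range(n_plates):
        pid = f"P{p + 1:02d}"
        for r in range(1, cfg.control_rows + 1):
            for c in range(1, cfg.n_cols + 1):
                plate_ids.append(pid); rows.append(r); cols.append(c)
                cdnas.append(cfg.control_label); plate_idx.append(p)
        for i, gene in enumerate(names[p * rows_avail:(p + 1) * rows_avail]):
            r = cfg.control_rows + 1 + i
            for c in range(1, cfg.replicates_per_cdna + 1):
                plate_ids.append(pid); rows.append(r); cols.append(c)
                cdnas.append(gene); plate_idx.append(p)

    n_wells = len(plate_ids)
    rows_a = np.asarray(rows)
    cols_a = np.asarray(cols)
    plate_idx_a = np.asarray(plate_idx)

    if cfg.plate_scale_sd > 0:
        plate_factors = np.exp(rng.normal(0.0, cfg.plate_scale_sd, n_plates))
    else:
        plate_factors = np.ones(n_plates)
    edge = (rows_a == 1) | (rows_a == cfg.n_rows) | (cols_a == 1) | (cols_a == cfg.n_cols)
    edge_factor = np.where(edge, 1.0 + cfg.edge_gradient, 1.0)
    effect = np.array([cfg.effect_map.get(g, 1.0) for g in cdnas])
    noise = _mean_one_lognormal(rng, cfg.well_noise_cv, n_wells)

    ratio = cfg.baseline_ratio * plate_factors[plate_idx_a] * edge_factor * effect * noise
    rluc = cfg.rluc_baseline * _mean_one_lognormal(rng, cfg.well_noise_cv, n_wells)
    fluc = ratio * rluc

    return pd.DataFrame(
        {
            "plate": plate_ids,
            "row": rows_a,
            "col": cols_a,
            "cdna": cdnas,
            "treatment": cfg.treatment,
            "fluc": fluc,
            "rluc": rluc,
        }
    )[PLATE_COLUMNS]


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountSimConfig:
    """Configuration for the trisomic/euploid count simulator.

    The default design is 4 trisomic vs 4 euploid littermates.  Per-gene
    expected counts are proportional to relative abundance x exon-union
    length x copy number / 2 x per-sample library factor, scaled so that a
    euploid sample's expected total is ``library_size``.  ``dispersion`` is
    the negative-binomial dispersion alpha in var = mu + alpha mu^2;
    ``dispersion=0`` gives the deterministic noise-free limit (counts equal
    rounded expectations).
    """

    n_genes: int
    n_trisomic_genes: int
    exon_length_range: tuple[int, int] = (500, 5000)
    n_trisomic_samples: int = 4
    n_euploid_samples: int = 4
    library_size: float = 1e6
    dispersion: float = 0.05
    library_factor_sd: float = 0.1
    abundance_sd: float = 1.0
    transchromosomic: bool = False
    deletion_segments: tuple[tuple[int, int], ...] = ()
    copy_number_map: dict[str, int] | None = None
    model_name: str = "TsSim"
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.n_trisomic_genes <= self.n_genes):
            raise ConfigError("need 0 <= n_trisomic_genes <= n_genes")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        lo, hi = self.exon_length_range
        if not (0 < lo <= hi):
            raise ConfigError("exon_length_range must be a positive increasing pair")
        if self.n_trisomic_samples < 1 or self.n_euploid_samples < 1:
            raise ConfigError("need at least one sample per genotype")
        if self.library_size <= 0:
            raise ConfigError("library_size must be > 0")
        for seg in self.deletion_segments:
            s, e = seg
            if not (0 <= s < e <= self.n_genes):
                raise ConfigError(f"deletion segment {seg} outside gene range [0, {self.n_genes})")


@dataclass
class SimulatedCounts:
    """Bundle returned by :func:`simulate_counts`.

    Attributes
    ----------
    counts : DataFrame
        Genes x samples integer counts (human-tagged rows included in
        transchromosomic mode).
    samples : DataFrame
        Sample metadata: sample, genotype, model.
    gene_models : list of GeneModel
        One model per count-matrix row, with species tags.
    truth : DataFrame
        Ground-truth table per mouse gene: copies, genelen, base mean and
        the expected fold change (copies/2; in transchromosomic mode the
        expectation refers to the ortholog-merged row).
    ortholog_map : DataFrame or None
        human_id/mouse_id pairs for the human-tagged rows (transchromosomic
        mode only).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_models: list[GeneModel]
    truth: pd.DataFrame
    ortholog_map: pd.DataFrame | None = None

    @property
    def genotype(self) -> pd.Series:
        return self.samples.set_index("sample")["genotype"]


def _make_exons(rng: np.random.Generator, start: int, total_len: int) -> list[tuple[int, int]]:
    """Split ``total_len`` exonic bases into 1-4 exons separated by introns."""
    k = int(rng.integers(1, 5)) if total_len >= 8 else 1
    if k > 1:
        cuts = np.sort(rng.choice(np.arange(1, total_len), size=k - 1, replace=False))
        lengths = np.diff(np.concatenate(([0], cuts, [total_len])))
    else:
        lengths = np.array([total_len])
    introns = rng.integers(100, 501, size=max(k - 1, 0))
    exons = []
    pos = start
    for i, ln in enumerate(lengths):
        exons.append((int(pos), int(pos + ln)))
        pos += int(ln)
        if i < len(introns):
            pos += int(introns[i])
    return exons


def simulate_counts(cfg: CountSimConfig) -> SimulatedCounts:
    """Simulate negative-binomial counts with copy-proportional dosage.

    Trisomic genes occupy the first ``n_trisomic_genes`` indices and sit on
    chromosome ``chrTri`` (the shared trisomic segment); all other genes sit
    on ``chrDis``.  Deletion segments reset the affected genes to two copies.
    In transchromosomic mode each remaining 3-copy gene keeps two copies on
    its mouse row while the third copy is emitted as a human-tagged row (on
    ``chr21``, same exon-union length) so that expected expression splits
    2:1 between species and the merged expectation stays 1.5x euploid.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    lo, hi = cfg.exon_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)

    copies = np.full(cfg.n_genes, 2, dtype=int)
    copies[: cfg.n_trisomic_genes] = 3
    for s, e in cfg.deletion_segments:
        copies[s:e] = 2
    if cfg.copy_number_map:
        for gid, c in cfg.copy_number_map.items():
            if gid not in gene_ids:
                raise ConfigError(f"copy_number_map references unknown gene {gid}")
            if c not in (2, 3):
                raise ConfigError("copy numbers must be 2 or 3")
            copies[gene_ids.index(gid)] = c

    models: list[GeneModel] = []
    cursors = {"chrTri": 0, "chrDis": 0}
    for i, gid in enumerate(gene_ids):
        chrom = "chrTri" if i < cfg.n_trisomic_genes else "chrDis"
        exons = _make_exons(rng, cursors[chrom], int(lengths[i]))
        cursors[chrom] = exons[-1][1] + 1000
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(gid, chrom, strand, exons, species_tag="mouse"))

    abundance = np.exp(rng.normal(0.0, cfg.abundance_sd, cfg.n_genes))
    weights = abundance * lengths
    base_mu = cfg.library_size * weights / weights.sum()  # euploid expectation at factor 1

    n_t, n_e = cfg.n_trisomic_samples, cfg.n_euploid_samples
    sample_names = [f"{cfg.model_name}_t{i + 1}" for i in range(n_t)] + [
        f"{cfg.model_name}_e{i + 1}" for i in range(n_e)
    ]
    genotypes = ["trisomic"] * n_t + ["euploid"] * n_e
    lib_factors = (
        np.exp(rng.normal(-0.5 * cfg.library_factor_sd**2, cfg.library_factor_sd, n_t + n_e))
        if cfg.library_factor_sd > 0
        else np.ones(n_t + n_e)
    )

    is_tri_sample = np.array([g == "trisomic" for g in genotypes])
    dosage = np.where(is_tri_sample[None, :], copies[:, None] / 2.0, 1.0)

    all_ids = list(gene_ids)
    ortho_rows = []
    if cfg.transchromosomic:
        # mouse rows keep two copies; the third copy becomes a human row
        mouse_dosage = np.ones_like(dosage)
        mu = base_mu[:, None] * mouse_dosage * lib_factors[None, :]
        human_mu_rows = []
        for i, gid in enumerate(gene_ids):
            if copies[i] != 3:
                continue
            hid = f"HSA-{gid}"
            all_ids.append(hid)
            ortho_rows.append({"human_id": hid, "mouse_id": gid})
            hmu = np.where(is_tri_sample, 0.5 * base_mu[i] * lib_factors, 0.0)
            human_mu_rows.append(hmu)
            # human row mirrors the mouse exon structure on chr21
            mm = models[i]
            models.append(GeneModel(hid, "chr21", mm.strand, list(mm.exons), species_tag="human"))
        if human_mu_rows:
            mu = np.vstack([mu, np.vstack(human_mu_rows)])
    else:
        mu = base_mu[:, None] * dosage * lib_factors[None, :]

    if cfg.dispersion == 0:
        counts = np.rint(mu).astype(np.int64)
    else:
        n_param = 1.0 / cfg.dispersion
        p = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p)
        counts = np.where(mu > 0, counts, 0).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=all_ids, columns=sample_names)
    counts_df.index.name = "gene_id"
    samples_df = pd.DataFrame(
        {"sample": sample_names, "genotype": genotypes, "model": cfg.model_name}
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": [m.chromosome for m in models[: cfg.n_genes]],
            "copies": copies,
            "genelen": lengths,
            "base_mean": base_mu,
            "expected_fold_change": copies / 2.0,
        }
    )
    ortho = pd.DataFrame(ortho_rows, columns=["human_id", "mouse_id"]) if ortho_rows else None
    return SimulatedCounts(
        counts=counts_df,
        samples=samples_df,
        gene_models=models,
        truth=truth,
        ortholog_map=ortho,
    )
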