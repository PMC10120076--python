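"""Trisomic gene-dosage expression summaries from RNA-seq count matrices.

A third gene copy is expected to raise expression by 3:2 = 1.5-fold when
expression is copy-proportional.  This module computes everything needed to
describe that dosage response from a genes x samples count matrix:

* exon-union gene lengths (``genelen``) from gene models,
* the length normalization ``len_norm = 50 * readcounts / genelen``,
* cross-species ortholog aggregation for transchromosomic genotypes, where a
  mouse carries a human chromosome and a trisomic gene's reads are split
  between a mouse-ortholog row and a human-transcript row,
* median-of-ratios size factors and per-gene trisomic/euploid fold changes,
* dosage binning (below / central 1.3-1.7 / above), FPKM/TPM, and the
  three-way detection filter used to exclude unexpressed genes.

The high-level entry point is :class:`DosageExperiment`, whose ``fit()``
returns a :class:`DosageResults` carrying the per-gene summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DosageError

logger = logging.getLogger(__name__)

#: multiplier in the length normalization formula len_norm = SCALE * counts / genelen
LENGTH_NORM_SCALE = 50.0

DOSAGE_BINS = ("below", "central", "above", "undetected")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene with its exon intervals (0-based half-open coordinates).

    Parameters
    ----------
    gene_id : str
        Unique gene identifier.
    chromosome : str
        Chromosome name.
    strand : str
        ``"+"`` or ``"-"``.
    exons : list of (int, int)
        Exon intervals, 0-based half-open.  Overlapping or duplicate exons
        (e.g. shared between transcripts) are allowed; lengths are always
        computed on the interval union.
    species_tag : str
        ``"mouse"`` or ``"human"``; used by the ortholog-aggregation path.
    """

    gene_id: str
    chromosome: str
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    species_tag: str = "mouse"

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def genelen(self) -> int:
        """Exon-union length in base pairs."""
        return exon_union_length(self.exons, gene_id=self.gene_id)


def exon_union_length(exons: Sequence[tuple[int, int]], gene_id: str = "?") -> int:
    """Total length of the union of exon intervals, counting overlaps once.

    Implements a merge-sorted sweep over 0-based half-open intervals.

    Raises
    ------
    DosageError
        If the gene has no exons or any interval has ``end <= start``.
    """
    if len(exons) == 0:
        raise DosageError(f"gene {gene_id}: no exons")
    for s, e in exons:
        if e <= s:
            raise DosageError(f"gene {gene_id}: malformed exon interval ({s}, {e})")
    total = 0
    cur_s, cur_e = None, None
    for s, e in sorted(exons):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return total


def gene_lengths(models: Iterable[GeneModel]) -> pd.Series:
    """Exon-union length per gene as a Series indexed by gene_id."""
    data = {m.gene_id: m.genelen for m in models}
    return pd.Series(data, name="genelen", dtype=int)


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------

def length_normalize(readcounts, genelen, scale: float = LENGTH_NORM_SCALE):
    """Length-normalized expression ``scale * readcounts / genelen``.

    With the default ``scale=50`` a gene whose read count equals its
    exon-union length returns exactly 50.  Accepts scalars or aligned arrays.
    """
    genelen_arr = np.asarray(genelen, dtype=float)
    if np.any(genelen_arr <= 0):
        raise DosageError("genelen must be > 0 for length normalization")
    result = scale * np.asarray(readcounts, dtype=float) / genelen_arr
    if np.ndim(readcounts) == 0 and np.ndim(genelen) == 0:
        return float(result)
    return result


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    For every gene with nonzero counts in all samples, each sample's
    count is divided by the gene's geometric mean across samples; the
    sample's factor is the median of those ratios.  Multiplying one
    sample's counts by ``c`` multiplies its factor by ``c``.

    Raises
    ------
    DosageError
        If no gene has nonzero counts in every sample.
    """
    values = counts.to_numpy(dtype=float)
    mask = (values > 0).all(axis=1)
    if not mask.any():
        raise DosageError("no gene with nonzero counts in all samples; cannot compute size factors")
    logv = np.log(values[mask])
    geomean = np.exp(logv.mean(axis=1, keepdims=True))
    ratios = values[mask] / geomean
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def fpkm(readcounts, genelen, total_mapped):
    """Fragments per kilobase of exon per million mapped reads."""
    if np.any(np.asarray(total_mapped) <= 0):
        raise DosageError("total_mapped must be > 0 for FPKM")
    genelen_arr = np.asarray(genelen, dtype=float)
    if np.any(genelen_arr <= 0):
        raise DosageError("genelen must be > 0 for FPKM")
    result = 1e9 * np.asarray(readcounts, dtype=float) / (genelen_arr * np.asarray(total_mapped, dtype=float))
    if np.ndim(result) == 0:
        return float(result)
    return result


def tpm(readcounts, genelen):
    """Transcripts per million over a gene set; sums to 1e6 by construction."""
    rc = np.asarray(readcounts, dtype=float)
    gl = np.asarray(genelen, dtype=float)
    if np.any(gl <= 0):
        raise DosageError("genelen must be > 0 for TPM")
    rates = rc / gl
    total = rates.sum()
    if total <= 0:
        raise DosageError("zero total rate; TPM undefined")
    return rates / total * 1e6


# ---------------------------------------------------------------------------
# ortholog aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregationResult:
    """Outcome of cross-species ortholog aggregation.

    Attributes
    ----------
    merged : DataFrame
        Length-normalized genes x samples matrix after adding each mapped
        human row onto its mouse-ortholog row (human rows removed).
    unmapped_human : list of str
        Human genes present in the matrix without a mouse partner; they are
        excluded from the merged matrix and from fold-change profiles.
    human_fraction : DataFrame
        Per mouse gene and sample, the fraction of the merged
        length-normalized signal derived from the human chromosome.
    """

    merged: pd.DataFrame
    unmapped_human: list[str]
    human_fraction: pd.DataFrame


def aggregate_orthologs(
    counts: pd.DataFrame,
    lengths: pd.Series | Mapping[str, int],
    ortholog_map: pd.DataFrame,
    species: pd.Series | Mapping[str, str],
    scale: float = LENGTH_NORM_SCALE,
) -> AggregationResult:
    """Length-normalize counts and sum human rows onto mouse-ortholog rows.

    ``ortholog_map`` needs columns ``human_id`` and ``mouse_id`` with at
    most one mouse partner per human gene.  Signal is conserved exactly:
    each merged row equals the sum of its species inputs.
    """
    lengths = pd.Series(dict(lengths)) if not isinstance(lengths, pd.Series) else lengths
    species = pd.Series(dict(species)) if not isinstance(species, pd.Series) else species
    missing_cols = {"human_id", "mouse_id"} - set(ortholog_map.columns)
    if missing_cols:
        raise DosageError(f"ortholog map missing columns: {sorted(missing_cols)}")
    if ortholog_map["human_id"].duplicated().any():
        raise DosageError("ortholog map assigns more than one mouse partner to a human gene")

    missing_len = [g for g in counts.index if g not in lengths.index]
    if missing_len:
        raise DosageError(f"genes with counts but no length: {missing_len[:5]}")

    lennorm = counts.div(lengths.reindex(counts.index), axis=0) * scale
    human_genes = [g for g in counts.index if species.get(g, "mouse") == "human"]
    partner = dict(zip(ortholog_map["human_id"], ortholog_map["mouse_id"]))

    merged = lennorm.drop(index=human_genes)
    human_contrib = pd.DataFrame(0.0, index=merged.index, columns=merged.columns)
    unmapped = []
    for h in human_genes:
        m = partner.get(h)
        if m is None or m not in merged.index:
            unmapped.append(h)
            logger.warning("human gene %s has no mouse ortholog row; excluded from profiles", h)
            continue
        merged.loc[m] = merged.loc[m] + lennorm.loc[h]
        human_contrib.loc[m] = human_contrib.loc[m] + lennorm.loc[h]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (human_contrib / merged).fillna(0.0)
    return AggregationResult(merged=merged, unmapped_human=unmapped, human_fraction=frac)


# ---------------------------------------------------------------------------
# fold changes and binning
# ---------------------------------------------------------------------------

def detectable(counts: pd.DataFrame, genotype: pd.Series, min_fraction: float = 0.5) -> pd.Series:
    """Detection flag: nonzero count in at least ``min_fraction`` of the
    samples of either genotype (the default reads 'half the samples')."""
    flags = pd.Series(False, index=counts.index)
    for _, cols in _genotype_columns(counts, genotype).items():
        sub = counts[cols]
        need = int(np.ceil(min_fraction * len(cols)))
        flags |= (sub > 0).sum(axis=1) >= max(need, 1)
    return flags


def _genotype_columns(counts: pd.DataFrame, genotype: pd.Series) -> dict[str, list]:
    genotype = genotype.reindex(counts.columns)
    if genotype.isna().any():
        raise DosageError("genotype missing for some samples")
    out: dict[str, list] = {}
    for g in ("trisomic", "euploid"):
        cols = [c for c in counts.columns if genotype[c] == g]
        if not cols:
            raise DosageError(f"no samples with genotype '{g}'")
        out[g] = cols
    return out


def fold_changes(
    normalized: pd.DataFrame,
    genotype: pd.Series,
    trisomic_genes: Iterable[str] | None = None,
    detected: pd.Series | None = None,
    pseudocount: float = 0.5,
    bin_lo: float = 1.3,
    bin_hi: float = 1.7,
) -> pd.DataFrame:
    """Per-gene trisomic/euploid fold change on a normalized matrix.

    The statistic is the ratio of genotype means of normalized counts.  A
    pseudocount is added to BOTH group means only when the euploid mean is
    zero but the gene passes detection, so typical genes are exact and no
    division by zero can occur.  Genes failing detection get fold change NaN
    and bin ``undetected``.

    Returns a DataFrame with columns ``mean_trisomic``, ``mean_euploid``,
    ``fold_change``, ``trisomic``, ``detected``, ``dosage_bin`` and
    ``mean_normalized_count``.
    """
    cols = _genotype_columns(normalized, genotype)
    mean_t = normalized[cols["trisomic"]].mean(axis=1)
    mean_e = normalized[cols["euploid"]].mean(axis=1)
    if detected is None:
        detected = detectable(normalized, genotype)
    detected = detected.reindex(normalized.index).fillna(False).astype(bool)

    fc = pd.Series(np.nan, index=normalized.index)
    plain = detected & (mean_e > 0)
    fc[plain] = mean_t[plain] / mean_e[plain]
    rescued = detected & (mean_e == 0)
    if rescued.any():
        logger.info("pseudocount applied to %d genes with all-zero euploid mean", int(rescued.sum()))
        fc[rescued] = (mean_t[rescued] + pseudocount) / (mean_e[rescued] + pseudocount)

    trisomic_set = set(trisomic_genes) if trisomic_genes is not None else set()
    out = pd.DataFrame(
        {
            "mean_trisomic": mean_t,
            "mean_euploid": mean_e,
            "fold_change": fc,
            "trisomic": [g in trisomic_set for g in normalized.index],
            "detected": detected,
            "mean_normalized_count": normalized.mean(axis=1),
        }
    )
    out["dosage_bin"] = assign_bins(out["fold_change"], lo=bin_lo, hi=bin_hi)
    out.index.name = "gene_id"
    return out


def assign_bins(fold_change: pd.Series, lo: float = 1.3, hi: float = 1.7) -> pd.Series:
    """Dosage bin per gene; the central bin is closed on both ends: [lo, hi]."""
    if lo >= hi:
        raise DosageError(f"bin bounds must satisfy lo < hi (got {lo}, {hi})")
    fc = fold_change.astype(float)
    bins = pd.Series("undetected", index=fc.index, dtype=object)
    bins[fc < lo] = "below"
    bins[(fc >= lo) & (fc <= hi)] = "central"
    bins[fc > hi] = "above"
    return bins


def dosage_bins(summary: pd.DataFrame | pd.Series, lo: float = 1.3, hi: float = 1.7) -> pd.Series:
    """Bin counts over a DosageSummary table (or a fold-change Series)."""
    if isinstance(summary, pd.DataFrame):
        fc = summary["fold_change"]
    else:
        fc = summary
    bins = assign_bins(fc, lo=lo, hi=hi)
    counts = bins.value_counts()
    return counts.reindex(DOSAGE_BINS, fill_value=0).astype(int)


def detection_filter(
    evidence: pd.DataFrame,
    fpkm_cut: float = 1.0,
    tpm_cut: float = 1.0,
) -> list[str]:
    """Genes failing ALL THREE lines of expression evidence.

    A gene is excluded iff it was not detected in the RNA-seq data AND every
    supplied FPKM value is below ``fpkm_cut`` AND every supplied TPM value is
    below ``tpm_cut`` (conjunction: a single piece of evidence rescues the
    gene).  ``evidence`` is indexed by gene with columns
    ``detected_in_rnaseq`` (bool) and ``fpkm_values`` / ``tpm_values``
    (list-valued cells); an empty evidence list cannot rescue a gene.
    """
    required = {"detected_in_rnaseq", "fpkm_values", "tpm_values"}
    missing = required - set(evidence.columns)
    if missing:
        raise DosageError(f"evidence table missing columns: {sorted(missing)}")
    excluded = []
    for gene, row in evidence.iterrows():
        if bool(row["detected_in_rnaseq"]):
            continue
        if any(v >= fpkm_cut for v in row["fpkm_values"]):
            continue
        if any(v >= tpm_cut for v in row["tpm_values"]):
            continue
        excluded.append(gene)
    return excluded


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class DosageExperiment:
    """Trisomic vs euploid dosage-expression analysis of a count matrix.

    Parameters
    ----------
    counts : DataFrame
        Raw genes x samples counts.
    samples : DataFrame
        Sample metadata with a ``genotype`` column (``trisomic``/``euploid``),
        indexed by (or containing a ``sample`` column matching) the count
        matrix columns.
    gene_models : iterable of GeneModel, optional
        Needed for the transchromosomic (length-normalized, ortholog-merged)
        path; ``gene_lengths`` may be given directly instead.
    ortholog_map : DataFrame, optional
        ``human_id``/``mouse_id`` pairs for the transchromosomic path.
    trisomic_genes : iterable of str, optional
        Genes carried at three copies; used for the trisomic flag and the
        group mean/SD fold-change summary.
    transchromosomic : bool
        If True, counts are length-normalized and human rows are merged onto
        mouse orthologs before size-factor normalization.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        gene_models: Iterable[GeneModel] | None = None,
        gene_lengths_: pd.Series | None = None,
        ortholog_map: pd.DataFrame | None = None,
        trisomic_genes: Iterable[str] | None = None,
        transchromosomic: bool = False,
    ):
        if "sample" in samples.columns:
            samples = samples.set_index("sample")
        if (counts.to_numpy() < 0).any():
            raise DosageError("counts must be nonnegative")
        self.counts = counts
        self.samples = samples
        self.genotype = samples["genotype"]
        self.gene_models = list(gene_models) if gene_models is not None else None
        if gene_lengths_ is not None:
            self.lengths = gene_lengths_
        elif self.gene_models is not None:
            self.lengths = gene_lengths(self.gene_models)
        else:
            self.lengths = None
        self.species = (
            pd.Series({m.gene_id: m.species_tag for m in self.gene_models})
            if self.gene_models is not None
            else None
        )
        self.ortholog_map = ortholog_map
        self.trisomic_genes = list(trisomic_genes) if trisomic_genes is not None else []
        self.transchromosomic = transchromosomic
        if transchromosomic and (self.lengths is None or ortholog_map is None):
            raise DosageError("transchromosomic mode requires gene lengths and an ortholog map")

    @classmethod
    def from_simulation(cls, sim, transchromosomic: bool | None = None) -> "DosageExperiment":
        """Build directly from a :class:`shhscreen.simulate.SimulatedCounts`."""
        trans = sim.ortholog_map is not None and len(sim.ortholog_map) > 0
        if transchromosomic is not None:
            trans = transchromosomic
        trisomic = sim.truth.loc[sim.truth["copies"] == 3, "gene_id"].tolist()
        return cls(
            counts=sim.counts,
            samples=sim.samples,
            gene_models=sim.gene_models,
            ortholog_map=sim.ortholog_map if trans else None,
            trisomic_genes=trisomic,
            transchromosomic=trans,
        )

    def fit(
        self,
        pseudocount: float = 0.5,
        bin_lo: float = 1.3,
        bin_hi: float = 1.7,
        size_factor_genes: str = "disomic",
    ) -> "DosageResults":
        """Run normalization and fold-change computation; return results.

        ``size_factor_genes="disomic"`` (default) estimates size factors on
        the genes outside the known trisomic set: with a sizable fraction of
        genes dosage-shifted in one direction, median-of-ratios factors
        computed over all genes absorb part of the trisomy signal and bias
        fold changes toward 1.  Falls back to all genes when the trisomic
        set is unknown; pass ``"all"`` to force the plain estimator.
        """
        if size_factor_genes not in ("disomic", "all"):
            raise DosageError("size_factor_genes must be 'disomic' or 'all'")
        aggregation = None
        if self.transchromosomic:
            aggregation = aggregate_orthologs(
                self.counts, self.lengths, self.ortholog_map, self.species
            )
            work = aggregation.merged
        else:
            work = self.counts.astype(float)
        trisomic_set = set(self.trisomic_genes)
        reference = [g for g in work.index if g not in trisomic_set]
        if size_factor_genes == "disomic" and trisomic_set and reference:
            factors = size_factors(work.loc[reference])
        else:
            factors = size_factors(work)
        normalized = work.div(factors, axis=1)
        detected = detectable(work, self.genotype)
        summaries = fold_changes(
            normalized,
            self.genotype,
            trisomic_genes=self.trisomic_genes,
            detected=detected,
            pseudocount=pseudocount,
            bin_lo=bin_lo,
            bin_hi=bin_hi,
        )
        return DosageResults(
            model=self,
            summaries=summaries,
            size_factors_=factors,
            aggregation=aggregation,
            bin_lo=bin_lo,
            bin_hi=bin_hi,
        )


class DosageResults:
    """Fold-change summaries from a :class:`DosageExperiment` fit."""

    def __init__(self, model, summaries, size_factors_, aggregation, bin_lo, bin_hi):
        self.model = model
        self.summaries = summaries
        self.size_factors = size_factors_
        self.aggregation = aggregation
        self.bin_lo = bin_lo
        self.bin_hi = bin_hi

    @property
    def trisomic_summaries(self) -> pd.DataFrame:
        return self.summaries[self.summaries["trisomic"]]

    @property
    def mean_trisomic_fold_change(self) -> float:
        """Mean fold change over detected trisomic genes."""
        fc = self.trisomic_summaries["fold_change"].dropna()
        return float(fc.mean())

    @property
    def sd_trisomic_fold_change(self) -> float:
        fc = self.trisomic_summaries["fold_change"].dropna()
        return float(fc.std(ddof=1))

    @property
    def bin_counts(self) -> pd.Series:
        """Dosage-bin counts over trisomic genes."""
        return dosage_bins(self.trisomic_summaries, lo=self.bin_lo, hi=self.bin_hi)

    def summary(self) -> str:
        n = len(self.summaries)
        bins = self.bin_counts
        lines = [
            "Dosage expression summary",
            "=" * 60,
            f"genes: {n}   trisomic: {len(self.trisomic_summaries)}   "
            f"detected: {int(self.summaries['detected'].sum())}",
            f"mean trisomic fold change: {self.mean_trisomic_fold_change:.3f} "
            f"+/- {self.sd_trisomic_fold_change:.3f} (s.d.)",
            f"trisomic bins  <{self.bin_lo}: {bins['below']}   "
            f"[{self.bin_lo}-{self.bin_hi}]: {bins['central']}   "
            f">{self.bin_hi}: {bins['above']}   undetected: {bins['undetected']}",
        ]
        if self.aggregation is not None:
            lines.append(f"unmapped human genes: {len(self.aggregation.unmapped_human)}")
        return "\n".join(lines)

    def plot_density(self, ax=None):
        """Density of fold changes, trisomic vs disomic genes (Gaussian KDE)."""
        import matplotlib.pyplot as plt
        from scipy.stats import gaussian_kde

        if ax is None:
            _, ax = plt.subplots()
        for label, mask in (("disomic", ~self.summaries["trisomic"]),
                            ("trisomic", self.summaries["trisomic"])):
            fc = self.summaries.loc[mask, "fold_change"].dropna()
            if len(fc) > 1:
                grid = np.linspace(0, max(3.0, fc.quantile(0.99)), 200)
                ax.plot(grid, gaussian_kde(fc)(grid), label=label)
        ax.set_xlabel("fold change")
        ax.set_ylabel("density")
        ax.legend()
        return ax

    def to_tsv(self, path) -> None:
        self.summaries.reset_index().to_csv(path, sep="\t", index=False)
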