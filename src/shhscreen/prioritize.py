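"""Integration of screen z-scores, expression evidence and mouse-model
trisomy into a ranked candidate table.

A candidate dosage-sensitive gene should (i) show a consistent direction of
effect across the reporter and differentiation screens, (ii) survive the
expression detection filter, and (iii) be trisomic in the mouse models that
show the phenotype.  ``integrate_screens`` averages per-screen z-scores,
``map_to_models`` resolves trisomic-segment membership (0-based half-open
intervals, deletions excluded), and ``rank_candidates`` produces the final
ordering with documented tie-breaking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import PrioritizeError

logger = logging.getLogger(__name__)


@dataclass
class ModelSegments:
    """Trisomic-segment definition for one mouse model.

    ``segments`` and ``deletions`` are (chromosome, start, end) intervals,
    0-based half-open; deletions must nest inside a segment.  ``gene_ids``
    optionally lists explicit members (used for genes without coordinates).
    """

    name: str
    segments: list[tuple[str, int, int]] = field(default_factory=list)
    deletions: list[tuple[str, int, int]] = field(default_factory=list)
    gene_ids: set[str] = field(default_factory=set)

    def __post_init__(self):
        for chrom, s, e in self.segments + self.deletions:
            if e <= s:
                raise PrioritizeError(f"model {self.name}: malformed interval ({chrom},{s},{e})")
        for d in self.deletions:
            if not any(
                d[0] == seg[0] and seg[1] <= d[1] and d[2] <= seg[2] for seg in self.segments
            ):
                raise PrioritizeError(
                    f"model {self.name}: deletion {d} not nested within a segment"
                )

    def contains(self, chromosome: str, pos: int) -> bool:
        """Trisomic iff the position falls in a segment and not a deletion."""
        in_seg = any(c == chromosome and s <= pos < e for c, s, e in self.segments)
        if not in_seg:
            return False
        in_del = any(c == chromosome and s <= pos < e for c, s, e in self.deletions)
        return not in_del

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSegments":
        return cls(
            name=d["name"],
            segments=[tuple(x) for x in d.get("segments", [])],
            deletions=[tuple(x) for x in d.get("deletions", [])],
            gene_ids=set(d.get("gene_ids", [])),
        )


def load_model_segments(path) -> list[ModelSegments]:
    """Read model definitions from a YAML/JSON file (list of mappings)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [ModelSegments.from_dict(d) for d in data]


def integrate_screens(
    z_tables: Mapping[str, pd.DataFrame],
    weak_z: float = 1.0,
    impute_zero: bool = False,
) -> pd.DataFrame:
    """Average per-screen z-scores into candidate skeletons.

    Parameters
    ----------
    z_tables : mapping screen name -> DataFrame
        Each indexed by cdna with a ``z`` column (a ScreenResults.scores
        table works directly).
    weak_z : float
        Direction is ``mixed`` when per-screen signs disagree and
        |average z| < weak_z.
    impute_zero : bool
        If True, genes unscored in a screen contribute z=0 there; by
        default the average runs over the screens in which the gene was
        scored.

    Returns
    -------
    DataFrame indexed by cdna with one ``z_<screen>`` column per screen,
    ``n_screens``, ``average_z`` and ``direction``.
    """
    if not z_tables:
        raise PrioritizeError("need at least one screen table")
    zcols = {}
    for name, tab in z_tables.items():
        if "z" not in tab.columns:
            raise PrioritizeError(f"screen '{name}' table lacks a z column")
        zcols[f"z_{name}"] = tab["z"]
    wide = pd.DataFrame(zcols)
    if wide.empty:
        raise PrioritizeError("empty union of screen gene universes")
    if wide.notna().sum(axis=1).eq(0).any():
        raise PrioritizeError("gene present with no finite z in any screen")
    if impute_zero:
        wide = wide.fillna(0.0)
    wide["n_screens"] = wide.filter(like="z_").notna().sum(axis=1)
    zmat = wide.filter(like="z_")
    wide["average_z"] = zmat.mean(axis=1)

    signs = np.sign(zmat)
    disagree = (signs.max(axis=1) > 0) & (signs.min(axis=1) < 0)
    direction = np.where(wide["average_z"] > 0, "activator",
                         np.where(wide["average_z"] < 0, "inhibitor", "mixed"))
    direction = np.where(disagree & (wide["average_z"].abs() < weak_z), "mixed", direction)
    wide["direction"] = direction
    wide.index.name = "cdna"
    return wide


def map_to_models(
    positions: pd.DataFrame,
    models: Iterable[ModelSegments],
    membership: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Per-model trisomy flags for each gene.

    ``positions`` is indexed by gene with ``chromosome`` and ``pos``
    columns (use the gene start).  Genes missing from ``positions`` must be
    covered by ``membership`` (gene -> model names) or by the model's
    explicit ``gene_ids``; otherwise an error lists them.  Deterministic
    and independent of input order.
    """
    models = list(models)
    membership = {k: set(v) for k, v in (membership or {}).items()}
    all_genes = list(positions.index) + [g for g in membership if g not in positions.index]
    missing = [
        g for g in membership
        if g not in positions.index and not membership[g]
    ]
    if missing:
        raise PrioritizeError(f"genes with neither position nor membership: {missing}")
    out = pd.DataFrame(index=pd.Index(sorted(set(all_genes)), name="gene_id"))
    for m in models:
        flags = []
        for g in out.index:
            if g in membership:
                flags.append(m.name in membership[g])
            elif g in m.gene_ids:
                flags.append(True)
            elif g in positions.index:
                row = positions.loc[g]
                flags.append(m.contains(str(row["chromosome"]), int(row["pos"])))
            else:
                raise PrioritizeError(f"gene {g} has neither position nor membership entry")
        out[f"trisomic_in_{m.name}"] = flags
    return out


def rank_candidates(
    report: pd.DataFrame,
    mode: str = "inhibitors",
) -> pd.DataFrame:
    """Rank expression-retained candidates by average z-score.

    Inhibitor mode sorts ascending (most negative average z first);
    activator mode descending.  Ties on average z are broken by the number
    of screens scored (more first), then lexicographic gene id.  Genes with
    ``expression_retained == False`` are absent from the ranked table (they
    remain in the input for auditing).
    """
    if mode not in ("inhibitors", "activators"):
        raise PrioritizeError(f"unknown mode '{mode}'")
    for col in ("average_z", "n_screens", "expression_retained"):
        if col not in report.columns:
            raise PrioritizeError(f"candidate report lacks column '{col}'")
    retained = report[report["expression_retained"]].copy()
    ascending = mode == "inhibitors"
    retained = (
        retained.rename_axis("cdna")
        .reset_index()
        .sort_values(
            by=["average_z", "n_screens", "cdna"],
            ascending=[ascending, False, True],
            kind="mergesort",
        )
        .set_index("cdna")
    )
    retained["rank"] = np.arange(1, len(retained) + 1)
    return retained


def build_candidate_report(
    z_tables: Mapping[str, pd.DataFrame],
    positions: pd.DataFrame | None = None,
    models: Iterable[ModelSegments] = (),
    excluded_genes: Iterable[str] = (),
    concordance: pd.DataFrame | None = None,
    weak_z: float = 1.0,
    impute_zero: bool = False,
) -> pd.DataFrame:
    """Assemble the full candidate table: averaged z-scores, concordance
    class, expression retention and per-model trisomy flags."""
    report = integrate_screens(z_tables, weak_z=weak_z, impute_zero=impute_zero)
    excluded = set(excluded_genes)
    report["expression_retained"] = [g not in excluded for g in report.index]
    if concordance is not None:
        report = report.join(concordance["class"].rename("concordance_class"))
    models = list(models)
    if models:
        if positions is None:
            raise PrioritizeError("model mapping requires gene positions")
        pos = positions.reindex(report.index).dropna(subset=["chromosome", "pos"])
        unknown = report.index.difference(pos.index)
        covered = {g for m in models for g in m.gene_ids}
        hard_missing = [g for g in unknown if g not in covered]
        if hard_missing:
            logger.warning("genes without coordinates or membership: %s", hard_missing[:5])
        flags = map_to_models(pos, models)
        report = report.join(flags)
        for m in models:
            col = f"trisomic_in_{m.name}"
            for g in unknown:
                report.loc[g, col] = g in m.gene_ids
            report[col] = report[col].fillna(False).astype(bool)
    return report
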