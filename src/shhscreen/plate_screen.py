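"""Dual-luciferase overexpression screen scoring.

The screen's raw signal is the ratio of pathway-responsive firefly
luciferase (Fluc) to constitutive Renilla luciferase (Rluc) in each well.
Scoring proceeds in four steps, each exposed as a function:

1. :func:`median_center_plate` — divide every well by its plate median
   (intra-plate median centering), removing plate-level scale and buffering
   spatial artifacts and outliers;
2. :func:`aggregate_replicates` — pooled arithmetic mean of normalized
   values per cDNA across wells and plates;
3. :func:`zscore_screen` — standardize each cDNA's activity against the set
   of all screened cDNAs (controls excluded), giving z-scores and centered
   deflections;
4. :func:`call_hits` — threshold at |z| >= 2 (strong, boundary inclusive)
   with a weak flag at |z| >= 1 used by the two-screen concordance rule.

:func:`cross_screen_concordance` classifies direction agreement between two
screens.  :class:`LuciferaseScreen` wraps the steps as a model object whose
``fit()`` returns :class:`ScreenResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PlateError, ScreenError

logger = logging.getLogger(__name__)

HIT_CLASSES = ("activator", "inhibitor", "none")


@dataclass
class ScreenThresholds:
    """Hit-calling thresholds in z-score units.

    ``strong_z`` calls hits in a single screen (default 2, i.e. z <= -2 or
    z >= 2); ``weak_z`` feeds the two-screen rule (default 1).
    """

    strong_z: float = 2.0
    weak_z: float = 1.0

    def validate(self) -> None:
        if not (self.strong_z >= self.weak_z > 0):
            raise ScreenError(
                f"thresholds must satisfy strong_z >= weak_z > 0 "
                f"(got {self.strong_z}, {self.weak_z})"
            )


def compute_ratio(wells: pd.DataFrame, drop_bad: bool = True) -> pd.DataFrame:
    """Attach the Fluc/Rluc ratio; drop (with a logged count) wells whose
    Rluc is missing, zero or negative rather than imputing them."""
    wells = wells.copy()
    bad = ~np.isfinite(wells["rluc"]) | (wells["rluc"] <= 0) | ~np.isfinite(wells["fluc"])
    if bad.any():
        if not drop_bad:
            raise PlateError(f"{int(bad.sum())} wells with invalid Rluc/Fluc")
        logger.warning("dropping %d wells with invalid Rluc/Fluc", int(bad.sum()))
        wells = wells[~bad]
    wells["ratio"] = wells["fluc"] / wells["rluc"]
    return wells


def median_center_plate(wells: pd.DataFrame, value_col: str = "ratio") -> pd.DataFrame:
    """Divide one plate's values by the plate median.

    All rows must share one ``plate`` id.  After centering the plate median
    of the ``normalized`` column is 1, which makes every downstream score
    invariant to rescaling the whole plate.
    """
    plates = wells["plate"].unique()
    if len(plates) != 1:
        raise PlateError(f"median_center_plate expects one plate, got {list(plates)}")
    values = wells[value_col].to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise PlateError(f"plate {plates[0]}: no finite values")
    med = float(np.median(finite))
    if not np.isfinite(med) or med == 0:
        raise PlateError(f"plate {plates[0]}: plate median is {med}; cannot normalize")
    out = wells.copy()
    out["normalized"] = values / med
    return out


def median_center(wells: pd.DataFrame, value_col: str = "ratio") -> pd.DataFrame:
    """Apply :func:`median_center_plate` plate by plate."""
    parts = [
        median_center_plate(group, value_col=value_col)
        for _, group in wells.groupby("plate", sort=False)
    ]
    return pd.concat(parts, axis=0)


def aggregate_replicates(
    wells: pd.DataFrame, min_wells: int = 8
) -> tuple[pd.Series, pd.DataFrame]:
    """Pooled mean of plate-normalized values per cDNA.

    Wells are pooled across plates (and treatment arms) before averaging.
    cDNAs with fewer than ``min_wells`` wells are excluded from scoring and
    returned in the flagged table.

    Returns
    -------
    activities : Series
        Mean normalized activity per cDNA (index cdna).
    excluded : DataFrame
        cDNAs below ``min_wells`` with their well counts.
    """
    grouped = wells.groupby("cdna")["normalized"]
    activities = grouped.mean()
    counts = grouped.size()
    low = counts[counts < min_wells]
    if len(low) > 0:
        logger.warning("excluding %d cDNAs with fewer than %d wells", len(low), min_wells)
    excluded = pd.DataFrame({"cdna": low.index, "n_wells": low.values, "reason": "below_min_wells"})
    activities = activities[counts >= min_wells]
    activities.name = "normalized_activity"
    return activities, excluded


def zscore_screen(
    activities: pd.Series,
    controls: tuple[str, ...] | list[str] = (),
    n_wells: pd.Series | None = None,
) -> pd.DataFrame:
    """Standardize per-cDNA activities against the screened cDNA set.

    Controls are excluded from both the set defining the mean/SD and the
    scored table (they serve QC only).  The SD is the sample SD (ddof=1);
    the deflection is the activity centered to the cDNA-set mean, so
    sign(deflection) == sign(z).

    Raises
    ------
    ScreenError
        With fewer than 3 scored cDNAs or a zero SD (degenerate screen).
    """
    scored = activities.drop(index=[c for c in controls if c in activities.index])
    if len(scored) < 3:
        raise ScreenError(f"need >= 3 screened cDNAs, got {len(scored)}")
    mean = float(scored.mean())
    sd = float(scored.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ScreenError("degenerate screen: zero variance across cDNA activities")
    deflection = scored - mean
    z = deflection / sd
    out = pd.DataFrame(
        {
            "cdna": scored.index,
            "normalized_activity": scored.values,
            "deflection": deflection.values,
            "z": z.values,
        }
    ).set_index("cdna")
    if n_wells is not None:
        out.insert(0, "n_wells", n_wells.reindex(out.index).astype(int))
    return out


def call_hits(scores: pd.DataFrame, thresholds: ScreenThresholds | None = None) -> pd.DataFrame:
    """Attach ``hit_class`` (activator / inhibitor / none, boundaries
    inclusive) and the ``weak_hit`` flag at |z| >= weak_z."""
    t = thresholds or ScreenThresholds()
    t.validate()
    out = scores.copy()
    z = out["z"]
    out["hit_class"] = np.select(
        [z >= t.strong_z, z <= -t.strong_z], ["activator", "inhibitor"], default="none"
    )
    out["weak_hit"] = z.abs() >= t.weak_z
    return out


def cross_screen_concordance(
    scores1: pd.DataFrame,
    scores2: pd.DataFrame,
    thresholds: ScreenThresholds | None = None,
) -> pd.DataFrame:
    """Classify direction agreement between two screens.

    The union hit set contains cDNAs that are strong hits (|z| >= strong_z)
    in either screen plus cDNAs with |z| >= weak_z in both.  Members are
    classified ``concordant_inhibitor`` / ``concordant_activator`` when the
    z signs agree, ``discordant`` when nonzero and opposite; everything
    else (including cDNAs scored in only one screen, which are warned
    about) is ``not_called``.
    """
    t = thresholds or ScreenThresholds()
    t.validate()
    universe = scores1.index.union(scores2.index)
    only = universe.difference(scores1.index.intersection(scores2.index))
    if len(only) > 0:
        logger.warning("%d cDNAs present in only one screen; marked not_called", len(only))
    records = []
    for cdna in universe:
        z1 = scores1["z"].get(cdna, np.nan)
        z2 = scores2["z"].get(cdna, np.nan)
        s1 = int(np.sign(z1)) if np.isfinite(z1) else 0
        s2 = int(np.sign(z2)) if np.isfinite(z2) else 0
        in_both = np.isfinite(z1) and np.isfinite(z2)
        strong = in_both and (abs(z1) >= t.strong_z or abs(z2) >= t.strong_z)
        weak_both = in_both and abs(z1) >= t.weak_z and abs(z2) >= t.weak_z
        if not in_both or not (strong or weak_both) or s1 == 0 or s2 == 0:
            cls = "not_called"
        elif s1 == s2:
            cls = "concordant_inhibitor" if s1 < 0 else "concordant_activator"
        else:
            cls = "discordant"
        records.append(
            {"cdna": cdna, "z_screen1": z1, "z_screen2": z2,
             "sign_screen1": s1, "sign_screen2": s2, "class": cls}
        )
    return pd.DataFrame(records).set_index("cdna")


def score_screen_values(
    wells: pd.DataFrame,
    value_col: str,
    control: str = "GFP",
    min_wells: int = 8,
    thresholds: ScreenThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-center / aggregate / z-score any single-channel plate readout.

    Used for the dual-luciferase ratio and, identically, for the alkaline-
    phosphatase differentiation screen's contribution to the integrated
    z-score average.  Returns (scores, excluded).
    """
    normalized = median_center(wells, value_col=value_col)
    activities, excluded = aggregate_replicates(normalized, min_wells=min_wells)
    n_wells = normalized.groupby("cdna").size()
    scores = zscore_screen(activities, controls=(control,), n_wells=n_wells)
    scores = call_hits(scores, thresholds)
    return scores, excluded


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class LuciferaseScreen:
    """A dual-luciferase screen ready to score.

    Parameters
    ----------
    wells : DataFrame
        Long-format well table with columns plate, row, col, cdna,
        treatment, fluc, rluc (the simulator's output format).
    control : str
        Control cDNA label (used for QC, excluded from z computation).
    min_wells : int
        Minimum technical replicates per cDNA (default 8).
    name : str
        Screen name used in reports.
    """

    REQUIRED = ("plate", "cdna", "fluc", "rluc")

    def __init__(
        self,
        wells: pd.DataFrame,
        control: str = "GFP",
        min_wells: int = 8,
        name: str = "screen",
    ):
        missing = [c for c in self.REQUIRED if c not in wells.columns]
        if missing:
            raise ScreenError(f"well table missing columns: {missing}")
        self.n_input_wells = len(wells)
        self.wells = compute_ratio(wells)
        self.n_dropped = self.n_input_wells - len(self.wells)
        self.control = control
        self.min_wells = min_wells
        self.name = name

    @classmethod
    def from_csv(cls, path, **kwargs) -> "LuciferaseScreen":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, thresholds: ScreenThresholds | None = None) -> "ScreenResults":
        """Normalize, aggregate, z-score and call hits."""
        t = thresholds or ScreenThresholds()
        t.validate()
        normalized = median_center(self.wells)
        activities, excluded = aggregate_replicates(normalized, min_wells=self.min_wells)
        n_wells = normalized.groupby("cdna").size()
        scores = call_hits(
            zscore_screen(activities, controls=(self.control,), n_wells=n_wells), t
        )
        control_activity = (
            float(activities[self.control]) if self.control in activities.index else np.nan
        )
        return ScreenResults(
            model=self,
            scores=scores,
            excluded=excluded,
            thresholds=t,
            control_activity=control_activity,
            n_dropped_wells=self.n_dropped,
        )


class ScreenResults:
    """Per-cDNA scores and hit calls from a :class:`LuciferaseScreen` fit."""

    def __init__(self, model, scores, excluded, thresholds, control_activity, n_dropped_wells):
        self.model = model
        self.scores = scores
        self.excluded = excluded
        self.thresholds = thresholds
        self.control_activity = control_activity
        self.n_dropped_wells = n_dropped_wells

    @property
    def hits(self) -> pd.DataFrame:
        return self.scores[self.scores["hit_class"] != "none"]

    @property
    def activators(self) -> list[str]:
        return self.scores.index[self.scores["hit_class"] == "activator"].tolist()

    @property
    def inhibitors(self) -> list[str]:
        return self.scores.index[self.scores["hit_class"] == "inhibitor"].tolist()

    def summary(self) -> str:
        s = self.scores
        lines = [
            f"Screen: {self.model.name}",
            "=" * 60,
            f"cDNAs scored: {len(s)}   wells dropped: {self.n_dropped_wells}   "
            f"excluded (< {self.model.min_wells} wells): {len(self.excluded)}",
            f"control ({self.model.control}) normalized activity: {self.control_activity:.3f}",
            f"strong hits (|z| >= {self.thresholds.strong_z:g}): "
            f"{len(self.activators)} activators, {len(self.inhibitors)} inhibitors",
        ]
        top = s.reindex(s["z"].abs().sort_values(ascending=False).index).head(10)
        lines.append("")
        lines.append(f"{'cdna':<12}{'n':>4}{'activity':>10}{'z':>8}  hit")
        for cdna, row in top.iterrows():
            lines.append(
                f"{cdna:<12}{int(row.get('n_wells', 0)):>4}"
                f"{row['normalized_activity']:>10.3f}{row['z']:>8.2f}  {row['hit_class']}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cols = ["n_wells", "normalized_activity", "deflection", "z", "hit_class", "weak_hit"]
        out = self.scores[[c for c in cols if c in self.scores.columns]]
        out.reset_index().to_csv(path, sep="\t", index=False)
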