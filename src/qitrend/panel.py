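"""Subject-year panel data model, readers/writers and filtering.

The analysis population for one quality indicator is a panel of
subject-year records: each row states whether the indicator event
occurred for one insuree in one year, together with the confounders
used for standardization (age, gender, comorbidity at study entry,
area-level deprivation score) and two flags (membership in the
reference 10% sample, family-doctor contract).

Regions play three roles: one intervention region, an ordered set of
control regions, and a reference region built from the 10% sample of
the surrounding federal state.  A record's region may change across
years (movers); each record is attributed to the region of its year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column order of a panel table
PANEL_COLUMNS = [
    "subject_id",
    "t",
    "region",
    "outcome",
    "age",
    "gender",
    "comorbidity_entry",
    "gisd",
    "in_reference_sample",
    "family_contract",
    "practice_id",
]

#: columns that must be present in an input file (practice_id is optional)
REQUIRED_COLUMNS = PANEL_COLUMNS[:-1]

DIRECTIONS = ("increase", "decrease", "undirected")


@dataclass(frozen=True)
class IndicatorDefinition:
    """Metadata of one quality indicator.

    Parameters
    ----------
    id : str
        Short machine identifier.
    label : str
        Human-readable name.
    direction : {"increase", "decrease", "undirected"}
        Which direction of a prevalence change counts as an improvement.
        Undirected indicators bypass the verbal grading.
    family_contract_sensitive : bool
        Whether events of this indicator are masked for insurees with a
        family-doctor contract (those subjects are then excluded).
    t_min, T : int
        First and last year index covered by the indicator (inclusive).
    """

    id: str
    label: str = ""
    direction: str = "increase"
    family_contract_sensitive: bool = False
    t_min: int = 0
    T: int = 9

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if self.t_min > self.T:
            raise ValidationError(f"t_min ({self.t_min}) must be <= T ({self.T})")

    @property
    def years(self) -> range:
        return range(self.t_min, self.T + 1)


@dataclass(frozen=True)
class RegionRegistry:
    """Role assignment of region codes.

    ``intervention`` is the focal region (index 0), ``controls`` the
    ordered control regions (indices 1..R) and ``reference`` the region
    formed by the reference sample (index R+1).
    """

    intervention: str
    controls: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "controls", tuple(self.controls))
        codes = self.all_regions
        if len(set(codes)) != len(codes):
            raise ValidationError("region codes must be pairwise distinct")
        if not self.controls:
            raise ValidationError("at least one control region is required")

    @property
    def all_regions(self) -> tuple[str, ...]:
        """All region codes in canonical order (intervention first)."""
        return (self.intervention, *self.controls, self.reference)

    @property
    def n_controls(self) -> int:
        return len(self.controls)

    def index_of(self, region: str) -> int:
        return self.all_regions.index(region)


@dataclass
class AnalysisPanel:
    """A validated subject-year panel plus indicator and region metadata."""

    records: pd.DataFrame
    indicator: IndicatorDefinition
    registry: RegionRegistry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnalysisPanel):
            return NotImplemented
        a = self.records[PANEL_COLUMNS].reset_index(drop=True)
        b = other.records[PANEL_COLUMNS].reset_index(drop=True)
        return (
            self.indicator == other.indicator
            and self.registry == other.registry
            and a.equals(b)
        )

    def validate(self) -> "AnalysisPanel":
        """Check the structural invariants; raise ``ValidationError`` if violated."""
        df = self.records
        bad = ~df["outcome"].isin([0, 1])
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-binary outcome value {df['outcome'].iloc[idx]!r} at row {idx}"
            )
        t = df["t"].to_numpy()
        if ((t < self.indicator.t_min) | (t > self.indicator.T)).any():
            raise ValidationError("year index outside the indicator's range")
        if (df["age"].to_numpy() < 0).any():
            raise ValidationError("negative age")
        if (df["comorbidity_entry"].to_numpy() < 0).any():
            raise ValidationError("negative comorbidity score")
        if df.duplicated(["subject_id", "t"]).any():
            raise ValidationError("a subject has more than one record in a year")
        n_levels = df.groupby("subject_id")["comorbidity_entry"].nunique()
        if (n_levels > 1).any():
            raise ValidationError(
                "comorbidity_entry must be constant across the years of a subject"
            )
        known = set(self.registry.all_regions)
        stray = ~df["region"].isin(known) & ~df["in_reference_sample"].astype(bool)
        if stray.any():
            raise ValidationError(
                f"{int(stray.sum())} records in regions outside the registry"
            )
        return self


def _coerce_records(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["subject_id"] = out["subject_id"].astype(str)
    out["t"] = out["t"].astype(np.int64)
    out["region"] = out["region"].astype(str)
    out["outcome"] = out["outcome"].astype(np.int64)
    out["age"] = out["age"].astype(float)
    out["gender"] = out["gender"].astype(np.int64)
    out["comorbidity_entry"] = out["comorbidity_entry"].astype(np.int64)
    out["gisd"] = out["gisd"].astype(float)
    out["in_reference_sample"] = out["in_reference_sample"].astype(bool)
    out["family_contract"] = out["family_contract"].astype(bool)
    if "practice_id" not in out.columns:
        out["practice_id"] = pd.NA
    return out[PANEL_COLUMNS]


def load_panel(
    path,
    indicator: IndicatorDefinition,
    registry: RegionRegistry,
    schema: Mapping[str, str] | None = None,
) -> AnalysisPanel:
    """Read a delimited subject-year file into a validated panel.

    Parameters
    ----------
    path
        CSV file (UTF-8, header row); ``.gz`` handled transparently.
    schema
        Optional mapping from canonical column names to the names used
        in the file, e.g. ``{"outcome": "event"}``.

    Rows whose year index falls outside the indicator's ``[t_min, T]``
    range are dropped with a logged count.
    """
    raw = pd.read_csv(path, float_precision="round_trip")
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    bad = ~raw["outcome"].isin([0, 1])
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"non-binary outcome value {raw['outcome'].iloc[idx]!r} at row {idx}"
        )
    df = _coerce_records(raw)
    in_range = (df["t"] >= indicator.t_min) & (df["t"] <= indicator.T)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.info(
            "dropped %d records outside years [%d, %d]",
            n_dropped,
            indicator.t_min,
            indicator.T,
        )
    panel = AnalysisPanel(
        df.loc[in_range],
        indicator,
        registry,
        meta={"n_dropped_out_of_range": n_dropped},
    )
    return panel.validate()


def write_panel(panel: AnalysisPanel, path) -> None:
    """Write the panel's records to CSV (canonical column order).

    Floats use %.17g so that write/load round-trips bit-exactly.
    """
    panel.records[PANEL_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def apply_exclusions(panel: AnalysisPanel) -> AnalysisPanel:
    """Remove record-years with a family-doctor contract for sensitive indicators.

    For indicators whose event definition is masked by the
    family-doctor-centred program, every record-year flagged
    ``family_contract`` is removed.  Non-sensitive indicators pass
    through unchanged.  Idempotent.
    """
    if not panel.indicator.family_contract_sensitive:
        return panel
    keep = ~panel.records["family_contract"].astype(bool)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("excluded %d family-contract record-years", n_removed)
    if not keep.any():
        logger.warning("exclusions removed every record of the panel")
    meta = dict(panel.meta)
    meta["n_contract_excluded"] = n_removed
    return AnalysisPanel(panel.records.loc[keep], panel.indicator, panel.registry, meta)


def crude_prevalences(panel: AnalysisPanel) -> pd.DataFrame:
    """Crude region x year event fractions with denominators.

    Returns a tidy frame over the full region x year grid with columns
    ``region, t, events, denominator, prevalence``; cells without any
    record carry denominator 0 and a missing prevalence.
    """
    if len(panel) == 0:
        raise ValidationError("panel is empty")
    df = panel.records
    g = df.groupby(["region", "t"])["outcome"].agg(events="sum", denominator="count")
    grid = pd.MultiIndex.from_product(
        [list(panel.registry.all_regions), list(panel.indicator.years)],
        names=["region", "t"],
    )
    out = g.reindex(grid, fill_value=0).reset_index()
    out["prevalence"] = np.where(
        out["denominator"] > 0, out["events"] / out["denominator"].replace(0, 1), np.nan
    )
    return out


def panel_summary(panel: AnalysisPanel) -> dict:
    """Summary counts for a JSON sidecar."""
    df = panel.records
    return {
        "indicator": panel.indicator.id,
        "n_records": int(len(df)),
        "n_subjects": int(df["subject_id"].nunique()),
        "n_events": int(df["outcome"].sum()),
        "years": sorted(int(v) for v in df["t"].unique()),
        "regions": sorted(df["region"].unique().tolist()),
        "n_reference_records": int(df["in_reference_sample"].sum()),
        **panel.meta,
    }
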