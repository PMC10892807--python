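"""Core data model: trait catalog, per-plant trait tables, study design.

The experiment this package models is a two-treatment (ambient control vs
infrared-heater warming), two-year factorial on potted *Impatiens oxyanthera*:
six 36-plant plots per treatment, 108 plants measured for morphology and a
36-plant subset measured for floral traits in each treatment-year. The
universal data currency is the trait table: one row per plant, design columns
first, then one column per trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TREATMENTS",
    "YEARS",
    "DESIGN_COLUMNS",
    "TraitDef",
    "TraitCatalog",
    "DEFAULT_CATALOG",
    "StudyDesign",
    "TraitTable",
    "TraitTableWarning",
    "read_trait_table",
    "write_trait_table",
    "validate_design",
    "ValidationReport",
]

TREATMENTS = ("control", "warming")
YEARS = (2017, 2018)
DESIGN_COLUMNS = ("plant_id", "plot_id", "treatment", "year")

#: tolerance for accepting a float as an integral count on read
COUNT_TOL = 1e-6
#: tolerance for the flower_longevity = male_phase + female_phase check
LONGEVITY_TOL = 1e-9


class TraitTableWarning(UserWarning):
    """Non-fatal data-quality issue in a trait table."""


@dataclass(frozen=True)
class TraitDef:
    """One trait in the catalog.

    kind is 'continuous' or 'count'; higher_is_better drives the default
    grading direction in the AHP stage.
    """

    name: str
    units: str
    kind: str = "continuous"
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "count"):
            raise ValueError(f"unknown trait kind {self.kind!r} for {self.name}")


class TraitCatalog:
    """Ordered collection of trait definitions with name lookup."""

    def __init__(self, defs: Iterable[TraitDef]):
        self._defs = list(defs)
        self._by_name = {d.name: d for d in self._defs}
        if len(self._by_name) != len(self._defs):
            raise ValueError("duplicate trait names in catalog")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self._defs]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> TraitDef:
        return self._by_name[name]

    def __iter__(self):
        return iter(self._defs)

    def __len__(self) -> int:
        return len(self._defs)

    def counts(self) -> list[str]:
        return [d.name for d in self._defs if d.kind == "count"]

    def to_dict(self) -> list[dict]:
        return [
            {
                "name": d.name,
                "units": d.units,
                "kind": d.kind,
                "higher_is_better": d.higher_is_better,
            }
            for d in self._defs
        ]

    @classmethod
    def from_dict(cls, items: Sequence[Mapping]) -> "TraitCatalog":
        return cls(TraitDef(**dict(it)) for it in items)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitCatalog":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


#: The 22 traits measured in the experiment, in canonical column order:
#: vegetative morphology first, then flowering phenology, then floral
#: morphology and pigmentation.
DEFAULT_CATALOG = TraitCatalog(
    [
        TraitDef("plant_height", "cm"),
        TraitDef("basal_diameter", "mm"),
        TraitDef("branch_number", "count", kind="count"),
        TraitDef("crown_width", "cm"),
        TraitDef("single_leaf_area", "cm2"),
        TraitDef("leaf_length", "cm"),
        TraitDef("leaf_width", "cm"),
        TraitDef("male_phase", "d"),
        TraitDef("female_phase", "d"),
        TraitDef("flower_longevity", "d"),
        TraitDef("flowering_duration", "d"),
        TraitDef("flower_number", "count", kind="count"),
        TraitDef("vexillum_length", "mm"),
        TraitDef("wing_petal_length", "mm"),
        TraitDef("corolla_diameter", "mm"),
        TraitDef("corolla_tube_length", "mm"),
        TraitDef("stripe_number", "count", kind="count"),
        TraitDef("nectar_spur_length", "mm"),
        TraitDef("nectar_spur_curvature", "degrees"),
        TraitDef("pedicel_length", "mm"),
        TraitDef("anthocyanin_vexillum", "A.g-1 FW"),
        TraitDef("anthocyanin_corolla", "A.g-1 FW"),
    ]
)


@dataclass(frozen=True)
class StudyDesign:
    """Plot/plant layout of one treatment-year cell.

    Defaults mirror the field experiment: 6 plots of 36 plants per treatment,
    108 plants measured for morphology and 36 for floral traits per
    treatment-year.
    """

    plots_per_treatment: int = 6
    plants_per_plot: int = 36
    n_morphology: int = 108
    n_floral: int = 36

    def __post_init__(self) -> None:
        for name in ("plots_per_treatment", "plants_per_plot", "n_morphology", "n_floral"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (
            self.n_floral <= self.n_morphology
            <= self.plots_per_treatment * self.plants_per_plot
        ):
            raise ValueError(
                "need n_floral <= n_morphology <= plots_per_treatment * plants_per_plot"
            )


class TraitTable:
    """Validated per-plant trait table.

    Wraps a DataFrame with columns ``plant_id, plot_id, treatment, year``
    followed by the catalog's trait columns. Missing trait values are NaN.
    """

    def __init__(self, df: pd.DataFrame, catalog: TraitCatalog = DEFAULT_CATALOG):
        self.catalog = catalog
        df = df.copy()
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing design columns: {', '.join(missing)}")
        unknown = [
            c for c in df.columns if c not in DESIGN_COLUMNS and c not in catalog
        ]
        if unknown:
            warnings.warn(
                f"unknown trait columns ignored by the catalog: {', '.join(unknown)}",
                TraitTableWarning,
                stacklevel=2,
            )
        df["plant_id"] = df["plant_id"].astype(str)
        df["plot_id"] = df["plot_id"].astype(str)
        df["treatment"] = df["treatment"].astype(str).str.lower()
        bad = sorted(set(df["treatment"]) - set(TREATMENTS))
        if bad:
            raise ValueError(f"unknown treatment levels: {bad}")
        df["year"] = df["year"].astype(int)
        trait_cols = [c for c in catalog.names if c in df.columns]
        ordered = list(DESIGN_COLUMNS) + trait_cols
        df = df[ordered + [c for c in df.columns if c not in ordered]]
        for c in trait_cols:
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        self.df = df.reset_index(drop=True)
        self.trait_columns = trait_cols
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        df = self.df
        dup = df.duplicated(subset=["treatment", "year", "plant_id"])
        if dup.any():
            ids = df.loc[dup, "plant_id"].unique()[:5]
            raise ValueError(
                f"duplicate plant_id within a treatment-year: {', '.join(ids)}"
            )
        plot_map = df.groupby("plot_id")["treatment"].nunique()
        mixed = plot_map[plot_map > 1]
        if not mixed.empty:
            raise ValueError(
                f"plot assigned to more than one treatment: {', '.join(mixed.index)}"
            )
        for c in self.trait_columns:
            vals = df[c].to_numpy()
            present = ~np.isnan(vals)
            if np.any(~np.isfinite(vals[present])):
                raise ValueError(f"non-finite value in trait {c}")
            if np.any(vals[present] < 0):
                raise ValueError(f"negative value in trait {c}")
            if self.catalog[c].kind == "count":
                off = present & (np.abs(vals - np.round(vals)) > COUNT_TOL)
                if off.any():
                    raise ValueError(
                        f"non-integral count in trait {c} at row(s) "
                        f"{np.flatnonzero(off)[:5].tolist()}"
                    )
                df[c] = np.where(present, np.round(vals), np.nan)
        self._check_longevity()

    def _check_longevity(self) -> None:
        cols = ("male_phase", "female_phase", "flower_longevity")
        if not all(c in self.df.columns for c in cols):
            return
        m, f, l = (self.df[c].to_numpy() for c in cols)
        full = ~(np.isnan(m) | np.isnan(f) | np.isnan(l))
        bad = full & (np.abs(m + f - l) > LONGEVITY_TOL)
        if bad.any():
            rows = np.flatnonzero(bad).tolist()
            warnings.warn(
                "flower_longevity != male_phase + female_phase at row(s) "
                f"{rows[:10]}{'...' if len(rows) > 10 else ''}",
                TraitTableWarning,
                stacklevel=3,
            )

    # -- convenience ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def cell(self, treatment: str, year: int) -> pd.DataFrame:
        df = self.df
        return df[(df["treatment"] == treatment) & (df["year"] == year)]

    def equals(self, other: "TraitTable") -> bool:
        return self.df.equals(other.df) and self.catalog.names == other.catalog.names


def read_trait_table(
    path: str | Path, catalog: TraitCatalog = DEFAULT_CATALOG
) -> TraitTable:
    """Read a comma-separated trait table.

    Empty cells and ``NA`` are missing values (never coerced to zero).
    Missing design columns or non-numeric trait cells are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        na_values=["", "NA"],
        keep_default_na=False,
        dtype={"plant_id": str, "plot_id": str},
        float_precision="round_trip",
    )
    for c in df.columns:
        if c in DESIGN_COLUMNS or c not in catalog:
            continue
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[c], errors="coerce")
            rows = df.index[bad.isna() & df[c].notna()].tolist()
            raise ValueError(
                f"non-numeric value in trait column {c!r} at row(s) {rows[:5]}"
            ) from exc
    return TraitTable(df, catalog)


def write_trait_table(table: TraitTable, path: str | Path) -> Path:
    """Write a trait table as UTF-8 comma-separated text.

    Column order is stable (design columns, then catalog order); missing
    values become empty cells. Writing the same table twice is byte-identical
    and read_trait_table round-trips it exactly.
    """
    path = Path(path)
    cols = list(DESIGN_COLUMNS) + table.trait_columns
    out = table.df[cols].copy()
    for c in table.trait_columns:
        if table.catalog[c].kind == "count":
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else str(int(round(v))))
        else:
            # repr gives the shortest digit string that round-trips exactly
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False, na_rep="", lineterminator="\n")
    return path


@dataclass
class ValidationReport:
    """Per-cell layout summary with deviations from the nominal design."""

    summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def validate_design(table: TraitTable, design: StudyDesign) -> ValidationReport:
    """Compare a trait table against the nominal plot/plant layout.

    Report-only: lists per treatment-year the plot count, plant count and
    per-trait non-missing counts, flagging deviations; never raises.
    """
    rows = []
    flags: list[str] = []
    floral_markers = [
        c for c in ("flowering_duration", "pedicel_length", "flower_longevity")
        if c in table.trait_columns
    ]
    for year in sorted(table.df["year"].unique()):
        for treatment in TREATMENTS:
            cell = table.cell(treatment, year)
            n_plots = cell["plot_id"].nunique()
            n_plants = len(cell)
            non_missing = {c: int(cell[c].notna().sum()) for c in table.trait_columns}
            rows.append(
                {
                    "treatment": treatment,
                    "year": year,
                    "n_plots": n_plots,
                    "n_plants": n_plants,
                    **{f"n_{c}": v for c, v in non_missing.items()},
                }
            )
            if n_plots != design.plots_per_treatment:
                flags.append(
                    f"{treatment} {year}: {n_plots} plots, expected "
                    f"{design.plots_per_treatment}"
                )
            if n_plants != design.n_morphology:
                flags.append(
                    f"{treatment} {year}: {n_plants} plants, expected "
                    f"{design.n_morphology}"
                )
            for c in floral_markers:
                if non_missing[c] != design.n_floral:
                    flags.append(
                        f"{treatment} {year}: trait {c} measured on "
                        f"{non_missing[c]} plants, expected {design.n_floral}"
                    )
    return ValidationReport(summary=pd.DataFrame(rows), flags=flags)
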