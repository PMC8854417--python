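"""Trait-table, regime and tree input/output, plus the packaged study data.

Two kinds of tabular input are supported: per-specimen raw SEM measurements
(one row per individual, lengths in micrometres) and species-level tables of
trait means with standard errors (the shape in which the study data are
packaged).  Trees are Newick with mandatory branch lengths, validated as
strictly bifurcating and ultrametric.

The packaged fixtures transcribe the study's species-level summary tables
(visual-system traits and antennal traits for the 18 miltogrammine species)
and the SAT / NON-SAT host-finding regime of each species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .trees import DEFAULT_ULTRAMETRIC_RTOL, TreeError, UltrametricTree

SAT = "SAT"
NON_SAT = "NON_SAT"
REGIMES = (SAT, NON_SAT)

SUBSTRATEGIES = ("necrophagous", "hole_searcher", "stalker_lurker", "satellite")

#: traits recognised in species-level tables (others pass through untouched)
KNOWN_TRAITS = (
    "H_width",
    "E_area",
    "OM_area",
    "OM_number",
    "delta_gamma",
    "OC_diameter",
    "F_length",
    "P_length",
    "A_length",
    "ANT_length",
)

_SPECIMEN_SCALARS = (
    "H_width",
    "E_widthA",
    "E_height",
    "E_widthL",
    "OC_diameter",
    "F_length",
    "P_length",
    "A_length",
)


class TraitTableError(ValueError):
    """Raised for malformed trait tables or regime files."""


# ---------------------------------------------------------------------- types
@dataclass
class SpecimenMeasurements:
    """Raw linear SEM measurements of one individual (micrometres)."""

    species_id: str
    specimen_id: str
    H_width: float | None = None
    E_widthA: float | None = None
    E_height: float | None = None
    E_widthL: float | None = None
    OM_diameters: list[float] = field(default_factory=list)
    OC_diameter: float | None = None
    F_length: float | None = None
    P_length: float | None = None
    A_length: float | None = None

    def __post_init__(self) -> None:
        for name in _SPECIMEN_SCALARS:
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise TraitTableError(
                    f"specimen {self.specimen_id!r}: {name} must be > 0, got {v!r}"
                )
        if any(not (d > 0) for d in self.OM_diameters):
            raise TraitTableError(
                f"specimen {self.specimen_id!r}: ommatidial diameters must be > 0"
            )


class SpeciesTraitTable:
    """Species x trait matrix of means, standard errors and sample sizes.

    Backed by a DataFrame indexed by ``species_id`` with columns
    ``<trait>_mean``, ``<trait>_se`` and optionally ``<trait>_n``.  Standard
    errors are ``sd / sqrt(n)`` across the individuals of a species; an SE
    may be missing (e.g. single-specimen species).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if df.index.name != "species_id":
            if "species_id" in df.columns:
                df = df.set_index("species_id")
            else:
                raise TraitTableError("trait table needs a species_id column")
        self.df = df.copy()
        self.df.index = self.df.index.astype(str).str.strip().str.replace(
            r"\s+", " ", regex=True
        )
        if validate:
            self._validate()

    # -- structure ---------------------------------------------------------
    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    @property
    def traits(self) -> list[str]:
        return [c[:-5] for c in self.df.columns if c.endswith("_mean")]

    def mean(self, trait: str) -> pd.Series:
        return self.df[f"{trait}_mean"]

    def se(self, trait: str) -> pd.Series:
        col = f"{trait}_se"
        if col not in self.df.columns:
            return pd.Series(np.nan, index=self.df.index)
        return self.df[col]

    def n(self, trait: str) -> pd.Series:
        col = f"{trait}_n"
        if col not in self.df.columns:
            return pd.Series(np.nan, index=self.df.index)
        return self.df[col]

    def _validate(self) -> None:
        if len(self.df) == 0:
            raise TraitTableError("no records")
        if self.df.index.duplicated().any():
            dup = self.df.index[self.df.index.duplicated()][0]
            raise TraitTableError(f"duplicate species_id {dup!r}")
        if not self.traits:
            raise TraitTableError("trait table has no <trait>_mean columns")
        for trait in self.traits:
            m = self.mean(trait)
            bad = m.index[~(m.astype(float) > 0) & m.notna()]
            if len(bad):
                raise TraitTableError(
                    f"trait {trait!r}: non-positive mean for species {bad[0]!r}"
                )
            se = self.se(trait)
            if (se.dropna() < 0).any():
                raise TraitTableError(f"trait {trait!r}: negative standard error")
            n = self.n(trait).dropna()
            if ((n < 1) | (n != n.round())).any():
                raise TraitTableError(f"trait {trait!r}: sample sizes must be integers >= 1")
        self._check_antenna_sum()

    def _check_antenna_sum(self, rel_tol: float = 0.05) -> None:
        # means of per-specimen sums and sums of trait means may differ when
        # the specimen subsets differ per trait, so this is a warning only
        parts = ("F_length", "P_length", "A_length", "ANT_length")
        if not all(f"{p}_mean" in self.df.columns for p in parts):
            return
        total = self.mean("ANT_length").astype(float)
        s = sum(self.mean(p).astype(float) for p in parts[:3])
        ok = total.notna() & s.notna()
        rel = ((total - s).abs() / total)[ok]
        if (rel >= rel_tol).any():
            sp = rel.index[rel >= rel_tol][0]
            warnings.warn(
                f"species {sp!r}: antennal length differs from "
                f"funiculus+pedicel+arista by {rel[sp]:.1%} (> {rel_tol:.0%})",
                stacklevel=2,
            )

    # -- combination and io ------------------------------------------------
    def join(self, other: "SpeciesTraitTable") -> "SpeciesTraitTable":
        if set(self.species) != set(other.species):
            raise TraitTableError("cannot join trait tables with different species sets")
        return SpeciesTraitTable(self.df.join(other.df, how="inner"))

    def subset(self, species: list[str]) -> "SpeciesTraitTable":
        missing = [s for s in species if s not in self.df.index]
        if missing:
            raise TraitTableError(f"species not in trait table: {missing}")
        return SpeciesTraitTable(self.df.loc[species])

    def to_csv(self, path) -> None:
        self.df.to_csv(path)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"SpeciesTraitTable({len(self)} species, traits={self.traits})"


@dataclass
class RegimeAssignment:
    """Binary host-finding regime (SAT vs NON-SAT) per species.

    ``substrategy`` is optional descriptive metadata (necrophagous, hole
    searcher, stalker/lurker, satellite) and is never used in computation.
    """

    regime: dict[str, str]
    substrategy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, r in self.regime.items():
            if r not in REGIMES:
                raise TraitTableError(f"species {sp!r}: unknown regime {r!r}")
        for sp, s in self.substrategy.items():
            if s not in SUBSTRATEGIES:
                raise TraitTableError(f"species {sp!r}: unknown substrategy {s!r}")

    def __getitem__(self, species: str) -> str:
        return self.regime[species]

    @property
    def species(self) -> list[str]:
        return list(self.regime)

    def group(self, regime: str) -> list[str]:
        return [s for s, r in self.regime.items() if r == regime]

    def check_covers(self, species: list[str]) -> None:
        missing = [s for s in species if s not in self.regime]
        if missing:
            raise TraitTableError(f"species without regime assignment: {missing}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegimeAssignment":
        if "species_id" in df.columns:
            df = df.set_index("species_id")
        idx = df.index.astype(str).str.strip().str.replace(r"\s+", " ", regex=True)
        regime = dict(zip(idx, df["regime"].astype(str).str.strip()))
        if len(regime) != len(df):
            raise TraitTableError("duplicate species_id in regime table")
        sub = {}
        if "substrategy" in df.columns:
            for sp, s in zip(idx, df["substrategy"]):
                if isinstance(s, str) and s.strip():
                    sub[sp] = s.strip()
        return cls(regime=regime, substrategy=sub)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "species_id": self.species,
                "regime": [self.regime[s] for s in self.species],
                "substrategy": [self.substrategy.get(s, "") for s in self.species],
            }
        ).to_csv(path, index=False)


# ----------------------------------------------------------------- operations
def _read_csv(path) -> pd.DataFrame:
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")  # sniff comma vs tab
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise TraitTableError(f"{path}: no records") from exc
    if len(df) == 0:
        raise TraitTableError(f"{path}: no records")
    return df


def _require_numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[coerced.isna() & out[col].notna()]
        if len(bad):
            raise TraitTableError(
                f"{path}: non-numeric value {out.loc[bad[0], col]!r} "
                f"in row {bad[0] + 2}, column {col!r}"
            )
        out[col] = coerced
    return out


def read_trait_table(path, level: str = "species"):
    """Read a CSV/TSV trait table.

    ``level='species'`` returns a :class:`SpeciesTraitTable` from
    ``<trait>_mean`` / ``<trait>_se`` / ``<trait>_n`` columns.
    ``level='specimen'`` returns a list of :class:`SpecimenMeasurements`;
    ommatidial diameters are taken from columns named ``OM_diam_1``,
    ``OM_diam_2``, ... (missing cells allowed).
    """
    if level == "species":
        df = _read_csv(path)
        value_cols = [c for c in df.columns if c != "species_id"]
        df = _require_numeric(df, value_cols, path)
        return SpeciesTraitTable(df)
    if level != "specimen":
        raise ValueError(f"unknown level {level!r}")

    df = _read_csv(path)
    for required in ("species_id", "specimen_id"):
        if required not in df.columns:
            raise TraitTableError(f"{path}: missing column {required!r}")
    if df["specimen_id"].duplicated().any():
        dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].iloc[0]
        raise TraitTableError(f"{path}: duplicate specimen_id {dup!r}")
    om_cols = sorted(
        (c for c in df.columns if c.startswith("OM_diam")),
        key=lambda c: (len(c), c),
    )
    numeric = [c for c in df.columns if c not in ("species_id", "specimen_id")]
    df = _require_numeric(df, numeric, path)

    specimens = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in _SPECIMEN_SCALARS:
            if name in df.columns and not math.isnan(row[name]):
                kwargs[name] = float(row[name])
        diams = [float(row[c]) for c in om_cols if not math.isnan(row[c])]
        specimens.append(
            SpecimenMeasurements(
                species_id=str(row["species_id"]).strip(),
                specimen_id=str(row["specimen_id"]).strip(),
                OM_diameters=diams,
                **kwargs,
            )
        )
    return specimens


def read_regimes(path) -> RegimeAssignment:
    return RegimeAssignment.from_frame(_read_csv(path))


def read_tree(
    path_or_newick,
    rescale: bool = True,
    rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
) -> UltrametricTree:
    """Read a Newick tree, validate it and (by default) rescale depth to 1."""
    text = str(path_or_newick)
    if "(" not in text:  # a path, not a Newick string
        with open(text) as fh:
            text = fh.read()
    if not text.strip():
        raise TreeError("empty tree input")
    return UltrametricTree.from_newick(text, rescale=rescale, rtol=rtol)


def builtin_fixture(name: str):
    """Return a packaged study fixture.

    ``table1``: visual-system traits (H_width, E_area, OM_area, OM_number,
    delta_gamma, OC_diameter) for the 18 species.  ``table2``: antennal
    traits (F_length, P_length, A_length, ANT_length).  ``traits``: the two
    joined.  ``regimes``: the SAT / NON-SAT assignment (10 SAT, 8 NON-SAT).
    """
    data = resources.files("flyvis") / "data"
    with warnings.catch_warnings():
        # one packaged species is known to have ANT_length != F+P+A (trait
        # means come from slightly different specimen subsets)
        warnings.filterwarnings("ignore", message=".*antennal length differs.*")
        if name == "table1":
            return read_trait_table(data / "table1.csv", level="species")
        if name == "table2":
            return read_trait_table(data / "table2.csv", level="species")
        if name == "traits":
            return builtin_fixture("table1").join(builtin_fixture("table2"))
        if name == "regimes":
            return read_regimes(data / "regimes.csv")
    raise KeyError(f"unknown fixture {name!r}; choose table1, table2, traits or regimes")
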