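"""Species-level dietary indices from heterogeneous entry-level diet records.

One *entry* is a single diet record for one species in one season/locality
from one study. Food items are binned into eight non-overlapping categories
(Leaves, Roots, Seeds, Fruits, Plants, Algae, Animal, Other). Entries are
normalized to percentages, averaged per species with equal weight, and
collapsed into two continuous indices:

* herbivory index ``H = (Leaves + Roots + Plants + Algae) / (all - Other)``
* folivory  index ``F = (Leaves + Plants) / (all - Other)``

Both live in [0, 1], with ``F <= H``. For correlation and model fitting the
indices are logit-transformed after substituting exact 0/1 boundary values
by the most extreme non-boundary values observed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import (
    DegenerateEntryError,
    UndefinedIndexError,
    ValidationError,
)

__all__ = [
    "CATEGORIES",
    "METHODS",
    "DEFAULT_SCORE_TABLE",
    "DietEntry",
    "DietProfile",
    "TraitVector",
    "normalize_entry",
    "species_profile",
    "dietary_indices",
    "logit_with_boundary",
    "read_entries",
    "compile_species_table",
]

CATEGORIES: Tuple[str, ...] = (
    "Leaves",
    "Roots",
    "Seeds",
    "Fruits",
    "Plants",
    "Algae",
    "Animal",
    "Other",
)

#: numerator of the herbivory index (denominator excludes "Other")
HERBIVORY_CATEGORIES = ("Leaves", "Roots", "Plants", "Algae")
#: numerator of the folivory index
FOLIVORY_CATEGORIES = ("Leaves", "Plants")

#: percentage-type methods whose raw values should already sum to ~100
PERCENT_METHODS = ("gut_percentage", "feeding_time", "fecal")
METHODS = PERCENT_METHODS + ("frequency_occurrence", "qualitative")

#: qualitative descriptor -> importance score on the 1 (rare) .. 4 (primary)
#: scale; overridable wherever a score table is accepted
DEFAULT_SCORE_TABLE: Dict[str, int] = {
    "primary": 4,
    "primarily": 4,
    "chiefly": 4,
    "mainly": 4,
    "important": 3,
    "major": 3,
    "frequent": 3,
    "common": 2,
    "regular": 2,
    "also": 2,
    "rare": 1,
    "rarely": 1,
    "trace": 1,
    "occasionally": 1,
}

#: tolerated deviation from 100 for percentage-type methods before a warning
PERCENT_SUM_TOLERANCE = 2.0


@dataclass
class DietEntry:
    """One study x season x locality diet record for one species."""

    species: str
    method: str
    categories: Dict[str, float]
    season: str = ""
    locality: str = ""
    n_sampled: Optional[int] = None
    #: qualitative entries: category -> descriptive adjective (or "" for none)
    descriptors: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown diet categories: {sorted(unknown)}")
        full = {c: float(self.categories.get(c, 0.0)) for c in CATEGORIES}
        if any(v < 0 for v in full.values()):
            raise ValidationError(f"negative category value in entry for {self.species}")
        if all(v == 0 for v in full.values()) and not any(self.descriptors.values()):
            raise DegenerateEntryError(f"all-zero diet entry for {self.species}")
        self.categories = full


@dataclass
class DietProfile:
    """Species-level mean category percentages and dietary indices."""

    species: str
    n_entries: int
    mean_categories: Dict[str, float]
    herbivory_index: float
    folivory_index: float


@dataclass
class TraitVector:
    """A transformed species -> value map ready for phylogenetic analysis."""

    trait_name: str
    values: Dict[str, float]
    #: species whose boundary values (0 or 1) were substituted, with the
    #: replacement proportion used
    transform_record: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, species: str) -> float:
        return self.values[species]

    def __contains__(self, species) -> bool:
        return species in self.values

    def keys(self):
        return self.values.keys()

    def items(self):
        return self.values.items()

    def restrict(self, species: Iterable[str]) -> "TraitVector":
        keep = {s: self.values[s] for s in species}
        return TraitVector(self.trait_name, keep, dict(self.transform_record))


def _as_vector(categories: Mapping[str, float]) -> np.ndarray:
    return np.array([float(categories.get(c, 0.0)) for c in CATEGORIES])


def normalize_entry(
    entry: DietEntry,
    score_table: Optional[Mapping[str, int]] = None,
) -> Dict[str, float]:
    """Normalize one entry to eight category percentages summing to 100.

    Percentage-type methods (gut contents, feeding time, feces) pass through
    if they already sum to ~100 and are renormalized otherwise (with a
    warning beyond a +/-2 tolerance). Frequency-of-occurrence entries are
    rescaled by their total. Qualitative entries score each consumed item on
    a 1-4 scale from its descriptor (items with no resolvable descriptor all
    score equally) and normalize the scores.
    """
    scores = dict(DEFAULT_SCORE_TABLE if score_table is None else score_table)
    if entry.method == "qualitative":
        consumed = [
            c
            for c in CATEGORIES
            if entry.categories.get(c, 0) > 0 or entry.descriptors.get(c, "")
        ]
        if not consumed:
            raise DegenerateEntryError(f"qualitative entry lists no items: {entry.species}")
        descs = {c: entry.descriptors.get(c, "").strip().lower() for c in consumed}
        # items whose descriptor is absent or not in the table all score the
        # scale midpoint, so an account with no usable adjectives weights its
        # items equally
        midpoint = (min(scores.values()) + max(scores.values())) / 2.0
        raw = {
            c: float(scores[d]) if d in scores else midpoint for c, d in descs.items()
        }
        vec = _as_vector(raw)
    else:
        vec = _as_vector(entry.categories)
        total = vec.sum()
        if total <= 0:
            raise DegenerateEntryError(f"all-zero diet entry for {entry.species}")
        if entry.method in PERCENT_METHODS and abs(total - 100.0) > PERCENT_SUM_TOLERANCE:
            warnings.warn(
                f"{entry.method} entry for {entry.species} sums to {total:.1f}; "
                "renormalizing to 100",
                stacklevel=2,
            )
    total = vec.sum()
    if total <= 0:
        raise DegenerateEntryError(f"all-zero diet entry for {entry.species}")
    vec = vec * (100.0 / total)
    return dict(zip(CATEGORIES, vec.tolist()))


def dietary_indices(mean_categories: Mapping[str, float]) -> Tuple[float, float]:
    """Herbivory and folivory indices from mean category percentages.

    'Other' (often unidentified matter) is excluded from both numerator and
    denominator.
    """
    denom = sum(float(mean_categories.get(c, 0.0)) for c in CATEGORIES if c != "Other")
    if denom <= 0:
        raise UndefinedIndexError(
            "dietary index undefined: all intake falls in the 'Other' category"
        )
    h = sum(float(mean_categories.get(c, 0.0)) for c in HERBIVORY_CATEGORIES) / denom
    f = sum(float(mean_categories.get(c, 0.0)) for c in FOLIVORY_CATEGORIES) / denom
    return h, f


def species_profile(
    entries: Sequence[DietEntry],
    score_table: Optional[Mapping[str, int]] = None,
) -> DietProfile:
    """Equal-weight mean of normalized entries for one species.

    Sample sizes (``n_sampled``) are metadata only and never used as
    weights.
    """
    if not entries:
        raise ValidationError("species_profile requires at least one entry")
    species = entries[0].species
    if any(e.species != species for e in entries):
        raise ValidationError("species_profile received entries for multiple species")
    mat = np.array(
        [_as_vector(normalize_entry(e, score_table)) for e in entries]
    )
    mean = mat.mean(axis=0)
    mean_categories = dict(zip(CATEGORIES, mean.tolist()))
    h, f = dietary_indices(mean_categories)
    return DietProfile(
        species=species,
        n_entries=len(entries),
        mean_categories=mean_categories,
        herbivory_index=h,
        folivory_index=f,
    )


def logit_with_boundary(
    values: Mapping[str, float], trait_name: str = "logit_H"
) -> TraitVector:
    """Logit transform with boundary substitution over the whole species set.

    Exact zeros are replaced by the minimum non-zero value in the set and
    exact ones by the maximum non-one value before applying
    ``logit(p) = ln(p / (1 - p))``. The substitutions are recorded.
    """
    vals = {s: float(v) for s, v in values.items()}
    for s, v in vals.items():
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"proportion out of [0,1] for {s}: {v}")
    nonzero = [v for v in vals.values() if v > 0.0]
    nonone = [v for v in vals.values() if v < 1.0]
    if not nonzero or not nonone:
        raise ValidationError(
            "boundary substitution impossible: no interior values in the set"
        )
    lo, hi = min(nonzero), max(nonone)
    record: Dict[str, float] = {}
    out: Dict[str, float] = {}
    for s, v in vals.items():
        if v == 0.0:
            record[s] = lo
            v = lo
        elif v == 1.0:
            record[s] = hi
            v = hi
        out[s] = math.log(v / (1.0 - v))
    return TraitVector(trait_name, out, record)


# ------------------------------------------------------------------ tables

_BASE_COLUMNS = ["species", "season", "locality", "method", "n_sampled"]


def read_entries(path_or_df, score_table=None) -> List[DietEntry]:
    """Read an entry table (CSV/TSV or DataFrame) into ``DietEntry`` records.

    Expected columns: species, season, locality, method, n_sampled, the
    eight category columns, and optional ``<Category>_desc`` descriptor
    columns for qualitative entries.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        sep = "\t" if str(path_or_df).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path_or_df, sep=sep)
    missing = [c for c in ("species", "method") if c not in df.columns]
    if missing:
        raise ValidationError(f"entry table missing columns: {missing}")
    for c in CATEGORIES:
        if c not in df.columns:
            raise ValidationError(f"entry table missing category column: {c}")
    entries = []
    for _, row in df.iterrows():
        n = row.get("n_sampled")
        n_sampled = None if pd.isna(n) else int(n)
        descriptors = {
            c: str(row[f"{c}_desc"])
            for c in CATEGORIES
            if f"{c}_desc" in df.columns and pd.notna(row.get(f"{c}_desc"))
        }
        entries.append(
            DietEntry(
                species=str(row["species"]),
                season=str(row.get("season", "") or ""),
                locality=str(row.get("locality", "") or ""),
                method=str(row["method"]),
                n_sampled=n_sampled,
                categories={c: float(0 if pd.isna(row[c]) else row[c]) for c in CATEGORIES},
                descriptors=descriptors,
            )
        )
    return entries


def entries_to_frame(entries: Sequence[DietEntry]) -> pd.DataFrame:
    """Entry records as a flat table (inverse of :func:`read_entries`)."""
    rows = []
    for e in entries:
        row = {
            "species": e.species,
            "season": e.season,
            "locality": e.locality,
            "method": e.method,
            "n_sampled": e.n_sampled,
        }
        row.update({c: e.categories.get(c, 0.0) for c in CATEGORIES})
        for c, d in e.descriptors.items():
            row[f"{c}_desc"] = d
        rows.append(row)
    df = pd.DataFrame(rows)
    return df


def compile_species_table(
    entries: Sequence[DietEntry],
    score_table=None,
    masses: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Species-level table: mean category sums, H, F, optional body mass (g)."""
    by_species: Dict[str, List[DietEntry]] = {}
    for e in entries:
        by_species.setdefault(e.species, []).append(e)
    rows = []
    for sp in sorted(by_species):
        prof = species_profile(by_species[sp], score_table)
        row = {"species": sp, "n_entries": prof.n_entries}
        row.update({c: prof.mean_categories[c] for c in CATEGORIES})
        row["herbivory_index"] = prof.herbivory_index
        row["folivory_index"] = prof.folivory_index
        if masses is not None:
            row["body_mass_g"] = float(masses[sp]) if sp in masses else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
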