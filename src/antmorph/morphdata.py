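"""Domain types and I/O for morphometric specimen tables.

The exchange object of the whole pipeline is the :class:`SpecimenTable`:
one row per ant worker, with a species label, a boolean infection status
and 21 linear trait measurements in micrometres.  The 21 traits follow the
standard *Temnothorax* measurement protocol (head, mesosoma, petiole,
postpetiole, scape, eye and propodeal-spine distances); their codes live in
the :class:`TraitRegistry`.

Validation is total: every malformed input raises a typed error from
:mod:`antmorph.errors`, never a silently coerced table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    InfectionEncodingError,
    SchemaError,
    TableValidationError,
)

#: Canonical order of the 21 linear trait codes (micrometres).
TRAIT_CODES: tuple[str, ...] = (
    "CL", "CWb", "EL", "FRS", "ML", "MW", "NOH", "NOL", "PEH", "PEW",
    "PoOC", "PPH", "PPL", "PPW", "SL", "SPL", "SPBA", "SPST", "SPTI",
    "SPWI", "PEL",
)

_TRAIT_DESCRIPTIONS: dict[str, str] = {
    "CL": "maximum cephalic length in median line",
    "CWb": "maximum head-capsule width behind the eyes",
    "EL": "maximum eye diameter",
    "FRS": "distance of the frontal carinae",
    "ML": "mesosoma length",
    "MW": "maximum mesosoma width",
    "NOH": "maximum petiolar-node height",
    "NOL": "petiolar-node length",
    "PEH": "maximum petiole height",
    "PEW": "maximum petiole width",
    "PoOC": "postocular distance",
    "PPH": "maximum postpetiole height",
    "PPL": "maximum postpetiole length",
    "PPW": "maximum postpetiole width",
    "SL": "maximum straight-line scape length",
    "SPL": "propodeal spiracle to subspinal excavation distance",
    "SPBA": "smallest distance of lateral spine margins at their base",
    "SPST": "propodeal stigma centre to spine tip distance",
    "SPTI": "distance of spine tips in dorsal view",
    "SPWI": "maximum distance between outer spine margins",
    "PEL": "diagonal petiolar length in lateral view",
}


@dataclass(frozen=True)
class TraitRegistry:
    """Ordered registry of trait codes with free-text descriptions.

    Invariants: codes are unique and, for the default registry, are
    exactly the 21 canonical codes in canonical order.
    """

    names: tuple[str, ...] = TRAIT_CODES
    descriptions: dict[str, str] = field(
        default_factory=lambda: dict(_TRAIT_DESCRIPTIONS)
    )

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise SchemaError("trait registry codes must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def describe(self, code: str) -> str:
        return self.descriptions.get(code, "")


DEFAULT_REGISTRY = TraitRegistry()

# Header synonyms for the metadata columns; user-extendable via
# TableDialect.  Matching is case-insensitive.
_DEFAULT_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "specimen_id": ("specimen_id", "specimen", "id", "sample", "code"),
    "species": ("species", "taxon", "sp"),
    "infected": ("infected", "infection", "infection_status", "parasitized",
                 "status"),
}

_TRUE_TOKENS = frozenset({"1", "true", "yes", "infected", "inf", "y", "t"})
_FALSE_TOKENS = frozenset({"0", "false", "no", "uninfected", "un",
                           "healthy", "n", "f"})


@dataclass(frozen=True)
class TableDialect:
    """Describes how a delimited specimen file is laid out.

    ``sep=None`` sniffs comma vs. tab from the header line.  ``scale``
    multiplies trait values on read (for replicating against deposits
    stored in mm rather than micrometres).  The synonym maps extend, not
    replace, the defaults.
    """

    sep: str | None = None
    column_synonyms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    true_tokens: frozenset[str] = frozenset()
    false_tokens: frozenset[str] = frozenset()
    scale: float = 1.0

    def resolve_synonyms(self) -> dict[str, tuple[str, ...]]:
        merged = {k: tuple(v) for k, v in _DEFAULT_COLUMN_SYNONYMS.items()}
        for key, extra in self.column_synonyms.items():
            merged[key] = tuple(extra) + merged.get(key, ())
        return merged

    @property
    def all_true_tokens(self) -> frozenset[str]:
        return _TRUE_TOKENS | frozenset(t.lower() for t in self.true_tokens)

    @property
    def all_false_tokens(self) -> frozenset[str]:
        return _FALSE_TOKENS | frozenset(t.lower() for t in self.false_tokens)


@dataclass(frozen=True)
class SpecimenTable:
    """A validated table of specimens: id, species, infection, 21 traits.

    ``data`` holds columns ``specimen_id`` (str), ``species`` (str),
    ``infected`` (bool) and one float64 column per registered trait, in
    registry order.  Trait values are strictly positive, finite
    micrometres; specimen ids are unique.  Construction through
    :meth:`from_dataframe` enforces all of this.
    """

    data: pd.DataFrame
    registry: TraitRegistry = DEFAULT_REGISTRY

    # -- construction -------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        registry: TraitRegistry = DEFAULT_REGISTRY,
        check_traits: bool = True,
    ) -> "SpecimenTable":
        """Validate ``df`` and return a canonicalised table.

        Raises :class:`SchemaError` for missing columns and
        :class:`TableValidationError` for bad values.  Row order is
        preserved.  Set ``check_traits=False`` only for internal tables
        that intentionally carry transformed (possibly non-positive,
        e.g. z-scaled) trait values.
        """
        missing = [c for c in ("specimen_id", "species", "infected")
                   if c not in df.columns]
        missing += [t for t in registry if t not in df.columns]
        if missing:
            raise SchemaError(
                f"missing required column(s): {', '.join(missing)}",
                missing=missing,
            )

        out = pd.DataFrame(index=pd.RangeIndex(len(df)))
        out["specimen_id"] = df["specimen_id"].astype(str).to_numpy()
        out["species"] = df["species"].astype(str).to_numpy()

        inf = df["infected"]
        if inf.dtype != bool:
            inf = _coerce_infection(inf)
        out["infected"] = np.asarray(inf, dtype=bool)

        dup = out["specimen_id"][out["specimen_id"].duplicated()]
        if len(dup):
            raise TableValidationError(
                f"duplicated specimen_id(s): {sorted(set(dup))}",
                rows=sorted(set(dup)),
            )

        for trait in registry:
            col = pd.to_numeric(df[trait], errors="coerce").to_numpy(float)
            bad = ~np.isfinite(col)
            if check_traits:
                bad |= col <= 0.0
            if bad.any():
                offenders = list(out["specimen_id"][bad])
                raise TableValidationError(
                    f"trait {trait!r} has non-numeric, non-finite or "
                    f"non-positive values for specimen(s) {offenders}",
                    rows=offenders,
                )
            out[trait] = col
        return cls(data=out, registry=registry)

    # -- accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def species_levels(self) -> list[str]:
        """Species labels in sorted (canonical) order."""
        return sorted(self.data["species"].unique())

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.registry.names)

    def trait_matrix(self) -> np.ndarray:
        """(n_specimens, n_traits) float array in registry order."""
        return self.data[list(self.registry)].to_numpy(float)

    def subset(self, mask) -> "SpecimenTable":
        return replace(
            self, data=self.data[np.asarray(mask)].reset_index(drop=True)
        )

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per specimen x trait, columns
        (specimen_id, species, infected, trait, value)."""
        return self.data.melt(
            id_vars=["specimen_id", "species", "infected"],
            value_vars=list(self.registry),
            var_name="trait",
            value_name="value",
        )

    def equals(self, other: "SpecimenTable") -> bool:
        return self.data.equals(other.data)


def _coerce_infection(series: pd.Series,
                      dialect: TableDialect | None = None) -> np.ndarray:
    dialect = dialect or TableDialect()
    tokens = series.astype(str).str.strip().str.lower()
    true_t, false_t = dialect.all_true_tokens, dialect.all_false_tokens
    unknown = sorted(set(tokens) - true_t - false_t)
    if unknown:
        raise InfectionEncodingError(
            f"unknown infection encoding value(s): {unknown}; extend the "
            "dialect's true/false token sets"
        )
    return tokens.isin(true_t).to_numpy()


# -- file I/O ---------------------------------------------------------


def read_table(
    path,
    dialect: TableDialect | None = None,
    registry: TraitRegistry = DEFAULT_REGISTRY,
) -> SpecimenTable:
    """Read a delimited specimen file into a validated table.

    The header must name the species and infection columns (synonyms
    accepted, case-insensitively) and all registered traits.  A missing
    ``specimen_id`` column is synthesised as the 1-based row number.
    Trait values are multiplied by ``dialect.scale`` (default 1, i.e.
    values already in micrometres).
    """
    dialect = dialect or TableDialect()
    sep = dialect.sep
    if sep is None:  # sniff comma vs tab from the header line
        if hasattr(path, "read"):
            head = path.readline()
            path.seek(0)
        else:
            with open(path, encoding="utf-8") as fh:
                head = fh.readline()
        sep = "\t" if head.count("\t") > head.count(",") else ","
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    raw.columns = [str(c).strip() for c in raw.columns]

    lower = {c.lower(): c for c in raw.columns}
    rename: dict[str, str] = {}
    for canonical, synonyms in dialect.resolve_synonyms().items():
        for syn in synonyms:
            if syn.lower() in lower:
                rename[lower[syn.lower()]] = canonical
                break
    # traits match case-insensitively too
    for trait in registry:
        if trait not in raw.columns and trait.lower() in lower:
            rename[lower[trait.lower()]] = trait
    df = raw.rename(columns=rename)

    if "specimen_id" not in df.columns:
        df = df.copy()
        df["specimen_id"] = [str(i + 1) for i in range(len(df))]
    if "infected" in df.columns and df["infected"].dtype != bool:
        df = df.copy()
        df["infected"] = _coerce_infection(df["infected"], dialect)
    if dialect.scale != 1.0:
        df = df.copy()
        for trait in registry:
            if trait in df.columns:
                df[trait] = pd.to_numeric(df[trait]) * dialect.scale
    return SpecimenTable.from_dataframe(df, registry=registry)


def write_table(table: SpecimenTable, path, sep: str = ",") -> None:
    """Write a specimen table as delimited text.

    Trait values are written with ``repr`` round-trip precision so that
    ``read_table(write_table(t)) == t`` exactly.
    """
    df = table.data.copy()
    df["infected"] = df["infected"].astype(int)
    buf = io.StringIO()
    # %.17g guarantees binary round-trip for float64
    df.to_csv(buf, sep=sep, index=False, float_format="%.17g")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


def summarize(table: SpecimenTable) -> pd.DataFrame:
    """Per species x infection specimen counts, with margins.

    Returns a tidy frame with columns (species, infected, n) plus a
    ``total`` row; an empty table yields a single all-zero total row.
    """
    if len(table) == 0:
        return pd.DataFrame(
            [{"species": "total", "infected": "", "n": 0}]
        )
    counts = (
        table.data.groupby(["species", "infected"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    counts["infected"] = counts["infected"].map(
        {True: "infected", False: "uninfected"}
    )
    total = pd.DataFrame(
        [{"species": "total", "infected": "", "n": len(table)}]
    )
    return pd.concat([counts, total], ignore_index=True)
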