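"""Wild-type trait reconstruction by distribution mapping.

For a given species and trait, let (mu_inf, sigma_inf) and
(mu_un, sigma_un) be the maximum-likelihood mean and SD of the infected
and uninfected trait distributions.  An infected specimen with observed
value ``y`` sits at the standardized distance

    d = (y - mu_inf) / sigma_inf

from the infected mean; its predicted wild-type (putative healthy) value
carries that standardized position onto the uninfected distribution:

    p = d * sigma_un + mu_inf + s,        s = mu_un - mu_inf

which is algebraically ``p = d * sigma_un + mu_un`` — the package
asserts the two forms agree rather than assuming it.  The map is affine
and strictly increasing (slope sigma_un/sigma_inf > 0), so within a
trait the ordering of specimens is preserved, and by construction the
reconstructed sample's ML mean and SD equal (mu_un, sigma_un) exactly —
this moment-transfer identity is asserted on every run.

Reconstruction is univariate per trait and species-specific: it requires
both infected and uninfected reference specimens of the species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateMomentsError, InsufficientDataError
from .morphdata import SpecimenTable

__all__ = [
    "CellMoments",
    "GroupMoments",
    "ReconstructedTable",
    "estimate_moments",
    "standardized_distance",
    "predict_wildtype",
    "reconstruct_table",
]

#: below this many specimens in a cell, moment estimates are noisy;
#: reconstruction warns but proceeds.
MIN_CELL_WARN = 5


@dataclass(frozen=True)
class CellMoments:
    """Infected/uninfected moments of one species x trait cell."""

    mu_inf: float
    sigma_inf: float
    mu_un: float
    sigma_un: float

    @property
    def s(self) -> float:
        """Contrast parameter: uninfected minus infected mean."""
        return self.mu_un - self.mu_inf

    def require_nondegenerate(self) -> None:
        if not (self.sigma_inf > 0 and self.sigma_un > 0):
            raise DegenerateMomentsError(
                "group SD is zero; the distribution map is undefined"
            )


@dataclass(frozen=True)
class GroupMoments:
    """Per species x trait moment table.

    ``table`` columns: species, trait, mu_inf, sigma_inf, mu_un,
    sigma_un, s.  ``ddof`` records the SD divisor convention (0 = ML
    divisor n, the default; 1 = sample SD) so outputs are
    self-describing.
    """

    table: pd.DataFrame
    ddof: int = 0

    def cell(self, species: str, trait: str) -> CellMoments:
        row = self.table[
            (self.table["species"] == species) & (self.table["trait"] == trait)
        ]
        if row.empty:
            raise KeyError(f"no moments for ({species!r}, {trait!r})")
        r = row.iloc[0]
        return CellMoments(
            mu_inf=float(r["mu_inf"]),
            sigma_inf=float(r["sigma_inf"]),
            mu_un=float(r["mu_un"]),
            sigma_un=float(r["sigma_un"]),
        )

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())


def estimate_moments(table: SpecimenTable, ddof: int = 0) -> GroupMoments:
    """Gaussian ML moments per species x infection-status x trait.

    Mean = arithmetic mean; SD uses divisor ``n - ddof`` (``ddof=0`` is
    the maximum-likelihood convention, recorded in the result).  Every
    species x infection cell must hold at least 2 specimens; cells
    smaller than ``MIN_CELL_WARN`` trigger a warning.
    """
    records = []
    for species in table.species_levels:
        sub = table.data[table.data["species"] == species]
        cells = {}
        for status, label in ((True, "inf"), (False, "un")):
            cell = sub[sub["infected"] == status]
            if len(cell) < 2:
                raise InsufficientDataError(
                    f"species {species!r}, "
                    f"{'infected' if status else 'uninfected'} cell has "
                    f"{len(cell)} specimen(s); need >= 2",
                    cell=(species, status),
                )
            if len(cell) < MIN_CELL_WARN:
                warnings.warn(
                    f"species {species!r} has only {len(cell)} "
                    f"{'infected' if status else 'uninfected'} specimens; "
                    "moment estimates will be noisy",
                    stacklevel=2,
                )
            cells[label] = cell
        for trait in table.registry:
            vi = cells["inf"][trait].to_numpy(float)
            vu = cells["un"][trait].to_numpy(float)
            mu_inf, sigma_inf = vi.mean(), vi.std(ddof=ddof)
            mu_un, sigma_un = vu.mean(), vu.std(ddof=ddof)
            records.append(
                {
                    "species": species,
                    "trait": trait,
                    "mu_inf": mu_inf,
                    "sigma_inf": sigma_inf,
                    "mu_un": mu_un,
                    "sigma_un": sigma_un,
                    "s": mu_un - mu_inf,
                }
            )
    return GroupMoments(table=pd.DataFrame(records), ddof=ddof)


def standardized_distance(y, moments: CellMoments):
    """d = (y - mu_inf) / sigma_inf, the specimen's position within the
    infected distribution in SD units."""
    moments.require_nondegenerate()
    return (np.asarray(y, dtype=float) - moments.mu_inf) / moments.sigma_inf


def predict_wildtype(y, moments: CellMoments):
    """Predicted wild-type value p = d * sigma_un + mu_inf + s.

    The equivalent form ``d * sigma_un + mu_un`` is computed too and the
    two are asserted to agree to floating-point tolerance.
    """
    moments.require_nondegenerate()
    d = standardized_distance(y, moments)
    p = d * moments.sigma_un + moments.mu_inf + moments.s
    p_alt = d * moments.sigma_un + moments.mu_un
    np.testing.assert_allclose(p, p_alt, rtol=0, atol=1e-9 * max(
        1.0, abs(moments.mu_un)))
    return p


@dataclass(frozen=True)
class ReconstructedTable:
    """Reconstruction output.

    ``data`` mirrors the input specimen-table schema plus a boolean
    ``reconstructed`` column: infected rows carry predicted wild-type
    trait values (``reconstructed=True``); uninfected rows, when
    included, pass through unchanged.  ``distances`` holds the
    standardized distances d (one row per infected specimen x trait)
    and ``original`` the infected specimens' observed values.
    """

    data: pd.DataFrame
    distances: pd.DataFrame
    original: pd.DataFrame
    moments: GroupMoments

    def as_specimen_table(self, registry) -> SpecimenTable:
        return SpecimenTable.from_dataframe(
            self.data.drop(columns=["reconstructed"]), registry=registry
        )


def reconstruct_table(
    table: SpecimenTable,
    moments: GroupMoments | None = None,
    include_uninfected: bool = True,
) -> ReconstructedTable:
    """Map every infected specimen's traits onto the uninfected
    distribution of its own species.

    ``moments`` defaults to moments estimated from ``table`` itself.
    After mapping, the ML mean/SD of the reconstructed values are
    asserted equal to (mu_un, sigma_un) per species x trait whenever the
    moments came from this table (the moment-transfer identity).
    """
    own_moments = moments is None
    if moments is None:
        moments = estimate_moments(table)

    df = table.data.copy()
    df["reconstructed"] = df["infected"].to_numpy()
    dist_rows = []
    for species in table.species_levels:
        mask = (df["species"] == species) & df["infected"]
        if not mask.any():
            continue
        for trait in table.registry:
            cell = moments.cell(species, trait)
            y = df.loc[mask, trait].to_numpy(float)
            d = standardized_distance(y, cell)
            p = predict_wildtype(y, cell)
            df.loc[mask, trait] = p
            if own_moments:
                # moment transfer is exact when the map's source moments
                # are the sample's own
                np.testing.assert_allclose(
                    p.mean(), cell.mu_un, rtol=0,
                    atol=1e-9 * max(1.0, abs(cell.mu_un)))
                np.testing.assert_allclose(
                    p.std(ddof=moments.ddof), cell.sigma_un, rtol=0,
                    atol=1e-9 * max(1.0, cell.sigma_un))
            for sid, di, yi in zip(df.loc[mask, "specimen_id"], d, y):
                dist_rows.append(
                    {"specimen_id": sid, "species": species, "trait": trait,
                     "d": di, "y": yi}
                )
    if not include_uninfected:
        df = df[df["infected"]].reset_index(drop=True)
    distances = pd.DataFrame(
        dist_rows, columns=["specimen_id", "species", "trait", "d", "y"]
    )
    original = table.data[table.data["infected"]].reset_index(drop=True)
    if not np.isfinite(df[list(table.registry)].to_numpy(float)).all():
        raise DegenerateMomentsError(
            "reconstruction produced non-finite values"
        )
    return ReconstructedTable(
        data=df, distances=distances, original=original, moments=moments
    )
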