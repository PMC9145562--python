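"""Linear-model analysis of infection effects on morphology.

Workflow: trait values are z-scaled *within species* (removing the
confounding species body-size scale), a global sequential ANOVA over
trait x infection x species tests whether infection effects differ among
traits and species, per-trait species x infection models localise the
effect, and marginal-mean contrasts quantify the uninfected-minus-
infected difference per species with Bonferroni-adjusted p-values.

Sequential (Type I) sums of squares are used throughout, with terms in
the order trait, infected, species, trait:infected, trait:species,
infected:species, trait:infected:species; F is the term mean square over
the residual mean square.  Contrasts are computed from predicted cell
means, so the factor coding cannot affect them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

from .errors import DegenerateScaleError, DesignError
from .morphdata import SpecimenTable

__all__ = [
    "ScaledTable",
    "AnovaResult",
    "TraitModelSet",
    "scale_by_species",
    "fit_global_model",
    "fit_trait_models",
    "estimate_contrasts",
    "residual_diagnostics",
    "bonferroni",
]

GLOBAL_TERMS = (
    "trait",
    "infected",
    "species",
    "trait:infected",
    "trait:species",
    "infected:species",
    "trait:infected:species",
)


def bonferroni(p, m: int):
    """Bonferroni adjustment: min(1, m * p)."""
    return np.minimum(1.0, m * np.asarray(p, dtype=float))


# -- per-species re-scaling -------------------------------------------


@dataclass(frozen=True)
class ScaledTable:
    """A specimen table whose traits are z-scaled within species.

    ``scaling`` records, per (species, trait), the subtracted mean and
    the divisor SD (``ddof`` degrees-of-freedom convention), which is
    sufficient to invert the scaling exactly.
    """

    table: SpecimenTable
    scaling: pd.DataFrame  # columns: species, trait, mean, sd
    ddof: int = 1

    def invert(self) -> SpecimenTable:
        """Undo the scaling, recovering the original micrometre table."""
        df = self.table.data.copy()
        lookup = self.scaling.set_index(["species", "trait"])
        for trait in self.table.registry:
            mu = df["species"].map(lookup["mean"].xs(trait, level="trait"))
            sd = df["species"].map(lookup["sd"].xs(trait, level="trait"))
            df[trait] = df[trait] * sd + mu
        return SpecimenTable.from_dataframe(df, registry=self.table.registry)

    def to_long(self) -> pd.DataFrame:
        return self.table.to_long()


def scale_by_species(table: SpecimenTable, ddof: int = 1) -> ScaledTable:
    """Z-scale every trait within each species (mean 0, SD 1).

    Raises :class:`DegenerateScaleError` if a trait is constant within a
    species.  ``ddof=1`` uses the sample SD (n-1 divisor).
    """
    df = table.data.copy()
    records = []
    for species, grp in df.groupby("species", sort=True):
        for trait in table.registry:
            vals = grp[trait].to_numpy(float)
            mu = vals.mean()
            sd = vals.std(ddof=ddof)
            if not sd > 0:
                raise DegenerateScaleError(species, trait)
            df.loc[grp.index, trait] = (vals - mu) / sd
            records.append(
                {"species": species, "trait": trait, "mean": mu, "sd": sd}
            )
    scaled = SpecimenTable.from_dataframe(
        df, registry=table.registry, check_traits=False
    )
    return ScaledTable(table=scaled, scaling=pd.DataFrame(records), ddof=ddof)


# -- ANOVA tables -----------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    """Sequential ANOVA table: one row per term plus a residual row.

    Columns: df (int), sum_sq, mean_sq, F, p; the residual row has NaN
    F and p.  Construction asserts the df bookkeeping identity
    sum(df) = n_observations - 1.
    """

    table: pd.DataFrame
    n_observations: int

    def __post_init__(self) -> None:
        total_df = int(self.table["df"].sum())
        if total_df != self.n_observations - 1:
            raise AssertionError(
                f"ANOVA df bookkeeping broken: terms sum to {total_df}, "
                f"expected n - 1 = {self.n_observations - 1}"
            )

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["Residuals", "df"])

    def df_of(self, term: str) -> int:
        return int(self.table.loc[term, "df"])

    def p_of(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def to_frame(self) -> pd.DataFrame:
        """Delimited-text-friendly layout (term, Df, Sum Sq, Mean Sq,
        F value, Pr(>F))."""
        out = self.table.rename(
            columns={"df": "Df", "sum_sq": "Sum Sq", "mean_sq": "Mean Sq",
                     "F": "F value", "p": "Pr(>F)"}
        )
        out.index.name = "term"
        return out.reset_index()


def _check_design(df: pd.DataFrame) -> None:
    cells = df.groupby(["species", "infected"], observed=True).size()
    full = pd.MultiIndex.from_product(
        [sorted(df["species"].unique()), [False, True]],
        names=["species", "infected"],
    )
    empty = [idx for idx in full if cells.get(idx, 0) == 0]
    if empty:
        raise DesignError(
            f"rank-deficient design; empty species x infection cell(s): "
            f"{empty}",
            empty_cells=empty,
        )


def _anova_frame(fit, rename: dict[str, str]) -> pd.DataFrame:
    tab = sm.stats.anova_lm(fit, typ=1)
    tab = tab.rename(
        index=rename,
        columns={"PR(>F)": "p", "mean_sq": "mean_sq"},
    )
    tab["mean_sq"] = tab["sum_sq"] / tab["df"]
    tab["df"] = tab["df"].astype(int)
    tab = tab.rename(index={"Residual": "Residuals"})
    return tab[["df", "sum_sq", "mean_sq", "F", "p"]]


def fit_global_model(long: pd.DataFrame) -> AnovaResult:
    """Sequential ANOVA of the global trait x infection x species model.

    ``long`` has one row per specimen x trait with columns ``value``,
    ``trait``, ``infected``, ``species`` (the output of
    ``SpecimenTable.to_long`` after any pre-scaling).  Terms appear in
    the fixed order of :data:`GLOBAL_TERMS`.
    """
    for col in ("value", "trait", "infected", "species"):
        if col not in long.columns:
            raise DesignError(f"long-format input lacks column {col!r}")
    _check_design(long)
    # factors with a single level carry no df and are dropped from the
    # formula, so the model degenerates gracefully (e.g. one trait and
    # one species leaves a plain two-group comparison on infection)
    active = [f for f in ("trait", "infected", "species")
              if long[f].nunique() >= 2]
    if not active:
        raise DesignError("no predictor has at least 2 levels")
    terms = [t for t in GLOBAL_TERMS
             if all(f in active for f in t.split(":"))]
    formula = "value ~ " + " + ".join(
        ":".join(f"C({f})" for f in t.split(":")) for t in terms
    )
    fit = smf.ols(formula, data=long).fit()
    rename = {
        ":".join(f"C({f})" for f in t.split(":")): t for t in terms
    }
    return AnovaResult(table=_anova_frame(fit, rename),
                       n_observations=len(long))


@dataclass(frozen=True)
class TraitModelSet:
    """Per-trait species x infection models on the scaled table.

    ``interaction_p`` has one row per trait with the raw and the
    Bonferroni-adjusted (family = all traits) p-value of the
    species:infected interaction.
    """

    anovas: dict[str, AnovaResult]
    fits: dict = field(repr=False, default_factory=dict)
    interaction_p: pd.DataFrame = field(default_factory=pd.DataFrame)
    family_size: int = 0


def fit_trait_models(scaled: ScaledTable) -> TraitModelSet:
    """Fit ``value ~ species * infected`` separately for every trait.

    Returns the per-trait sequential ANOVA tables, the fitted models
    (for contrast extraction) and the interaction p-values adjusted
    across the trait family.
    """
    table = scaled.table
    _check_design(table.data)
    anovas: dict[str, AnovaResult] = {}
    fits: dict = {}
    raws = []
    rename = {
        "C(species)": "species",
        "C(infected)": "infected",
        "C(species):C(infected)": "species:infected",
    }
    for trait in table.registry:
        df = table.data[["species", "infected", trait]].rename(
            columns={trait: "value"}
        )
        fit = smf.ols(
            "value ~ C(species) + C(infected) + C(species):C(infected)",
            data=df,
        ).fit()
        res = AnovaResult(table=_anova_frame(fit, rename),
                          n_observations=len(df))
        anovas[trait] = res
        fits[trait] = fit
        raws.append(res.p_of("species:infected"))
    m = len(table.registry)
    interaction = pd.DataFrame(
        {
            "trait": list(table.registry),
            "p_raw": raws,
            "p_adjusted": bonferroni(raws, m),
        }
    )
    return TraitModelSet(anovas=anovas, fits=fits, interaction_p=interaction,
                         family_size=m)


def estimate_contrasts(
    model_set: TraitModelSet, family_size: int | None = None
) -> pd.DataFrame:
    """Uninfected-minus-infected marginal-mean contrast per species x trait.

    The estimate is the difference of the model's predicted cell means,
    with SE from the OLS coefficient covariance, a t statistic on the
    residual df, a two-sided raw p, and a Bonferroni-adjusted p.  The
    default family size is the number of traits (one family per
    species); pass ``family_size`` to declare a different family.
    """
    if family_size is None:
        family_size = max(len(model_set.anovas), 1)
    rows = []
    for trait, fit in model_set.fits.items():
        design_info = fit.model.data.design_info
        species_levels = sorted(fit.model.data.frame["species"].unique())
        for sp in species_levels:
            cells = pd.DataFrame(
                {"species": [sp, sp], "infected": [False, True]}
            )
            (exog,) = build_design_matrices([design_info], cells)
            L = np.asarray(exog)[0] - np.asarray(exog)[1]  # un - inf
            tt = fit.t_test(L)
            rows.append(
                {
                    "species": sp,
                    "trait": trait,
                    "estimate": float(tt.effect.item()),
                    "se": float(tt.sd.item()),
                    "t": float(tt.tvalue.item()),
                    "df": float(fit.df_resid),
                    "p_raw": float(tt.pvalue.item()),
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bonferroni(out["p_raw"], family_size)
    return out


def residual_diagnostics(fit, outdir, prefix: str = "model") -> list[str]:
    """Write residual-vs-fitted and normal-quantile plots for a fit.

    Visual checks only; nothing is gated on them.  Returns the two file
    paths.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resid = np.asarray(fit.resid)
    fitted = np.asarray(fit.fittedvalues)

    paths = []
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(fitted, resid, s=8, alpha=0.6)
    ax.axhline(0.0, color="grey", lw=1)
    ax.set_xlabel("fitted value")
    ax.set_ylabel("residual")
    ax.set_title("Residuals vs fitted")
    p1 = outdir / f"{prefix}_resid_vs_fitted.png"
    fig.savefig(p1, dpi=120)
    plt.close(fig)
    paths.append(str(p1))

    fig, ax = plt.subplots(figsize=(5, 4))
    scipy.stats.probplot(resid, dist="norm", plot=ax)
    ax.set_title("Normal Q-Q of residuals")
    p2 = outdir / f"{prefix}_qq.png"
    fig.savefig(p2, dpi=120)
    plt.close(fig)
    paths.append(str(p2))
    return paths
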