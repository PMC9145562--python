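"""Scaling, sequential ANOVA, contrasts: oracles and bookkeeping."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from antmorph import (
    SpecimenTable,
    TRAIT_CODES,
    bonferroni,
    estimate_contrasts,
    fit_global_model,
    fit_trait_models,
    scale_by_species,
)
from antmorph.anova import GLOBAL_TERMS, ScaledTable, residual_diagnostics
from antmorph.errors import DegenerateScaleError, DesignError
from conftest import make_table


def _constant_trait_table(values_by_cell):
    """All 21 traits share the same per-specimen value; cells given as
    {(species, infected): [values]}."""
    rows = []
    i = 0
    for (species, infected), values in values_by_cell.items():
        for v in values:
            row = {"specimen_id": f"s{i}", "species": species,
                   "infected": infected}
            row.update({t: float(v) for t in TRAIT_CODES})
            rows.append(row)
            i += 1
    return SpecimenTable.from_dataframe(pd.DataFrame(rows))


# -- scaling ----------------------------------------------------------


def test_scale_three_values_gives_unit_z_scores():
    t = _constant_trait_table({("a", False): [1, 2], ("a", True): [3]})
    scaled = scale_by_species(t)
    np.testing.assert_allclose(
        scaled.table.data["CL"].to_numpy(), [-1.0, 0.0, 1.0], atol=1e-12
    )


def test_scaling_is_mean0_sd1_within_species(study_table):
    scaled = scale_by_species(study_table)
    for species, grp in scaled.table.data.groupby("species"):
        for trait in TRAIT_CODES:
            assert abs(grp[trait].mean()) < 1e-10
            assert abs(grp[trait].std(ddof=1) - 1.0) < 1e-10


def test_scale_invert_round_trip(study_table):
    scaled = scale_by_species(study_table)
    back = scaled.invert()
    np.testing.assert_allclose(
        back.trait_matrix(), study_table.trait_matrix(), rtol=1e-12
    )


def test_constant_trait_raises_degenerate_scale_error():
    t = _constant_trait_table({("a", False): [5, 5], ("a", True): [5, 5]})
    with pytest.raises(DegenerateScaleError) as exc:
        scale_by_species(t)
    assert exc.value.species == "a"


# -- global model -----------------------------------------------------


def test_global_model_terms_in_canonical_order(study_table):
    res = fit_global_model(scale_by_species(study_table).to_long())
    assert list(res.table.index) == list(GLOBAL_TERMS) + ["Residuals"]


def test_global_model_df_bookkeeping_and_ss_decomposition(study_table):
    long = scale_by_species(study_table).to_long()
    res = fit_global_model(long)
    assert int(res.table["df"].sum()) == len(long) - 1
    total_ss = ((long["value"] - long["value"].mean()) ** 2).sum()
    np.testing.assert_allclose(res.table["sum_sq"].sum(), total_ss,
                               rtol=1e-8)


def test_global_model_reduces_to_two_group_f_equals_t_squared():
    """One species, one trait: the infection F must equal the squared
    pooled-variance two-sample t statistic."""
    rng = np.random.default_rng(0)
    a, b = rng.normal(10, 1, 12), rng.normal(11, 1, 9)
    long = pd.DataFrame(
        {
            "value": np.concatenate([a, b]),
            "infected": [False] * 12 + [True] * 9,
            "species": "sp",
            "trait": "CL",
        }
    )
    res = fit_global_model(long)
    t_stat, _ = scipy.stats.ttest_ind(a, b, equal_var=True)
    np.testing.assert_allclose(res.table.loc["infected", "F"], t_stat ** 2,
                               rtol=1e-10)
    assert res.residual_df == 21 - 2


def test_empty_cell_raises_design_error():
    t = _constant_trait_table(
        {("a", False): [1, 2, 3], ("a", True): [2, 3, 4],
         ("b", False): [1, 2, 4]}
    )
    with pytest.raises(DesignError) as exc:
        fit_global_model(t.to_long())
    assert ("b", True) in exc.value.empty_cells


# -- per-trait models -------------------------------------------------


def test_per_trait_dfs_on_published_design(study_table):
    ms = fit_trait_models(scale_by_species(study_table))
    assert len(ms.anovas) == 21
    for res in ms.anovas.values():
        assert res.df_of("species") == 2
        assert res.df_of("infected") == 1
        assert res.df_of("species:infected") == 2
        assert res.residual_df == 81 - 6


def test_bonferroni_adjustment_arithmetic():
    np.testing.assert_allclose(bonferroni(0.0122, 21), 0.2562)
    assert float(np.round(bonferroni(0.0122, 21), 3)) == 0.256
    assert bonferroni(0.9, 21) == 1.0  # clipped at 1
    p = np.array([0.001, 0.04])
    np.testing.assert_allclose(bonferroni(p, 21), [0.021, 0.84])


def test_interaction_p_adjusted_equals_min_one_m_times_raw(study_table):
    ms = fit_trait_models(scale_by_species(study_table))
    np.testing.assert_allclose(
        ms.interaction_p["p_adjusted"],
        np.minimum(1.0, 21 * ms.interaction_p["p_raw"]),
    )


# -- contrasts --------------------------------------------------------


def _scaled_from_values(values_by_cell):
    """ScaledTable wrapper around hand-set (already scaled) values."""
    rows = []
    i = 0
    for (species, infected), values in values_by_cell.items():
        for v in values:
            row = {"specimen_id": f"s{i}", "species": species,
                   "infected": infected}
            row.update({t: float(v) for t in TRAIT_CODES})
            rows.append(row)
            i += 1
    table = SpecimenTable.from_dataframe(pd.DataFrame(rows),
                                         check_traits=False)
    return ScaledTable(table=table, scaling=pd.DataFrame(), ddof=1)


def test_balanced_contrast_equals_cell_mean_difference_exactly():
    scaled = _scaled_from_values(
        {
            ("a", False): [0.9, 1.1],   # uninfected mean exactly 1
            ("a", True): [-0.1, 0.1],   # infected mean exactly 0
            ("b", False): [2.0, 4.0],
            ("b", True): [1.0, 1.5],
        }
    )
    ct = estimate_contrasts(fit_trait_models(scaled))
    row = ct[(ct["species"] == "a") & (ct["trait"] == "CL")].iloc[0]
    np.testing.assert_allclose(row["estimate"], 1.0, atol=1e-12)
    row_b = ct[(ct["species"] == "b") & (ct["trait"] == "CL")].iloc[0]
    np.testing.assert_allclose(row_b["estimate"], 3.0 - 1.25, atol=1e-12)


def test_contrast_sign_pattern_on_study_like_scenario(study_table):
    """Uninfected minus infected: positive for the two shrinking
    species, negative for the enlarging one."""
    ct = estimate_contrasts(fit_trait_models(scale_by_species(study_table)))
    means = ct.groupby("species")["estimate"].mean()
    assert means["T_nylanderi"] > 0
    assert means["T_sordidulus"] > 0
    assert means["T_unifasciatus"] < 0


def test_contrasts_match_r_emmeans_oracle(tmp_path):
    """Independent oracle: R's emmeans on the same per-trait model must
    reproduce estimate, SE, df and p."""
    t = make_table({"a": (6, 4), "b": (5, 7)}, seed=3,
                   infection_shift=-8.0)
    scaled = scale_by_species(t)
    ct = estimate_contrasts(fit_trait_models(scaled))
    data = scaled.table.data[["species", "infected", "CL"]].rename(
        columns={"CL": "value"}
    )
    data = data.assign(infected=np.where(data["infected"], "inf", "un"))
    csv_in = tmp_path / "d.csv"
    csv_out = tmp_path / "emm.csv"
    data.to_csv(csv_in, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(emmeans))
        d <- read.csv("{csv_in}")
        d$species <- factor(d$species)
        d$infected <- factor(d$infected, levels = c("un", "inf"))
        m <- lm(value ~ species * infected, data = d)
        ct <- as.data.frame(pairs(emmeans(m, ~ infected | species),
                                  adjust = "none"))
        write.csv(ct, "{csv_out}", row.names = FALSE)
    """)
    rfile = tmp_path / "emm.R"
    rfile.write_text(script)
    subprocess.run(["Rscript", str(rfile)], check=True, capture_output=True)
    oracle = pd.read_csv(csv_out)
    for sp in ("a", "b"):
        mine = ct[(ct["species"] == sp) & (ct["trait"] == "CL")].iloc[0]
        theirs = oracle[oracle["species"] == sp].iloc[0]
        np.testing.assert_allclose(mine["estimate"], theirs["estimate"],
                                   rtol=1e-8)
        np.testing.assert_allclose(mine["se"], theirs["SE"], rtol=1e-8)
        assert mine["df"] == theirs["df"]
        np.testing.assert_allclose(mine["p_raw"], theirs["p.value"],
                                   rtol=1e-6)


def test_contrast_recovery_within_2_se_at_large_n():
    """A -0.8 SD simulated infection effect is recovered (as +0.8
    uninfected minus infected) within 2 SE at n = 200 per cell."""
    from dataclasses import replace

    from antmorph import default_study_scenario, generate

    spec = default_study_scenario(seed=42).with_counts(200, 200)
    spec = replace(spec, species=spec.species[:1])  # shift -0.8 species
    table = generate(spec)
    ct = estimate_contrasts(fit_trait_models(scale_by_species(table)))
    mean_est = ct["estimate"].mean()
    mean_se = ct["se"].mean()
    assert abs(mean_est - 0.8) < 2 * mean_se


# -- diagnostics ------------------------------------------------------


def test_residual_diagnostics_writes_two_plots(tmp_path, study_table):
    ms = fit_trait_models(scale_by_species(study_table))
    paths = residual_diagnostics(ms.fits["CL"], tmp_path, prefix="CL")
    assert len(paths) == 2
    for p in paths:
        assert (tmp_path / p.split("/")[-1]).stat().st_size > 0
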