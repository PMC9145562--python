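"""End-to-end orchestration: validate -> scale -> anova -> classify ->
reconstruct -> ordination.

A single :class:`RunConfig` (one global seed, fanned out to per-stage
seeds by fixed offsets) fully determines the run.  Every stage writes
its artifact as delimited text into the output directory and logs its
input/output row counts; the config itself is serialised alongside for
provenance.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import anova as anova_mod
from . import classifier as clf_mod
from . import ordination as ord_mod
from . import reconstruct as rec_mod
from . import synth
from .errors import AntmorphError
from .morphdata import SpecimenTable, read_table, summarize, write_table

__all__ = ["RunConfig", "run_pipeline"]

# fixed per-stage seed offsets from the one global seed
_SEED_SCENARIO = 0
_SEED_CV = 1
_SEED_NN = 2


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input`` (a specimen CSV/TSV) or ``scenario`` (a
    scenario YAML path, or the built-in name ``study_like``) must be
    set.  ``prescale`` controls the measurement scale entering the
    global model: ``factor:0.001`` (micrometres to millimetres, the
    default), ``species-z``, or ``none`` for raw micrometres.
    """

    outdir: str = "antmorph_run"
    input: str | None = None
    scenario: str | None = "study_like"
    seed: int = 0
    prescale: str = "factor:0.001"
    family_size: int | None = None
    cv_k: int = 10
    nn_learning_rate: float = 0.05
    nn_epochs: int = 5000
    averaging: str = "macro"
    make_plots: bool = True

    def nn_config(self) -> clf_mod.NNConfig:
        return clf_mod.NNConfig(
            learning_rate=self.nn_learning_rate,
            epochs=self.nn_epochs,
            seed=self.seed + _SEED_NN,
        )


def _load_input(config: RunConfig, log: logging.Logger) -> SpecimenTable:
    if config.input:
        log.info("stage=load input=%s", config.input)
        return read_table(config.input)
    if config.scenario == "study_like":
        spec = synth.default_study_scenario(seed=config.seed + _SEED_SCENARIO)
    else:
        spec = synth.load_scenario(config.scenario).with_seed(
            config.seed + _SEED_SCENARIO
        )
    log.info("stage=simulate scenario=%s seed=%d", config.scenario,
             spec.seed)
    return synth.generate(spec)


def _prescaled_long(table: SpecimenTable, prescale: str) -> pd.DataFrame:
    if prescale == "species-z":
        return anova_mod.scale_by_species(table).to_long()
    if prescale == "none":
        return table.to_long()
    if prescale.startswith("factor:"):
        factor = float(prescale.split(":", 1)[1])
        long = table.to_long()
        long["value"] *= factor
        return long
    raise AntmorphError(
        f"unknown prescale mode {prescale!r}; use species-z, none or "
        "factor:<x>"
    )


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run every stage and return a name -> path map of the artifacts.

    Any stage error propagates (typed) after being logged with its stage
    name; artifacts of completed stages remain on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("antmorph.pipeline")
    if not any(isinstance(h, logging.FileHandler)
               and Path(getattr(h, "baseFilename", "")) ==
               (outdir / "run.log").resolve()
               for h in log.handlers):
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(logging.INFO)

    artifacts: dict[str, str] = {}
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    artifacts["config"] = str(outdir / "config.yaml")

    stage = "load"
    try:
        table = _load_input(config, log)
        write_table(table, outdir / "table.csv")
        artifacts["table"] = str(outdir / "table.csv")
        summarize(table).to_csv(outdir / "summary.csv", index=False)
        artifacts["summary"] = str(outdir / "summary.csv")
        log.info("stage=load rows=%d species=%d", len(table),
                 len(table.species_levels))

        stage = "anova-global"
        long = _prescaled_long(table, config.prescale)
        global_res = anova_mod.fit_global_model(long)
        global_res.to_frame().to_csv(outdir / "anova_global.csv", index=False)
        artifacts["anova_global"] = str(outdir / "anova_global.csv")
        log.info("stage=anova-global n_obs=%d residual_df=%d", len(long),
                 global_res.residual_df)

        stage = "anova-traits"
        scaled = anova_mod.scale_by_species(table)
        model_set = anova_mod.fit_trait_models(scaled)
        model_set.interaction_p.to_csv(
            outdir / "anova_traits_interaction.csv", index=False
        )
        artifacts["anova_traits"] = str(outdir / "anova_traits_interaction.csv")

        stage = "contrasts"
        contrasts = anova_mod.estimate_contrasts(
            model_set, family_size=config.family_size
        )
        contrasts.to_csv(outdir / "contrasts.csv", index=False)
        artifacts["contrasts"] = str(outdir / "contrasts.csv")
        log.info("stage=contrasts rows=%d", len(contrasts))

        if config.make_plots:
            first_trait = table.registry.names[0]
            artifacts["diagnostics"] = ";".join(
                anova_mod.residual_diagnostics(
                    model_set.fits[first_trait], outdir / "diagnostics",
                    prefix=first_trait,
                )
            )

        stage = "classify"
        report = clf_mod.cross_validate(
            table, k=config.cv_k, config=config.nn_config(),
            seed=config.seed + _SEED_CV, averaging=config.averaging,
        )
        report.to_frame().to_csv(outdir / "cv_report.csv", index=False)
        artifacts["cv_report"] = str(outdir / "cv_report.csv")
        log.info("stage=classify k=%d averaged_accuracy=%.4f", config.cv_k,
                 report.averaged["accuracy"])

        stage = "reconstruct"
        recon = rec_mod.reconstruct_table(table)
        recon.moments.table.to_csv(outdir / "moments.csv", index=False)
        artifacts["moments"] = str(outdir / "moments.csv")
        recon.data.assign(infected=lambda d: d["infected"].astype(int),
                          reconstructed=lambda d:
                          d["reconstructed"].astype(int)).to_csv(
            outdir / "reconstructed.csv", index=False
        )
        artifacts["reconstructed"] = str(outdir / "reconstructed.csv")
        log.info("stage=reconstruct infected_rows=%d",
                 int(recon.data["reconstructed"].sum()))

        stage = "ordination"
        ords = ord_mod.per_species_ordination(table, recon)
        scores = pd.concat(
            [frame.assign(species=sp) for sp, (_, frame) in ords.items()],
            ignore_index=True,
        )
        scores.to_csv(outdir / "pca_scores.csv", index=False)
        artifacts["pca_scores"] = str(outdir / "pca_scores.csv")
        if config.make_plots:
            artifacts["pca_figures"] = ";".join(
                ord_mod.plot_ordination(ords, outdir / "figures")
            )
        log.info("stage=ordination species=%d", len(ords))
    except Exception as exc:
        log.error("stage=%s failed: %s", stage, exc)
        raise
    return artifacts
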