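"""End-to-end pipeline: classify -> stats -> link -> habitual -> tables ->
scenarios -> determinants, with a hash manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition, io, lasso, linkage, substitution
from .config import BREAD_CATEGORIES, PipelineConfig, dump_config
from .habitual import fit_habitual
from .synthetic import generate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def fibre_density_per_person(habitual: pd.DataFrame) -> pd.DataFrame:
    """Per-person bread fibre density: habitual fibre / habitual bread * 100.

    Persons with zero habitual bread intake are dropped (undefined density).
    """
    totals = habitual[habitual["category"] == "total"].pivot(
        index="person_id", columns="quantity", values="habitual"
    )
    totals = totals[totals["bread_grams"] > 0]
    out = pd.DataFrame({
        "person_id": totals.index,
        "fibre_density": 100.0 * totals["fibre_grams"] / totals["bread_grams"],
    }).reset_index(drop=True)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the artifact manifest.

    Any stage error aborts with a :class:`StageError` naming the stage.
    Identical config (including seed) yields identical manifest hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        io.write_csv(df, out / name)
        written.append(out / name)

    # --- inputs -----------------------------------------------------------
    try:
        if config.simulate is not None:
            cohort_cfg = config.simulate.model_copy(update={"seed": config.seed})
            persons, events = generate_cohort(cohort_cfg)
        else:
            persons = io.read_csv_checked(config.persons_csv, "persons")
            events = io.read_csv_checked(config.events_csv, "events")
        if config.samples_csv is not None:
            samples = io.read_csv_checked(config.samples_csv, "samples")
        else:
            from .synthetic import generate_bread_samples

            retail = generate_bread_samples(seed=config.seed)
            bakery = composition.load_bakery_wholegrain_fixture()
            samples = pd.concat([retail, bakery], ignore_index=True)
        _write(persons, "persons.csv")
        _write(events, "events.csv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", exc) from exc

    # --- classification and composition stats ------------------------------
    try:
        samples = composition.classify_samples(samples, config.threshold)
        _write(samples, "samples.csv")
        stats_table = composition.category_stats(samples)
        _write(stats_table, "table1.csv")
        densities = config.density_override or composition.fibre_density_table(stats_table)
        _write(io.densities_to_frame(densities), "densities.csv")
    except Exception as exc:
        raise StageError("bread_composition", exc) from exc

    # --- linkage ------------------------------------------------------------
    try:
        n_days = int(events["recall_day"].max()) if len(events) else 2
        persondays = linkage.link_fibre(events, densities, persons=persons, n_recall_days=n_days)
        _write(persondays, "persondays.csv")
        nonrep = linkage.nonreporter_table(persons, events)
        _write(nonrep, "nonreporters.csv")
    except Exception as exc:
        raise StageError("recall_linkage", exc) from exc

    # --- habitual intake ----------------------------------------------------
    try:
        habitual = fit_habitual(persondays, persons, spec=config.habitual)
        _write(habitual, "habitual.csv")
        bread = habitual[(habitual["quantity"] == "bread_grams") & (habitual["category"] != "total")]
        table2 = linkage.contribution_table(bread, persons)
        _write(table2, "table2.csv")
        fibre = habitual[(habitual["quantity"] == "fibre_grams") & (habitual["category"] != "total")]
        table4 = linkage.contribution_table(fibre, persons)
        _write(table4, "table4.csv")
    except Exception as exc:
        raise StageError("habitual_intake", exc) from exc

    # --- substitution scenarios ---------------------------------------------
    try:
        summaries = []
        for scenario in config.scenarios:
            results, summary = substitution.scenario_deltas(
                persons, events, scenario, densities,
                spec=config.habitual, n_recall_days=n_days,
            )
            _write(results, f"scenario_{scenario.name}_results.csv")
            plot_path = out / f"scenario_{scenario.name}.png"
            substitution.plot_scenario(summary, plot_path)
            summaries.append({
                k: v for k, v in summary.items() if not k.startswith("hist_")
            })
        _write(pd.DataFrame(summaries), "scenario_summary.csv")
    except Exception as exc:
        raise StageError("substitution_scenarios", exc) from exc

    # --- determinants ---------------------------------------------------------
    try:
        density_pp = fibre_density_per_person(habitual).merge(persons, on="person_id")
        det = lasso.select_determinants(density_pp, seed=config.seed)
        table3 = lasso.determinant_report(density_pp, det["selection"])
        _write(table3, "table3.csv")
        fit_json = {
            "selection": det["selection"],
            "fit_all": det["fit_all"].to_dict(),
            "fit_adults": det["fit_adults"].to_dict() if det["fit_adults"] else None,
        }
        (out / "lasso_fit.json").write_text(json.dumps(fit_json, indent=2, sort_keys=True))
        written.append(out / "lasso_fit.json")
    except Exception as exc:
        raise StageError("determinants_selection", exc) from exc

    # --- manifest -------------------------------------------------------------
    # out_dir is a run location, not a scientific parameter: normalize it so
    # that identical configurations hash identically wherever they are run.
    dump_config(config.model_copy(update={"out_dir": Path(".")}), out / "config_resolved.yaml")
    written.append(out / "config_resolved.yaml")
    manifest = {
        "files": {p.name: _sha256(p) for p in sorted(written)},
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
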