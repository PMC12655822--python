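"""End-to-end orchestration: references -> mixtures -> cells -> classifier -> embedding.

``run_pipeline`` executes the full analysis on synthetic (or supplied)
spectra and writes a report bundle: the reference library, the mixture-panel
recovery table with its correlation, the per-cell profile table, the
classifier report (confusion counts and fractions), the mixed-population
prediction summary, the embedding-selection audit, and a machine-readable
run summary.  All randomness derives from the single top-level seed, so two
runs with the same config and seed produce byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, embed, synthetic, unmix
from .config import PipelineConfig
from .spectra import baseline_correct, boxcar_smooth, read_spectrum_table, write_spectrum_table
from .synthetic import (
    MARKERS,
    REPORTER_ORDER,
    ReferenceLibrary,
    PopulationConfig,
    default_reference_library,
)

__all__ = ["PipelineError", "run_pipeline", "build_library", "FLOAT_FORMAT"]

logger = logging.getLogger("serscyto")

FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def build_library(config: PipelineConfig) -> ReferenceLibrary:
    """Build (or read) the five-nanotag reference library."""
    source = config["references"]["source"]
    axis = config.axis_spec()
    if source == "simulate":
        return default_reference_library(axis)
    path = Path(source)
    if not path.exists():
        raise PipelineError("references", f"reference spectrum table not found: {path}")
    spectra = read_spectrum_table(path)
    refs = {s.meta["name"]: s for s in spectra}
    return ReferenceLibrary(axis, refs, "measured")


def _preprocess(spectra, cfg) -> list:
    if not cfg["enabled"]:
        return list(spectra)
    out = []
    for s in spectra:
        s = baseline_correct(
            s,
            n_segments=cfg["n_segments"],
            degree=cfg["degree"],
            n_iterations=cfg["n_iterations"],
            floor_at_zero=cfg["floor_at_zero"],
        )
        out.append(boxcar_smooth(s, cfg["boxcar_window"]))
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run every stage and write the report bundle into ``out_dir``.

    Returns the run summary (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config["seed"] if seed is None else seed
    rng = np.random.default_rng(seed)
    stage_seeds = {
        name: int(s)
        for name, s in zip(
            ("panel", "population", "classifier", "mixed", "embedding"),
            rng.integers(0, 2**31 - 1, size=5),
        )
    }
    logger.info("pipeline start: seed=%s derived seeds=%s", seed, stage_seeds)
    summary: dict = {"seed": seed, "stage_seeds": stage_seeds}

    # --- stage: references -------------------------------------------------
    library = build_library(config)
    write_spectrum_table(list(library.references.values()), out / "references.csv")
    logger.info("references: %d reporters on %d-point axis", len(library.references), len(library.wavenumbers))
    # unmix against references run through the identical preprocessing chain,
    # so weights stay relative to the references as the pipeline sees them
    if config["preprocess"]["enabled"]:
        processed_refs = dict(
            zip(library.references, _preprocess(library.references.values(), config["preprocess"]))
        )
        unmix_library = ReferenceLibrary(library.axis_spec, processed_refs, library.provenance)
    else:
        unmix_library = library

    # --- stage: mixture panel ---------------------------------------------
    try:
        panel = synthetic.make_mixture_panel(
            library,
            config["panel"]["designs"],
            noise_sd=config["panel"]["noise_sd"],
            seed=stage_seeds["panel"],
        )
        rows, results = [], []
        for d, (fractions, spectrum) in enumerate(panel):
            profile = unmix.cls_unmix(spectrum, library, mode=config["unmix"]["mode"])
            recovered = profile.as_array()
            rec_frac = recovered / recovered.sum()
            results.append((fractions, recovered))
            for k, rep in enumerate(REPORTER_ORDER):
                rows.append(
                    {
                        "design": d,
                        "reporter": rep,
                        "true_fraction": fractions[k],
                        "recovered_weight": recovered[k],
                        "recovered_fraction": rec_frac[k],
                    }
                )
        pd.DataFrame(rows).to_csv(out / "mixture_recovery.csv", index=False, float_format=FLOAT_FORMAT)
        corr = unmix.recovery_correlation(results)
        summary["mixture_recovery"] = {
            "r": corr.r, "p": corr.p, "slope": corr.slope, "intercept": corr.intercept, "n": corr.n,
        }
        logger.info("mixture panel: r=%.4f over %d pairs (seed %d)", corr.r, corr.n, stage_seeds["panel"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("mixture_panel", str(exc)) from exc

    # --- stage: cell population + unmixing ---------------------------------
    try:
        pop_cfg = config["population"]
        kwargs = dict(
            sd=pop_cfg["sd"],
            bounds=tuple(pop_cfg["bounds"]),
            n_per_line=pop_cfg["n_per_line"],
            noise_sd=pop_cfg["noise_sd"],
            baseline_amp=pop_cfg["baseline_amp"],
            seed=stage_seeds["population"],
        )
        if pop_cfg["means"] is not None:
            kwargs["line_means"] = pop_cfg["means"]
        population = PopulationConfig(**kwargs)
        truth, spectra = synthetic.simulate_cell_population(population, library, return_spectra=True)
        spectra = _preprocess(spectra, config["preprocess"])
        profiles = unmix.unmix_spectra(spectra, unmix_library, mode=config["unmix"]["mode"])
        cells = truth[["cell_id", "label", "split"]].merge(profiles, on="cell_id")
        cells.to_csv(out / "cells.csv", index=False, float_format=FLOAT_FORMAT)
        logger.info("population: %d cells unmixed (seed %d)", len(cells), stage_seeds["population"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("population", str(exc)) from exc

    # --- stage: classification ---------------------------------------------
    try:
        clf_cfg = config["classifier"]
        result = classify.repeat_training(
            cells,
            n_iterations=clf_cfg["n_iterations"],
            seed=stage_seeds["classifier"],
            train_fraction=clf_cfg["train_fraction"],
            n_trees=clf_cfg["n_trees"],
            max_depth=clf_cfg["max_depth"],
        )
        classes = result.reports[0].classes
        mean_counts = np.mean([r.confusion_counts for r in result.reports], axis=0)
        mean_fracs = np.mean([r.confusion_fractions for r in result.reports], axis=0)
        pd.DataFrame(mean_counts, index=classes, columns=classes).to_csv(
            out / "confusion_counts.csv", float_format=FLOAT_FORMAT
        )
        pd.DataFrame(mean_fracs, index=classes, columns=classes).to_csv(
            out / "confusion_fractions.csv", float_format=FLOAT_FORMAT
        )
        summary["classifier"] = {
            "mean_macro_f1": result.mean_macro_f1,
            "mean_accuracy": result.mean_accuracy,
            "n_iterations": clf_cfg["n_iterations"],
        }
        logger.info(
            "classifier: mean macro F1 %.4f, mean accuracy %.4f over %d iterations",
            result.mean_macro_f1, result.mean_accuracy, clf_cfg["n_iterations"],
        )

        # retrain on all labelled cells, predict a fresh mixed population
        model = classify.train_forest(
            cells, n_trees=clf_cfg["n_trees"], max_depth=clf_cfg["max_depth"],
            seed=stage_seeds["classifier"],
        )
        mixed_cfg = PopulationConfig(**{**kwargs, "n_per_line": config["mixed_population"]["n_per_line"],
                                        "seed": stage_seeds["mixed"]})
        mixed_truth, mixed_spectra = synthetic.simulate_cell_population(
            mixed_cfg, library, return_spectra=True
        )
        mixed_spectra = _preprocess(mixed_spectra, config["preprocess"])
        mixed_profiles = unmix.unmix_spectra(mixed_spectra, unmix_library, mode=config["unmix"]["mode"])
        prediction = classify.predict_population(model, mixed_profiles)
        train_means = cells.groupby("label")[list(MARKERS)].mean().reindex(model.classes_)
        corr_pred = unmix.pearson_with_slope_p(
            train_means.to_numpy().ravel(), prediction.mean_profiles.to_numpy().ravel()
        )
        prediction.mean_profiles.to_csv(out / "prediction_profiles.csv", float_format=FLOAT_FORMAT)
        summary["prediction"] = {
            "counts": prediction.counts,
            "n_total": prediction.n_total,
            "profile_correlation_r": corr_pred.r,
            "profile_correlation_p": corr_pred.p,
        }
        logger.info("prediction: counts=%s, profile r=%.4f", prediction.counts, corr_pred.r)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("classifier", str(exc)) from exc

    # --- stage: embedding selection -----------------------------------------
    if config["embedding"]["enabled"]:
        try:
            selection = embed.select_perplexity(
                cells,
                cells["label"].to_numpy(),
                perplexities=config["embedding"]["perplexities"],
                n_replicates=config["embedding"]["n_replicates"],
                seed=stage_seeds["embedding"],
            )
            audit = pd.DataFrame(
                {
                    "perplexity": [f.perplexity for f in selection.all_fits],
                    "replicate": [f.replicate for f in selection.all_fits],
                    "kl_divergence": [f.kl_divergence for f in selection.all_fits],
                    "seed": [f.seed for f in selection.all_fits],
                }
            )
            audit["dbi_of_best"] = [
                selection.dbi[f.perplexity]
                if selection.best_fits[f.perplexity].replicate == f.replicate
                else np.nan
                for f in selection.all_fits
            ]
            audit.to_csv(out / "embedding_audit.csv", index=False, float_format=FLOAT_FORMAT)
            coords = pd.DataFrame(selection.chosen_fit.coordinates, columns=["tsne_1", "tsne_2"])
            coords.insert(0, "cell_id", cells["cell_id"].to_numpy())
            coords.to_csv(out / "embedding_coordinates.csv", index=False, float_format=FLOAT_FORMAT)
            summary["embedding"] = {
                "chosen_perplexity": selection.chosen_perplexity,
                "dbi": selection.dbi[selection.chosen_perplexity],
                "kl_divergence": selection.chosen_fit.kl_divergence,
            }
            logger.info(
                "embedding: perplexity %s chosen (DBI %.4f, seed %d)",
                selection.chosen_perplexity,
                selection.dbi[selection.chosen_perplexity],
                stage_seeds["embedding"],
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("embedding", str(exc)) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return summary
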