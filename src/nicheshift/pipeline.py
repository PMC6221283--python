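"""End-to-end scenario orchestration.

One call to :func:`run` takes a configuration (synthetic scenario or
file-based inputs), and produces, per taxon: a fitted model file, per-era
suitability maps (with soil-masked variants when a mask exists), an
evaluation report and per-era suitability extractions at the taxon's
points; and per taxon pair: the PCA environmental space, density grids,
the equivalency test and both directional similarity tests. Every stage
is seeded from one master seed by hashing the stage name, so a rerun with
the same config reproduces every numeric output and any stage can be
rerun in isolation.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import pathlib
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from . import geo_io, maxent, niche_space, overlap, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "summarize_boxplot", "stage_seed"]

PRESENT_ERA = "present"


def stage_seed(master_seed: int, *parts: str) -> int:
    """Deterministically fan a master seed out to a named stage (< 2**31)."""
    h = hashlib.sha256(("/".join(str(p) for p in parts) + f":{master_seed}").encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def summarize_boxplot(values) -> dict:
    """Standard boxplot summary: five numbers, Tukey whiskers, outliers.

    Quantiles use linear interpolation (type 7). Whiskers extend to the
    most extreme data point within 1.5 x IQR of the quartiles; points
    beyond are listed as outliers.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to summarize")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return {
        "n": int(values.size),
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(outliers.size),
        "outliers": [float(v) for v in np.sort(outliers)],
        "quantile_rule": "type7-linear",
    }


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: a synthetic ``scenario`` or file paths
    (``era_stacks`` mapping era -> directory of ``.asc`` layers,
    ``occurrences`` CSV, optional ``soil_mask`` .asc). The master seed is
    fanned out per stage and recorded in every output.
    """

    output_dir: str
    master_seed: int = 0
    scenario: synthetic.ScenarioConfig | None = None
    era_stacks: dict[str, str] = field(default_factory=dict)
    occurrences_csv: str | None = None
    soil_mask_path: str | None = None
    variables: list[str] | None = None
    split_fraction: float = 0.7
    reg_multiplier: float = 1.0
    r_threshold: float = 0.95
    background_n: int = 10000
    R: int = 100
    n_reps: int = 100
    era_order: list[str] | None = None

    def __post_init__(self) -> None:
        synth = self.scenario is not None
        files = bool(self.era_stacks) or self.occurrences_csv is not None
        if synth == files:
            raise ValueError("config must use exactly one input mode: "
                             "synthetic scenario or file paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scenario = None
        if "scenario" in raw:
            scenario = _scenario_from_dict(raw.pop("scenario"))
        return cls(scenario=scenario, **raw)


def _scenario_from_dict(d: dict) -> synthetic.ScenarioConfig:
    taxa = d.pop("taxa", {})
    era_shifts = {k: np.asarray(v, dtype=float) for k, v in d.pop("era_shifts", {}).items()}
    layer_names = tuple(d.pop("layer_names", synthetic.DEFAULT_LAYER_NAMES))
    corr = d.pop("layer_cross_correlation", None)
    cfg = synthetic.ScenarioConfig(
        layer_names=layer_names,
        era_shifts=era_shifts,
        layer_cross_correlation=None if corr is None else np.asarray(corr, dtype=float),
        **{k: (tuple(v) if k == "origin" else v) for k, v in d.items()},
    )
    for name, spec in taxa.items():
        cfg.niches[name] = synthetic.TrueNiche(
            taxon_id=name,
            beta0=float(spec.get("beta0", 0.0)),
            beta_linear=np.asarray(spec.get("beta_linear", np.zeros(cfg.n_layers)), dtype=float),
            beta_quadratic=np.asarray(spec.get("beta_quadratic", np.zeros(cfg.n_layers)), dtype=float),
        )
        cfg.n_occurrences[name] = int(spec.get("n_occurrences", 50))
    cfg.validate()
    return cfg


class _RunLog:
    """Plain-text run log with ISO timestamps (side channel; not part of the
    deterministic numeric outputs)."""

    def __init__(self, path: pathlib.Path):
        self.path = path
        self.fh = open(path, "w")

    def write(self, msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        self.fh.write(f"{stamp} {msg}\n")
        self.fh.flush()

    def close(self) -> None:
        self.fh.close()


def _simulate_inputs(config: RunConfig, out: pathlib.Path, log: _RunLog):
    """Materialize the synthetic scenario: era stacks, soil mask, occurrences."""
    scen = config.scenario
    stack = synthetic.generate_layers(scen, seed=stage_seed(config.master_seed, "layers"))
    soil = synthetic.generate_soil_mask(
        scen.geometry, scen.soil_fraction, scen.soil_patch_scale,
        seed=stage_seed(config.master_seed, "soil"),
    )
    eras = {PRESENT_ERA: stack}
    for era, offsets in scen.era_shifts.items():
        eras[era] = synthetic.apply_era_shift(stack, offsets)
    occ_sets: dict[str, geo_io.OccurrenceSet] = {}
    for taxon, niche in scen.niches.items():
        suit = synthetic.true_suitability(stack, niche)
        occ_sets[taxon] = synthetic.sample_occurrences(
            suit, soil, scen.n_occurrences[taxon],
            seed=stage_seed(config.master_seed, "occ", taxon),
            geometry=scen.geometry, taxon_id=taxon,
        )
    inputs = out / "inputs"
    for era, st in eras.items():
        geo_io.write_stack(st, inputs / f"stack_{era}")
    geo_io.write_ascii_grid(soil.astype(float), scen.geometry, inputs / "soil_mask.asc")
    geo_io.write_occurrences(list(occ_sets.values()), inputs / "occurrences.csv")
    log.write(f"simulated scenario: {len(eras)} eras, {len(occ_sets)} taxa")
    return eras, soil, occ_sets


def _load_inputs(config: RunConfig, log: _RunLog):
    eras = {era: geo_io.read_stack(path) for era, path in config.era_stacks.items()}
    if PRESENT_ERA not in eras:
        raise ValueError(f"file mode requires an era named {PRESENT_ERA!r}")
    soil = None
    if config.soil_mask_path:
        soil_stack = geo_io.read_ascii_grid(config.soil_mask_path)
        soil = (next(iter(soil_stack.layers.values())) > 0).astype(np.int8)
    occ_sets = geo_io.read_occurrences(config.occurrences_csv)
    log.write(f"loaded {len(eras)} era stacks, {len(occ_sets)} taxa")
    return eras, soil, occ_sets


def run(config: RunConfig) -> pathlib.Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure aborts with the stage name in the raised error and
    leaves the partial log on disk.
    """
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out / "run.log")
    log.write(f"master_seed={config.master_seed}")
    stage = "inputs"
    try:
        if config.scenario is not None:
            eras, soil, occ_sets = _simulate_inputs(config, out, log)
        else:
            eras, soil, occ_sets = _load_inputs(config, log)
        present = eras[PRESENT_ERA]
        era_order = config.era_order or sorted(e for e in eras if e != PRESENT_ERA) + [PRESENT_ERA]

        stage = "variable_selection"
        n_occ_total = min(len(o) for o in occ_sets.values())
        selection = maxent.select_variables(
            present.select(config.variables) if config.variables else present,
            r_threshold=config.r_threshold, n_occurrences=n_occ_total,
        )
        pd.DataFrame({"kept": selection.kept}).to_csv(out / "variables_kept.csv", index=False)
        log.write(f"variables kept: {selection.kept} (guard_ok={selection.guard_ok})")
        work = {era: st.select(selection.kept) for era, st in eras.items()}
        present = work[PRESENT_ERA]

        stage = "background"
        background = maxent.sample_background(
            present, n=config.background_n,
            seed=stage_seed(config.master_seed, "background"),
        )

        models: dict[str, maxent.MaxEntModel] = {}
        occ_env: dict[str, pd.DataFrame] = {}
        suitability_rows = []
        eval_rows = []
        for taxon, occ in occ_sets.items():
            stage = f"fit:{taxon}"
            occ = geo_io.dedupe_per_pixel(occ, present.geometry)
            occ_sets[taxon] = occ
            train, test = maxent.split_occurrences(
                occ, config.split_fraction,
                seed=stage_seed(config.master_seed, "split", taxon),
            )
            train_env = geo_io.extract_at_points(present, train.points)
            test_env = geo_io.extract_at_points(present, test.points)
            train_env = train_env[train_env["flag"] == "ok"]
            test_env = test_env[test_env["flag"] == "ok"]
            model = maxent.fit_maxent(
                train_env, background, reg_multiplier=config.reg_multiplier,
            )
            model.save(out / f"model_{taxon}.txt")
            models[taxon] = model

            stage = f"evaluate:{taxon}"
            report_test = maxent.evaluate(model, test_env, background,
                                          n_train=len(train_env))
            report_train = maxent.evaluate(model, train_env, background,
                                           n_train=len(train_env))
            eval_rows.append({"taxon": taxon, "split": "test", **report_test.to_dict()})
            eval_rows.append({"taxon": taxon, "split": "train", **report_train.to_dict()})
            log.write(f"{taxon}: test AUC={report_test.auc:.3f} TSS={report_test.tss:.3f}")

            stage = f"project:{taxon}"
            for era in era_order:
                suit = models[taxon].predict_stack(work[era])
                geo_io.write_ascii_grid(suit, present.geometry,
                                        out / f"suitability_{taxon}_{era}.asc")
                if soil is not None:
                    masked = maxent.apply_soil_mask(suit, soil)
                    geo_io.write_ascii_grid(masked, present.geometry,
                                            out / f"suitability_{taxon}_{era}_soil.asc")
                stage = f"extract:{taxon}:{era}"
                ext = geo_io.extract_at_points(work[era], occ.points)
                scores = models[taxon].predict(ext[ext["flag"] == "ok"])
                for pid, val in zip(ext[ext["flag"] == "ok"]["point_id"], scores):
                    suitability_rows.append(
                        {"taxon": taxon, "era": era, "point_id": int(pid),
                         "suitability": float(val)}
                    )
            occ_env[taxon] = geo_io.extract_at_points(present, occ.points)
            occ_env[taxon] = occ_env[taxon][occ_env[taxon]["flag"] == "ok"]

        pd.DataFrame(eval_rows).to_csv(out / "evaluation.csv", index=False)
        suit_df = pd.DataFrame(suitability_rows)
        suit_df.to_csv(out / "suitability_at_points.csv", index=False)
        box_rows = []
        for (taxon, era), grp in suit_df.groupby(["taxon", "era"], sort=False):
            summary = summarize_boxplot(grp["suitability"])
            summary.pop("outliers")
            box_rows.append({"taxon": taxon, "era": era, **summary})
        pd.DataFrame(box_rows).to_csv(out / "suitability_boxplots.csv", index=False)

        stage = "niche_comparison"
        space = niche_space.fit_pca_env(background, variables=selection.kept)
        space.to_frame().to_csv(out / "pca_loadings.csv")
        bg_scores = niche_space.project_scores(space, background)
        comparison_rows = []
        taxa = list(occ_sets)
        for ta, tb in itertools.combinations(taxa, 2):
            stage = f"compare:{ta}:{tb}"
            sa = niche_space.project_scores(space, occ_env[ta])
            sb = niche_space.project_scores(space, occ_env[tb])
            eq = overlap.equivalency_test(
                sa, sb, bg_scores, bg_scores, R=config.R, n_reps=config.n_reps,
                seed=stage_seed(config.master_seed, "equivalency", ta, tb),
            )
            sim_ab = overlap.similarity_test(
                sa, sb, bg_scores, bg_scores, R=config.R, n_reps=config.n_reps,
                seed=stage_seed(config.master_seed, "similarity", ta, tb),
                direction=(ta, tb),
            )
            sim_ba = overlap.similarity_test(
                sb, sa, bg_scores, bg_scores, R=config.R, n_reps=config.n_reps,
                seed=stage_seed(config.master_seed, "similarity", tb, ta),
                direction=(tb, ta),
            )
            for res in (eq, sim_ab, sim_ba):
                comparison_rows.append({"taxon_a": ta, "taxon_b": tb, **res.to_dict()})
                tag = res.kind if res.direction is None else f"{res.kind}_{res.direction[0]}_to_{res.direction[1]}"
                pd.DataFrame({"replicate": np.arange(res.n_reps),
                              "null_D": res.null_D}).to_csv(
                    out / f"null_{ta}_vs_{tb}_{tag}.csv", index=False)
                with open(out / f"hist_{ta}_vs_{tb}_{tag}.json", "w") as fh:
                    json.dump(res.histogram(), fh, indent=1)
            log.write(f"{ta} vs {tb}: D={eq.D_obs:.4f} "
                      f"equivalency p={eq.p_value:.4f} ({eq.verdict})")
        pd.DataFrame(comparison_rows).to_csv(out / "niche_comparisons.csv", index=False)
        with open(out / "run_meta.json", "w") as fh:
            json.dump({"master_seed": config.master_seed, "eras": era_order,
                       "taxa": taxa, "variables": selection.kept,
                       "R": config.R, "n_reps": config.n_reps}, fh, indent=1)
        log.write("run complete")
    except Exception as exc:
        log.write(f"FAILED at stage {stage}: {exc}")
        log.close()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    log.close()
    return out
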