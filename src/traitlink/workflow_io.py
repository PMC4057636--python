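"""File formats, the packaged twin-correlation table, and the end-to-end
pipeline runner.

All tabular artifacts are comma-delimited text: response matrices (one
header row of item ids; first columns ``person_id``, ``cohort_id``; missing
cell ``NA``), item keys, twin score files, calibrations and latent scores.
Structured results (meta-analysis fits, pipeline status) are JSON.

The packaged fixture ``data/table1.csv`` transcribes the published
sex-by-zygosity twin correlations and pair counts for the six twin cohorts
(27 correlations per trait; pooled "All" rows excluded); it is verified
against a checksum at load time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InvalidParameterError
from .irt_core import MISSING, Calibration, CalibrationOptions, ItemParameters, LatentScores, ResponseMatrix

logger = logging.getLogger(__name__)

TABLE1_SHA256 = "5cc042176e40c349d1c3ef730c1d7b88302f2241cee13567c8119b5d5d7541b9"


# ---------------------------------------------------------------------------
# response matrices and item keys
# ---------------------------------------------------------------------------


def write_item_key(key: pd.DataFrame, path: str | Path) -> None:
    cols = ["item_id", "inventory", "trait", "n_categories", "reverse_keyed"]
    key[cols].to_csv(path, index=False)


def read_item_key(path: str | Path) -> pd.DataFrame:
    key = pd.read_csv(path)
    needed = {"item_id", "inventory", "trait", "n_categories", "reverse_keyed"}
    if not needed.issubset(key.columns):
        raise ConfigurationError(f"item key must have columns {sorted(needed)}")
    return key


def write_response_matrix(responses: ResponseMatrix, path: str | Path) -> None:
    df = pd.DataFrame(responses.values, columns=responses.item_ids)
    df = df.mask(df < 0)
    df.insert(0, "cohort_id", responses.cohort_ids)
    df.insert(0, "person_id", responses.person_ids)
    df.to_csv(path, index=False, na_rep="NA")


def read_response_matrix(path: str | Path, item_key: pd.DataFrame) -> ResponseMatrix:
    """Read a delimited response matrix, validating codes against the item
    key and recoding reverse-keyed items so calibration always sees
    positively keyed codes."""
    df = pd.read_csv(path, na_values=["NA"])
    if "person_id" not in df.columns or "cohort_id" not in df.columns:
        raise ConfigurationError("response file must start with person_id, cohort_id columns")
    item_ids = [c for c in df.columns if c not in ("person_id", "cohort_id")]
    known = set(item_key["item_id"])
    unknown = [i for i in item_ids if i not in known]
    if unknown:
        raise ConfigurationError(f"unknown item ids in response file: {unknown}")
    kinfo = item_key.set_index("item_id")
    values = np.full((len(df), len(item_ids)), MISSING, dtype=np.int64)
    for col, iid in enumerate(item_ids):
        raw = df[iid].to_numpy(float)
        obs = ~np.isnan(raw)
        codes = raw[obs].astype(np.int64)
        k = int(kinfo.loc[iid, "n_categories"])
        bad = (codes < 0) | (codes >= k)
        if bad.any():
            row = df.index[obs][int(np.flatnonzero(bad)[0])]
            raise InvalidParameterError(
                f"code {codes[bad][0]} out of range for {k}-category item {iid!r} (row {row})"
            )
        if int(kinfo.loc[iid, "reverse_keyed"]):
            codes = (k - 1) - codes
        values[obs, col] = codes
    return ResponseMatrix(
        values, df["person_id"].to_numpy(), item_ids, df["cohort_id"].to_numpy()
    )


# ---------------------------------------------------------------------------
# calibrations and scores
# ---------------------------------------------------------------------------


def write_calibration(calib: Calibration, path: str | Path) -> None:
    kmax = max(p.thresholds.size for p in calib.items.values())
    rows = []
    for iid, p in calib.items.items():
        row = {"item_id": iid, "discrimination": p.discrimination}
        for t in range(kmax):
            row[f"threshold_{t + 1}"] = p.thresholds[t] if t < p.thresholds.size else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calibration(path: str | Path) -> Calibration:
    df = pd.read_csv(path)
    tcols = sorted(
        (c for c in df.columns if c.startswith("threshold_")), key=lambda c: int(c.split("_")[1])
    )
    items = {}
    for _, row in df.iterrows():
        th = row[tcols].to_numpy(float)
        th = th[~np.isnan(th)]
        items[str(row["item_id"])] = ItemParameters(float(row["discrimination"]), th)
    return Calibration(items=items)


def write_scores(scores: LatentScores, path: str | Path) -> None:
    pd.DataFrame(
        {
            "person_id": scores.person_ids,
            "cohort_id": scores.cohort_ids,
            "score": scores.score,
            "sd": scores.sd,
            "n_items": scores.n_items,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# twin score files and the packaged correlation table
# ---------------------------------------------------------------------------


def write_twin_data(data: pd.DataFrame, path: str | Path) -> None:
    data[["cohort", "group", "age", "score1", "score2"]].to_csv(path, index=False, na_rep="NA")


def read_twin_data(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"])
    needed = {"cohort", "group", "age", "score1", "score2"}
    if not needed.issubset(df.columns):
        raise ConfigurationError(f"twin file must have columns {sorted(needed)}")
    if (df["score1"].isna() & df["score2"].isna()).any():
        raise InvalidParameterError("twin records need at least one observed score")
    return df


def load_table1_fixture(trait: str | None = None) -> pd.DataFrame:
    """The packaged table of published twin correlations (27 per trait).

    Columns: cohort, group (MZM/DZM/MZF/DZF/DOS), trait, r, n, ci_low,
    ci_high.  Pooled across-sex rows are not part of the fixture — the
    meta-analysis operates on the sex-by-zygosity rows only.  The file's
    checksum is verified so silent edits of transcribed data cannot pass
    unnoticed.
    """
    ref = resources.files("traitlink").joinpath("data/table1.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise ConfigurationError(
            "packaged twin-correlation table failed its checksum; refusing to use it"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    if trait is not None:
        if trait not in set(df["trait"]):
            raise ConfigurationError(f"unknown trait {trait!r}")
        df = df[df["trait"] == trait].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_KNOWN_STAGES = ("simulate", "calibrate", "score", "dif", "twinmeta", "power")


@dataclass
class PipelineConfig:
    """Which stages to run, with per-stage option blocks.

    Unknown stage names or option keys are rejected rather than ignored so a
    typo cannot silently disable an analysis choice.
    """

    stages: list[str] = field(default_factory=lambda: list(_KNOWN_STAGES))
    seed: int = 0
    out_dir: str | Path = "pipeline_out"
    simulate: dict = field(default_factory=dict)
    dif: dict = field(default_factory=dict)
    twinmeta: dict = field(default_factory=dict)
    power: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _KNOWN_STAGES]
        if unknown:
            raise ConfigurationError(f"unknown pipeline stages {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {"stages", "seed", "out_dir", "simulate", "dif", "twinmeta", "power", "log_level"}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order, writing every intermediate artifact.

    Returns ``{"status": 0, "artifacts": {...}}`` on success; a stage
    failure halts the run and returns status 1 with a stage-named message.
    Every stochastic stage logs its effective seed.
    """
    from . import invariance, linking, power_study, synthetic_data, twin_meta
    from .irt_core import calibrate_mml, score_eap

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    state: dict = {}
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(_KNOWN_STAGES, ss.spawn(len(_KNOWN_STAGES)))
    }

    def _artifact(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    current_stage = "none"
    try:
        if "simulate" in config.stages:
            current_stage = "simulate"
            seed = stage_seeds["simulate"]
            logger.info("stage simulate: seed=%d", seed)
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", seed)
            sim_config = synthetic_data.SimulationConfig(**sim_kwargs)
            study = synthetic_data.simulate_study(sim_config)
            state["study"] = study
            write_response_matrix(study.responses, out / "responses.csv")
            write_item_key(study.item_key, out / "item_key.csv")
            _artifact("responses", out / "responses.csv")
            _artifact("item_key", out / "item_key.csv")
            twins = synthetic_data.gen_twin_pairs(
                synthetic_data.TwinSimConfig(seed=seed + 1)
            )
            state["twins"] = twins
            write_twin_data(twins, out / "twins.csv")
            _artifact("twins", out / "twins.csv")

        if "calibrate" in config.stages:
            current_stage = "calibrate"
            study = state.get("study")
            if study is None:
                raise ConfigurationError("calibrate stage requires the simulate stage")
            logger.info("stage calibrate: concurrent calibration per cohort")
            design = linking.LinkingDesign(study.inventories)
            calibs = {}
            for cohort in np.unique(study.responses.cohort_ids):
                sub = study.responses.subset_persons(study.responses.cohort_ids == cohort)
                calib = linking.concurrent_calibration(sub, design)
                calibs[cohort] = calib
                path = out / f"calibration_{cohort}.csv"
                write_calibration(calib, path)
                _artifact(f"calibration_{cohort}", path)
            state["calibrations"] = calibs

        if "score" in config.stages:
            current_stage = "score"
            study, calibs = state.get("study"), state.get("calibrations")
            if study is None or calibs is None:
                raise ConfigurationError("score stage requires simulate and calibrate stages")
            logger.info("stage score: EAP scores from richest calibration")
            blocks = []
            for cohort, calib in calibs.items():
                sub = study.responses.subset_persons(study.responses.cohort_ids == cohort)
                blocks.append(score_eap(sub, calib))
            scores = LatentScores(
                np.concatenate([b.person_ids for b in blocks]),
                np.concatenate([b.cohort_ids for b in blocks]),
                np.concatenate([b.score for b in blocks]),
                np.concatenate([b.sd for b in blocks]),
                np.concatenate([b.n_items for b in blocks]),
            )
            write_scores(scores, out / "scores.csv")
            _artifact("scores", out / "scores.csv")

        if "dif" in config.stages:
            current_stage = "dif"
            study = state.get("study")
            if study is None:
                raise ConfigurationError("dif stage requires the simulate stage")
            seed = stage_seeds["dif"]
            opts = dict(config.dif)
            cap = int(opts.pop("cap", 500))
            sweeps = int(opts.pop("n_sweeps", 1200))
            burn = int(opts.pop("burn_in", 400))
            logger.info("stage dif: seed=%d cap=%d sweeps=%d", seed, cap, sweeps)
            sub = invariance.subsample_cohorts(study.responses, cap, seed=seed)
            complete = (sub.values >= 0).all(axis=1)
            sub = sub.subset_persons(complete)
            model = invariance.fit_hierarchical(
                sub, invariance.McmcOptions(n_sweeps=sweeps, burn_in=burn, seed=seed)
            )
            report = invariance.dif_report(model)
            pd.DataFrame(
                [
                    {"item_id": e.item_id, "bayes_factor": e.bayes_factor, "classification": e.classification}
                    for e in report
                ]
            ).to_csv(out / "dif_report.csv", index=False)
            moments = invariance.cohort_moments(model)
            pd.DataFrame(
                {
                    "cohort": moments.cohorts,
                    "mean": moments.mean,
                    "mean_se": moments.mean_se,
                    "variance": moments.variance,
                    "variance_se": moments.variance_se,
                }
            ).to_csv(out / "cohort_moments.csv", index=False)
            _artifact("dif_report", out / "dif_report.csv")
            _artifact("cohort_moments", out / "cohort_moments.csv")

        if "twinmeta" in config.stages:
            current_stage = "twinmeta"
            logger.info("stage twinmeta")
            opts = dict(config.twinmeta)
            source = opts.pop("source", "fixture")
            trait = opts.pop("trait", "neuroticism")
            if source == "fixture":
                table = load_table1_fixture(trait)
            else:
                twins = state.get("twins")
                if twins is None:
                    raise ConfigurationError("twinmeta on simulated data requires simulate stage")
                fits = [twin_meta.fit_saturated_twin(twins, c) for c in twins["cohort"].unique()]
                table = twin_meta.correlation_table(fits)
            table.to_csv(out / "twin_correlations.csv", index=False)
            result = twin_meta.lrt_sequence(table)
            sel = result["selected"]
            payload = {
                "comparisons": result["comparisons"],
                "selected_model": sel.model,
                "chisq": sel.chisq,
                "df": sel.df,
                "h2_m": sel.params.h2_m,
                "h2_f": sel.params.h2_f,
                "d2_m": sel.params.d2_m,
                "d2_f": sel.params.d2_f,
                "r_dos_free": sel.params.r_dos_free,
            }
            (out / "meta.json").write_text(json.dumps(payload, indent=2))
            _artifact("twin_correlations", out / "twin_correlations.csv")
            _artifact("meta", out / "meta.json")

        if "power" in config.stages:
            current_stage = "power"
            seed = stage_seeds["power"]
            opts = dict(config.power)
            n_reps = int(opts.pop("n_reps", 20))
            logger.info("stage power: seed=%d n_reps=%d", seed, n_reps)
            bank = synthetic_data.default_item_bank(
                [synthetic_data.InventorySpec("A", 12, 5), synthetic_data.InventorySpec("B", 12, 5)],
                seed=seed,
            )
            all_items = list(bank)
            short_items = all_items[:12]
            snp_small = synthetic_data.SnpDesign(maf=0.5, q2=0.009, n=1000)
            snp_large = synthetic_data.SnpDesign(maf=0.5, q2=0.009, n=3000)
            scen = [
                power_study.PowerScenario(
                    "short-inventory", {i: bank[i] for i in short_items},
                    [(1.0, short_items)], snp_small, n_reps=n_reps, seed=seed,
                ),
                power_study.PowerScenario(
                    "linked-inventories", bank, [(1.0, all_items)], snp_large,
                    n_reps=n_reps, seed=seed + 1,
                ),
            ]
            ests = [power_study.run_power_scenario(s) for s in scen]
            pd.DataFrame(power_study.compare_schemes(ests)).to_csv(out / "power.csv", index=False)
            _artifact("power", out / "power.csv")

    except Exception as exc:  # halt with a stage-named message
        logger.error("pipeline stage %s failed: %s", current_stage, exc)
        return {
            "status": 1,
            "error": f"stage {current_stage}: {type(exc).__name__}: {exc}",
            "artifacts": artifacts,
        }

    return {"status": 0, "artifacts": artifacts}
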