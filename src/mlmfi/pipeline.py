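"""End-to-end pipeline: simulate (or load) -> filter -> ascertain ->
select -> score -> stratify -> survival evaluation -> report.

Every stage persists its artifact under the output directory so stages
are independently inspectable and a rerun with the same config and seed
reproduces every artifact byte-for-byte (no timestamps are written into
stage outputs; the manifest records a config hash and library versions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import claims_deficits as cd
from . import frailty_index as fi
from . import risk_groups as rg
from . import survival_eval as se
from .exceptions import ConfigError, PipelineError
from .synthetic_cohort import (
    BASELINE_START,
    ClaimCountModel,
    SimulationConfig,
    generate_cohort,
    make_catalog,
    write_cohort,
)

logger = logging.getLogger(__name__)

AGE_BANDS_TABLE1 = ((65, 69), (70, 74), (75, 79), (80, 84), (85, 200))
DEFAULT_OUTCOMES = (
    "all_cause_mortality", "unplanned_hospitalization", "icu_admission",
)
DEFAULT_HORIZONS = (1, 5, 8)


@dataclass
class PipelineConfig:
    output_dir: str = "mlmfi_run"
    seed: int = 0
    # exactly one of (simulation, external file paths) may be active
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    claims_path: str | None = None
    registry_path: str | None = None
    catalog_path: str | None = None
    # ascertainment window (baseline year by default)
    window_start: str = "2005-01-01"
    window_end: str = "2005-12-31"
    # cohort filter
    age_min: int = 65
    age_max: int = 100
    sex: str | None = None                 # None, "M" or "F"
    # condition selection
    rf: fi.RFSettings = field(default_factory=fi.RFSettings)
    k_grid: list[int] | None = None
    k_stride: int = 1
    target_outcome: str = "all_cause_mortality"
    target_horizon_years: float = 8.0
    reference_catalog_path: str | None = None
    # stratification
    grid_start_month: int = 12
    grid_end_month: int = 96
    min_group_size: int | None = None
    # survival evaluation
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    horizons: tuple[int, ...] = DEFAULT_HORIZONS
    make_plots: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        external = [self.claims_path, self.registry_path]
        if self.simulation is not None and any(external):
            raise ConfigError(
                "simulation: both a simulation block and external file paths are "
                "set; exactly one input source must be active"
            )
        if self.simulation is None and not all(external):
            raise ConfigError(
                "claims_path/registry_path: required when no simulation block is set"
            )
        if self.simulation is not None:
            self.simulation.validate()
        if self.age_min > self.age_max:
            raise ConfigError("age_min: must not exceed age_max")
        if self.sex not in (None, "M", "F"):
            raise ConfigError("sex: must be one of None, 'M', 'F'")
        if self.grid_start_month >= self.grid_end_month:
            raise ConfigError("grid_start_month: must precede grid_end_month")
        for o in self.outcomes:
            if o not in se.OUTCOME_COLUMNS:
                raise ConfigError(f"outcomes: unknown outcome {o!r}")
        if self.k_stride < 1:
            raise ConfigError("k_stride: must be >= 1")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulation")
        if sim is not None:
            ccm = sim.get("claim_count_model")
            if ccm is not None:
                sim = {**sim, "claim_count_model": ClaimCountModel(**ccm)}
            if "age_range" in sim and sim["age_range"] is not None:
                sim = {**sim, "age_range": tuple(sim["age_range"])}
            d["simulation"] = SimulationConfig(**sim)
        if d.get("rf") is not None and not isinstance(d["rf"], fi.RFSettings):
            d["rf"] = fi.RFSettings(**d["rf"])
        for key in ("outcomes", "horizons"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config: PipelineConfig
    descriptives: pd.DataFrame
    model: fi.FrailtyIndexModel
    stratification: rg.StratificationResult
    hr_table: pd.DataFrame
    logrank: dict
    c_indices: dict
    group_sizes: dict
    provenance: dict
    output_dir: Path


def describe_cohort(scores: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) frailty index by 5-year age band x sex, per index kind.

    Empty bands are emitted with count 0 and blank statistics.
    """
    merged = scores.merge(
        subjects[["subject_id", "age_at_baseline", "sex"]], on="subject_id"
    )
    rows = []
    bands = [*AGE_BANDS_TABLE1, ("total", "total")]
    for kind, sub in merged.groupby("index_kind"):
        for lo, hi in bands:
            if lo == "total":
                band_df, label = sub, "total"
            else:
                band_df = sub[sub["age_at_baseline"].between(lo, hi)]
                label = f"{lo}-{hi}" if hi < 150 else f">={lo}"
            for sex_label, sex_df in (
                ("all", band_df),
                ("M", band_df[band_df["sex"] == "M"]),
                ("F", band_df[band_df["sex"] == "F"]),
            ):
                rows.append(
                    {
                        "index_kind": kind,
                        "age_band": label,
                        "sex": sex_label,
                        "n": len(sex_df),
                        "mean": float(sex_df["value"].mean()) if len(sex_df) else np.nan,
                        "sd": float(sex_df["value"].std(ddof=1)) if len(sex_df) > 1 else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def _stage(manifest: dict, name: str):
    """Context manager recording stage completion into the manifest."""
    class _Ctx:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc_type is None:
                manifest["stages"][name] = "ok"
                logger.info("stage %s: done (%.1fs)", name, _time.perf_counter() - self.t0)
                return False
            manifest["stages"][name] = "failed"
            if exc_type is PipelineError:
                return False
            raise PipelineError(name, str(exc)) from exc
    return _Ctx()


def _load_inputs(config: PipelineConfig, out: Path):
    """Stage 1: simulate or read external files; returns registry, claims,
    catalog, truth (truth is None for external data)."""
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        subjects, claims, truth = generate_cohort(sim)
        catalog = cd.ConditionCatalog.from_frame(make_catalog(sim.n_conditions))
        write_cohort(subjects, claims, out, catalog=catalog.to_frame(), truth=truth)
        # re-read through the documented dialect so both paths are identical
        subjects = cd.read_registry(out / "registry.csv")
        claims = cd.read_claims(out / "claims.csv")
        return subjects, claims, catalog, truth
    subjects = cd.read_registry(config.registry_path)
    claims = cd.read_claims(config.claims_path)
    if config.catalog_path is None:
        raise ConfigError("catalog_path: required with external inputs")
    catalog = cd.ConditionCatalog.read_csv(config.catalog_path)
    return subjects, claims, catalog, None


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order, persisting artifacts after each."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
    }
    config.to_yaml(out / "resolved_config.yaml")
    try:
        with _stage(manifest, "simulate_or_load"):
            subjects, claims, catalog, truth = _load_inputs(config, out)

        with _stage(manifest, "filter_cohort"):
            subjects = cd.filter_cohort(subjects, config.age_min, config.age_max)
            if config.sex is not None:
                subjects = subjects[subjects["sex"] == config.sex].reset_index(drop=True)

        with _stage(manifest, "ascertain"):
            window = (pd.Timestamp(config.window_start), pd.Timestamp(config.window_end))
            matrix = cd.ascertain_deficits(
                claims, catalog, window, subject_ids=subjects["subject_id"].tolist()
            )
            matrix.to_wide_csv(out / "deficits_wide.csv")
            matrix.to_triplets_csv(out / "deficits_triplets.csv")

        with _stage(manifest, "select"):
            target_spec = se.OutcomeSpec(config.target_outcome, config.target_horizon_years)
            t_target, e_target = se.build_outcome(subjects, target_spec)
            ranked = fi.rank_importance(matrix, e_target, config.rf)
            p = len(matrix.condition_ids)
            k_grid = config.k_grid or list(range(1, p + 1, config.k_stride))
            if p not in k_grid and config.k_grid is None:
                k_grid.append(p)
            model = fi.select_k(
                matrix, e_target, ranked, k_grid=k_grid, settings=config.rf,
                target_outcome=config.target_outcome,
            )
            model.to_json(out / "model.json")

        with _stage(manifest, "score"):
            scores = fi.compute_fi(matrix, model.selected_ids)
            all_scores = [scores]
            if config.reference_catalog_path:
                ref = cd.ConditionCatalog.read_csv(config.reference_catalog_path)
                all_scores.append(fi.compute_reference_fi(matrix, ref))
            scores_df = pd.concat(all_scores, ignore_index=True)
            scores_df.to_csv(out / "scores.csv", index=False)

        with _stage(manifest, "stratify"):
            grid = np.arange(config.grid_start_month, config.grid_end_month + 1)
            strat_spec = se.OutcomeSpec("all_cause_mortality", config.horizons[-1])
            t_strat, e_strat = se.build_outcome(subjects, strat_spec)
            strat = rg.search_cutpoints(
                scores["value"].to_numpy(), t_strat, e_strat, grid=grid,
                min_group_size=config.min_group_size,
            )
            strat.to_json(out / "stratification.json")
            if not strat.feasible:
                raise PipelineError(
                    "stratify",
                    f"no feasible cut-point triple (constraint: {strat.failed_constraint})",
                )
            groups = rg.assign_groups(scores["value"].to_numpy(), strat.cutpoints)
            pd.DataFrame(
                {"subject_id": scores["subject_id"], "group": groups}
            ).to_csv(out / "groups.csv", index=False)

        with _stage(manifest, "survival"):
            specs = [
                se.OutcomeSpec(o, h) for o in config.outcomes for h in config.horizons
            ]
            hr_table = se.hazard_ratio_table(subjects, groups, specs)
            hr_table.to_csv(out / "hr_table.csv", index=False)
            logrank = {}
            km_frames = []
            for o in config.outcomes:
                spec = se.OutcomeSpec(o, config.horizons[-1])
                t, e = se.build_outcome(subjects, spec)
                chi2, dof, pval = se.logrank_test(t, e, groups)
                logrank[o] = {"chi_square": chi2, "dof": dof, "p": pval}
                cs = rg.curve_set(t, e, groups, grid=np.arange(config.grid_start_month,
                                                               config.grid_end_month + 1))
                for g in se.GROUP_ORDER:
                    f = cs.curves[g].to_frame()
                    f.insert(0, "group", g)
                    f.insert(0, "outcome", o)
                    km_frames.append(f)
            pd.concat(km_frames, ignore_index=True).to_csv(
                out / "km_curves.csv", index=False
            )
            (out / "logrank.json").write_text(json.dumps(logrank, indent=2, sort_keys=True))
            c_indices = {}
            for o in config.outcomes:
                spec = se.OutcomeSpec(o, config.horizons[-1])
                t, e = se.build_outcome(subjects, spec)
                c_indices[o] = se.concordance(t, e, scores["value"].to_numpy())
            (out / "c_indices.json").write_text(
                json.dumps(c_indices, indent=2, sort_keys=True)
            )

        with _stage(manifest, "report"):
            descriptives = describe_cohort(scores_df, subjects)
            descriptives.to_csv(out / "descriptives.csv", index=False)
            group_sizes = pd.Series(groups).value_counts().to_dict()
            _write_report_md(out, config, descriptives, model, strat, hr_table,
                             logrank, c_indices, group_sizes)
            if config.make_plots:
                _make_plots(out, model, t_strat, e_strat, groups)
    finally:
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return RunReport(
        config=config, descriptives=descriptives, model=model, stratification=strat,
        hr_table=hr_table, logrank=logrank, c_indices=c_indices,
        group_sizes={k: int(v) for k, v in group_sizes.items()},
        provenance={"config_hash": manifest["config_hash"], "seed": config.seed,
                    "versions": manifest["versions"]},
        output_dir=out,
    )


def run_stratified(
    config: PipelineConfig, strata: str = "sex", min_viable_n: int = 500
) -> dict[str, RunReport]:
    """Rerun the whole pipeline per stratum (sex, or age bands
    65-75 / 76-85 / >=85), so each stratum gets its own condition set,
    selected k and cut-points. Understrength strata are skipped with a
    warning."""
    config.validate()
    if strata == "sex":
        filters = {"M": {"sex": "M"}, "F": {"sex": "F"}}
    elif strata == "age":
        filters = {
            "65-75": {"age_min": 65, "age_max": 75},
            "76-85": {"age_min": 76, "age_max": 85},
            ">=85": {"age_min": 86, "age_max": 200},  # 76-85 band owns age 85
        }
    else:
        raise ConfigError("strata: must be 'sex' or 'age'")

    reports: dict[str, RunReport] = {}
    for name, override in filters.items():
        sub = dataclasses.replace(
            config,
            output_dir=str(Path(config.output_dir) / f"stratum_{name.replace('>=', 'ge')}"),
            **override,
        )
        n = _stratum_size(sub)
        if n < min_viable_n:
            logger.warning("stratum %s: only %d subjects (< %d); skipped",
                           name, n, min_viable_n)
            continue
        reports[name] = run_pipeline(sub)
    return reports


def _stratum_size(config: PipelineConfig) -> int:
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        subjects, _, _ = generate_cohort(sim)
    else:
        subjects = cd.read_registry(config.registry_path)
    subjects = cd.filter_cohort(subjects, config.age_min, config.age_max)
    if config.sex is not None:
        subjects = subjects[subjects["sex"] == config.sex]
    return len(subjects)


def _versions() -> dict:
    import lifelines
    import sklearn

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "lifelines": lifelines.__version__,
    }


def _write_report_md(out, config, descriptives, model, strat, hr_table,
                     logrank, c_indices, group_sizes) -> None:
    lines = ["# ML-mFI pipeline report", ""]
    lines += [f"- config hash: `{config.config_hash()}`",
              f"- seed: {config.seed}", ""]
    lines += ["## Condition selection", "",
              f"- selected k: **{model.selected_k}** conditions "
              f"(OOB accuracy {model.selected_accuracy:.4f})",
              f"- target outcome: {model.target_outcome}", ""]
    lines += ["## Frailty-status cut-points", ""]
    c1, c2, c3 = strat.cutpoints.as_tuple()
    lines += [
        f"- fit: [0, {c1:.4f})  (n={group_sizes.get('fit', 0)})",
        f"- mild: [{c1:.4f}, {c2:.4f})  (n={group_sizes.get('mild', 0)})",
        f"- moderate: [{c2:.4f}, {c3:.4f})  (n={group_sizes.get('moderate', 0)})",
        f"- severe: [{c3:.4f}, 1]  (n={group_sizes.get('severe', 0)})",
        f"- min-over-t distance index: {strat.objective_min_distance:.4f}",
        f"- max-over-t coverage index: {strat.objective_max_coverage:.4f}",
        "",
    ]
    lines += ["## Cohort descriptives (mean FI by age band x sex)", "",
              descriptives.to_markdown(index=False), ""]
    lines += ["## Hazard ratios (fit = reference)", "",
              hr_table.to_markdown(index=False), ""]
    lines += ["## Log-rank tests (8-year)", ""]
    for o, r in logrank.items():
        lines.append(f"- {o}: chi2={r['chi_square']:.1f}, dof={r['dof']}, p={r['p']:.3g}")
    lines += ["", "## Concordance (ML-mFI score)", ""]
    for o, c in c_indices.items():
        lines.append(f"- {o}: C = {c:.3f}")
    (out / "report.md").write_text("\n".join(lines) + "\n")


def _make_plots(out, model, time, event, groups) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ks = [k for k, _ in model.accuracy_trace]
    accs = [a for _, a in model.accuracy_trace]
    ax.plot(ks, accs, marker="o", ms=3)
    ax.axvline(model.selected_k, color="red", ls="--", lw=1)
    ax.set_xlabel("number of conditions k")
    ax.set_ylabel("OOB accuracy")
    fig.tight_layout()
    fig.savefig(out / "accuracy_trace.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.arange(0, 97)
    cs = rg.curve_set(time, event, groups, grid=grid)
    for i, g in enumerate(se.GROUP_ORDER):
        ax.step(grid, cs.surv[i], where="post", label=g)
        ax.fill_between(grid, cs.ci_lower[i], cs.ci_upper[i], step="post", alpha=0.2)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "km_curves.png", dpi=120)
    plt.close(fig)
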