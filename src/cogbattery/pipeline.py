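"""One reproducible run: simulate (or load) a dataset, analyze, report.

``run_pipeline`` executes the stages in order — simulate → descriptives →
associations → profiles → factors → selection — writing each stage's
output (CSV/JSON) into a run directory together with the seed and a hash
of the configuration, then renders a markdown report.  Supplying an input
directory containing ``participants.csv``/``results.csv`` skips the
simulation, so the same analysis runs on externally collected data with
the documented schema.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import associations as assoc_mod
from . import descriptives as desc_mod
from . import factors as fact_mod
from . import profiles as prof_mod
from .cohort import CohortConfig, StudyDataset, generate_study_dataset
from .errors import PipelineError
from .profiles import ProfileThresholds
from .registry import Registry, load_registry
from .staircase import EngineConfig

#: registrants contacted in the reference deployment; used only to report
#: a registration rate when simulating the default study.
DEFAULT_N_CONTACTED = 365_782


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    ceiling_floor_threshold_pct: float = 10.0
    profile_thresholds: ProfileThresholds = field(default_factory=ProfileThresholds)
    retention: str | int = "parallel"
    loading_threshold: float = 0.40
    signed_flags: bool = True
    profile_direction_policy: str = "aligned_higher_better"
    factor_direction_policy: str = "raw_orientation"
    criteria: fact_mod.SelectionCriteria = field(default_factory=fact_mod.SelectionCriteria)
    min_completers: int = 10
    n_contacted: int | None = DEFAULT_N_CONTACTED


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self):
        # one seed drives the run; keep the cohort block in sync
        self.cohort.seed = self.seed

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**{
            **raw.get("cohort", {}),
            "age_bin_counts": tuple(
                (tuple(b), c) for b, c in raw.get("cohort", {}).get("age_bin_counts", CohortConfig().age_bin_counts)
            ),
        }) if "cohort" in raw else CohortConfig()
        engine = EngineConfig(**raw.get("engine", {})) if "engine" in raw else EngineConfig()
        ana_raw = dict(raw.get("analysis", {}))
        if "profile_thresholds" in ana_raw:
            ana_raw["profile_thresholds"] = ProfileThresholds(**ana_raw["profile_thresholds"])
        if "criteria" in ana_raw:
            crit = {k: tuple(v) for k, v in ana_raw["criteria"].items()}
            ana_raw["criteria"] = fact_mod.SelectionCriteria(**crit)
        analysis = AnalysisConfig(**ana_raw)
        return cls(seed=int(raw.get("seed", 0)), cohort=cohort, engine=engine, analysis=analysis)


def _write_csv(frame: pd.DataFrame, path: Path, provenance: str, index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {provenance}\n")
        frame.to_csv(fh, index=index)


def _write_json(obj, path: Path, provenance: dict) -> None:
    payload = {"provenance": provenance, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    input_dir: str | Path | None = None,
    registry: Registry | None = None,
) -> Path:
    """Execute all stages; returns the run directory.

    On stage failure, outputs written so far are retained, a
    ``FAILED.json`` marker names the stage, and a ``PipelineError`` is
    raised with the stage context.
    """
    registry = registry or load_registry()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov_line = f"cogbattery seed={config.seed} config_hash={config.config_hash()}"
    prov = {"seed": config.seed, "config_hash": config.config_hash()}
    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    config.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        if input_dir is not None:
            dataset = StudyDataset.from_dir(input_dir)
        else:
            dataset = generate_study_dataset(config.cohort, registry, config.engine)
        _write_csv(dataset.participants_frame(), out / "participants.csv", prov_line)
        _write_csv(dataset.results, out / "results.csv", prov_line)

        stage = "descriptives"
        ana = config.analysis
        desc = desc_mod.descriptives_table(dataset, registry, ana.ceiling_floor_threshold_pct)
        _write_csv(desc, out / "descriptives.csv", prov_line)
        completion = desc_mod.completion_summary(dataset, registry, ana.n_contacted)
        _write_json(completion.as_dict(), out / "completion.json", prov)
        _write_csv(desc_mod.demographics_frame(dataset.participants), out / "demographics.csv", prov_line)

        stage = "associations"
        assoc = assoc_mod.association_screen(dataset, ana.alpha, registry=registry)
        _write_csv(assoc, out / "associations.csv", prov_line)

        stage = "profiles"
        completers = prof_mod.select_completers(dataset, registry)
        if len(completers) >= ana.min_completers:
            wide = prof_mod.completer_score_matrix(dataset, registry)
            z_aligned = prof_mod.zscore_transform(wide, registry, ana.profile_direction_policy)
            _write_csv(z_aligned.values, out / "zscores.csv", prov_line + f" policy={z_aligned.direction_policy}", index=True)
            composites, comp_summary = prof_mod.composite_scores(z_aligned)
            _write_json(comp_summary.as_dict(), out / "composites.json", prov)
            prof = prof_mod.profile_table(z_aligned, registry, ana.profile_thresholds)
            _write_csv(prof, out / "profiles.csv", prov_line)

            stage = "factors"
            z_factor = prof_mod.zscore_transform(wide, registry, ana.factor_direction_policy)
            solution = fact_mod.fit_factor_solution(
                z_factor,
                retention=ana.retention,
                threshold=ana.loading_threshold,
                signed_flags=ana.signed_flags,
            )
            _write_json(solution.suitability.as_dict(), out / "suitability.json", prov)
            loadings = solution.loadings.copy()
            for c in solution.flags.columns:
                loadings[f"{c}_flag"] = solution.flags[c]
            _write_csv(loadings, out / "factor_solution.csv", prov_line, index=True)

            stage = "selection"
            inputs = fact_mod.build_selection_inputs(desc, assoc, solution, registry)
            report = fact_mod.select_core_battery(inputs, ana.criteria)
            _write_csv(report.table, out / "selection_report.csv", prov_line, index=True)
        else:
            (out / "SKIPPED_STAGES.json").write_text(json.dumps({
                "skipped": ["profiles", "factors", "selection"],
                "reason": f"only {len(completers)} completers (< {ana.min_completers})",
            }, indent=2))

        stage = "report"
        render_report(out)
    except Exception as exc:
        (out / "FAILED.json").write_text(json.dumps({
            "stage": stage, "error": str(exc), "traceback": traceback.format_exc(),
        }, indent=2))
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    return out


def _md_table(frame: pd.DataFrame, max_rows: int | None = None, floatfmt: str = "{:.3f}") -> str:
    frame = frame.head(max_rows) if max_rows else frame
    def fmt(v):
        if isinstance(v, float):
            return floatfmt.format(v)
        return str(v)
    header = "| " + " | ".join(map(str, frame.columns)) + " |"
    sep = "|" + "---|" * len(frame.columns)
    lines = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in frame.itertuples(index=False)]
    return "\n".join([header, sep, *lines])


def render_report(run_dir: str | Path) -> str:
    """Render (and write) a human-readable markdown summary of a run.

    Missing stage outputs are noted, not fatal: a partial run still
    produces a report describing what exists.
    """
    run = Path(run_dir)
    parts = ["# cogbattery run report", ""]
    prov_path = run / "provenance.json"
    if prov_path.exists():
        prov = json.loads(prov_path.read_text())
        parts.append(f"Seed {prov.get('seed')}, config hash `{prov.get('config_hash')}`.")
        parts.append("")

    def read_csv(name):
        path = run / name
        if not path.exists():
            return None
        return pd.read_csv(path, comment="#")

    demo = read_csv("demographics.csv")
    parts.append("## Demographics")
    if demo is None:
        parts.append("_demographics stage not run_")
    else:
        parts.append(_md_table(demo))
    parts.append("")

    parts.append("## Completion")
    comp_path = run / "completion.json"
    if comp_path.exists():
        c = json.loads(comp_path.read_text())
        parts.append(
            f"- registered: {c['n_registered']}; completed ≥1: {c['n_completed_any']} "
            f"({c['pct_completed_any']:.1f}%); completed all: {c['n_completed_all']} "
            f"({c['pct_completed_all']:.1f}%)"
        )
        if c.get("registration_rate_pct") is not None:
            parts.append(f"- registration rate: {c['registration_rate_pct']:.2f}%")
        for b, n, pct in zip(c["bins"], c["bin_counts"], c["bin_pcts"]):
            parts.append(f"- completed {b}: {n} ({pct:.1f}%)")
    else:
        parts.append("_completion stage not run_")
    parts.append("")

    desc = read_csv("descriptives.csv")
    parts.append("## Assessment descriptives")
    if desc is None:
        parts.append("_descriptives stage not run_")
    else:
        parts.append(_md_table(desc))
        flagged = desc[desc["ceiling_floor_flag"] == True]  # noqa: E712
        parts.append("")
        parts.append(
            f"Ceiling/floor effects (≥ threshold at either bound): {len(flagged)} flagged, "
            f"{len(desc) - len(flagged)} clean."
        )
        if len(flagged):
            parts.append("Flagged: " + ", ".join(flagged["assessment"]) + ".")
    parts.append("")

    assoc = read_csv("associations.csv")
    parts.append("## Demographic associations")
    if assoc is None:
        parts.append("_associations stage not run_")
    else:
        for cov in ("age", "education_years", "gender", "race"):
            sub = assoc[assoc["covariate"] == cov]
            sig = sub[sub["significant"] == True]  # noqa: E712
            parts.append(f"- {cov}: {len(sig)}/{len(sub)} assessments significant")
            if len(sig):
                parts.append("  - " + ", ".join(sig["assessment"]))
    parts.append("")

    parts.append("## Composites and cognitive profiles")
    comp_path = run / "composites.json"
    prof = read_csv("profiles.csv")
    if comp_path.exists() and prof is not None:
        cj = json.loads(comp_path.read_text())
        parts.append(
            f"- composite z over completers: mean {cj['mean']:.3f}, SD {cj['sd']:.2f}, "
            f"range {cj['range'][0]:.2f} to {cj['range'][1]:.2f}"
        )
        counts = prof["label"].value_counts()
        for label in ("high", "low", "auditory_strong", "visual_strong", "unclassified"):
            parts.append(f"- {label}: {int(counts.get(label, 0))}")
    else:
        parts.append("_profile stage not run_")
    parts.append("")

    parts.append("## Factor structure")
    suit_path = run / "suitability.json"
    fsol = read_csv("factor_solution.csv")
    if suit_path.exists() and fsol is not None:
        s = json.loads(suit_path.read_text())
        parts.append(
            f"- Bartlett χ²({s['bartlett_df']}) = {s['bartlett_chi2']:.1f}, "
            f"p = {s['bartlett_p']:.2g}; KMO = {s['kmo_overall']:.2f}"
        )
        k = sum(1 for c in fsol.columns if c.startswith("factor_") and not c.endswith("_flag"))
        parts.append(f"- retained factors: {k}")
        parts.append("")
        parts.append(_md_table(fsol))
    else:
        parts.append("_factor stage not run_")
    parts.append("")

    sel = read_csv("selection_report.csv")
    parts.append("## Core-battery selection")
    if sel is None:
        parts.append("_selection stage not run_")
    else:
        kept = sel[sel["retained"] == True]  # noqa: E712
        parts.append(f"- retained {len(kept)} of {len(sel)} assessments:")
        parts.append("  " + ", ".join(kept.iloc[:, 0]))
    parts.append("")

    text = "\n".join(parts)
    (run / "report.md").write_text(text)
    return text
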