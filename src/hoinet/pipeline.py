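"""End-to-end orchestration: simulate -> prep -> search -> infer -> behave.

The pipeline consumes a :class:`RunConfig`, generates (or loads) the
cohort, reduces every participant-session to per-band representative
trials, runs the greedy discriminative search in both directions for every
requested measure and band, fits the baseline-adjusted ANCOVA grid with
per-(measure, direction) FDR control, and computes the behavioral
summaries, group tests, and prevalence estimates.  Everything is
deterministic given the seed, and the result bundle carries a hash of the
configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import inference, io
from .cohort import (
    SESSIONS,
    Cohort,
    CohortConfig,
    EpochSet,
    generate_behavior,
    generate_epochs,
    participant_table,
)
from .gsa import DEFAULT_START_ORDER, SearchTrace, run_gsa
from .preprocessing import (
    BandSpec,
    BandTrial,
    average_reference,
    bandpass_trial,
    representative_trial,
)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "prep_band_trials",
    "run_pipeline",
    "load_external_epochs",
    "config_hash",
]


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bands: tuple[BandSpec, ...] | None = None  # None: the cohort's bands
    measures: tuple[str, ...] = ("TC", "DTC", "O", "negO")
    start_orders: tuple[tuple[str, int], ...] = tuple(DEFAULT_START_ORDER.items())
    max_order: int = 16
    fdr_q: float = 0.05
    alpha: float = 0.05
    prevalence_mc_runs: int = 10_000
    output_dir: str | None = None
    seed: int = 0

    @property
    def analysis_bands(self) -> tuple[BandSpec, ...]:
        return self.bands if self.bands is not None else self.cohort.bands

    def seeded_cohort(self) -> CohortConfig:
        return dataclasses.replace(self.cohort, seed=self.seed)


@dataclass
class PipelineResult:
    config: RunConfig
    traces: list[SearchTrace]
    ancova: pd.DataFrame
    behavior_summary: pd.DataFrame
    group_tests: pd.DataFrame
    prevalence: dict[str, beh.PrevalenceEstimate]
    groups: dict[str, str]
    config_hash: str


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def preprocess_epochs(epochs: EpochSet, bands: tuple[BandSpec, ...]) -> dict[str, BandTrial]:
    """Average-reference, trial-average, and band-filter one epoch set."""
    referenced = average_reference(epochs.data)
    rep = representative_trial(referenced)
    out = {}
    for band in bands:
        out[band.name] = BandTrial(
            participant=epochs.participant,
            session=epochs.session,
            band=band,
            data=bandpass_trial(rep, band, epochs.fs),
            fs=epochs.fs,
        )
    return out


def prep_band_trials(
    config: CohortConfig,
    bands: tuple[BandSpec, ...],
    epochs: dict[tuple[str, str], EpochSet] | None = None,
) -> dict[tuple[str, str], dict[str, BandTrial]]:
    """Per-(band, session) representative trials for every participant.

    With ``epochs=None``, participant-sessions are generated one at a time
    from the config and reduced immediately, bounding peak memory to a
    single epoch set.  Returns {(band, session): {participant: BandTrial}}.
    """
    out: dict[tuple[str, str], dict[str, BandTrial]] = {
        (b.name, s): {} for b in bands for s in SESSIONS
    }
    for participant, group in participant_table(config):
        for session in SESSIONS:
            if epochs is None:
                es = generate_epochs(config, participant, group, session)
            else:
                es = epochs[(participant, session)]
            for band_name, bt in preprocess_epochs(es, bands).items():
                out[(band_name, session)][participant] = bt
    return out


def _behavior_tables(config: CohortConfig) -> dict[tuple[str, str], pd.DataFrame]:
    tables = {}
    for idx, (participant, group) in enumerate(participant_table(config)):
        for s_idx, session in enumerate(SESSIONS):
            rng = np.random.default_rng([config.seed, 2, idx, s_idx])
            tables[(participant, session)] = generate_behavior(config, group, session, rng)
    return tables


def _behavior_stage(
    config: RunConfig,
    tables: dict[tuple[str, str], pd.DataFrame],
    groups: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, beh.PrevalenceEstimate]]:
    rows = []
    for (participant, session), table in tables.items():
        for trial_class in beh.TRIAL_CLASSES:
            s = beh.summarize_behavior(table, trial_class, participant, session)
            rows.append(dataclasses.asdict(s))
    summary = pd.DataFrame(rows)

    tests = []
    for session in SESSIONS:
        for trial_class in beh.TRIAL_CLASSES:
            for metric in ("median_rt_ms", "accuracy_pct"):
                sub = summary.query("session == @session and trial_class == @trial_class")
                t = sub[sub["participant"].map(groups) == "treatment"][metric]
                c = sub[sub["participant"].map(groups) == "control"][metric]
                u, p = beh.mann_whitney_u(t.to_numpy(), c.to_numpy())
                tests.append(
                    {"session": session, "trial_class": trial_class,
                     "metric": metric, "U": u, "p": p}
                )
    group_tests = pd.DataFrame(tests)

    prevalence = {}
    prev_rng = np.random.default_rng([config.seed, 4])
    for group in ("treatment", "control"):
        pids = [p for p, g in groups.items() if g == group]
        hits = sum(
            beh.within_participant_rt_tests(
                tables[(p, "baseline")], tables[(p, "follow_up")], config.alpha
            )
            for p in pids
        )
        prevalence[group] = beh.bayesian_prevalence(
            hits, len(pids), config.alpha, config.prevalence_mc_runs, prev_rng
        )
    return summary, group_tests, prevalence


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and (optionally) write the results bundle."""
    cohort_cfg = config.seeded_cohort()
    bands = config.analysis_bands
    groups = dict(participant_table(cohort_cfg))
    start_orders = dict(config.start_orders)

    band_trials = prep_band_trials(cohort_cfg, bands)

    traces: list[SearchTrace] = []
    results: list[inference.AncovaResult] = []
    for band in bands:
        follow = band_trials[(band.name, "follow_up")]
        base = band_trials[(band.name, "baseline")]
        for measure in config.measures:
            for direction in ("maximize", "minimize"):
                trace = run_gsa(
                    follow,
                    groups,
                    measure,
                    direction,
                    start_order=start_orders.get(measure),
                    max_order=config.max_order,
                    band_name=band.name,
                )
                traces.append(trace)
                baseline_vals = inference.baseline_backcompute(trace, base)
                for step in trace.steps:
                    pids = list(step.values)
                    res = inference.ancova_group_effect(
                        np.array([step.values[p] for p in pids]),
                        np.array([baseline_vals[step.order][p] for p in pids]),
                        np.array([groups[p] for p in pids]),
                    )
                    res.band, res.measure = band.name, measure
                    res.direction, res.order = direction, step.order
                    results.append(res)
    inference.apply_fdr(results, q=config.fdr_q)
    ancova = inference.results_table(results)

    tables = _behavior_tables(cohort_cfg)
    summary, group_tests, prevalence = _behavior_stage(config, tables, groups)

    result = PipelineResult(
        config=config,
        traces=traces,
        ancova=ancova,
        behavior_summary=summary,
        group_tests=group_tests,
        prevalence=prevalence,
        groups=groups,
        config_hash=config_hash(config),
    )
    if config.output_dir is not None:
        write_bundle(result, Path(config.output_dir), tables)
    return result


def write_bundle(
    result: PipelineResult,
    out_dir: Path,
    behavior_tables: dict[tuple[str, str], pd.DataFrame] | None = None,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = result.config.cohort.channel_names
    io.save_traces(result.traces, out_dir / "search_traces.json", names)
    result.ancova.to_csv(out_dir / "ancova_results.tsv", sep="\t", index=False)
    result.behavior_summary.to_csv(out_dir / "behavior_summary.tsv", sep="\t", index=False)
    result.group_tests.to_csv(out_dir / "behavior_group_tests.tsv", sep="\t", index=False)
    prev = {g: dataclasses.asdict(p) for g, p in result.prevalence.items()}
    (out_dir / "prevalence.json").write_text(json.dumps(prev, indent=1))
    if behavior_tables is not None:
        beh_dir = out_dir / "behavior"
        for (participant, session), table in behavior_tables.items():
            io.save_behavior(table, beh_dir / f"{participant}_{session}.tsv")
    manifest = {
        "config_hash": result.config_hash,
        "seed": result.config.seed,
        "groups": result.groups,
        "n_traces": len(result.traces),
        "selection_caveat": inference.SELECTION_CAVEAT,
        "config": json.loads(
            json.dumps(dataclasses.asdict(result.config), default=str)
        ),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))


def load_external_epochs(path: str | Path) -> tuple[dict[tuple[str, str], EpochSet], dict[str, str]]:
    """Load a user-supplied cohort from the array-container + sidecar layout."""
    return io.load_epoch_dir(path)
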