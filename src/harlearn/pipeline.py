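"""Leave-one-subject-out personalization experiments.

For each held-out subject the protocol is:

* **Step 1** — pool every other subject's windows, train ``n_ui_models``
  user-independent base models (bootstrap at the pooled size S, SFS, fit),
  adding each to the ensemble and evaluating on the subject's test part.
  The ensemble after this step is the static user-independent baseline.
* **Step 2 / Step 3** — label the subject's first / second personalization
  chunk under the configured policy (the oracle simulates the user with
  ground-truth lookups), train three personal base models per chunk, adding
  and evaluating after each.  The final ensemble holds 3 user-independent
  plus 6 personal members and was evaluated 9 times.

The subject's own data is split, per contiguous activity block and before
windowing, into three equal-length raw-signal thirds assigned in temporal
order to (personalize-1, personalize-2, test); windows never straddle a cut,
so the parts share no raw samples and no leakage is possible.

A control variant grows the ensemble with six additional user-independent
models instead of personal ones; the error rate should then stay flat,
demonstrating that the improvement comes from personalization and not mere
ensemble growth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ProtocolError
from .features import FeatureConfig, FeatureSet, featurize
from .labeling import LabeledChunk, LabelingPolicy, Oracle, label_chunk
from .learnpp import EnsembleModel
from .metrics import balanced_accuracy, error_rate, macro_fnr  # noqa: F401 (re-export)
from .signal_io import RawRecording, WindowSpec, segment_windows
from .synthetic_data import SyntheticConfig, generate_cohort
from .training import TrainConfig, train_base_model

logger = logging.getLogger(__name__)

PART_NAMES = ("part1", "part2", "test")


def _stream(seed: int, subject_index: int, round_index: int,
            replicate: int) -> np.random.Generator:
    """Independent RNG stream per (seed, subject, round, replicate)."""
    return np.random.default_rng([seed, subject_index, round_index, replicate])


@dataclass
class PersonalSplit:
    """Three disjoint parts of one subject's data (features + raw coverage).

    ``intervals`` maps each part to its raw half-open sample intervals per
    class, used to assert the no-leakage invariant.
    """

    part1: FeatureSet
    part2: FeatureSet
    test: FeatureSet
    intervals: dict[str, list[tuple[str, int, int]]]

    def part(self, name: str) -> FeatureSet:
        return getattr(self, name)


def split_personal(
    rec: RawRecording,
    window_spec: WindowSpec,
    feature_cfg: FeatureConfig,
    part_order: tuple[str, str, str] = PART_NAMES,
) -> PersonalSplit:
    """Split a subject's recording into personalization and test parts.

    Every contiguous same-label block is cut into three equal-length thirds
    at sample resolution (trailing remainder samples are dropped); the
    thirds go to ``part_order`` in temporal order.  Windows are computed
    independently inside each third.
    """
    if sorted(part_order) != sorted(PART_NAMES):
        raise ProtocolError(f"part_order must permute {PART_NAMES}")
    labels = rec.labels
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(labels)]])
    thirds: dict[str, list[tuple[str, int, int]]] = {p: [] for p in PART_NAMES}
    for s, e in zip(bounds[:-1], bounds[1:]):
        cls = str(labels[s])
        third = (e - s) // 3
        for i, part in enumerate(part_order):
            thirds[part].append((cls, int(s + i * third), int(s + (i + 1) * third)))
    parts: dict[str, FeatureSet] = {}
    offset = 0
    for part in PART_NAMES:
        windows = []
        for cls, s, e in thirds[part]:
            wins = segment_windows(rec.slice(s, e), window_spec)
            if len(wins) < 3:
                raise ProtocolError(
                    f"subject {rec.subject_id}, class {cls!r}: block too short "
                    f"for 3 windows per part ({len(wins)} windows in a third)"
                )
            windows.extend(wins)
        fs = featurize(windows, feature_cfg)
        fs.w = offset + np.arange(len(fs))
        offset += len(fs)
        parts[part] = fs
    return PersonalSplit(parts["part1"], parts["part2"], parts["test"],
                         intervals=thirds)


@dataclass
class CohortFeatures:
    """Featurized cohort: full-recording windows per subject (the UI pool
    material) plus each subject's three-way personal split."""

    subject_ids: list[str]
    full: dict[str, FeatureSet]
    splits: dict[str, PersonalSplit]

    def pool_excluding(self, subject_id: str) -> FeatureSet:
        return FeatureSet.concat(
            [self.full[s] for s in self.subject_ids if s != subject_id]
        )


def prepare_cohort(
    recordings: list[RawRecording],
    window_spec: WindowSpec,
    feature_cfg: FeatureConfig,
    part_order: tuple[str, str, str] = PART_NAMES,
) -> CohortFeatures:
    """Window and featurize a cohort once, for reuse across held-out subjects."""
    full, splits = {}, {}
    for rec in recordings:
        full[rec.subject_id] = featurize(
            segment_windows(rec, window_spec), feature_cfg
        )
        splits[rec.subject_id] = split_personal(
            rec, window_spec, feature_cfg, part_order
        )
    return CohortFeatures([r.subject_id for r in recordings], full, splits)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment configuration (window, features, training, policy)."""

    classifier_kind: str = "lda"
    policy: LabelingPolicy = field(default_factory=LabelingPolicy)
    window: WindowSpec = field(default_factory=WindowSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_ui_models: int = 3
    part_order: tuple[str, str, str] = PART_NAMES
    seed: int = 0


@dataclass
class StepRecord:
    """Ensemble score on the test part after one base-model addition."""

    n_members: int
    added_origin: str
    balanced_accuracy: float

    @property
    def error_rate(self) -> float:
        return 1.0 - self.balanced_accuracy

    @property
    def macro_fnr(self) -> float:
        return 1.0 - self.balanced_accuracy


@dataclass
class RoundRecord:
    """Labeling outcome of one personalization round."""

    round_index: int
    threshold: float | None
    query_fraction: float
    replaced_fraction: float
    n_windows: int
    skipped: bool = False


@dataclass
class ExperimentTrace:
    """Per-subject record of ensemble growth and evaluation."""

    subject_id: str
    policy_mode: str
    steps: list[StepRecord]
    rounds: list[RoundRecord]
    baseline_balanced_accuracy: float

    @property
    def final_balanced_accuracy(self) -> float:
        return self.steps[-1].balanced_accuracy

    @property
    def baseline_error(self) -> float:
        return 1.0 - self.baseline_balanced_accuracy

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"step": i + 1, "n_members": s.n_members,
             "added_origin": s.added_origin,
             "balanced_accuracy": s.balanced_accuracy,
             "error_rate": s.error_rate, "macro_fnr": s.macro_fnr}
            for i, s in enumerate(self.steps)
        ])


def _eval_step(ens: EnsembleModel, test: FeatureSet, origin: str) -> StepRecord:
    preds = np.array([p.label for p in ens.predict_batch(test)], dtype=object)
    return StepRecord(
        n_members=ens.n_members,
        added_origin=origin,
        balanced_accuracy=balanced_accuracy(test.labels, preds),
    )


def _run_subject(
    subject_id: str,
    cohort: CohortFeatures,
    cfg: ExperimentConfig,
    policies: list[LabelingPolicy],
    include_ui_control: bool = False,
) -> dict[str, ExperimentTrace]:
    """Run the protocol for one held-out subject under several policies.

    The user-independent phase does not depend on the policy (its RNG
    streams are keyed by (seed, subject, round 0, replicate)), so it is
    computed once and shared; results are bit-identical to running each
    policy in isolation.
    """
    sidx = cohort.subject_ids.index(subject_id)
    pool = cohort.pool_excluding(subject_id)
    split = cohort.splits[subject_id]
    test = split.test

    ui_ens = EnsembleModel()
    ui_steps: list[StepRecord] = []
    for rep in range(cfg.n_ui_models):
        rng = _stream(cfg.seed, sidx, 0, rep)
        model = train_base_model(pool, cfg.classifier_kind, "user_independent",
                                 cfg.train, rng)
        ui_ens.add_base_model(model)
        ui_steps.append(_eval_step(ui_ens, test, "user_independent"))
    baseline = ui_steps[-1].balanced_accuracy

    oracle = Oracle.from_feature_set(FeatureSet.concat([split.part1, split.part2]))
    results: dict[str, ExperimentTrace] = {}
    for pol in policies:
        ens = ui_ens.copy()
        steps = list(ui_steps)
        rounds: list[RoundRecord] = []
        for rnd, chunk in ((1, split.part1), (2, split.part2)):
            labeled = label_chunk(ens, chunk, pol, oracle, round_index=rnd)
            if labeled.threshold is not None:
                logger.info(
                    "subject %s %s round %d: th=%.2f, %d/%d queried",
                    subject_id, pol.mode, rnd, labeled.threshold,
                    int(labeled.query_fraction * len(labeled)), len(labeled),
                )
            record = RoundRecord(
                round_index=rnd,
                threshold=labeled.threshold,
                query_fraction=labeled.query_fraction,
                replaced_fraction=labeled.replaced_fraction,
                n_windows=len(labeled),
            )
            training_set = labeled.labeled_features()
            if len(np.unique(training_set.labels)) < 2:
                logger.warning(
                    "subject %s %s round %d: degenerate labeled chunk, skipped",
                    subject_id, pol.mode, rnd,
                )
                record.skipped = True
                rounds.append(record)
                continue
            for rep in range(cfg.train.n_models_per_chunk):
                rng = _stream(cfg.seed, sidx, rnd, rep)
                model = train_base_model(training_set, cfg.classifier_kind,
                                         "personal", cfg.train, rng)
                ens.add_base_model(model)
                steps.append(_eval_step(ens, test, "personal"))
            rounds.append(record)
        results[pol.mode] = ExperimentTrace(
            subject_id=subject_id,
            policy_mode=pol.mode,
            steps=steps,
            rounds=rounds,
            baseline_balanced_accuracy=baseline,
        )

    if include_ui_control:
        ens = ui_ens.copy()
        steps = list(ui_steps)
        for rnd in (1, 2):
            for rep in range(cfg.train.n_models_per_chunk):
                rng = _stream(cfg.seed, sidx, rnd, rep)
                model = train_base_model(pool, cfg.classifier_kind,
                                         "user_independent", cfg.train, rng)
                ens.add_base_model(model)
                steps.append(_eval_step(ens, test, "user_independent"))
        results["ui_control"] = ExperimentTrace(
            subject_id=subject_id,
            policy_mode="ui_control",
            steps=steps,
            rounds=[],
            baseline_balanced_accuracy=baseline,
        )
    return results


def run_personalization(subject_id: str, cohort: CohortFeatures,
                        cfg: ExperimentConfig) -> ExperimentTrace:
    """Full protocol for one held-out subject under ``cfg.policy``."""
    return _run_subject(subject_id, cohort, cfg, [cfg.policy])[cfg.policy.mode]


def run_ui_only_control(subject_id: str, cohort: CohortFeatures,
                        cfg: ExperimentConfig) -> ExperimentTrace:
    """Like :func:`run_personalization` but Steps 2–3 add fresh
    user-independent models instead of personal ones."""
    return _run_subject(subject_id, cohort, cfg, [],
                        include_ui_control=True)["ui_control"]


def run_loso(
    cohort: CohortFeatures,
    cfg: ExperimentConfig,
    policies: list[LabelingPolicy] | None = None,
    include_ui_control: bool = False,
) -> dict[str, list[ExperimentTrace]]:
    """Leave-one-subject-out over the whole cohort.

    Returns traces grouped by policy mode (plus ``"ui_control"`` when
    requested).  The user-independent phase is shared across policies for
    each subject.
    """
    policies = policies if policies is not None else [cfg.policy]
    traces: dict[str, list[ExperimentTrace]] = {}
    for subject_id in cohort.subject_ids:
        results = _run_subject(subject_id, cohort, cfg, policies,
                               include_ui_control)
        for mode, trace in results.items():
            traces.setdefault(mode, []).append(trace)
    return traces


def aggregate_traces(traces: dict[str, list[ExperimentTrace]]) -> pd.DataFrame:
    """Mean and SD of balanced accuracy per policy and step, plus the static
    user-independent baseline (a Table-1-style layout)."""
    rows = []
    for mode, tlist in traces.items():
        n_steps = max(len(t.steps) for t in tlist)
        for step in range(n_steps):
            vals = [t.steps[step].balanced_accuracy
                    for t in tlist if len(t.steps) > step]
            rows.append({"policy": mode, "step": step + 1,
                         "mean_balanced_accuracy": float(np.mean(vals)),
                         "sd_balanced_accuracy": float(np.std(vals, ddof=1))
                         if len(vals) > 1 else 0.0})
        rows.append({"policy": mode, "step": "baseline",
                     "mean_balanced_accuracy": float(np.mean(
                         [t.baseline_balanced_accuracy for t in tlist])),
                     "sd_balanced_accuracy": float(np.std(
                         [t.baseline_balanced_accuracy for t in tlist], ddof=1))
                     if len(tlist) > 1 else 0.0})
    return pd.DataFrame(rows)


ALL_POLICIES = (
    LabelingPolicy(mode="non_supervised"),
    LabelingPolicy(mode="semi_supervised"),
    LabelingPolicy(mode="supervised"),
)


def run_seeded_comparison(
    seeds: list[int],
    synth_cfg: SyntheticConfig | None = None,
    exp_cfg: ExperimentConfig | None = None,
    policies: tuple[LabelingPolicy, ...] = ALL_POLICIES,
    include_ui_control: bool = True,
) -> dict:
    """Repeat the full LOSO policy comparison over several cohort seeds.

    For each seed a fresh synthetic cohort is generated (``synth_cfg`` with
    its seed replaced) and the experiment seed is set likewise.  Returns the
    per-run final/baseline scores, query summaries and control drift needed
    to compare the policies.
    """
    synth_cfg = synth_cfg or SyntheticConfig()
    exp_cfg = exp_cfg or ExperimentConfig()
    out: dict = {
        "final_ba": {p.mode: [] for p in policies},
        "baseline_ba": [],
        "thresholds": {1: [], 2: []},
        "query_fraction": {1: [], 2: []},
        "replaced_fraction": {1: [], 2: []},
        "control_err_step3": [],
        "control_err_step9": [],
        "final_member_origins": None,
        "n_runs": 0,
    }
    for seed in seeds:
        cohort = prepare_cohort(
            generate_cohort(replace(synth_cfg, seed=seed)),
            exp_cfg.window, exp_cfg.features, exp_cfg.part_order,
        )
        traces = run_loso(cohort, replace(exp_cfg, seed=seed),
                          policies=list(policies),
                          include_ui_control=include_ui_control)
        for p in policies:
            for t in traces[p.mode]:
                out["final_ba"][p.mode].append(t.final_balanced_accuracy)
        for t in traces[policies[0].mode]:
            out["baseline_ba"].append(t.baseline_balanced_accuracy)
            out["n_runs"] += 1
            if out["final_member_origins"] is None:
                origins = [s.added_origin for s in t.steps]
                out["final_member_origins"] = {
                    o: origins.count(o) for o in sorted(set(origins))
                }
        if "semi_supervised" in traces:
            for t in traces["semi_supervised"]:
                for r in t.rounds:
                    out["thresholds"][r.round_index].append(r.threshold)
                    out["query_fraction"][r.round_index].append(r.query_fraction)
                    out["replaced_fraction"][r.round_index].append(
                        r.replaced_fraction)
        if include_ui_control:
            for t in traces["ui_control"]:
                out["control_err_step3"].append(t.steps[2].error_rate)
                out["control_err_step9"].append(t.steps[-1].error_rate)
    return out
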