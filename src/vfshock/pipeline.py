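"""End-to-end orchestration: simulate -> features -> train -> evaluate -> report.

The experiment protocol is: generate (or load) a cohort; compute AMSA from
each pre-shock episode; split *patients* (never shocks) into training and
validation halves; per stratum (first / subsequent shocks) train the four
feature combinations with each method; derive the 90%-specificity
threshold from training scores; report validation AUC and threshold
metrics plus pairwise tests against the AMSA-only baseline.

A single top-level seed fans out deterministically to the generator, the
split, and the per-feature-set network initialisations, so identical
configurations yield identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvalidArgumentError, SchemaError
from .evaluation import (
    PerformanceReport,
    classification_metrics,
    compare_auc,
    compare_proportions,
    performance_table,
    roc_curve,
    threshold_at_specificity,
)
from .features import FEATURE_SETS, PatientSequence, ShockRecord, build_feature_table
from .models import fit_all_combinations, predict_score
from .synthetic import GeneratorConfig, SyntheticCohort, generate_cohort
from .waveform import EcgEpisode, amsa_from_episode

logger = logging.getLogger("vfshock")

MANIFEST_COLUMNS = ["patient_id", "shock_index", "outcome", "amsa_mvhz",
                    "episode_file"]


@dataclass
class ExperimentConfig:
    """Full configuration of one simulate-train-evaluate experiment."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    split_fraction_training: float = 0.5
    band: tuple[float, float] = (2.0, 48.0)
    target_specificity: float = 0.90
    methods: tuple[str, ...] = ("network", "logistic")
    strata: tuple[str, ...] = ("first", "subsequent")
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.split_fraction_training < 1.0:
            raise InvalidArgumentError("split fraction must be in (0, 1)")
        self.generator.validate()

    def fan_out_seeds(self) -> dict[str, int]:
        """Derive the component seeds from the top-level seed."""
        state = np.random.SeedSequence(self.seed).generate_state(3) % (2**31)
        return {"generator": int(state[0]), "split": int(state[1]),
                "models": int(state[2])}

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        for key in ("methods", "strata"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=gen, **raw)


@dataclass
class ExperimentResult:
    """Per-stratum, per-method performance tables and pairwise tests."""

    summary: dict
    reports: dict       # stratum -> method -> feature set -> report dict
    comparisons: dict   # stratum -> method -> feature set -> test dicts
    config: dict
    seeds: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentResult":
        return cls(**d)

    def __eq__(self, other) -> bool:
        return isinstance(other, ExperimentResult) and self.to_dict() == other.to_dict()

    def table(self, stratum: str, method: str) -> pd.DataFrame:
        recs = {name: PerformanceReport(**r)
                for name, r in self.reports[stratum][method].items()}
        return performance_table(recs)


def split_cohort(cohort: SyntheticCohort, fraction: float, seed: int
                 ) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Patient-level random partition; all of a patient's shocks stay together."""
    if len(cohort.sequences) < 2:
        raise InvalidArgumentError("need at least 2 patients to split")
    n = len(cohort.sequences)
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise InvalidArgumentError(
            f"fraction {fraction} leaves an empty side with {n} patients"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = set(order[:n_train].tolist())

    def _subset(keep_train: bool) -> SyntheticCohort:
        seqs, eps = [], [] if cohort.episodes is not None else None
        offset = 0
        for i, seq in enumerate(cohort.sequences):
            take = (i in train_idx) == keep_train
            if take:
                seqs.append(seq)
                if eps is not None:
                    eps.extend(cohort.episodes[offset:offset + len(seq)])
            offset += len(seq)
        return SyntheticCohort(seqs, eps, cohort.config_used)

    return _subset(True), _subset(False)


def _episode_feature_frame(cohort: SyntheticCohort,
                           band: tuple[float, float]) -> pd.DataFrame:
    """Canonical feature table; AMSA recomputed from episodes when present."""
    if cohort.episodes is not None:
        j = 0
        seqs = []
        for seq in cohort.sequences:
            shocks = []
            for s in seq.shocks:
                amsa = amsa_from_episode(cohort.episodes[j], band)
                shocks.append(ShockRecord(s.patient_id, s.shock_index,
                                          float(amsa), s.outcome))
                j += 1
            seqs.append(PatientSequence(seq.patient_id, shocks))
        cohort = SyntheticCohort(seqs, None, cohort.config_used)
    return cohort.to_frame()


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentResult:
    """Execute the full protocol and (optionally) write the result to disk."""
    config.validate()
    seeds = config.fan_out_seeds()
    gen = dataclasses.replace(config.generator, seed=seeds["generator"])

    try:
        cohort = generate_cohort(gen)
        frame = _episode_feature_frame(cohort, config.band)
        train_cohort, valid_cohort = split_cohort(
            cohort, config.split_fraction_training, seeds["split"]
        )
        train_ids = {s.patient_id for s in train_cohort.sequences}
        train_frame = frame[frame["patient_id"].isin(train_ids)]
        valid_frame = frame[~frame["patient_id"].isin(train_ids)]
    except Exception as exc:
        raise type(exc)(f"[stage: simulate/split] {exc}") from exc

    summary = {
        "n_patients": int(frame["patient_id"].nunique()),
        "n_shocks": int(len(frame)),
        "n_patients_training": len(train_ids),
        "n_patients_validation": int(valid_frame["patient_id"].nunique()),
        "n_shocks_training": int(len(train_frame)),
        "n_shocks_validation": int(len(valid_frame)),
        "success_rate_training": float(train_frame["outcome"].mean()),
        "success_rate_validation": float(valid_frame["outcome"].mean()),
    }
    logger.info("cohort: %(n_patients)d patients, %(n_shocks)d shocks", summary)

    model_seeds = np.random.SeedSequence(seeds["models"]).generate_state(
        len(config.strata) * len(config.methods)) % (2**31)
    reports: dict = {}
    comparisons: dict = {}
    si = 0
    for stratum in config.strata:
        reports[stratum] = {}
        comparisons[stratum] = {}
        for method in config.methods:
            try:
                rep, cmp_ = _evaluate_stratum(
                    train_frame, valid_frame, stratum, method,
                    config.target_specificity, int(model_seeds[si]),
                )
            except Exception as exc:
                raise type(exc)(
                    f"[stage: {method}/{stratum}] {exc}"
                ) from exc
            reports[stratum][method] = {k: asdict(v) for k, v in rep.items()}
            comparisons[stratum][method] = cmp_
            si += 1

    result = ExperimentResult(
        summary=summary, reports=reports, comparisons=comparisons,
        config=_config_dict(config), seeds=seeds,
    )
    if out_dir is not None:
        write_result(result, out_dir)
    return result


def _evaluate_stratum(train_frame, valid_frame, stratum, method,
                      target_specificity, seed):
    """Train all four feature sets on one stratum and score validation shocks."""
    train_rows = build_feature_table(train_frame, "C3", stratum)
    valid_rows = build_feature_table(valid_frame, "C3", stratum)
    # one first shock per patient: a patient random intercept is
    # unidentifiable there, so the pooled logistic is used
    models = fit_all_combinations(
        train_rows, method=method, seed=seed,
        random_intercept=(stratum != "first"),
    )
    labels = valid_rows["outcome"].to_numpy(dtype=int)
    rep: dict[str, PerformanceReport] = {}
    scores: dict[str, np.ndarray] = {}
    for name in FEATURE_SETS:
        model = models[name]
        s_train = predict_score(model, train_rows)
        thr = threshold_at_specificity(
            roc_curve(s_train, train_rows["outcome"].to_numpy(dtype=int)),
            target_specificity,
        )
        s_valid = predict_score(model, valid_rows)
        scores[name] = s_valid
        rep[name] = classification_metrics(s_valid, labels, thr,
                                           feature_set=name)
    cmp_: dict[str, dict] = {}
    for name in ("C1", "C2", "C3"):
        a, b = rep[name], rep["AMSA"]
        tests = {"auc_z": asdict(compare_auc(scores[name], scores["AMSA"], labels))}
        tests["sensitivity_chi2"] = asdict(compare_proportions(
            a.tp, a.tp + a.fn, b.tp, b.tp + b.fn))
        tests["ppv_chi2"] = asdict(compare_proportions(
            a.tp, max(a.tp + a.fp, 1), b.tp, max(b.tp + b.fp, 1)))
        tests["npv_chi2"] = asdict(compare_proportions(
            a.tn, max(a.tn + a.fn, 1), b.tn, max(b.tn + b.fn, 1)))
        tests["pa_chi2"] = asdict(compare_proportions(
            a.tp + a.tn, len(labels), b.tp + b.tn, len(labels)))
        cmp_[name] = tests
    return rep, cmp_


def _config_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["band"] = list(d["band"])
    d["methods"] = list(d["methods"])
    d["strata"] = list(d["strata"])
    return d


# ---------------------------------------------------------------------------
# cohort and result I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a cohort as manifest CSV + per-shock episode CSVs + config YAML.

    Episode files hold one header comment line ``# fs_hz=<rate>`` and a
    single column of mV samples.  When the cohort has no waveforms the
    manifest's ``episode_file`` column is empty and AMSA values travel in
    ``amsa_mvhz``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    j = 0
    for seq in cohort.sequences:
        for s in seq.shocks:
            fname = ""
            if cohort.episodes is not None:
                ep = cohort.episodes[j]
                fname = f"episode_{s.patient_id}_{s.shock_index:02d}.csv"
                with open(out_dir / fname, "w") as fh:
                    fh.write(f"# fs_hz={ep.sampling_rate}\n")
                    np.savetxt(fh, ep.samples, fmt="%.10g")
            rows.append((s.patient_id, s.shock_index, s.outcome, s.amsa, fname))
            j += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "generator_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cohort.config_used), fh, sort_keys=False)
    return out_dir / "manifest.csv"


def read_manifest(path) -> SyntheticCohort:
    """Load a cohort written by :func:`write_cohort` (lossless round-trip)."""
    path = Path(path)
    manifest = pd.read_csv(path, keep_default_na=False,
                           dtype={"episode_file": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise SchemaError(f"manifest missing columns {missing}")
    dup = manifest.duplicated(["patient_id", "shock_index"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise SchemaError(
            f"duplicate (patient_id, shock_index) at manifest row {row + 2}"
        )
    cfg_path = path.parent / "generator_config.yaml"
    config = None
    if cfg_path.exists():
        with open(cfg_path) as fh:
            config = GeneratorConfig(**yaml.safe_load(fh))

    sequences, episodes = [], []
    have_episodes = bool((manifest["episode_file"] != "").all()) and len(manifest)
    for pid, grp in manifest.groupby("patient_id", sort=True):
        grp = grp.sort_values("shock_index")
        shocks = []
        for _, r in grp.iterrows():
            shocks.append(ShockRecord(str(pid), int(r["shock_index"]),
                                      float(r["amsa_mvhz"]), int(r["outcome"])))
            if have_episodes:
                episodes.append(read_episode_csv(
                    path.parent / r["episode_file"], patient_id=str(pid),
                    shock_index=int(r["shock_index"]),
                ))
        sequences.append(PatientSequence(str(pid), shocks))
    return SyntheticCohort(sequences, episodes if have_episodes else None,
                           config if config is not None else GeneratorConfig())


def read_episode_csv(path, patient_id: str = "", shock_index: int = 1
                     ) -> EcgEpisode:
    """Read one episode CSV (``# fs_hz=<rate>`` header + one mV column)."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs_hz="):
            raise SchemaError(f"{path}: expected '# fs_hz=' header, got {header!r}")
        fs = float(header.split("=", 1)[1])
        samples = np.loadtxt(fh, ndmin=1)
    return EcgEpisode(samples, fs, patient_id=patient_id, shock_index=shock_index)


def write_result(result: ExperimentResult, out_dir) -> Path:
    """Write an ExperimentResult as JSON plus per-stratum CSV tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "experiment_result.json"
    with open(json_path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    for stratum, per_method in result.reports.items():
        for method in per_method:
            result.table(stratum, method).to_csv(
                out_dir / f"performance_{stratum}_{method}.csv"
            )
    return json_path


def read_result(path) -> ExperimentResult:
    with open(path) as fh:
        return ExperimentResult.from_dict(json.load(fh))
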