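"""End-to-end orchestration: simulate -> analyse -> group model -> report.

A run directory is produced in stages (each stage reads only the run
directory and the config):

``simulate``   task schedules, ground truth, per-subject behavior traces and
               ROI BOLD series (raw EMG is regenerated deterministically
               from (config, seed) by the ``emg`` stage instead of being
               stored: a full cohort's 2 kHz EMG is ~0.5 GB as text).
``behavior``   block RMSEs, condition test, improvement covariate.
``emg``        preprocessing, segmentation, per-repetition MDF/amplitude,
               normalization, contrasts, mean-MDF covariate.
``invert``     subject-level DCM posteriors.
``peb``        group design (measured covariates), PEB fit, greedy Bayesian
               model reduction, Bayesian model averaging.
``loocv``      leave-one-out predictive validity for designated connections.
``report``     summary tables (connectivity means + posterior probabilities;
               normalized EMG features) and the hashed manifest.

Every output file is hashed into ``manifest.json``; identical (config, seed)
produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import dcm_core as dcm
from . import emg as emg_mod
from . import loocv as loocv_mod
from . import peb as peb_mod
from . import synthetic_data as gen

STAGES = ("simulate", "behavior", "emg", "invert", "peb", "loocv", "report")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_subjects": 14,
    "n_sessions": 3,
    "stages": list(STAGES),
    "generator": {
        "obs_noise_sd": gen.DEFAULT_OBS_NOISE_SD,
        "between_subject_sd": gen.DEFAULT_BETWEEN_SUBJECT_SD,
        "line_hum_amp": 0.5,
        "emg_branch": True,
        "write_raw_emg": False,
    },
    "inversion": {
        "max_iter": 64,
        "staged": True,
        "method": "rk4",
    },
    "loocv": {
        # (covariate, connections): the report mirrors the published tests —
        # improvement from the motor self- and visuomotor modulations, mean
        # MDF from the cerebellar modulation by the motor cortex
        "targets": [["improved_rmse", ["b222"]],
                    ["improved_rmse", ["b232"]],
                    ["mean_mdf", ["b122"]]],
    },
    "emg": {"paired_tests": False},
}

#: citations for config defaults that mirror measured task constants
PROVENANCE = {
    "block_s": "task blocks of 21 s",
    "rest_s": "15 s rests between blocks",
    "blocks": "3 feedback + 3 no-feedback blocks per session, random order",
    "tr_s": "repetition time 1.91 s",
    "te_s": "echo time 31 ms",
    "behavior_fs": "target/feedback traces sampled at 30 Hz",
    "emg_fs": "8-channel surface EMG at 2000 Hz",
    "target": "25 px steps, jitter in [0, 2] px, range [200, 600] px",
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Defaults merged with a YAML/JSON file and keyword overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must hold a mapping")
        cfg = _merge(cfg, loaded)
    return _merge(cfg, overrides)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class Run:
    """A pipeline run bound to a directory and a resolved config."""

    def __init__(self, out_dir: str | Path, config: dict | None = None):
        self.dir = Path(out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        cfg_file = self.dir / "config.yaml"
        if config is None:
            if not cfg_file.exists():
                raise FileNotFoundError(f"no config at {cfg_file}")
            config = load_config(cfg_file)
        self.cfg = config
        cfg_file.write_text(yaml.safe_dump(self.cfg, sort_keys=True))

    # -- helpers ------------------------------------------------------------
    @property
    def seed(self) -> int:
        return int(self.cfg["seed"])

    def _schedules(self) -> list[gen.TaskSchedule]:
        return gen.generate_task_schedule(int(self.cfg["n_sessions"]),
                                          seed=self.seed)

    def _truth(self) -> gen.GroundTruthGroup:
        return gen.GroundTruthGroup.from_json(self.dir / "ground_truth.json")

    # -- stages -------------------------------------------------------------
    def simulate(self) -> None:
        cfg = self.cfg
        g = cfg["generator"]
        schedules = self._schedules()
        gen.write_schedules(schedules, self.dir / "schedules.tsv")
        truth = gen.make_ground_truth(
            n_subjects=int(cfg["n_subjects"]), seed=self.seed,
            between_subject_sd=float(g["between_subject_sd"]))
        truth.to_json(self.dir / "ground_truth.json")
        for i in range(truth.n_subjects):
            row = truth.covariates.iloc[i]
            traces = gen.generate_subject_behavior(
                schedules, rmse_tt=float(row["rmse_tt"]),
                rmse_ttnf=float(row["rmse_ttnf"]), seed=self.seed,
                subject_index=i)
            gen.write_behavior(traces, self.dir / "behavior" / f"sub{i:02d}.tsv")
            params = gen.sample_subject_params(truth, i)
            data = gen.simulate_subject_bold(
                params, schedules, obs_noise_sd=float(g["obs_noise_sd"]),
                seed=self.seed, subject_index=i)
            data.write(self.dir / "bold" / f"sub{i:02d}")
            if g.get("write_raw_emg") and g.get("emg_branch", True):
                for rec in gen.generate_subject_emg(
                        schedules, mdf_ratio=float(row["mean_mdf"]),
                        amp_ratio=gen.AMP_RATIO_MEAN, seed=self.seed,
                        subject_index=i,
                        line_hum_amp=float(g["line_hum_amp"])):
                    rec.write(self.dir / "emg_raw"
                              / f"sub{i:02d}_ses{rec.session_index}")

    def behavior(self) -> None:
        n = int(self.cfg["n_subjects"])
        traces = {i: gen.read_behavior(self.dir / "behavior" / f"sub{i:02d}.tsv")
                  for i in range(n)}
        summary = bhv.summarize_group(traces)
        _write_tsv(summary.table, self.dir / "behavior_summary.tsv")
        test = bhv.paired_condition_test(summary)
        (self.dir / "behavior_test.json").write_text(json.dumps(
            {"t": test.t, "p": test.p, "n": test.n,
             "degenerate": test.degenerate}, indent=1, sort_keys=True))
        _write_tsv(summary.covariates(), self.dir / "covariates_behavior.tsv")

    def emg(self) -> None:
        g = self.cfg["generator"]
        if not g.get("emg_branch", True):
            return
        schedules = self._schedules()
        truth = self._truth()
        feats = []
        raw_dir = self.dir / "emg_raw"
        for i in range(truth.n_subjects):
            row = truth.covariates.iloc[i]
            for s, sch in enumerate(schedules):
                raw = raw_dir / f"sub{i:02d}_ses{s}"
                if raw.with_suffix(".tsv").exists():
                    rec = gen.EmgRecording.read(raw)
                else:  # regenerate deterministically from (config, seed)
                    rec = gen.generate_subject_emg(
                        [sch], mdf_ratio=float(row["mean_mdf"]),
                        amp_ratio=gen.AMP_RATIO_MEAN, seed=self.seed,
                        subject_index=i,
                        line_hum_amp=float(g["line_hum_amp"]))[0]
                tgt = gen.generate_target_trace(sch, seed=self.seed + 7919 * i)
                clean = emg_mod.preprocess_emg(rec)
                bounds = emg_mod.segment_repetitions(clean, tgt)
                df = emg_mod.repetition_features(clean, bounds, subject=i)
                df["session"] = s
                feats.append(df)
        features = pd.concat(feats, ignore_index=True)
        normalized = emg_mod.normalize_by_ttnf(features)
        _write_tsv(normalized, self.dir / "emg_features.tsv")
        _write_tsv(emg_mod.condition_summary(normalized),
                   self.dir / "emg_tables.tsv")
        paired = bool(self.cfg["emg"].get("paired_tests", False))
        rows = []
        for feature in ("norm_mdf", "norm_amplitude"):
            c = emg_mod.condition_contrast(normalized, feature, paired=paired)
            t = pd.concat([c.per_muscle, c.mean_across], ignore_index=True)
            t["feature"] = feature
            t["corrected"] = c.corrected
            rows.append(t)
        _write_tsv(pd.concat(rows, ignore_index=True),
                   self.dir / "emg_contrasts.tsv")
        _write_tsv(emg_mod.mean_mdf_covariate(normalized),
                   self.dir / "covariates_emg.tsv")

    def invert(self) -> None:
        inv = self.cfg["inversion"]
        n = int(self.cfg["n_subjects"])
        for i in range(n):
            data = dcm.RoiTimeSeriesSet.read(self.dir / "bold" / f"sub{i:02d}")
            post = dcm.invert_subject(
                data, max_iter=int(inv["max_iter"]),
                staged=bool(inv["staged"]), method=inv["method"])
            post.write(self.dir / "posteriors" / f"sub{i:02d}")
            pred = pd.DataFrame(post.prediction, columns=list(dcm.REGIONS))
            _write_tsv(pred, self.dir / "posteriors" / f"sub{i:02d}_pred.tsv")

    def _covariate_table(self) -> pd.DataFrame:
        n = int(self.cfg["n_subjects"])
        cov = pd.DataFrame({"subject": np.arange(n)})
        b = self.dir / "covariates_behavior.tsv"
        if b.exists():
            cov = cov.merge(pd.read_csv(b, sep="\t")
                            [["subject", "improved_rmse"]], on="subject")
        e = self.dir / "covariates_emg.tsv"
        if e.exists():
            cov = cov.merge(pd.read_csv(e, sep="\t")
                            [["subject", "mean_mdf"]], on="subject")
        return cov

    def _subject_posteriors(self):
        n = int(self.cfg["n_subjects"])
        means, covs = [], []
        for i in range(n):
            post = dcm.SubjectPosterior.read(self.dir / "posteriors" / f"sub{i:02d}")
            m, S = post.marginal(list(dcm.PARAM_NAMES))
            means.append(m)
            covs.append(S)
        return means, covs

    def peb(self) -> None:
        cov = self._covariate_table()
        design = peb_mod.build_design(cov, [c for c in cov.columns
                                            if c != "subject"])
        _write_tsv(design, self.dir / "design.tsv")
        means, covs = self._subject_posteriors()
        model = peb_mod.fit_peb(means, covs, design)
        search = peb_mod.greedy_search(model)
        result = peb_mod.bma(model, search)
        _write_tsv(result.table, self.dir / "peb" / "bma.tsv")
        (self.dir / "peb" / "models.json").write_text(json.dumps({
            "free_energy": model.free_energy,
            "gamma": model.gamma,
            "pruned": [list(c) for c in search.pruned],
            "surviving": [list(c) for c in search.surviving],
            "models": result.model_ledger.assign(
                off=result.model_ledger["off"].map(list)).to_dict("records"),
        }, indent=1, sort_keys=True))
        _write_tsv(search.ledger, self.dir / "peb" / "search_ledger.tsv")

    def loocv(self) -> None:
        cov = self._covariate_table()
        means, covs = self._subject_posteriors()
        _, _, prior_var = dcm.default_priors(list(dcm.PARAM_NAMES))
        for covariate, conns in self.cfg["loocv"]["targets"]:
            if covariate not in cov.columns:
                continue
            rep = loocv_mod.loo_predict(
                means, covs, cov, conns, covariate,
                param_names=list(dcm.PARAM_NAMES), prior_var=prior_var)
            name = f"{covariate}_" + "_".join(conns)
            rep.write(self.dir / "loocv" / name)

    def report(self) -> None:
        missing = []
        rep = self.dir / "report"
        rep.mkdir(exist_ok=True)
        bma_path = self.dir / "peb" / "bma.tsv"
        if bma_path.exists():
            bma = pd.read_csv(bma_path, sep="\t")
            bma["display"] = np.where(
                bma["pruned"], "-",
                bma["mean"].map("{:.3f}".format)
                + " (" + bma["pp"].map("{:.2f}".format) + ")")
            table = bma.pivot(index="param", columns="column",
                              values="display")
            table = table.reindex(list(dcm.PARAM_NAMES))
            table.reset_index().to_csv(rep / "connectivity.tsv", sep="\t",
                                       index=False)
        else:
            missing.append("peb")
        emg_path = self.dir / "emg_tables.tsv"
        if emg_path.exists():
            t = pd.read_csv(emg_path, sep="\t")
            for feature, fname in (("norm_mdf", "mdf"),
                                   ("norm_amplitude", "amplitude")):
                wide = t.pivot(index="condition", columns="muscle",
                               values=[f"{feature}_mean", f"{feature}_std"])
                out = pd.DataFrame({
                    f"{cond} {stat}": wide[f"{feature}_{stat}"].loc[cond]
                    for cond in ("TTNF", "TT") for stat in ("mean", "std")
                }).T
                cols = [m for m in list(gen.MUSCLES) + ["Mean"]
                        if m in out.columns]
                out = out[cols].round(3)
                out.reset_index(names="row").to_csv(
                    rep / f"emg_{fname}.tsv", sep="\t", index=False,
                    float_format="%.3f")
        elif self.cfg["generator"].get("emg_branch", True):
            missing.append("emg")
        summary = {}
        for f in sorted((self.dir / "loocv").glob("*.json")) if (self.dir / "loocv").exists() else []:
            summary[f.stem] = json.loads(f.read_text())
        (rep / "loocv_summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        if missing:
            (rep / "MISSING").write_text("\n".join(missing))
        self._manifest()

    def _manifest(self) -> dict:
        files = {}
        for f in sorted(self.dir.rglob("*")):
            if f.is_file() and f.name != "manifest.json":
                files[str(f.relative_to(self.dir))] = hashlib.sha256(
                    f.read_bytes()).hexdigest()
        manifest = {"config_hash": _config_hash(self.cfg), "files": files,
                    "provenance": PROVENANCE}
        (self.dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        return manifest

    def run(self, stages: Sequence[str] | None = None) -> dict:
        stages = list(stages) if stages is not None else list(self.cfg["stages"])
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for stage in STAGES:
            if stage not in stages:
                continue
            try:
                getattr(self, stage)()
            except Exception as exc:   # preserve partial outputs
                self._manifest()
                raise StageError(stage, exc) from exc
        return self._manifest()


def run_pipeline(config: dict, out_dir: str | Path,
                 stages: Sequence[str] | None = None) -> dict:
    """Execute the pipeline into ``out_dir``; returns the manifest."""
    return Run(out_dir, config).run(stages)
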