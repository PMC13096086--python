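"""End-to-end orchestration of the analysis pipeline.

Stages run in dependency order (simulate -> prep -> spectra -> segment ->
sort -> backfit -> metrics -> stats -> classify); each stage reads its
upstream artifacts from the output directory, so any stage can be re-run
alone. A manifest records per-stage artifacts with checksums, seeds, and
timing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import backfit as bf
from . import classify as clf
from . import io as fio
from . import microstates as ms
from . import prep as pp
from . import spectral as sp
from . import stats as st
from . import synthetic as syn
from .core import BandDefinition, DEFAULT_BANDS

log = logging.getLogger("freqstate")

STAGES = ("simulate", "prep", "spectra", "segment", "sort", "backfit",
          "metrics", "stats", "classify")

_SCHEMA = {
    "seed": int,
    "out": str,
    "bands": dict,
    "cohort": dict,
    "microstate": dict,
    "backfit": dict,
    "stats": dict,
    "classification": dict,
}
_COHORT_KEYS = {"n_subjects", "conditions", "n_templates", "n_channels",
                "rate", "duration_s", "dwell_mean_ms", "dwell_shape",
                "carrier_bands", "snr", "between_subject_sd"}
_MICROSTATE_KEYS = {"k_range", "fixed_k", "restarts", "tol", "max_iter"}
_CLS_KEYS = {"model", "cv", "top_n", "paper_mode", "feature_bands"}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    for key in cfg:
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config key: {key}")
    for section, allowed in (("cohort", _COHORT_KEYS),
                             ("microstate", _MICROSTATE_KEYS),
                             ("classification", _CLS_KEYS)):
        for key in cfg.get(section, {}):
            if key not in allowed:
                raise ConfigError(f"unknown key {section}.{key}")
    cfg.setdefault("seed", 0)
    cfg.setdefault("bands", {k: list(v) for k, v in DEFAULT_BANDS.items()})
    cfg.setdefault("cohort", {})
    cfg.setdefault("microstate", {})
    cfg.setdefault("classification", {})
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _band_defs(cfg: dict) -> list[BandDefinition]:
    return [BandDefinition(name, float(lo), float(hi))
            for name, (lo, hi) in cfg["bands"].items()]


def _spec_from_config(cfg: dict) -> syn.SyntheticSpec:
    kw = dict(cfg.get("cohort", {}))
    if "conditions" in kw:
        kw["conditions"] = tuple(kw["conditions"])
    if "carrier_bands" in kw:
        kw["carrier_bands"] = {
            cond: [tuple(b) for b in bands]
            for cond, bands in kw["carrier_bands"].items()}
    return syn.SyntheticSpec(seed=cfg["seed"], **kw)


class PipelineRun:
    """Stateful runner; artifacts live under ``outdir``."""

    def __init__(self, cfg: dict, outdir):
        self.cfg = validate_config(cfg)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
            "seed": self.cfg["seed"],
            "stages": {},
        }

    # -- helpers -----------------------------------------------------------
    def _record_stage(self, name: str, files: list[Path], t0: float) -> None:
        self.manifest["stages"][name] = {
            "status": "complete",
            "elapsed_s": round(time.time() - t0, 3),
            "files": {str(f.relative_to(self.outdir)): _sha256(f)
                      for f in files},
        }
        log.info("stage=%s files=%d elapsed=%.2fs", name, len(files),
                 time.time() - t0)

    def _keys(self):
        spec = _spec_from_config(self.cfg)
        for si in range(spec.n_subjects):
            for cond in spec.conditions:
                yield f"S{si + 1:02d}", cond

    # -- stages ------------------------------------------------------------
    def simulate(self):
        t0 = time.time()
        spec = _spec_from_config(self.cfg)
        recordings, truths = syn.generate_cohort(spec)
        rec_dir = self.outdir / "recordings"
        truth_dir = self.outdir / "truth"
        rec_dir.mkdir(exist_ok=True)
        truth_dir.mkdir(exist_ok=True)
        files = []
        for (subject, cond), rec in recordings.items():
            base = rec_dir / f"{subject}_{cond}"
            fio.write_recording(rec, base)
            files += [base.with_suffix(".npz"), base.with_suffix(".json")]
            truth = truths[(subject, cond)]
            tpath = truth_dir / f"{subject}_{cond}.json"
            tpath.write_text(json.dumps({
                "dwell_mean_ms": truth.dwell_mean_ms.tolist(),
                "occurrence_per_s": truth.occurrence_per_s.tolist(),
                "coverage": truth.coverage.tolist(),
                "templates": truth.templates.tolist(),
            }))
            files.append(tpath)
        self._record_stage("simulate", files, t0)

    def prep(self):
        t0 = time.time()
        bands = _band_defs(self.cfg)
        files = []
        for subject, cond in self._keys():
            rec = fio.read_recording(self.outdir / "recordings" / f"{subject}_{cond}")
            rec = pp.average_reference(rec)
            for band in bands:
                out = pp.bandpass(rec, band)
                out = pp.average_reference(out)
                base = self.outdir / "prep" / band.name / f"{subject}_{cond}"
                base.parent.mkdir(parents=True, exist_ok=True)
                fio.write_recording(out, base)
                files += [base.with_suffix(".npz"), base.with_suffix(".json")]
        self._record_stage("prep", files, t0)

    def spectra(self):
        t0 = time.time()
        bands = _band_defs(self.cfg)
        tables = []
        for subject, cond in self._keys():
            rec = fio.read_recording(self.outdir / "recordings" / f"{subject}_{cond}")
            rec = pp.average_reference(rec)
            summary = sp.multitaper_psd(rec)
            tables.append(sp.band_power(summary, bands, subject=subject,
                                        condition=cond))
        table = pd.concat(tables, ignore_index=True)
        out = self.outdir / "band_power.csv"
        table.to_csv(out, index=False)
        files = [out]
        conds = set(table["condition"])
        if "wake" in conds and len(conds) > 1:
            norm = sp.normalize_to_baseline(table, "wake")
            nout = self.outdir / "band_power_wake_normalized.csv"
            norm.to_csv(nout, index=False)
            files.append(nout)
        self._record_stage("spectra", files, t0)

    def segment(self):
        t0 = time.time()
        mcfg = self.cfg["microstate"]
        fixed_k = int(mcfg.get("fixed_k", 7))
        restarts = int(mcfg.get("restarts", 20))
        tol = float(mcfg.get("tol", 1e-7))
        max_iter = int(mcfg.get("max_iter", 300))
        files = []
        for band_name in self.cfg["bands"]:
            for subject, cond in self._keys():
                rec = fio.read_recording(
                    self.outdir / "prep" / band_name / f"{subject}_{cond}")
                gfp = ms.compute_gfp(rec)
                peak_maps = rec.data[:, gfp.peak_indices].T
                model = ms.modified_kmeans(peak_maps, fixed_k,
                                           n_restarts=restarts, tol=tol,
                                           max_iter=max_iter,
                                           seed=self.cfg["seed"])
                model.band = band_name
                out = (self.outdir / "models" / "individual" / band_name /
                       f"{subject}_{cond}.json")
                out.parent.mkdir(parents=True, exist_ok=True)
                fio.write_model(model, out)
                files.append(out)
        self._record_stage("segment", files, t0)

    def sort(self):
        t0 = time.time()
        spec = _spec_from_config(self.cfg)
        layout = None
        files = []
        for band_name in self.cfg["bands"]:
            ind_dir = self.outdir / "models" / "individual" / band_name
            per_cond = {}
            models_by_key = {}
            for subject, cond in self._keys():
                model = fio.read_model(ind_dir / f"{subject}_{cond}.json")
                models_by_key[(subject, cond)] = model
                per_cond.setdefault(cond, []).append(model)
            if layout is None:
                rec = fio.read_recording(
                    self.outdir / "prep" / band_name /
                    f"S01_{spec.conditions[0]}")
                layout = rec.layout
            canon = bf.canonical_templates(layout)
            # provisional sort of individuals against canonical stand-ins so
            # class positions correspond before averaging
            for key, model in models_by_key.items():
                models_by_key[key], _ = bf.sort_by_template(model, canon)
            cond_models = {}
            for cond, _ in per_cond.items():
                sorted_ms = [models_by_key[(s, c)] for s, c in self._keys()
                             if c == cond]
                cond_models[cond] = bf.mean_maps(sorted_ms, level="condition")
            grand = bf.mean_maps(list(cond_models.values()), level="grand")
            grand, corr = bf.sort_by_template(grand, canon)
            grand.band = band_name
            gout = self.outdir / "models" / f"grand_{band_name}.json"
            fio.write_model(grand, gout)
            files.append(gout)
            for cond, cmodel in cond_models.items():
                cmodel, _ = bf.sort_to_model(cmodel, grand)
                cmodel.band = band_name
                cout = self.outdir / "models" / f"condition_{band_name}_{cond}.json"
                fio.write_model(cmodel, cout)
                files.append(cout)
        self._record_stage("sort", files, t0)

    def backfit(self):
        t0 = time.time()
        files = []
        for band_name in self.cfg["bands"]:
            grand = fio.read_model(self.outdir / "models" / f"grand_{band_name}.json")
            for subject, cond in self._keys():
                rec = fio.read_recording(
                    self.outdir / "prep" / band_name / f"{subject}_{cond}")
                seq = bf.backfit(rec, grand)
                rows = [{"class": (seq.class_names[c] if seq.class_names else c),
                         "start_s": s / seq.rate, "end_s": e / seq.rate,
                         "truncated": trunc}
                        for c, s, e, trunc in seq.segments]
                out = (self.outdir / "labels" / band_name /
                       f"{subject}_{cond}.csv")
                out.parent.mkdir(parents=True, exist_ok=True)
                pd.DataFrame(rows, columns=["class", "start_s", "end_s",
                                            "truncated"]).to_csv(out, index=False)
                files.append(out)
        self._record_stage("backfit", files, t0)

    def metrics(self):
        t0 = time.time()
        frames = []
        for band_name in self.cfg["bands"]:
            grand = fio.read_model(self.outdir / "models" / f"grand_{band_name}.json")
            for subject, cond in self._keys():
                rec = fio.read_recording(
                    self.outdir / "prep" / band_name / f"{subject}_{cond}")
                seq = bf.backfit(rec, grand)
                m = bf.metrics_with_iev(rec, grand, seq)
                frames.append(m.to_frame(subject=subject, condition=cond,
                                         band=band_name))
        table = pd.concat(frames, ignore_index=True)
        out = self.outdir / "metrics.csv"
        table.to_csv(out, index=False)
        self._record_stage("metrics", [out], t0)

    def stats(self):
        t0 = time.time()
        table = pd.read_csv(self.outdir / "metrics.csv")
        spec = _spec_from_config(self.cfg)
        conds = list(spec.conditions)
        rows = []
        if len(conds) >= 2:
            for (band, cls), grp in table.groupby(["band", "class"]):
                for metric in ("duration_ms", "occurrence", "coverage"):
                    wide = grp.pivot(index="subject", columns="condition",
                                     values=metric)[conds]
                    if wide.isna().any().any() or len(wide) < 3:
                        continue
                    res = st.rm_anova_with_pairwise(wide.to_numpy(), conds)
                    for pair, p_corr in res.pairwise.items():
                        rows.append({"metric": metric, "band": band,
                                     "class": cls, "F": res.F,
                                     "df1": res.df[0], "df2": res.df[1],
                                     "p": res.p, "pair": f"{pair[0]}-{pair[1]}",
                                     "p_corr": p_corr})
        out = self.outdir / "stats.csv"
        pd.DataFrame(rows, columns=["metric", "band", "class", "F", "df1",
                                    "df2", "p", "pair", "p_corr"]).to_csv(
            out, index=False)
        self._record_stage("stats", [out], t0)

    def classify(self):
        t0 = time.time()
        ccfg = self.cfg["classification"]
        table = pd.read_csv(self.outdir / "metrics.csv")
        bands = ccfg.get("feature_bands", list(self.cfg["bands"]))
        features = clf.build_features(table, bands)
        labels = [cond for _, cond in features.index]
        n_feats = features.shape[1]
        top_n = min(int(ccfg.get("top_n", 10)), n_feats)
        report = clf.evaluate(
            features, labels,
            model=ccfg.get("model", "linear_svm"),
            cv=ccfg.get("cv", "loocv"),
            nested_selection=not bool(ccfg.get("paper_mode", False)),
            top_n=top_n, seed=self.cfg["seed"])
        out = self.outdir / "classification_report.json"
        out.write_text(json.dumps(report.to_dict(), indent=2))
        pout = self.outdir / "classification_predictions.csv"
        report.predictions.to_csv(pout, index=False)
        self._record_stage("classify", [out, pout], t0)

    # -- driver ------------------------------------------------------------
    def run_all(self) -> dict:
        for stage in STAGES:
            try:
                getattr(self, stage)()
            except Exception as exc:
                self.manifest["stages"][stage] = {"status": "failed",
                                                  "error": str(exc)}
                log.error("stage=%s failed: %s", stage, exc)
                break
        mpath = self.outdir / "manifest.json"
        mpath.write_text(json.dumps(self.manifest, indent=2))
        return self.manifest


def run_all(cfg: dict, outdir) -> dict:
    return PipelineRun(cfg, outdir).run_all()
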