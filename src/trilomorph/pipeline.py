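"""End-to-end pipeline: scan/simulate -> profiles -> landmarks -> statistics.

One :class:`RunConfig` drives the whole run; every stage writes its artifacts
into the output directory and the run closes with a ``manifest.json``
recording inputs, defaults, seed and a checksum per artifact, so two runs
with the same config and seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InsufficientReliefError, PipelineError, TrilomorphError
from .landmarking import (LandmarkConfiguration, configs_to_csv,
                          detect_landmarks, read_tps, write_tps)
from .morpho_stats import (bonferroni, cva_analysis, goodall_f,
                           procrustes_anova, shape_pca)
from .procrustes import gpa
from .profile_tools import Profile, relief_by_group
from .simulate import simulate_study

log = logging.getLogger("trilomorph")


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run.

    ``profiles_dir`` may point at a directory of per-specimen profile CSVs
    (columns s_mm,z_mm) plus a ``labels.csv`` (specimen,population); with
    ``simulate=True`` the study generator provides them instead. Landmarks
    come from automatic detection unless ``tps_path`` supplies a manually
    digitized TPS file, which takes precedence.
    """

    out_dir: str = "results"
    seed: int = 0
    simulate: bool = True
    profiles_dir: str | None = None
    tps_path: str | None = None
    n_samples: int = 1500
    smoothing_window: int | None = None
    min_prominence: float = 0.003
    run_statistics: bool = True
    n_permutations: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise TrilomorphError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.simulate:
            if self.profiles_dir is None:
                raise TrilomorphError("either simulate=true or profiles_dir is required")
            if not Path(self.profiles_dir).is_dir():
                raise TrilomorphError(f"profiles_dir {self.profiles_dir!r} not found")
        if self.tps_path is not None and not Path(self.tps_path).is_file():
            raise TrilomorphError(f"tps_path {self.tps_path!r} not found")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_profiles(profiles_dir: str) -> tuple[list[Profile], list[str]]:
    d = Path(profiles_dir)
    lab_file = d / "labels.csv"
    if not lab_file.is_file():
        raise PipelineError("load", f"no labels.csv in {d}")
    labels_df = pd.read_csv(lab_file)
    profiles, labels = [], []
    for _, row in labels_df.iterrows():
        f = d / f"{row['specimen']}.csv"
        if not f.is_file():
            raise PipelineError("load", "profile CSV missing", str(row["specimen"]))
        with open(f) as fh:
            profiles.append(Profile.from_csv(fh, specimen_id=str(row["specimen"])))
        labels.append(str(row["population"]))
    return profiles, labels


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the results manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": asdict(config), "stages": {}, "artifacts": {}}
    written: list[Path] = []

    def _stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"started": True}
        return time.perf_counter()

    def _done(name, t0, **info):
        manifest["stages"][name].update(elapsed_s=round(time.perf_counter() - t0, 3), **info)

    # ---- profiles
    t0 = _stage("profiles")
    if config.simulate:
        bundle = simulate_study(seed=config.seed, n_samples=config.n_samples)
        profiles, labels = bundle.profiles, bundle.labels
        written += bundle.write(out / "profiles")
    else:
        profiles, labels = _load_profiles(config.profiles_dir)
    _done("profiles", t0, n_specimens=len(profiles))

    # ---- relief table
    t0 = _stage("relief")
    relief = relief_by_group(profiles, labels)
    f = out / "relief_by_specimen.csv"
    relief.per_specimen.to_csv(f, index=False)
    written.append(f)
    f = out / "relief_by_population.csv"
    relief.per_population.to_csv(f)
    written.append(f)
    _done("relief", t0)

    # ---- landmarks
    t0 = _stage("landmarks")
    configs: list[LandmarkConfiguration] = []
    effaced: list[str] = []
    if config.tps_path:  # manual landmarks take precedence
        configs = read_tps(Path(config.tps_path).read_text())
    else:
        for prof, lab in zip(profiles, labels):
            try:
                lm = detect_landmarks(prof, smoothing_window=config.smoothing_window,
                                      min_prominence=config.min_prominence)
            except InsufficientReliefError as exc:
                log.info("specimen %s effaced: %s", prof.specimen_id, exc)
                effaced.append(prof.specimen_id)
                continue
            except TrilomorphError as exc:
                raise PipelineError("landmarks", str(exc), prof.specimen_id) from exc
            lm.population = lab
            configs.append(lm)
    f = out / "landmarks.tps"
    with open(f, "w") as fh:
        write_tps(configs, fh)
    written.append(f)
    f = out / "landmarks.csv"
    with open(f, "w") as fh:
        configs_to_csv(configs, fh)
    written.append(f)
    _done("landmarks", t0, n_landmarked=len(configs), effaced=effaced)

    # ---- statistics
    if config.run_statistics:
        t0 = _stage("statistics")
        if len(configs) < 3:
            raise PipelineError("statistics", "fewer than 3 landmarked specimens")
        lm_labels = [c.population for c in configs]
        fit = gpa(configs)
        pca = shape_pca(fit)
        pd.DataFrame(pca.scores,
                     columns=[f"PC{i + 1}" for i in range(pca.scores.shape[1])],
                     index=[c.specimen_id for c in configs]).to_csv(out / "pca_scores.csv")
        pd.DataFrame({"eigenvalue": pca.eigenvalues,
                      "pct_variance": pca.pct_variance}).to_csv(out / "pca_variance.csv",
                                                               index=False)
        written += [out / "pca_scores.csv", out / "pca_variance.csv"]

        size_r, shape_r = procrustes_anova(fit, lm_labels,
                                           n_resamples=config.n_permutations,
                                           seed=config.seed)
        groups = list(dict.fromkeys(lm_labels))
        rows = [{"test": "centroid_size_anova", "F": size_r.F, "df_num": size_r.df_num,
                 "df_den": size_r.df_den, "p_param": size_r.p_param,
                 "p_resample": size_r.p_resample},
                {"test": "shape_procrustes_anova", "F": shape_r.F,
                 "df_num": shape_r.df_num, "df_den": shape_r.df_den,
                 "p_param": shape_r.p_param, "p_resample": shape_r.p_resample}]
        n_pairs = len(groups) * (len(groups) - 1) // 2
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                r = goodall_f(fit, a, b, n_resamples=config.n_permutations,
                              seed=config.seed, labels=lm_labels)
                rows.append({"test": f"goodall_{a}_vs_{b}", "F": r.F,
                             "df_num": r.df_num, "df_den": r.df_den,
                             "p_param": r.p_param, "p_resample": r.p_resample,
                             "p_bonferroni": bonferroni(r.p_resample, n_pairs)})
        pd.DataFrame(rows).to_csv(out / "goodall_tests.csv", index=False)
        written.append(out / "goodall_tests.csv")

        cva = cva_analysis(fit, lm_labels, n_permutations=config.n_permutations,
                           seed=config.seed)
        pd.DataFrame(cva.cv_scores,
                     columns=[f"CV{i + 1}" for i in range(cva.cv_scores.shape[1])],
                     index=[c.specimen_id for c in configs]).to_csv(out / "cv_scores.csv")
        for name, mat in (("mahalanobis", cva.mahalanobis),
                          ("mahalanobis_p", cva.p_mahalanobis),
                          ("procrustes_dist", cva.procrustes_dist),
                          ("procrustes_dist_p", cva.p_procrustes)):
            pd.DataFrame(mat, index=cva.groups, columns=cva.groups).to_csv(
                out / f"cva_{name}.csv")
            written.append(out / f"cva_{name}.csv")
        written.append(out / "cv_scores.csv")
        _done("statistics", t0, groups=groups)

    for f in sorted(set(written)):
        manifest["artifacts"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
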