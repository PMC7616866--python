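"""End-to-end orchestration: derivation and external-validation runs.

A derivation run executes simulate -> preprocess -> train -> embed ->
cluster -> survival -> PheWAS -> saliency from one config, persisting every
stage artifact and a manifest.  An external-validation run takes frozen
model weights and centroids and produces assignment plus survival outputs
only — nothing is ever refitted.

Every stage derives its seed deterministically from the global seed and the
stage name, so stages can be rerun independently and whole runs are
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .embedding import ECGEmbedder
from .explain import average_saliency
from .phenogroup import Phenogrouper
from .phewas import biobank_phewas, disease_phewas, encode_group
from .preprocess import ECGPreprocessor
from .survival import adjusted_phenogroup_hr, km_estimate, logrank_test
from .synthetic import Cohort, CohortConfig, simulate_cohort

logger = logging.getLogger("ecgpheno.pipeline")

__all__ = ["PipelineConfig", "RunManifest", "stage_seed",
           "run_derivation", "run_external_validation"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """One config drives a whole run; every stage seed derives from ``seed``."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    arch: str = "sharp"
    epochs: int = 4
    batch_size: int = 32
    learning_rate: float = 2e-3
    k: int = 3
    k_range: tuple[int, int] = (2, 9)
    covariate_spec: tuple[str, ...] = ("age", "sex")
    phewas_alpha: float = 0.05
    saliency_n: int = 1000
    out_dir: str = "ecgpheno_run"
    seed: int = 0

    def _to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = cio.cohort_config_to_dict(self.cohort)
        d["k_range"] = list(d["k_range"])
        d["covariate_spec"] = list(d["covariate_spec"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self._to_dict(), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            d = yaml.safe_load(f)
        d["cohort"] = cio.cohort_config_from_dict(d["cohort"])
        d["k_range"] = tuple(d["k_range"])
        d["covariate_spec"] = tuple(d["covariate_spec"])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self._to_dict()
        d.pop("out_dir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True,
                       default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    artifacts: dict[str, str]
    timings: dict[str, float]
    counts: dict[str, int]
    results: dict[str, float]

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, sort_keys=True)


class PipelineStageError(RuntimeError):
    """Raised with the failing stage's name; prior artifacts stay on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


class _Stages:
    """Tiny helper running named stages with timing + logging."""

    def __init__(self):
        self.timings: dict[str, float] = {}

    def run(self, name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s ...", name)
        try:
            out = fn()
        except Exception as exc:  # keep prior artifacts, name the stage
            raise PipelineStageError(name, exc) from exc
        self.timings[name] = time.perf_counter() - t0
        logger.info("stage %s done in %.1fs", name, self.timings[name])
        return out


def _phenogroup_survival(cohort: Cohort, assignment: pd.DataFrame,
                         covariate_spec, out: Path, prefix: str = ""):
    """KM per phenogroup, log-rank, adjusted Cox; returns summary numbers."""
    df = cohort.survival.merge(assignment[["subject_id", "phenogroup"]],
                               on="subject_id")
    km_rows = []
    for letter, sub in df.groupby("phenogroup"):
        curve = km_estimate(sub["time_years"], sub["event"])
        for t, s, v in zip(curve.times, curve.survival, curve.variance):
            km_rows.append({"phenogroup": letter, "time": t,
                            "survival": s, "variance": v})
    pd.DataFrame(km_rows).to_csv(out / f"{prefix}km_curves.csv", index=False)
    lr = logrank_test(df["time_years"], df["event"], df["phenogroup"])
    results = {f"{prefix}logrank_chi2": lr.statistic,
               f"{prefix}logrank_p": lr.p_value}
    fit = adjusted_phenogroup_hr(cohort.survival, assignment,
                                 list(covariate_spec))
    fit.summary().to_csv(out / f"{prefix}cox_adjusted.csv")
    for name, hr in zip(fit.names, fit.hr):
        if name.startswith("phenogroup_"):
            results[f"{prefix}hr_{name.removeprefix('phenogroup_')}"] = float(hr)
    return results


def run_derivation(config: PipelineConfig) -> RunManifest:
    """Full derivation run; artifacts and a manifest land in ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    st = _Stages()
    artifacts: dict[str, str] = {}
    counts: dict[str, int] = {}
    results: dict[str, float] = {}

    cohort_cfg = dataclasses.replace(config.cohort,
                                     seed=stage_seed(config.seed, "simulate"))
    cohort = st.run("simulate", lambda: simulate_cohort(cohort_cfg))
    counts["subjects"] = cohort.config.n
    st.run("save_cohort", lambda: cio.save_cohort(cohort, out / "cohort"))
    artifacts["cohort"] = str(out / "cohort")

    pre = ECGPreprocessor()
    X = st.run("preprocess", lambda: pre.transform(cohort.records))

    emb = ECGEmbedder(arch=config.arch, epochs=config.epochs,
                      batch_size=config.batch_size,
                      learning_rate=config.learning_rate,
                      random_state=stage_seed(config.seed, "train"))
    y = cohort.labels.drop(columns="subject_id").to_numpy()
    st.run("train", lambda: emb.fit(X, y))
    emb.save(out / "model.npz")
    artifacts["model"] = str(out / "model.npz")
    for name, auc in emb.auroc_.items():
        results[f"auroc_{name}"] = auc

    E = st.run("embed", lambda: emb.transform(X))
    np.save(out / "embeddings.npy", E)
    artifacts["embeddings"] = str(out / "embeddings.npy")
    counts["embedding_dim"] = E.shape[1]

    def _cluster():
        pg = Phenogrouper(k=config.k, k_range=range(config.k_range[0],
                                                    config.k_range[1] + 1),
                          random_state=stage_seed(config.seed, "cluster"))
        pg.fit(E)
        rates = {}
        ev = cohort.survival["event"].to_numpy()
        for c in range(pg.k_):
            members = pg.labels_ == c
            rates[c] = float(ev[members].mean()) if members.any() else 0.0
        pg.map_letters_by_mortality(rates)
        return pg

    pg = st.run("cluster", _cluster)
    pg.save(out / "phenogroups.npz")
    artifacts["phenogroups"] = str(out / "phenogroups.npz")
    assignment = pg.assign(E, cohort.subject_ids)
    assignment.to_csv(out / "assignments.csv", index=False)
    artifacts["assignments"] = str(out / "assignments.csv")
    for letter, cnt in assignment["phenogroup"].value_counts().items():
        counts[f"phenogroup_{letter}"] = int(cnt)

    results.update(st.run("survival", lambda: _phenogroup_survival(
        cohort, assignment, config.covariate_spec, out)))
    artifacts["km_curves"] = str(out / "km_curves.csv")
    artifacts["cox_adjusted"] = str(out / "cox_adjusted.csv")

    def _phewas():
        ab = assignment[assignment["phenogroup"].isin(["A", "B"])]
        counts["phewas_subjects"] = len(ab)
        g01 = encode_group(ab["phenogroup"].to_numpy())
        merged = ab[["subject_id"]].merge(cohort.phenotypes, on="subject_id")
        # tiny cohorts can leave every disease column single-class
        dis_cols = [c for c in cohort.phenotypes.columns
                    if c.endswith("_incident")
                    and merged[c].nunique() == 2]
        if dis_cols:
            dis = disease_phewas(g01, merged[["subject_id"] + dis_cols],
                                 alpha=config.phewas_alpha)
        else:
            logger.info("no testable disease columns; skipping disease scan")
            dis = pd.DataFrame(columns=["phenotype", "approach", "effect",
                                        "se", "p", "n", "testable",
                                        "significant"])
        bio_cols = [c for c in cohort.phenotypes.columns
                    if c != "subject_id" and not c.endswith("_incident")]
        bio = biobank_phewas(g01, merged[["subject_id"] + bio_cols],
                             alpha=config.phewas_alpha)
        dis.to_csv(out / "phewas_disease.csv", index=False)
        bio.to_csv(out / "phewas_biobank.csv", index=False)
        results["phewas_significant"] = float(
            dis["significant"].sum() + bio["significant"].sum())
        return dis, bio

    st.run("phewas", _phewas)
    artifacts["phewas_disease"] = str(out / "phewas_disease.csv")
    artifacts["phewas_biobank"] = str(out / "phewas_biobank.csv")

    def _saliency():
        inv = {v: k for k, v in pg.letter_map_.items()}
        maps = {}
        for letter, cidx in inv.items():
            if (assignment["cluster"] == cidx).any():
                sal = average_saliency(
                    emb.net_, X, pg.cluster_centers_, cidx,
                    n=config.saliency_n, embeddings=E,
                    assignments=assignment["cluster"].to_numpy())
                maps[letter] = sal
        arrays = {f"saliency_{letter}": s.values for letter, s in maps.items()}
        arrays.update({f"n_{letter}": np.array(s.n_averaged)
                       for letter, s in maps.items()})
        np.savez(out / "saliency.npz", **arrays)
        return maps

    st.run("saliency", _saliency)
    artifacts["saliency"] = str(out / "saliency.npz")

    manifest = RunManifest(config_hash=config.config_hash(),
                           artifacts=artifacts, timings=st.timings,
                           counts=counts, results=results)
    manifest.save(out / "manifest.json")
    config.to_yaml(out / "pipeline_config.yaml")
    return manifest


def run_external_validation(config: PipelineConfig,
                            phenogrouper: Phenogrouper,
                            embedder: ECGEmbedder,
                            external_cohort: Cohort | None = None) -> RunManifest:
    """Fixed-centroid transfer: assignment + survival only, no refitting.

    Weights and centroids are hashed before and after; any mutation aborts
    the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    st = _Stages()

    def _hash_state():
        h = hashlib.sha256()
        for k in sorted(embedder.net_.state_dict()):
            h.update(embedder.net_.state_dict()[k].tobytes())
        h.update(np.ascontiguousarray(phenogrouper.cluster_centers_).tobytes())
        return h.hexdigest()

    frozen = _hash_state()
    if external_cohort is None:
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=stage_seed(config.seed, "external_simulate"))
        external_cohort = st.run("simulate",
                                 lambda: simulate_cohort(cohort_cfg))
    cohort = external_cohort

    X = st.run("preprocess", lambda: ECGPreprocessor().transform(cohort.records))
    E = st.run("embed", lambda: embedder.transform(X))
    assignment = st.run("assign",
                        lambda: phenogrouper.assign(E, cohort.subject_ids))
    assignment.to_csv(out / "external_assignments.csv", index=False)
    results = st.run("survival", lambda: _phenogroup_survival(
        cohort, assignment, config.covariate_spec, out, prefix="external_"))
    if _hash_state() != frozen:
        raise PipelineStageError(
            "freeze_check", RuntimeError("model or centroids were mutated"))
    counts = {f"phenogroup_{letter}": int(cnt) for letter, cnt
              in assignment["phenogroup"].value_counts().items()}
    counts["subjects"] = len(assignment)
    manifest = RunManifest(config_hash=config.config_hash(),
                           artifacts={"assignments":
                                      str(out / "external_assignments.csv")},
                           timings=st.timings, counts=counts, results=results)
    manifest.save(out / "external_manifest.json")
    return manifest
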