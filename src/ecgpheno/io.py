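"""Cohort persistence: HDF5 signal container, CSV tables, YAML config.

The signal container mirrors the layout of public ECG dumps this pipeline
is designed around: one ``signals`` dataset of shape (n, 12, L) with
``fs`` and ``lead_names`` attributes, plus a ``subject_id`` dataset.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synthetic import Cohort, CohortConfig, ECGRecord, LEAD_NAMES

__all__ = ["save_signals", "load_signals", "save_cohort", "load_cohort",
           "save_config", "load_config"]


def save_signals(path, signals: np.ndarray, fs: float,
                 subject_ids: list[str] | None = None) -> None:
    signals = np.asarray(signals)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("signals", data=signals.astype(np.float32))
        ds.attrs["fs"] = float(fs)
        ds.attrs["lead_names"] = [n.encode() for n in LEAD_NAMES]
        if subject_ids is not None:
            f.create_dataset("subject_id",
                             data=np.array(subject_ids, dtype="S16"))


def load_signals(path) -> tuple[np.ndarray, float, list[str]]:
    with h5py.File(path, "r") as f:
        ds = f["signals"]
        signals = ds[...]
        fs = float(ds.attrs["fs"])
        if "subject_id" in f:
            ids = [s.decode() for s in f["subject_id"][...]]
        else:
            ids = [f"S{i}" for i in range(signals.shape[0])]
    return signals, fs, ids


def cohort_config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["group_proportions"] = list(d["group_proportions"])
    d["group_morphology"] = {k: list(v)
                             for k, v in d["group_morphology"].items()}
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    d["group_proportions"] = tuple(d["group_proportions"])
    d["group_morphology"] = {k: tuple(v)
                             for k, v in d["group_morphology"].items()}
    return CohortConfig(**d)


def save_config(path, config: CohortConfig) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cohort_config_to_dict(config), f, sort_keys=True)


def load_config(path) -> CohortConfig:
    with open(path) as f:
        return cohort_config_from_dict(yaml.safe_load(f))


def save_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "signals": out / "signals.h5",
        "labels": out / "labels.csv",
        "groups": out / "groups.csv",
        "survival": out / "survival.csv",
        "phenotypes": out / "phenotypes.csv",
        "config": out / "config.yaml",
    }
    save_signals(paths["signals"], cohort.signals_array(),
                 cohort.config.fs, cohort.subject_ids)
    cohort.labels.to_csv(paths["labels"], index=False)
    cohort.groups.to_csv(paths["groups"], index=False)
    cohort.survival.to_csv(paths["survival"], index=False)
    cohort.phenotypes.to_csv(paths["phenotypes"], index=False)
    save_config(paths["config"], cohort.config)
    return paths


def load_cohort(in_dir) -> Cohort:
    """Rebuild a cohort bundle from disk (per-record metadata is not kept)."""
    d = Path(in_dir)
    signals, fs, ids = load_signals(d / "signals.h5")
    config = load_config(d / "config.yaml")
    records = [
        ECGRecord(signal=signals[i].astype(float), fs=fs,
                  duration=signals.shape[2] / fs, subject_id=ids[i])
        for i in range(signals.shape[0])
    ]
    return Cohort(
        records=records,
        labels=pd.read_csv(d / "labels.csv"),
        groups=pd.read_csv(d / "groups.csv"),
        survival=pd.read_csv(d / "survival.csv"),
        phenotypes=pd.read_csv(d / "phenotypes.csv"),
        config=config,
    )
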