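"""Scenario harness: per-species, global, and cross-species transfer runs.

Three evaluation scenarios, mirroring how species coverage of the training
set affects counting accuracy:

* ``per_species`` — one model per species, trained and tested on the same
  single species (held-out specimens);
* ``global`` — one model for all species;
* ``transfer`` — trained on some species, tested on a species absent from
  training (train/test species sets must be disjoint).

"Training" for the deterministic baseline backend means fitting its colour
palette on the training split only, so all three scenarios exercise the
same train/test discipline a CNN backend would, at CPU speed.  Any backend
honouring the detector contract can be substituted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .annotations import ORGAN_ORDER, CountVector
from .detection import BaselineDetector, count_detections, filter_detections, fit_palette
from .metrics import (
    error_records,
    letter_values,
    mae,
    presence_dominance,
    r_squared_report,
)
from .synthetic_data import GroundTruth

__all__ = ["ScenarioConfig", "ScenarioReport", "run_scenario"]


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: Literal["per_species", "global", "transfer"]
    train_species: tuple[str, ...]
    test_species: tuple[str, ...]
    seed: int = 0
    tau: float = 0.5
    test_fraction: float = 0.2
    backend: str = "baseline"

    def __post_init__(self) -> None:
        if self.scenario == "transfer":
            overlap = set(self.train_species) & set(self.test_species)
            if overlap:
                raise ValueError(
                    f"transfer scenario requires disjoint species sets; overlap: {sorted(overlap)}"
                )
        if self.scenario == "per_species":
            if not (len(self.train_species) == 1 and self.train_species == self.test_species):
                raise ValueError("per_species scenario needs train == test == one species")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ScenarioReport:
    config: ScenarioConfig
    n_train: int
    n_test: int
    mae: dict[str, float | None]
    r2: dict[str, float | None]
    error_letter_values: dict[str, tuple[float, float, float]]
    presence_dominance: dict
    true_counts: list[CountVector] = field(repr=False, default_factory=list)
    pred_counts: list[CountVector] = field(repr=False, default_factory=list)

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "config_digest": self.config.digest(),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "mae": self.mae,
            "r2": self.r2,
            "error_letter_values": {
                k: list(v) for k, v in self.error_letter_values.items()
            },
            "presence_dominance": self.presence_dominance,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def _split_ids(ids: list[str], fraction: float, seed: int) -> tuple[set[str], set[str]]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = max(int(np.floor(fraction * len(ids) + 0.5)), 1)
    test = {ids[i] for i in perm[:n_test]}
    return set(ids) - test, test


def run_scenario(
    cfg: ScenarioConfig,
    specimens: Sequence[tuple[np.ndarray, GroundTruth]],
    out_dir: str | Path | None = None,
) -> ScenarioReport:
    """Train the backend on the scenario's training split, predict counts on
    the test split, and evaluate.

    For ``per_species``/``global`` the test split is a seeded held-out
    fraction of the scenario's species; for ``transfer`` every specimen of
    the test species is evaluated and none enters training (asserted on
    specimen ids).  Deterministic: identical (config, data) produce an
    identical report.
    """
    by_species: dict[str, list[tuple[np.ndarray, GroundTruth]]] = {}
    for img, truth in specimens:
        by_species.setdefault(truth.species, []).append((img, truth))
    for sp in (*cfg.train_species, *cfg.test_species):
        if sp not in by_species:
            raise ValueError(f"species {sp!r} not present in the data")

    if cfg.scenario == "transfer":
        train = [pair for sp in cfg.train_species for pair in by_species[sp]]
        test = [pair for sp in cfg.test_species for pair in by_species[sp]]
    else:
        ids = sorted(
            pair[1].specimen_id
            for sp in set(cfg.train_species) | set(cfg.test_species)
            for pair in by_species[sp]
        )
        train_ids, test_ids = _split_ids(ids, cfg.test_fraction, cfg.seed)
        pool = [pair for sp in set(cfg.train_species) | set(cfg.test_species) for pair in by_species[sp]]
        train = [p for p in pool if p[1].specimen_id in train_ids]
        test = [p for p in pool if p[1].specimen_id in test_ids]

    train_ids = {t.specimen_id for _, t in train}
    test_ids = {t.specimen_id for _, t in test}
    assert not (train_ids & test_ids), "test specimens leaked into training"

    if cfg.backend != "baseline":
        raise ValueError(f"unknown backend {cfg.backend!r}")
    palette = fit_palette(
        [img for img, _ in train],
        [[(inst.organ, inst.mask) for inst in t.instances] for _, t in train],
        groups=[t.species for _, t in train],
    )
    detector = BaselineDetector(palette=palette)

    true_counts: list[CountVector] = []
    pred_counts: list[CountVector] = []
    for img, truth in sorted(test, key=lambda p: p[1].specimen_id):
        dets = filter_detections(detector.detect(img, truth.specimen_id), cfg.tau)
        pred_counts.append(count_detections(dets, specimen_id=truth.specimen_id))
        true_counts.append(truth.count_vector)

    records = error_records(true_counts, pred_counts)
    lv = letter_values([r.e for r in records], rule="tukey")
    report = ScenarioReport(
        config=cfg,
        n_train=len(train),
        n_test=len(test),
        mae=mae(records, grouping="all"),
        r2=r_squared_report(records),
        error_letter_values=lv.levels,
        presence_dominance=presence_dominance(true_counts, pred_counts).to_dict(),
        true_counts=true_counts,
        pred_counts=pred_counts,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"scenario-{cfg.scenario}-{cfg.digest()}.json").write_text(
            report.to_json()
        )
    return report
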