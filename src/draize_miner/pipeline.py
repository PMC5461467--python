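"""End-to-end orchestration: simulate/load -> classify -> reproducibility
-> endpoint tree -> hazard scan -> read-across, with table-shaped CSV
outputs and a run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ghs import RuleThresholds, aggregate_features, classify_rulebook
from .hazards import screen_single_hazards, screen_to_frame, triplet_search
from .io import filter_eye_studies, read_collection, write_collection
from .model import IrritationCategory, SubstanceRecord
from .normalize import SynonymTable, coverage, mode_category
from .reproducibility import agreement_summary, conditional_matrix
from .similarity import similarity_edges, sweep_to_frame, threshold_sweep
from .simulate import GeneratorConfig, generate
from .tree import confusion, fit_tree, render

__all__ = ["RunConfig", "run", "build_endpoint_dataset", "classify_records"]

log = logging.getLogger(__name__)

DEFAULT_SWEEP = [round(0.7 + 0.025 * i, 3) for i in range(12)]  # 0.7 .. 0.975


@dataclass
class RunConfig:
    """One orchestrated run: exactly one input source, stage toggles."""

    out_dir: Path
    input_path: Optional[Path] = None
    generator: Optional[GeneratorConfig] = None
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {
        "classify": True, "repro": True, "tree": True,
        "hazard_scan": True, "knn": True, "graph": True,
    })
    thresholds: RuleThresholds = field(default_factory=RuleThresholds)
    synonyms: Optional[SynonymTable] = None
    knn_thresholds: list[float] = field(default_factory=lambda: list(DEFAULT_SWEEP))
    graph_min_sim: float = 0.7
    min_pos: int = 100
    min_neg: int = 100
    triplet_top_k: int = 0  # 0 disables the exhaustive triplet search

    def validate(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path or generator required")

    @classmethod
    def from_file(cls, path: str | Path, out_dir: Optional[Path] = None
                  ) -> "RunConfig":
        """Load a run configuration from YAML or JSON.

        Recognized keys: ``input`` (path) or ``simulate`` (mapping with
        ``n`` and any GeneratorConfig scalar field), ``seed``,
        ``out_dir``, ``stages`` (mapping stage -> bool), ``knn_thresholds``,
        ``graph_min_sim``, ``min_pos``, ``min_neg``, ``triplet_top_k``.
        """
        import yaml

        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: run config must be a mapping")
        generator = None
        if "simulate" in doc:
            sim = dict(doc["simulate"])
            generator = GeneratorConfig(n_substances=int(sim.pop("n", 1000)))
            for key, val in sim.items():
                if not hasattr(generator, key):
                    raise ValueError(f"unknown generator field {key!r}")
                setattr(generator, key, val)
        config = cls(
            out_dir=Path(doc.get("out_dir", out_dir or "out")),
            input_path=Path(doc["input"]) if "input" in doc else None,
            generator=generator,
            seed=int(doc.get("seed", 0)),
        )
        for key in ("knn_thresholds", "graph_min_sim", "min_pos", "min_neg",
                    "triplet_top_k"):
            if key in doc:
                setattr(config, key, doc[key])
        for stage, enabled in doc.get("stages", {}).items():
            if stage not in config.stages:
                raise ValueError(f"unknown stage {stage!r}")
            config.stages[stage] = bool(enabled)
        if out_dir is not None:
            config.out_dir = Path(out_dir)
        return config


def classify_records(
    records: Sequence[SubstanceRecord],
    thresholds: Optional[RuleThresholds] = None,
    mode: str = "strict",
) -> pd.DataFrame:
    """Rulebook category per substance; one row per classifiable substance.

    ``strict`` keeps complete-case substances only; ``relaxed`` keeps any
    substance whose available features suffice for the rulebook (which
    needs all four endpoints, so relaxation here concerns reversibility
    defaults handled upstream).
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError("mode must be 'strict' or 'relaxed'")
    rows = []
    for rec in records:
        if not rec.studies:
            continue
        feats = aggregate_features(rec, thresholds)
        if mode == "strict" and not feats.complete:
            continue
        try:
            cat = classify_rulebook(feats, thresholds)
        except ValueError:
            continue
        rows.append({"id": rec.id, "rulebook_category": cat.value,
                     "dossier_category": rec.dossier_category.value})
    return pd.DataFrame(rows)


def build_endpoint_dataset(
    records: Sequence[SubstanceRecord],
    table: Optional[SynonymTable] = None,
    mode: str = "strict",
    drop_rare_below: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-substance endpoint feature table with mode-verdict labels.

    Substances without a mappable verdict are dropped; under ``strict``
    so are substances missing any endpoint feature.  ``drop_rare_below``
    removes classes with fewer instances than the threshold (useful for
    discarding a class too rare to learn, e.g. a handful of Type 2B).
    """
    feats_rows, labels = [], []
    for rec in records:
        if not rec.studies:
            continue
        label = mode_category(rec, table)
        if label is IrritationCategory.UNKNOWN:
            continue
        feats = aggregate_features(rec)
        if mode == "strict" and not feats.complete:
            continue
        feats_rows.append({
            "chemosis_mean": feats.chemosis_mean, "chemosis_max": feats.chemosis_max,
            "iris_mean": feats.iris_mean, "iris_max": feats.iris_max,
            "cornea_mean": feats.cornea_mean, "cornea_max": feats.cornea_max,
            "conjunctivae_mean": feats.conjunctivae_mean,
            "conjunctivae_max": feats.conjunctivae_max,
            "reversibility": (feats.reversibility.value
                              if feats.reversibility else None),
        })
        labels.append(label.value)
    frame = pd.DataFrame(feats_rows)
    if drop_rare_below > 0 and labels:
        counts = pd.Series(labels).value_counts()
        keep = [i for i, l in enumerate(labels)
                if counts[l] >= drop_rare_below]
        frame = frame.iloc[keep].reset_index(drop=True)
        labels = [labels[i] for i in keep]
    return frame, labels


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the run log (also written to disk).

    Stage failures abort the run with the partial outputs preserved and
    the failing stage recorded in the log.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"version": __version__, "seed": config.seed,
                     "numpy": np.__version__, "pandas": pd.__version__,
                     "stages": {}}

    def finish(status: str) -> dict:
        run_log["status"] = status
        with open(out / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(run_log, fh, indent=1)
        return run_log

    stage = "input"
    try:
        if config.generator is not None:
            gen = config.generator
            gen.seed = config.seed
            records, truth = generate(gen)
            write_collection(records, out / "collection.json")
            truth.to_csv(out / "truth.csv", index=False)
        else:
            records = read_collection(config.input_path)
        filtered = filter_eye_studies(records, require_reliability=True)
        run_log["n_substances"] = len(records)
        run_log["n_studies"] = int(sum(len(r.studies) for r in filtered))
        run_log["verdict_coverage"] = coverage(filtered, config.synonyms)
        run_log["stages"]["input"] = "ok"

        if config.stages.get("classify", True):
            stage = "classify"
            classify_records(filtered, config.thresholds).to_csv(
                out / "categories.csv", index=False)
            run_log["stages"][stage] = "ok"

        if config.stages.get("repro", True):
            stage = "repro"
            matrix = conditional_matrix(filtered, config.synonyms)
            matrix.to_frame().to_csv(out / "table3.csv")
            agreement_summary(matrix).to_csv(out / "repro_summary.csv")
            run_log["stages"][stage] = "ok"

        if config.stages.get("tree", True):
            stage = "tree"
            X, y = build_endpoint_dataset(filtered, config.synonyms,
                                          drop_rare_below=10)
            if len(X):
                tree = fit_tree(X, y, min_leaf=2)
                tree.to_json(out / "tree.json")
                (out / "tree.txt").write_text(render(tree) + "\n",
                                              encoding="utf-8")
                confusion(tree, X, y).to_frame().to_csv(out / "table4.csv")
            else:
                log.warning("tree stage: empty endpoint dataset")
            run_log["stages"][stage] = "ok"

        if config.stages.get("hazard_scan", True):
            stage = "hazard_scan"
            rows = screen_single_hazards(records, config.min_pos, config.min_neg)
            screen_to_frame(rows).to_csv(out / "table5.csv", index=False)
            if config.triplet_top_k > 0:
                codes = sorted({c for r in records for c in r.hazards
                                if c not in ("H318", "H319", "H320")})
                trips = triplet_search(records, codes,
                                       top_k=config.triplet_top_k)
                pd.DataFrame([
                    {"hazards": "+".join(t.codes), "rule": t.rule,
                     "bac": t.metrics.bac, "ppv": t.metrics.ppv,
                     "npv": t.metrics.npv, "n": t.n_substances}
                    for t in trips
                ]).to_csv(out / "triplets.csv", index=False)
            run_log["stages"][stage] = "ok"

        if config.stages.get("knn", True):
            stage = "knn"
            sweep = threshold_sweep(records, config.knn_thresholds)
            sweep_to_frame(sweep).to_csv(out / "table6.csv", index=False)
            run_log["stages"][stage] = "ok"

        if config.stages.get("graph", True):
            stage = "graph"
            edges, degrees = similarity_edges(records, config.graph_min_sim)
            pd.DataFrame(edges, columns=["id_a", "id_b", "similarity"]).to_csv(
                out / "edges.csv", index=False)
            pd.DataFrame(sorted(degrees.items()),
                         columns=["id", "degree"]).to_csv(
                out / "degrees.csv", index=False)
            run_log["stages"][stage] = "ok"
    except Exception as exc:
        run_log["stages"][stage] = f"failed: {exc}"
        finish("failed")
        raise
    return finish("ok")
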